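"""First-stage OLS, IV probit (two-stage and joint MLE), 2SLS and plain probit.

The causal model is a continuous endogenous exposure X (drinks per day)
instrumented by state-year excise taxes Z, and a binary outcome Y generated
by a latent-index probit.  Structurally::

    X  = pi'Z + gamma'C + eps
    Y  = 1[ beta*X + delta'C + u > 0 ],   (eps, u) ~ bivariate normal,
                                          corr(eps, u) = rho, Var(u) = 1.

``rho != 0`` is endogeneity: a plain probit of Y on (X, C) is then biased.
Two IV estimators are provided:

* :func:`fit_iv_probit_2sps` — two-stage predictor substitution: OLS first
  stage, then a probit of Y on (X_hat, C).  Its second-stage covariance
  ignores first-stage noise and is flagged as such; ratio inference goes
  through the bootstrap, which re-runs both stages per replicate.
* :func:`fit_iv_probit_mle` — the joint maximum-likelihood estimator with
  bivariate-normal errors (the standard software default), parameterised
  via atanh(rho) and log(sigma) for unconstrained optimisation.  It supplies
  the Wald test of exogeneity (H0: rho = 0).

:func:`fit_2sls_lpm` fits the two-stage least-squares linear probability
model used by the imperfect-instrument bounds, with heteroscedasticity-
robust standard errors (LPM errors are heteroscedastic by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import log_ndtr, ndtr, ndtri

from .cohort_io import AnalysisDataset
from .exceptions import EstimationError

__all__ = [
    "FirstStageFit",
    "IVProbitFit",
    "LinearIVFit",
    "TestResult",
    "fit_first_stage",
    "fit_probit",
    "fit_iv_probit_2sps",
    "fit_iv_probit_mle",
    "wald_exogeneity",
    "fit_2sls_lpm",
]

_Z95 = 1.959963984540054
_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _norm_logpdf(z: np.ndarray) -> np.ndarray:
    return -0.5 * z * z - _LOG_SQRT_2PI


# ---------------------------------------------------------------------------
# results


@dataclass
class TestResult:
    statistic: float
    df: int
    pvalue: float
    null: str

    def to_dict(self) -> dict:
        return {"statistic": float(self.statistic), "df": int(self.df),
                "pvalue": float(self.pvalue), "null": self.null}


@dataclass
class FirstStageFit:
    """OLS of exposure on instruments and covariates, with the partial F
    statistic for the excluded instruments."""

    coef: np.ndarray
    se: np.ndarray
    names: list[str]
    z_names: list[str]
    residuals: np.ndarray
    resid_sd: float
    partial_f: float
    df_num: int
    df_den: int
    n: int
    cov: np.ndarray

    @property
    def pi(self) -> dict:
        return {z: float(self.coef[self.names.index(z)]) for z in self.z_names}

    @property
    def pi_se(self) -> dict:
        return {z: float(self.se[self.names.index(z)]) for z in self.z_names}

    def conf_int(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return (float(self.coef[i] - _Z95 * self.se[i]),
                float(self.coef[i] + _Z95 * self.se[i]))

    def to_dict(self) -> dict:
        return {
            "partial_f": float(self.partial_f),
            "n": int(self.n),
            "resid_sd": float(self.resid_sd),
            "instruments": {
                z: {"coef": self.pi[z], "se": self.pi_se[z],
                    "ci": list(self.conf_int(z))}
                for z in self.z_names
            },
        }


@dataclass
class IVProbitFit:
    """Probit-type fit with structural coefficients (exposure first).

    ``tag`` is one of ``{"naive", "2sps", "mle"}``.  For the MLE the error
    correlation ``rho`` and first-stage scale ``sigma`` are estimated
    jointly; for 2SPS the stored covariance is the naive second-stage one
    (``cov_is_naive``) — ratio inference should bootstrap both stages.
    """

    tag: str
    coef: np.ndarray
    names: list[str]
    cov: np.ndarray
    n: int
    converged: bool
    loglik: float | None = None
    rho: float | None = None
    sigma: float | None = None
    atanh_rho: float | None = None
    se_atanh_rho: float | None = None
    first_stage: FirstStageFit | None = None
    cov_is_naive: bool = False
    boundary: bool = False
    n_iter: int = 0
    theta: np.ndarray | None = field(default=None, repr=False)

    @property
    def beta(self) -> float:
        return float(self.coef[0])

    @property
    def beta_se(self) -> float:
        return float(np.sqrt(self.cov[0, 0]))

    def beta_ci(self) -> tuple[float, float]:
        return (self.beta - _Z95 * self.beta_se, self.beta + _Z95 * self.beta_se)

    @property
    def intercept(self) -> float:
        return float(self.coef[self.names.index("const")])

    def structural_params(self) -> tuple[float, np.ndarray, list[str]]:
        """(beta, covariate coefficients incl. intercept, their names)."""
        return self.beta, self.coef[1:], self.names[1:]

    def to_dict(self) -> dict:
        d = {
            "tag": self.tag,
            "n": int(self.n),
            "beta": self.beta,
            "beta_se": self.beta_se,
            "beta_ci": list(self.beta_ci()),
            "coef": {k: float(v) for k, v in zip(self.names, self.coef)},
            "converged": bool(self.converged),
            "cov_is_naive": bool(self.cov_is_naive),
        }
        if self.rho is not None:
            d["rho"] = float(self.rho)
            d["sigma"] = float(self.sigma)
        if self.loglik is not None:
            d["loglik"] = float(self.loglik)
        if self.first_stage is not None:
            d["first_stage"] = self.first_stage.to_dict()
        return d


@dataclass
class LinearIVFit:
    """2SLS coefficient on the exposure with robust SE and 95% CI."""

    coef: float
    se: float
    instruments: list[str]
    n: int
    coef_all: np.ndarray = field(repr=False, default=None)
    names: list[str] = field(default_factory=list)

    def conf_int(self) -> tuple[float, float]:
        return (self.coef - _Z95 * self.se, self.coef + _Z95 * self.se)

    def to_dict(self) -> dict:
        lo, hi = self.conf_int()
        return {"coef": float(self.coef), "se": float(self.se),
                "ci": [float(lo), float(hi)],
                "instruments": list(self.instruments), "n": int(self.n)}


# ---------------------------------------------------------------------------
# linear algebra helpers


def _check_full_rank(G: np.ndarray, names: list[str]) -> None:
    """G is a (small) Gram matrix; raise naming suspect columns if singular."""
    rank = np.linalg.matrix_rank(G)
    if rank < G.shape[0]:
        # pivoted QR flags the columns that add no rank
        from scipy.linalg import qr
        _, _, piv = qr(G, pivoting=True)
        bad = [names[i] for i in piv[rank:]]
        raise EstimationError("design matrix is rank deficient; collinear column(s): "
                              + ", ".join(bad))


def _solve(A: np.ndarray, b: np.ndarray, context: str) -> np.ndarray:
    try:
        return np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"singular system in {context}") from exc


def _ols(y: np.ndarray, W: np.ndarray, names: list[str], check_rank: bool = True):
    G = W.T @ W
    if check_rank:
        _check_full_rank(G, names)
    coef = _solve(G, W.T @ y, "least squares")
    resid = y - W @ coef
    return coef, resid, G


def fit_first_stage(data: AnalysisDataset, cluster: str | None = None,
                    check_rank: bool = True) -> FirstStageFit:
    """OLS of exposure on [Z, C]; partial F for the excluded instruments.

    partial F = ((RSS_restricted - RSS_full)/k) / (RSS_full/(n - p_full)),
    the restricted model dropping all k instruments.
    """
    W = np.column_stack([data.Z, data.C])
    names = list(data.z_names) + list(data.c_names)
    n, p = W.shape
    k = data.Z.shape[1]
    coef, resid, G = _ols(data.x, W, names, check_rank=check_rank)
    rss_full = float(resid @ resid)

    coef_r, resid_r, _ = _ols(data.x, data.C, list(data.c_names),
                              check_rank=check_rank)
    rss_restr = float(resid_r @ resid_r)
    partial_f = max(((rss_restr - rss_full) / k) / (rss_full / (n - p)), 0.0)

    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular first-stage design") from exc
    if cluster == "state":
        cov = _cluster_sandwich(Ginv, W, resid, data.state)
    else:
        s2 = rss_full / (n - p)
        cov = s2 * Ginv
    se = np.sqrt(np.diag(cov))
    return FirstStageFit(
        coef=coef, se=se, names=names, z_names=list(data.z_names),
        residuals=resid, resid_sd=float(np.sqrt(rss_full / (n - p))),
        partial_f=float(partial_f), df_num=k, df_den=n - p, n=n, cov=cov,
    )


def _cluster_sandwich(Ainv: np.ndarray, X: np.ndarray, resid: np.ndarray,
                      groups: np.ndarray) -> np.ndarray:
    Xu = X * resid[:, None]
    _, inv = np.unique(groups, return_inverse=True)
    m = inv.max() + 1
    S = np.zeros((m, X.shape[1]))
    np.add.at(S, inv, Xu)
    meat = S.T @ S
    return Ainv @ meat @ Ainv


# ---------------------------------------------------------------------------
# probit engine


def probit_newton(y: np.ndarray, X: np.ndarray, names: list[str] | None = None,
                  max_iter: int = 100, tol: float = 1e-9,
                  start: np.ndarray | None = None, check_rank: bool = True):
    """Newton-Raphson probit with analytic gradient and Hessian.

    Returns (coef, cov, loglik, n_iter).  Raises on separation (diverging
    linear predictor) or non-convergence.  ``start`` warm-starts the solver
    (used by the bootstrap); ``check_rank`` may be disabled when the design
    was already validated on the full sample.
    """
    n, p = X.shape
    names = names or [f"x{i}" for i in range(p)]
    if check_rank:
        _check_full_rank(X.T @ X, names)
    q = 2.0 * y - 1.0

    if start is not None:
        coef = np.asarray(start, dtype=float).copy()
    else:
        coef = np.zeros(p)
        ones = np.all(X == 1.0, axis=0)
        if ones.any():
            pbar = float(np.clip(y.mean(), 1e-6, 1 - 1e-6))
            coef[np.argmax(ones)] = ndtri(pbar)

    xb = X @ coef
    ll = float(log_ndtr(q * xb).sum())
    for it in range(1, max_iter + 1):
        z = q * xb
        lam = q * np.exp(_norm_logpdf(z) - log_ndtr(z))        # score per obs
        wgt = lam * (lam + xb)                                  # -d2ll/dxb2 > 0
        g = X.T @ lam
        H = (X * wgt[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise EstimationError(f"probit Hessian singular at iteration {it}") from exc
        # halving line search on the log-likelihood
        scale = 1.0
        for _ in range(25):
            new = coef + scale * step
            xb_new = X @ new
            ll_new = float(log_ndtr(q * xb_new).sum())
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        coef, xb, ll_prev, ll = new, xb_new, ll, ll_new
        if np.max(np.abs(xb)) > 40.0:
            raise EstimationError(
                "probit separation: linear predictor diverging; some exposure "
                "stratum may perfectly predict the outcome (try a larger sample)")
        if np.max(np.abs(g)) < tol * n or abs(ll - ll_prev) < tol * (1 + abs(ll)):
            cov = np.linalg.inv(H)
            return coef, cov, ll, it
    raise EstimationError(f"probit did not converge in {max_iter} iterations "
                          f"(|grad|_max = {np.max(np.abs(g)):.3g})")


def fit_probit(data: AnalysisDataset, start: np.ndarray | None = None,
               check_rank: bool = True) -> IVProbitFit:
    """Conventional (non-IV) probit of Y on [X, C] — biased when rho != 0."""
    X = np.column_stack([data.x, data.C])
    names = ["drinks_per_day"] + list(data.c_names)
    coef, cov, ll, it = probit_newton(data.y, X, names, start=start,
                                      check_rank=check_rank)
    return IVProbitFit(tag="naive", coef=coef, names=names, cov=cov,
                       n=data.n, converged=True, loglik=ll, n_iter=it)


def fit_iv_probit_2sps(data: AnalysisDataset, start: np.ndarray | None = None,
                       check_rank: bool = True) -> IVProbitFit:
    """Two-stage predictor substitution: probit of Y on (X_hat, C).

    The stored covariance is the naive second-stage probit covariance
    (``cov_is_naive=True``): it ignores that X_hat is estimated.  Confidence
    intervals for standardised ratios should use the bootstrap, which
    re-runs both stages per replicate.
    """
    fs = fit_first_stage(data, check_rank=check_rank)
    xhat = data.x - fs.residuals
    X = np.column_stack([xhat, data.C])
    names = ["drinks_per_day"] + list(data.c_names)
    coef, cov, ll, it = probit_newton(data.y, X, names, start=start,
                                      check_rank=check_rank)
    return IVProbitFit(tag="2sps", coef=coef, names=names, cov=cov, n=data.n,
                       converged=True, loglik=ll, first_stage=fs,
                       cov_is_naive=True, n_iter=it)


# ---------------------------------------------------------------------------
# joint MLE


def _mle_nll_grad(theta, y, q, V, W, fix_rho):
    """Negative mean log-likelihood and gradient of the joint IV probit.

    theta = [b (struct), alpha (first stage), atanh(rho) (unless fixed),
    log(sigma)].  Per observation:
    ln phi((x - w'a)/sigma) - ln sigma + ln Phi(q*m),
    m = (v'b + (rho/sigma)(x - w'a)) / sqrt(1 - rho^2).
    """
    n = y.shape[0]
    pv, pw = V.shape[1], W.shape[1]
    b = theta[:pv]
    alpha = theta[pv:pv + pw]
    if fix_rho is None:
        a = theta[pv + pw]
        s = theta[pv + pw + 1]
        rho = np.tanh(a)
    else:
        s = theta[pv + pw]
        rho = fix_rho
    sigma = np.exp(s)
    t = np.sqrt(1.0 - rho * rho)

    x = V[:, 0]
    e = x - W @ alpha
    m = (V @ b + (rho / sigma) * e) / t
    z = q * m
    ll = (log_ndtr(z) - _LOG_SQRT_2PI - s - e * e / (2 * sigma * sigma))
    lam = q * np.exp(_norm_logpdf(z) - log_ndtr(z))  # d ll / d m

    g_b = V.T @ lam / t
    g_alpha = W.T @ (e / sigma**2 - lam * rho / (sigma * t))
    g_s = float(np.sum(-1.0 + e * e / sigma**2 - lam * rho * e / (sigma * t)))
    if fix_rho is None:
        g_a = float(np.sum(lam * (t * e / sigma + m * rho)))
        grad = np.concatenate([g_b, g_alpha, [g_a, g_s]])
    else:
        grad = np.concatenate([g_b, g_alpha, [g_s]])
    return -float(ll.sum()) / n, -grad / n


def _numeric_hessian(grad_fn, theta: np.ndarray) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient."""
    p = theta.size
    H = np.zeros((p, p))
    for j in range(p):
        h = 1e-5 * (1.0 + abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2 * h)
    return 0.5 * (H + H.T)


def fit_iv_probit_mle(data: AnalysisDataset, fix_rho: float | None = None,
                      max_iter: int = 200, gtol: float = 1e-7,
                      compute_cov: bool = True,
                      start: np.ndarray | None = None,
                      check_rank: bool = True) -> IVProbitFit:
    """Joint MLE of the linear-first-stage / probit-second-stage model.

    Initialised from the control-function probit (probit of Y on X, C and
    the first-stage residual), whose coefficients are a smooth reparameter-
    isation of the MLE; BFGS with the analytic gradient then polishes to the
    optimum.  The covariance is the inverse observed information, obtained
    by finite-differencing the analytic gradient.

    ``fix_rho`` constrains the error correlation (``fix_rho=0`` factorises
    the likelihood into a plain probit plus first-stage OLS).
    """
    V = np.column_stack([data.x, data.C])
    W = np.column_stack([data.Z, data.C])
    v_names = ["drinks_per_day"] + list(data.c_names)
    w_names = list(data.z_names) + list(data.c_names)
    y = data.y
    q = 2.0 * y - 1.0
    n = data.n

    # --- initial values from first stage + control-function probit
    fs = fit_first_stage(data, check_rank=check_rank)
    if start is not None:
        theta0 = np.asarray(start, dtype=float).copy()
    else:
        alpha0 = fs.coef.copy()
        sigma0 = float(np.sqrt(fs.residuals @ fs.residuals / n))
        Xcf = np.column_stack([V, fs.residuals])
        cf_coef, _, _, _ = probit_newton(y, Xcf, v_names + ["fs_resid"],
                                         check_rank=check_rank)
        b_eps = cf_coef[-1]
        tcf = b_eps * sigma0
        rho0 = tcf / np.sqrt(1.0 + tcf * tcf)
        scale0 = np.sqrt(1.0 - rho0 * rho0)
        b0 = cf_coef[:-1] * scale0

        if fix_rho is None:
            theta0 = np.concatenate([b0, alpha0,
                                     [np.arctanh(np.clip(rho0, -0.99, 0.99)),
                                      np.log(sigma0)]])
        else:
            sc = np.sqrt(1.0 - fix_rho**2)
            theta0 = np.concatenate([cf_coef[:-1] * sc, alpha0, [np.log(sigma0)]])

    fun = lambda th: _mle_nll_grad(th, y, q, V, W, fix_rho)
    res = optimize.minimize(fun, theta0, jac=True, method="BFGS",
                            options={"maxiter": max_iter, "gtol": gtol})
    gnorm = float(np.max(np.abs(res.jac)))
    if gnorm > 1e-4:
        # one refinement pass from the incumbent
        res2 = optimize.minimize(fun, res.x, jac=True, method="L-BFGS-B",
                                 options={"maxiter": max_iter})
        if np.max(np.abs(res2.jac)) < gnorm:
            res = res2
            gnorm = float(np.max(np.abs(res.jac)))
    if gnorm > 1e-3:
        raise EstimationError(
            f"IV probit MLE did not converge: |grad|_max = {gnorm:.3g} "
            f"after {max_iter} iterations")

    theta = res.x
    pv, pw = V.shape[1], W.shape[1]
    b_hat = theta[:pv]
    if fix_rho is None:
        a_hat, s_hat = theta[pv + pw], theta[pv + pw + 1]
        rho_hat = float(np.tanh(a_hat))
    else:
        a_hat = np.arctanh(fix_rho) if abs(fix_rho) < 1 else np.nan
        s_hat = theta[pv + pw]
        rho_hat = float(fix_rho)
    sigma_hat = float(np.exp(s_hat))
    loglik = -res.fun * n

    cov_struct = np.full((pv, pv), np.nan)
    se_a = None
    if compute_cov:
        grad_total = lambda th: fun(th)[1] * n
        H = _numeric_hessian(grad_total, theta)
        try:
            cov_all = np.linalg.inv(H)
        except np.linalg.LinAlgError as exc:
            raise EstimationError("observed information is singular") from exc
        cov_struct = cov_all[:pv, :pv]
        if fix_rho is None:
            se_a = float(np.sqrt(max(cov_all[pv + pw, pv + pw], 0.0)))

    # refresh the reported first stage at the MLE's alpha (diagnostics keep
    # the OLS fit, which is the profile optimum under rho=0 only)
    fit = IVProbitFit(
        tag="mle", coef=b_hat, names=v_names, cov=cov_struct, n=n,
        converged=True, loglik=float(loglik), rho=rho_hat, sigma=sigma_hat,
        atanh_rho=float(a_hat), se_atanh_rho=se_a, first_stage=fs,
        boundary=bool(abs(rho_hat) > 0.995), n_iter=int(res.nit),
        theta=theta,
    )
    return fit


def wald_exogeneity(fit: IVProbitFit) -> TestResult:
    """Wald chi-square(1) test of H0: rho = 0, on the atanh(rho) scale."""
    if fit.tag != "mle" or fit.atanh_rho is None:
        raise EstimationError("Wald exogeneity test requires an MLE fit")
    if fit.se_atanh_rho is None or not np.isfinite(fit.se_atanh_rho) or fit.se_atanh_rho == 0:
        if fit.atanh_rho == 0.0:
            return TestResult(0.0, 1, 1.0, "rho = 0 (exposure exogeneity)")
        raise EstimationError("missing covariance for atanh(rho)")
    stat = (fit.atanh_rho / fit.se_atanh_rho) ** 2
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult(float(stat), 1, p, "rho = 0 (exposure exogeneity)")


# ---------------------------------------------------------------------------
# 2SLS linear probability model


def fit_2sls_lpm(data: AnalysisDataset, instrument_set: list[str] | None = None,
                 outcome: np.ndarray | None = None,
                 cluster: str | None = None) -> LinearIVFit:
    """2SLS of Y on X with instruments Z and exogenous covariates C.

    Heteroscedasticity-robust (HC0) standard errors by default; optional
    state-cluster sandwich.  ``outcome`` overrides ``data.y`` (used for
    continuous mediator outcomes).
    """
    if instrument_set is None:
        instrument_set = list(data.z_names)
    if not instrument_set:
        raise EstimationError("instrument set must be non-empty")
    missing = [z for z in instrument_set if z not in data.z_names]
    if missing:
        raise EstimationError("unknown instrument(s): " + ", ".join(missing))
    cols = [data.z_names.index(z) for z in instrument_set]
    y = data.y if outcome is None else np.asarray(outcome, dtype=float)

    W = np.column_stack([data.Z[:, cols], data.C])
    w_names = list(instrument_set) + list(data.c_names)
    Xf = np.column_stack([data.x, data.C])
    x_names = ["drinks_per_day"] + list(data.c_names)

    G = W.T @ W
    _check_full_rank(G, w_names)
    # first-stage projection of every endogenous/exogenous column
    F1 = _solve(G, W.T @ Xf, "2SLS first stage")
    Xhat = W @ F1
    A = Xhat.T @ Xf
    _check_full_rank(0.5 * (A + A.T), x_names)
    coef = _solve(A, Xhat.T @ y, "2SLS")
    resid = y - Xf @ coef

    try:
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError as exc:
        raise EstimationError("singular 2SLS system") from exc
    if cluster == "state":
        cov = _cluster_sandwich(Ainv, Xhat, resid, data.state)
    else:
        meat = (Xhat * (resid ** 2)[:, None]).T @ Xhat
        cov = Ainv @ meat @ Ainv.T
    return LinearIVFit(coef=float(coef[0]), se=float(np.sqrt(cov[0, 0])),
                       instruments=list(instrument_set), n=data.n,
                       coef_all=coef, names=x_names)
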