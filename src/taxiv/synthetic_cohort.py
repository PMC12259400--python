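"""Synthetic cohort generator with known structural parameters.

The generator realises the structural graph of a tax-instrument design:
state-year excise taxes Z shift individual drinks per day X through a linear
first stage; an unobserved confounder links X and the binary outcome Y
(complete tooth loss) through a correlated bivariate-normal error pair
(eps, u) with correlation ``rho``; Y follows a latent-index probit in X and
the covariates.  Because every coefficient is known, all estimators in the
package can be validated by parameter recovery, type-I error and coverage
experiments against the oracle :func:`true_marginal_rr`.

Two presets ship as plain-text YAML:

``paperlike``
    Tax moments, first-stage coefficient magnitudes and signs, covariate
    marginals and the ~4.3% outcome prevalence follow the descriptive
    statistics of the pooled 2003-2012 BRFSS/alcohol-tax extract this
    design emulates.

``calibration``
    Identical structural model, but the first-stage coefficients are scaled
    (x16, preserving the sign pattern and beverage mix) so that the
    instrument-relevance precondition (partial F > 10) holds at the smaller
    Monte-Carlo sample sizes used in recovery and calibration experiments,
    and so the Monte-Carlo standard error of those experiments sits well
    below their tolerances.  See docs/methods.md for the power analysis.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr

from . import schema
from .cohort_io import encode_covariates
from .exceptions import ConfigError

__all__ = [
    "SimulationTruth",
    "load_preset",
    "available_presets",
    "simulate_taxes",
    "simulate_individuals",
    "simulate_study",
    "true_marginal_rr",
    "RatioOracle",
]

# Covariate marginals of the emulated adult cohort (age truncated at >= 30).
AGE_MEAN, AGE_SD, AGE_MIN = 54.5, 14.2, 30.0
P_FEMALE = 0.546
RACE_PROBS = {"White": 0.842, "Black": 0.054, "Hispanic": 0.056, "Other": 0.048}
EDUCATION_PROBS = {
    "no_certificate": 0.001,
    "elementary": 0.013,
    "some_high_school": 0.032,
    "high_school_graduate": 0.237,
    "some_college": 0.265,
    "college_graduate": 0.452,
}
SMOKING_PROBS = {"never": 0.486, "current": 0.177, "former": 0.337}

#: Lower truncation floor for simulated exposure: everyone remains a
#: current drinker, mirroring the analysis restriction.
EXPOSURE_FLOOR = 0.1

# Fixed per-table substream offsets so tables regenerate independently.
_SUB_TAXES, _SUB_INDIV, _SUB_ORACLE = 11, 23, 37


def _truncnorm_mean(mu: float, sd: float, lower: float) -> float:
    from scipy.stats import norm
    a = (lower - mu) / sd
    return mu + sd * norm.pdf(a) / norm.sf(a)


@dataclass(frozen=True)
class SimulationTruth:
    """Full structural parameterisation of one synthetic study.

    Tax order everywhere: (beer, wine, spirits), in currency per gallon.
    Coefficient dictionaries are keyed by covariate design-column names
    (see :data:`taxiv.schema.DESIGN_COLUMNS`); omitted columns get 0.
    """

    n_states: int = 51
    n_years: int = 7
    n_individuals: int = 100_000
    tax_means: tuple[float, float, float] = (0.6, 1.5, 8.4)
    tax_sds: tuple[float, float, float] = (0.5, 1.1, 4.5)
    tax_state_persistence: float = 0.9
    cigarette_tax_mean: float = 4.4
    cigarette_tax_sd: float = 2.2
    pi: tuple[float, float, float] = (-0.017, 0.012, -0.003)
    gamma: dict = field(default_factory=lambda: {
        "age": -0.004, "female": -0.3, "smoke_current": 0.3, "smoke_former": 0.1,
    })
    x_intercept: float = 2.31
    sigma_eps: float = 1.05
    beta: float = 0.05
    delta: dict = field(default_factory=lambda: {
        "age": 0.045, "female": -0.05,
        "race_black": 0.3, "race_hispanic": 0.1, "race_other": 0.1,
        "edu_no_certificate": 1.0, "edu_elementary": 0.9,
        "edu_some_high_school": 0.7, "edu_high_school_graduate": 0.4,
        "edu_some_college": 0.2,
        "smoke_current": 0.6, "smoke_former": 0.25,
    })
    intercept: float = -5.05
    rho: float = 0.06
    #: Correlation between the (standardised) beer tax and the latent
    #: outcome error: 0 for a valid instrument, nonzero to study
    #: imperfect-instrument robustness.
    instrument_u_corr: float = 0.0
    mediator_effects: dict = field(default_factory=lambda: {
        "bmi": 0.4, "dental_visit": 0.15, "chd": 0.08,
    })
    negative_fraction: float = 0.1
    seed: int = 20240501

    def __post_init__(self):
        if self.n_states < 2 or self.n_years < 1 or self.n_individuals < 1:
            raise ConfigError("n_states >= 2, n_years >= 1, n_individuals >= 1 required")
        if not (-1.0 < self.rho < 1.0):
            raise ConfigError("rho must lie strictly inside (-1, 1)")
        if self.sigma_eps <= 0:
            raise ConfigError("sigma_eps must be positive")
        if any(s < 0 for s in self.tax_sds):
            raise ConfigError("tax_sds must be non-negative")
        if not (0.0 <= self.tax_state_persistence <= 1.0):
            raise ConfigError("tax_state_persistence must lie in [0, 1]")
        if self.rho ** 2 + self.instrument_u_corr ** 2 >= 1.0:
            raise ConfigError("rho^2 + instrument_u_corr^2 must be < 1")

    def replace(self, **changes) -> "SimulationTruth":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    def delta_vector(self, c_names) -> np.ndarray:
        v = np.array([self.delta.get(c, 0.0) for c in c_names])
        v[list(c_names).index("const")] = self.intercept
        return v

    def gamma_vector(self, c_names) -> np.ndarray:
        v = np.array([self.gamma.get(c, 0.0) for c in c_names])
        v[list(c_names).index("const")] = self.x_intercept
        return v


def available_presets() -> list[str]:
    root = importlib.resources.files("taxiv") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name_or_path: str, **overrides) -> SimulationTruth:
    """Load a shipped preset by name, or any YAML file by path."""
    root = importlib.resources.files("taxiv") / "presets"
    res = root / f"{name_or_path}.yaml"
    try:
        text = res.read_text()
    except (FileNotFoundError, NotADirectoryError):
        with open(name_or_path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    for k in ("tax_means", "tax_sds", "pi"):
        if k in raw:
            raw[k] = tuple(raw[k])
    raw.update(overrides)
    return SimulationTruth(**raw)


# ---------------------------------------------------------------------------
# generation


def _years(truth: SimulationTruth) -> list[int]:
    base = list(schema.STUDY_YEARS)
    if truth.n_years <= len(base):
        return base[: truth.n_years]
    return base + [base[-1] + 1 + i for i in range(truth.n_years - len(base))]


def simulate_taxes(truth: SimulationTruth) -> pd.DataFrame:
    """One row per (state, year): a persistent state tax level plus year noise.

    Each tax is ``mean + state_effect + year_innovation`` with the state
    effect carrying ``tax_state_persistence`` of the variance, truncated at 0.
    Deterministic given ``truth.seed``.
    """
    rng = np.random.default_rng([truth.seed, _SUB_TAXES])
    states = [f"S{i:02d}" for i in range(1, truth.n_states + 1)]
    years = _years(truth)
    n_s, n_y = len(states), len(years)

    rows = {"state_code": np.repeat(states, n_y), "year": np.tile(years, n_s)}
    specs = list(zip(
        ("beer_tax", "wine_tax", "spirits_tax"), truth.tax_means, truth.tax_sds,
    )) + [("cigarette_tax", truth.cigarette_tax_mean, truth.cigarette_tax_sd)]
    lam = truth.tax_state_persistence
    for name, mean, sd in specs:
        state_part = rng.normal(0.0, sd * np.sqrt(lam), size=n_s)
        year_part = rng.normal(0.0, sd * np.sqrt(1.0 - lam), size=(n_s, n_y))
        vals = mean + state_part[:, None] + year_part
        rows[name] = np.maximum(vals, 0.0).ravel()
    return pd.DataFrame(rows)


def _draw_covariates(rng, n: int, age_range=(AGE_MIN, None)) -> pd.DataFrame:
    lo, hi = age_range
    if hi is None:
        # truncated-normal age via rejection-free inverse CDF
        from scipy.stats import norm
        a = norm.cdf((lo - AGE_MEAN) / AGE_SD)
        u = rng.uniform(a, 1.0, size=n)
        age = AGE_MEAN + AGE_SD * norm.ppf(u)
    else:
        age = rng.uniform(lo, hi, size=n)
    sex = np.where(rng.uniform(size=n) < P_FEMALE, "female", "male")
    race = rng.choice(list(RACE_PROBS), size=n,
                      p=np.array(list(RACE_PROBS.values())) / sum(RACE_PROBS.values()))
    edu = rng.choice(list(EDUCATION_PROBS), size=n,
                     p=np.array(list(EDUCATION_PROBS.values())) / sum(EDUCATION_PROBS.values()))
    smoke = rng.choice(list(SMOKING_PROBS), size=n,
                       p=np.array(list(SMOKING_PROBS.values())) / sum(SMOKING_PROBS.values()))
    return pd.DataFrame({
        "age": age, "sex": sex, "race_ethnicity": race,
        "education": edu, "smoking": smoke,
    })


def _generate_block(rng, truth: SimulationTruth, taxes: pd.DataFrame, n: int,
                    beta: float, intercept: float, age_range) -> pd.DataFrame:
    """One cohort block: covariates, exposure, outcomes, mediators."""
    cell = taxes.sample(n=n, replace=True, random_state=np.random.RandomState(
        rng.integers(0, 2**31 - 1))).reset_index(drop=True)
    cov = _draw_covariates(rng, n, age_range)
    df = pd.concat([cell[["state_code", "year"]], cov], axis=1)

    C, c_names = encode_covariates(df)
    Zmat = cell[["beer_tax", "wine_tax", "spirits_tax"]].to_numpy(dtype=float)
    pi = np.asarray(truth.pi, dtype=float)
    gamma = truth.gamma_vector(c_names)

    eps = rng.normal(0.0, truth.sigma_eps, size=n)
    eta = rng.normal(size=n)
    w_eps, w_z = truth.rho, truth.instrument_u_corr
    if w_z != 0.0:
        beer = Zmat[:, 0]
        zstar = (beer - beer.mean()) / beer.std()
    else:
        zstar = 0.0
    u = w_eps * (eps / truth.sigma_eps) + w_z * zstar \
        + np.sqrt(1.0 - w_eps**2 - w_z**2) * rng.normal(size=n)

    x = np.maximum(C @ gamma + Zmat @ pi + eps, EXPOSURE_FLOOR)
    delta = truth.delta_vector(c_names)
    delta[c_names.index("const")] = intercept
    y_latent = C @ delta + beta * x + u
    df["drinks_per_day"] = x
    df["edentulous"] = (y_latent > 0).astype(int)
    df["y_latent"] = y_latent  # truth-only column, for linear-model oracles

    me = truth.mediator_effects
    df["bmi"] = 26.8 + me.get("bmi", 0.0) * x + rng.normal(0.0, 5.0, size=n)
    df["dental_visit"] = (
        0.22 + me.get("dental_visit", 0.0) * x + rng.normal(size=n) > 0
    ).astype(int)
    df["chd"] = (
        -1.71 + me.get("chd", 0.0) * x + 0.02 * (df["age"].to_numpy() - 55.0)
        + rng.normal(size=n) > 0
    ).astype(int)
    return df


def simulate_individuals(truth: SimulationTruth, taxes: pd.DataFrame) -> pd.DataFrame:
    """Individual-level cohort linked to the given tax table.

    Adults (age >= 30) carry the structural effect ``truth.beta``; a separate
    negative-control stratum (``negative_control`` flag, ages 10-15) is
    generated with the exposure effect forced to 0 and an intercept offset
    compensating the age effect, so falsification analyses have a stratum
    with non-degenerate outcome prevalence and a known null effect.
    """
    if len(taxes) == 0:
        raise ConfigError("tax table is empty")
    if not (-1.0 < truth.rho < 1.0):
        raise ConfigError("rho must lie strictly inside (-1, 1)")
    rng = np.random.default_rng([truth.seed, _SUB_INDIV])

    adults = _generate_block(
        rng, truth, taxes, truth.n_individuals,
        beta=truth.beta, intercept=truth.intercept, age_range=(AGE_MIN, None),
    )
    adults["negative_control"] = False

    n_neg = int(round(truth.negative_fraction * truth.n_individuals))
    if n_neg > 0:
        adult_age = _truncnorm_mean(AGE_MEAN, AGE_SD, AGE_MIN)
        offset = truth.delta.get("age", 0.0) * (adult_age - 12.5)
        neg = _generate_block(
            rng, truth, taxes, n_neg,
            beta=0.0, intercept=truth.intercept + offset, age_range=(10.0, 15.0),
        )
        neg["negative_control"] = True
        adults = pd.concat([adults, neg], ignore_index=True)
    return adults


def simulate_study(truth: SimulationTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: (individuals, taxes) for one synthetic study."""
    taxes = simulate_taxes(truth)
    return simulate_individuals(truth, taxes), taxes


# ---------------------------------------------------------------------------
# oracle


@dataclass(frozen=True)
class RatioOracle:
    """True marginally standardised risk ratio with its Monte-Carlo SE."""

    value: float
    mc_se: float
    n: int
    x_mean: float
    x_sd: float

    def __float__(self):
        return self.value


def true_marginal_rr(truth: SimulationTruth, n: int = 1_000_000,
                     shift: float | None = None) -> RatioOracle:
    """Monte-Carlo value of the estimand targeted by marginal standardisation.

    Draws ``n`` covariate rows and exposures from the generator's own
    distributions and returns
    ``mean_i Phi(a + b*(xbar+s) + d'C_i) / mean_i Phi(a + b*xbar + d'C_i)``
    where ``xbar``/``s`` are the population exposure mean and SD (or a
    caller-supplied ``shift``).  The Monte-Carlo SE comes from the delta
    method on the ratio of means.
    """
    rng = np.random.default_rng([truth.seed, _SUB_ORACLE])
    cov = _draw_covariates(rng, n, (AGE_MIN, None))
    C, c_names = encode_covariates(cov)

    # exposure draw for the population mean/SD of X (taxes enter through pi)
    taxes = simulate_taxes(truth)
    cell = taxes.sample(n=n, replace=True, random_state=np.random.RandomState(
        rng.integers(0, 2**31 - 1)))
    Zmat = cell[["beer_tax", "wine_tax", "spirits_tax"]].to_numpy(dtype=float)
    gamma = truth.gamma_vector(c_names)
    x = np.maximum(C @ gamma + Zmat @ np.asarray(truth.pi) +
                   rng.normal(0.0, truth.sigma_eps, size=n), EXPOSURE_FLOOR)
    x_mean, x_sd = float(x.mean()), float(x.std(ddof=1))
    s = x_sd if shift is None else float(shift)

    delta = truth.delta_vector(c_names)
    base = C @ delta
    p1 = ndtr(base + truth.beta * (x_mean + s))
    p0 = ndtr(base + truth.beta * x_mean)
    m1, m0 = p1.mean(), p0.mean()
    rr = m1 / m0
    v1, v0 = p1.var(ddof=1) / n, p0.var(ddof=1) / n
    c01 = np.cov(p1, p0, ddof=1)[0, 1] / n
    rel_var = max(v1 / m1**2 + v0 / m0**2 - 2 * c01 / (m1 * m0), 0.0)
    mc_se = abs(rr) * np.sqrt(rel_var)
    return RatioOracle(value=float(rr), mc_se=float(mc_se), n=n,
                       x_mean=x_mean, x_sd=x_sd)
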