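"""Orchestrate the full quasi-experimental study from a single config.

``run_study`` produces one JSON-serialisable report with:

* primary block — per subgroup (all / men / women): first-stage partial F,
  first-stage coefficients with CIs, joint-MLE second-stage coefficient and
  Wald exogeneity test, a 2SPS concordance fit, and the marginally
  standardised risk ratio per SD with a bootstrap CI;
* probit block — conventional prevalence ratios for comparison;
* sensitivity blocks — cigarette-tax adjustment and beer+spirits-only
  instruments;
* controls block — 2SLS on BMI (continuous mediator), IV probit ratios for
  dental visits and the positive-control outcome (CHD), and the
  negative-control stratum (known-null effect) falsification fit;
* bounds block — per-instrument imperfect-instrument bounds on the 2SLS
  linear-probability coefficient.

Reports are deterministic given the config and seed (no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import AnalysisDataset, link_and_filter, load_individuals, load_taxes
from .exceptions import ConfigError, DataError, EstimationError
from .iv_estimators import (fit_2sls_lpm, fit_first_stage, fit_iv_probit_2sps,
                            fit_iv_probit_mle, fit_probit, wald_exogeneity)
from .partial_id import bound_report, nevo_rosen_bounds
from .standardisation import BootstrapPlan, bootstrap_ratio, standardised_ratio, \
    standardised_ratio_wald_ci
from .synthetic_cohort import SimulationTruth, load_preset, simulate_study

__all__ = ["StudyConfig", "run_primary", "run_sensitivity", "run_controls",
           "run_bounds", "run_study"]

ALL_INSTRUMENTS = ("beer_tax", "wine_tax", "spirits_tax")


@dataclass
class StudyConfig:
    """Study configuration: inputs, instruments, subgroups, toggles, bootstrap."""

    preset: str | None = "paperlike"
    cohort_path: str | None = None
    taxes_path: str | None = None
    n_individuals: int | None = None
    seed: int = 1
    instruments: tuple[str, ...] = ALL_INSTRUMENTS
    min_age: float = 30.0
    subgroups: tuple[str, ...] = ("all", "men", "women")
    adjust_cigarette_tax: bool = False
    beer_spirits_only: bool = False
    bootstrap_replicates: int = 250
    bootstrap_unit: str = "individual"
    ratio_estimator: str = "2sps"     # pipeline bootstrapped for ratio CIs
    min_subgroup_n: int = 500
    stratum_sd: str = "own"           # per-SD contrast within strata: own|pooled

    def __post_init__(self):
        if not self.instruments:
            raise ConfigError("instrument list must be non-empty")
        if self.preset is None and (self.cohort_path is None or self.taxes_path is None):
            raise ConfigError("either a preset or cohort+taxes paths are required")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "instruments" in raw:
            raw["instruments"] = tuple(raw["instruments"])
        if "subgroups" in raw:
            raw["subgroups"] = tuple(raw["subgroups"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# data assembly


def _load_inputs(config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.cohort_path is not None:
        individuals, _ = load_individuals(config.cohort_path)
        taxes, _ = load_taxes(config.taxes_path)
        return individuals, taxes
    truth = load_preset(config.preset, seed=config.seed,
                        **({"n_individuals": config.n_individuals}
                           if config.n_individuals else {}))
    return simulate_study(truth)


def _subgroup_frames(individuals: pd.DataFrame, subgroups) -> dict[str, pd.DataFrame]:
    neg = individuals.get("negative_control")
    adults = individuals if neg is None else individuals.loc[~neg.astype(bool)]
    frames = {}
    for sg in subgroups:
        if sg == "all":
            frames[sg] = adults
        elif sg == "men":
            frames[sg] = adults.loc[adults["sex"] == "male"]
        elif sg == "women":
            frames[sg] = adults.loc[adults["sex"] == "female"]
        else:
            raise ConfigError(f"unknown subgroup {sg!r}")
    return frames


def _dataset_for(frame: pd.DataFrame, taxes: pd.DataFrame, config: StudyConfig,
                 instruments=None, extra_covariates=(), outcome="edentulous",
                 min_age=None, max_age=None, drop_sex=False) -> AnalysisDataset:
    ds = link_and_filter(
        frame, taxes,
        min_age=config.min_age if min_age is None else min_age,
        max_age=max_age,
        instruments=tuple(instruments or config.instruments),
        outcome=outcome,
        extra_covariates=tuple(extra_covariates),
    )
    if drop_sex and "female" in ds.c_names:
        # (single-sex strata usually lose the column automatically as an
        # empty dummy; this covers datasets where it survives as constant)
        ds = ds.drop_covariate("female")
    return ds


# ---------------------------------------------------------------------------
# analysis blocks


def _analysis_block(ds: AnalysisDataset, config: StudyConfig, seed: int,
                    shift: float | None = None) -> dict:
    """Table-2-shaped block: relevance, exogeneity, both IV fits, RR per SD."""
    fs = fit_first_stage(ds)
    mle = fit_iv_probit_mle(ds)
    wald = wald_exogeneity(mle)
    tsps = fit_iv_probit_2sps(ds)

    plan = BootstrapPlan(replicates=config.bootstrap_replicates, seed=seed,
                         unit=config.bootstrap_unit)
    rr = bootstrap_ratio(ds, estimator=config.ratio_estimator, plan=plan, shift=shift)
    rr_mle = standardised_ratio(mle, ds, shift=shift)
    rr_mle_ci = standardised_ratio_wald_ci(mle, ds, shift=shift)
    return {
        "n": ds.n,
        "exposure_mean": ds.x_mean,
        "exposure_sd": ds.x_sd,
        "partial_f": fs.partial_f,
        "first_stage": fs.to_dict(),
        "wald_exogeneity": wald.to_dict(),
        "iv_probit_mle": mle.to_dict(),
        "iv_probit_2sps": tsps.to_dict(),
        "risk_ratio": rr.to_dict(),
        "risk_ratio_mle": {"ratio": rr_mle,
                           "wald_ci": [rr_mle_ci[1], rr_mle_ci[2]]},
    }


def run_primary(config: StudyConfig, individuals: pd.DataFrame,
                taxes: pd.DataFrame) -> dict:
    """Primary IV analysis for the full sample and sex strata."""
    frames = _subgroup_frames(individuals, config.subgroups)
    pooled_sd = None
    block = {}
    for i, (sg, frame) in enumerate(frames.items()):
        if len(frame) < config.min_subgroup_n:
            warnings.warn(f"subgroup {sg!r} below size floor; skipped")
            block[sg] = {"skipped": True, "n": int(len(frame))}
            continue
        ds = _dataset_for(frame, taxes, config, drop_sex=(sg in ("men", "women")))
        if sg == "all":
            pooled_sd = ds.x_sd
        shift = None if config.stratum_sd == "own" else pooled_sd
        block[sg] = _analysis_block(ds, config, seed=config.seed + 1000 + i,
                                    shift=shift)

        probit = fit_probit(ds)
        pr = standardised_ratio(probit, ds, shift=shift)
        pr_ci = standardised_ratio_wald_ci(probit, ds, shift=shift)
        block[sg]["probit_pr"] = {"ratio": pr, "wald_ci": [pr_ci[1], pr_ci[2]],
                                  "coef": probit.beta}
    return block


def run_sensitivity(config: StudyConfig, individuals: pd.DataFrame,
                    taxes: pd.DataFrame) -> dict:
    """Cigarette-tax adjustment and beer+spirits-only instrument variants."""
    frames = _subgroup_frames(individuals, ("all",))
    frame = frames["all"]
    out = {}
    if config.adjust_cigarette_tax:
        if "cigarette_tax" not in taxes.columns:
            raise DataError("cigarette_tax column required for the cigarette-tax "
                            "sensitivity analysis")
        ds = _dataset_for(frame, taxes, config, extra_covariates=("cigarette_tax",))
        out["cigarette_tax_adjusted"] = _analysis_block(
            ds, config, seed=config.seed + 2001)
    if config.beer_spirits_only:
        ds = _dataset_for(frame, taxes, config,
                          instruments=("beer_tax", "spirits_tax"))
        out["beer_spirits_instruments"] = _analysis_block(
            ds, config, seed=config.seed + 2002)
    return out


def run_controls(config: StudyConfig, individuals: pd.DataFrame,
                 taxes: pd.DataFrame) -> dict:
    """Mediator, positive-control and negative-control analyses.

    BMI (continuous) uses linear 2SLS; dental visits and CHD use the IV
    probit with standardised ratios; the negative-control stratum (known
    null) reports the IV coefficient and whether its CI covers zero.
    Missing columns skip their block with a warning.
    """
    frames = _subgroup_frames(individuals, ("all",))
    frame = frames["all"]
    out = {}

    if "bmi" in frame.columns and frame["bmi"].notna().any():
        ds_bmi = _dataset_for(frame.dropna(subset=["bmi"]), taxes, config,
                              outcome="bmi")
        out["bmi_2sls"] = fit_2sls_lpm(ds_bmi).to_dict()
    else:
        warnings.warn("bmi column absent; mediator block skipped")

    for col, label in (("dental_visit", "dental_visit_iv_probit"),
                       ("chd", "chd_iv_probit")):
        if col in frame.columns and frame[col].notna().any():
            ds = _dataset_for(frame.dropna(subset=[col]), taxes, config, outcome=col)
            mle = fit_iv_probit_mle(ds)
            rr, lo, hi = standardised_ratio_wald_ci(mle, ds)
            out[label] = {"beta": mle.beta, "beta_ci": list(mle.beta_ci()),
                          "ratio": rr, "ratio_wald_ci": [lo, hi], "n": ds.n}
        else:
            warnings.warn(f"{col} column absent; control block skipped")

    if "negative_control" in frame.columns or "negative_control" in individuals.columns:
        neg = individuals.loc[individuals["negative_control"].astype(bool)]
        if len(neg) >= config.min_subgroup_n:
            ds = _dataset_for(neg, taxes, config, min_age=0, max_age=15.9)
            mle = fit_iv_probit_mle(ds)
            lo, hi = mle.beta_ci()
            out["negative_control_iv_probit"] = {
                "beta": mle.beta, "beta_ci": [lo, hi],
                "ci_covers_zero": bool(lo <= 0.0 <= hi), "n": ds.n,
            }
        else:
            warnings.warn("negative-control stratum below size floor; skipped")
    else:
        warnings.warn("negative_control column absent; falsification block skipped")
    return out


def run_bounds(config: StudyConfig, individuals: pd.DataFrame,
               taxes: pd.DataFrame, direction: str = "positive") -> dict:
    """Per-instrument imperfect-instrument bounds on the 2SLS LPM coefficient."""
    frame = _subgroup_frames(individuals, ("all",))["all"]
    ds = _dataset_for(frame, taxes, config)
    results = []
    for z in config.instruments:
        try:
            results.append(nevo_rosen_bounds(ds, z, direction=direction))
        except EstimationError as exc:
            warnings.warn(f"bounds for {z}: {exc}")
    rep = bound_report(results)
    rep["lpm_2sls"] = fit_2sls_lpm(ds).to_dict()
    return rep


def run_study(config: StudyConfig) -> dict:
    """Full study: primary + sensitivity + controls + bounds, one report."""
    individuals, taxes = _load_inputs(config)
    report = {
        "provenance": {
            "package": "taxiv",
            "version": __version__,
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
        "primary": run_primary(config, individuals, taxes),
        "sensitivity": run_sensitivity(config, individuals, taxes),
        "controls": run_controls(config, individuals, taxes),
        "bounds": run_bounds(config, individuals, taxes),
    }
    return report


def report_to_json(report: dict, path=None) -> str:
    text = json.dumps(report, sort_keys=True, indent=2, default=_json_default)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
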