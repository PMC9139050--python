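"""Synthetic bronchiectasis-registry generator with a planted neutrophil effect.

The generator emulates the statistical structure of a large multicentre
bronchiectasis registry: a right-skewed blood neutrophil distribution, severity
score *components* (lung function, age, dyspnea grade, colonization,
exacerbation and hospitalization counts) whose distributions shift in patients
above a planted neutrophil cut-off, inflammatory analytes (CRP, ESR,
fibrinogen, platelets) elevated and nutritional analytes (total protein,
albumin) depressed above the cut-off, and binary traits with group-dependent
prevalences. Severity scores are *not* generated directly — they are computed
from the generated components, so the scoring engine is exercised end to end.

Effect injection is a threshold step: every affected variable receives its
configured shift (continuous), rate shift (count), or above-threshold
prevalence/probability vector (binary/categorical) exactly for patients whose
drawn neutrophil count is at or above ``planted_threshold``. With
``planted_threshold=None`` the generator is a null model: all patients share
the below-threshold marginals.

Binary and categorical variables are sampled by inverse-CDF from one uniform
draw per patient, so raising a prevalence (or shifting probability mass
toward worse categories) changes patient outcomes monotonically at a fixed
seed — a property the parameter-recovery tests rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = ["GeneratorConfig", "ConfigError", "default_config", "generate_cohort"]


class ConfigError(ValueError):
    """Invalid generator configuration; message names the offending field."""


# --------------------------------------------------------------------------
# Default marginals (below-threshold stratum) and threshold-step effects.
#
# Continuous marginals: dist in {normal, lognormal}; lognormal is
# moment-matched to (mean, sd) so heavy-tailed analytes stay positive.
# Counts: Poisson with the given rate. Binary: prevalence. Categorical:
# probability vector over the listed levels.
# --------------------------------------------------------------------------

DEFAULT_MARGINALS: dict[str, dict[str, Any]] = {
    "age": {"dist": "normal", "mean": 67.1, "sd": 14.6, "lo": 18.0, "hi": 105.0},
    "bmi": {"dist": "normal", "mean": 25.7, "sd": 4.9, "lo": 12.0, "hi": 60.0},
    "fev1_pct": {"dist": "normal", "mean": 78.0, "sd": 24.0, "lo": 10.0, "hi": 200.0},
    "fvc_pct": {"dist": "normal", "mean": 88.0, "sd": 21.0, "lo": 10.0, "hi": 200.0},
    "fev1_fvc": {"dist": "normal", "mean": 70.0, "sd": 12.0, "lo": 20.0, "hi": 100.0},
    "dlco_pct": {"dist": "normal", "mean": 86.0, "sd": 22.0, "lo": 10.0, "hi": 200.0},
    "lymphocytes": {"dist": "lognormal", "mean": 2130.0, "sd": 1200.0},
    "eosinophils": {"dist": "lognormal", "mean": 210.0, "sd": 200.0},
    "platelets": {"dist": "normal", "mean": 239e3, "sd": 67e3, "lo": 10e3},
    "crp": {"dist": "lognormal", "mean": 2.89, "sd": 8.54},
    "esr": {"dist": "lognormal", "mean": 16.03, "sd": 14.62},
    "fibrinogen": {"dist": "normal", "mean": 396.5, "sd": 109.5, "lo": 50.0},
    "total_protein": {"dist": "normal", "mean": 7.04, "sd": 0.59, "lo": 3.0},
    "albumin": {"dist": "normal", "mean": 4.23, "sd": 0.41, "lo": 1.5},
    "pack_years": {"dist": "lognormal", "mean": 28.2, "sd": 24.8},
    "exacerbations_prior_year": {"dist": "poisson", "rate": 1.5},
    "hospitalizations_prior_year": {"dist": "poisson", "rate": 0.5},
    "charlson": {"dist": "poisson", "rate": 1.8},
    "radiological_lobes": {"dist": "poisson", "rate": 1.88, "offset": 1, "hi": 6},
    "dyspnea_mmrc": {"probs": [0.32, 0.30, 0.21, 0.12, 0.05]},
    "smoking_status": {"probs": [0.64, 0.07, 0.29]},
    "cystic_bronchiectasis": {"prev": 0.20},
    "pa_colonization": {"prev": 0.215},
    "other_colonization": {"prev": 0.20},
    "copd": {"prev": 0.082},
    "asthma": {"prev": 0.100},
    "myocardial_infarction": {"prev": 0.032},
    "heart_failure": {"prev": 0.060},
    "dementia": {"prev": 0.004},
    "diabetes": {"prev": 0.102},
    "kidney_failure": {"prev": 0.023},
}

#: Above-threshold effects. Continuous/count: additive shift (variable units /
#: rate). Binary: (below, above) prevalence pair. Categorical: above-threshold
#: probability vector.
DEFAULT_EFFECTS: dict[str, Any] = {
    "age": 3.2,
    "bmi": 0.5,
    "fev1_pct": -14.0,
    "fvc_pct": -9.0,
    "fev1_fvc": -6.0,
    "dlco_pct": -13.0,
    "eosinophils": -30.0,
    "platelets": 38e3,
    "crp": 2.42,
    "esr": 6.24,
    "fibrinogen": 104.0,
    "total_protein": -0.15,
    "albumin": -0.15,
    "pack_years": 7.2,
    "exacerbations_prior_year": 0.2,
    "hospitalizations_prior_year": 0.6,
    "charlson": 0.4,
    "dyspnea_mmrc": [0.18, 0.26, 0.26, 0.19, 0.11],
    "smoking_status": [0.48, 0.12, 0.40],
    "pa_colonization": (0.215, 0.335),
    "copd": (0.082, 0.184),
    "asthma": (0.100, 0.107),
    "myocardial_infarction": (0.032, 0.059),
    "heart_failure": (0.060, 0.131),
    "dementia": (0.004, 0.018),
    "diabetes": (0.102, 0.151),
    "kidney_failure": (0.023, 0.059),
}

DEFAULT_MISSINGNESS: dict[str, float] = {
    "bmi": 0.02,
    "dlco_pct": 0.10,
    "crp": 0.03,
    "esr": 0.05,
    "fibrinogen": 0.05,
    "total_protein": 0.03,
    "albumin": 0.03,
}

CATEGORICAL_LEVELS: dict[str, list] = {
    "dyspnea_mmrc": [0, 1, 2, 3, 4],
    "smoking_status": ["never", "current", "ex"],
}

#: Residual leukocyte fraction (monocytes + basophils), truncated normal >= 0.
_RESIDUAL_MEAN, _RESIDUAL_SD = 600.0, 200.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterisation of one synthetic cohort.

    Attributes
    ----------
    n_patients
        Cohort size (>= 0).
    seed
        Seed for the generator's single random stream.
    planted_threshold
        Neutrophil cut-off (cells/µL) above which effects apply; ``None``
        disables all effects (null model).
    neutrophil_log_mean, neutrophil_log_sd
        Log-scale parameters of the lognormal neutrophil distribution
        (cells/µL). Defaults put the sub-threshold stratum mean/sd near
        3.4e3 (0.9e3) cells/µL and roughly a third of patients above
        4990 cells/µL.
    effect_sizes, marginals, missingness
        Per-variable overrides merged over the package defaults.
    """

    n_patients: int = 1034
    seed: int = 0
    planted_threshold: float | None = 4990.0
    neutrophil_log_mean: float = math.log(4100.0)
    neutrophil_log_sd: float = 0.48
    effect_sizes: Mapping[str, Any] = field(default_factory=dict)
    marginals: Mapping[str, Mapping[str, Any]] = field(default_factory=dict)
    missingness: Mapping[str, float] = field(default_factory=dict)

    def merged_marginals(self) -> dict[str, dict[str, Any]]:
        out = {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
        for k, v in self.marginals.items():
            out[k] = {**out.get(k, {}), **dict(v)}
        return out

    def merged_effects(self) -> dict[str, Any]:
        if self.planted_threshold is None:
            return {}
        return {**DEFAULT_EFFECTS, **dict(self.effect_sizes)}

    def merged_missingness(self) -> dict[str, float]:
        return {**DEFAULT_MISSINGNESS, **dict(self.missingness)}

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        if self.planted_threshold is not None and self.planted_threshold <= 0:
            raise ConfigError("planted_threshold must be > 0 when present")
        if self.neutrophil_log_sd <= 0:
            raise ConfigError("neutrophil_log_sd must be > 0")
        for name, m in self.merged_marginals().items():
            if "sd" in m and m["sd"] <= 0:
                raise ConfigError(f"marginal '{name}': sd must be > 0")
            if "prev" in m and not 0.0 <= m["prev"] <= 1.0:
                raise ConfigError(f"marginal '{name}': prevalence not in [0, 1]")
            if "rate" in m and m["rate"] < 0:
                raise ConfigError(f"marginal '{name}': rate must be >= 0")
            if "probs" in m:
                p = np.asarray(m["probs"], float)
                if (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
                    raise ConfigError(f"marginal '{name}': probs must be a distribution")
        for name, eff in self.merged_effects().items():
            if isinstance(eff, (tuple, list)) and len(eff) == 2 and name not in CATEGORICAL_LEVELS:
                lo, hi = eff
                if not (0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0):
                    raise ConfigError(f"effect '{name}': prevalences not in [0, 1]")


def default_config(**overrides: Any) -> GeneratorConfig:
    """Registry-calibrated configuration; keyword overrides replace fields."""
    return replace(GeneratorConfig(), **overrides)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    # moment matching: E[X]=mean, SD[X]=sd
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _draw_continuous(rng: np.random.Generator, m: Mapping[str, Any], n: int) -> np.ndarray:
    if m["dist"] == "normal":
        x = rng.normal(m["mean"], m["sd"], size=n)
    elif m["dist"] == "lognormal":
        mu, sigma = _lognormal_params(m["mean"], m["sd"])
        x = rng.lognormal(mu, sigma, size=n)
    else:  # pragma: no cover - guarded by validate()
        raise ConfigError(f"unknown continuous dist '{m['dist']}'")
    return x


def _clip(x: np.ndarray, m: Mapping[str, Any]) -> np.ndarray:
    lo = m.get("lo", 0.0)
    hi = m.get("hi", None)
    return np.clip(x, lo, hi)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Draw a synthetic cohort; a pure function of the config (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    marginals = config.merged_marginals()
    effects = config.merged_effects()

    cols: dict[str, np.ndarray | list] = {}
    cols["patient_id"] = [f"P{i:05d}" for i in range(n)]

    neutro = rng.lognormal(config.neutrophil_log_mean, config.neutrophil_log_sd, size=n)
    above = (
        neutro >= config.planted_threshold
        if config.planted_threshold is not None
        else np.zeros(n, dtype=bool)
    )
    cols["neutrophils"] = neutro

    # fixed variable order => determinism of the single RNG stream
    for name in DEFAULT_MARGINALS:
        m = marginals[name]
        eff = effects.get(name)
        if "probs" in m:  # categorical (incl. ordinal grades)
            levels = CATEGORICAL_LEVELS[name]
            below_cdf = np.cumsum(np.asarray(m["probs"], float))
            above_cdf = np.cumsum(np.asarray(eff, float)) if eff is not None else below_cdf
            u = rng.uniform(size=n)
            idx_b = np.searchsorted(below_cdf, u, side="left")
            idx_a = np.searchsorted(above_cdf, u, side="left")
            idx = np.where(above, idx_a, idx_b).clip(0, len(levels) - 1)
            cols[name] = np.asarray(levels, dtype=object)[idx]
        elif "prev" in m:  # binary: one uniform per patient, stratum prevalence
            p_below = m["prev"]
            p_above = eff[1] if eff is not None else p_below
            if eff is not None:
                p_below = eff[0]
            u = rng.uniform(size=n)
            p = np.where(above, p_above, p_below)
            cols[name] = (u < p).astype(int)
        elif m["dist"] == "poisson":
            rate = np.full(n, float(m["rate"]))
            if eff is not None:
                rate = np.where(above, np.maximum(rate + eff, 0.0), rate)
            x = rng.poisson(rate) + int(m.get("offset", 0))
            if "hi" in m:
                x = np.minimum(x, int(m["hi"]))
            cols[name] = x
        else:  # continuous
            x = _draw_continuous(rng, m, n)
            if eff is not None:
                x = x + np.where(above, float(eff), 0.0)
            cols[name] = _clip(x, m)

    # leukocyte additivity: neutrophils + lymphocytes + eosinophils + residual
    residual = np.maximum(rng.normal(_RESIDUAL_MEAN, _RESIDUAL_SD, size=n), 0.0)
    cols["leukocytes"] = (
        np.asarray(cols["neutrophils"], float)
        + np.asarray(cols["lymphocytes"], float)
        + np.asarray(cols["eosinophils"], float)
        + residual
    )

    df = pd.DataFrame(cols)
    # pack-years only meaningful for ever-smokers
    if n:
        df.loc[df["smoking_status"] == "never", "pack_years"] = 0.0
        df["dyspnea_mmrc"] = df["dyspnea_mmrc"].astype(int)

    # missing-completely-at-random per variable (after all values are drawn,
    # so the missingness pattern does not perturb the value stream)
    for name, prob in sorted(config.merged_missingness().items()):
        if name not in df.columns:
            raise ConfigError(f"missingness for unknown variable '{name}'")
        if not 0.0 <= prob <= 1.0:
            raise ConfigError(f"missingness '{name}': probability not in [0, 1]")
        if n and prob > 0:
            mask = rng.uniform(size=n) < prob
            df[name] = df[name].astype(float)
            df.loc[mask, name] = np.nan

    from .cohort import COLUMNS

    order = [c for c in COLUMNS if c in df.columns]
    df = df[order]
    label = (
        f"synthetic(seed={config.seed}, n={n}, "
        f"planted_threshold={config.planted_threshold})"
    )
    return Cohort(df, provenance=label)
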