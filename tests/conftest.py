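"""Shared fixtures: synthetic cohorts at the registry's study scale."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import neutroclust as nc
from neutroclust.simulate import DEFAULT_EFFECTS, DEFAULT_MARGINALS


def scaled_effects(factor: float) -> dict:
    """Interpolate/extrapolate the default above-threshold effects by
    ``factor`` (0 = null, 1 = defaults)."""
    eff: dict = {}
    for k, v in DEFAULT_EFFECTS.items():
        if isinstance(v, (int, float)):
            eff[k] = v * factor
        elif isinstance(v, tuple):
            lo, hi = v
            eff[k] = (lo, float(np.clip(lo + (hi - lo) * factor, 0.0, 1.0)))
        else:  # categorical probability vector
            base = np.array(DEFAULT_MARGINALS[k]["probs"], float)
            tgt = np.array(v, float)
            p = np.clip(base + factor * (tgt - base), 1e-6, None)
            eff[k] = (p / p.sum()).tolist()
    return eff


def recovery_config(seed: int, factor: float = 1.0, n: int = 1034) -> nc.GeneratorConfig:
    """Cut-point recovery design: the cut is planted at the neutrophil
    distribution's balance point (log-median 5000 cells/µL), so the balance
    criterion is consistent with the plant and the significance gate is what
    the sweep must get right."""
    return nc.default_config(
        n_patients=n,
        seed=seed,
        planted_threshold=5000.0,
        neutrophil_log_mean=float(np.log(5000.0)),
        effect_sizes=scaled_effects(factor),
    )


@pytest.fixture(scope="session")
def planted_scored() -> pd.DataFrame:
    cfg = nc.default_config(n_patients=1034, seed=0)
    return nc.score_cohort(nc.generate_cohort(cfg))


@pytest.fixture(scope="session")
def null_scored() -> pd.DataFrame:
    cfg = nc.default_config(n_patients=1034, seed=1, planted_threshold=None)
    return nc.score_cohort(nc.generate_cohort(cfg))


@pytest.fixture(scope="session")
def assignment(planted_scored) -> nc.ClusterAssignment:
    return nc.dichotomize(planted_scored, 4990.0)


@pytest.fixture()
def tiny_cohort() -> nc.Cohort:
    df = pd.DataFrame(
        {
            "patient_id": ["A", "B", "C"],
            "age": [55.0, 72.5, np.nan],
            "neutrophils": [3200.0, 6100.123456789012, np.nan],
            "leukocytes": [6000.0, 9000.0, 7000.0],
            "pa_colonization": [0, 1, 0],
            "smoking_status": ["never", "ex", "current"],
        }
    )
    return nc.Cohort(df, provenance="hand-made")
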