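"""Mann-Whitney sweep, threshold selection, and the sklearn estimator."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.base import clone
from sklearn.exceptions import NotFittedError

import neutroclust as nc
from neutroclust.threshold import ThresholdScan, mann_whitney_u

from conftest import recovery_config


def exact_mwu_oracle(a, b) -> float:
    """Exhaustive-permutation two-sided p: enumerate all C(n, n_a) splits of
    the pooled sample and compare U to its permutation distribution."""
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    ranks = stats.rankdata(pooled)
    u_obs = float(np.sum(ranks[:na]) - na * (na + 1) / 2)
    us = [
        float(np.sum(ranks[list(idx)]) - na * (na + 1) / 2)
        for idx in itertools.combinations(range(n), na)
    ]
    us = np.asarray(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2.0 * min(p_low, p_high))


def test_mwu_separated_samples_exact_p():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)
    assert "exact" in res.method


def test_mwu_identical_multisets_symmetric():
    res = mann_whitney_u([1, 2, 5, 9], [1, 2, 5, 9])
    assert res.statistic == pytest.approx(res.n_a * res.n_b / 2)
    assert res.p_value >= 0.99


def test_mwu_empty_sample_rejected():
    with pytest.raises(ValueError, match="empty"):
        mann_whitney_u([], [1.0, 2.0])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    na=st.integers(2, 8),
    nb=st.integers(2, 8),
    seed=st.integers(0, 10_000),
)
def test_mwu_exact_path_matches_permutation_enumeration(na, nb, seed):
    rng = np.random.default_rng(seed)
    pooled = rng.permutation(np.arange(na + nb, dtype=float) + rng.uniform(0, 0.3))
    a, b = pooled[:na], pooled[na:]
    res = mann_whitney_u(a, b)
    assert "exact" in res.method
    assert res.p_value == pytest.approx(exact_mwu_oracle(a, b), abs=1e-12)


def test_mwu_asymptotic_matches_scipy_with_ties():
    rng = np.random.default_rng(3)
    a = rng.integers(0, 8, 60).astype(float)
    b = rng.integers(0, 8, 90).astype(float) + 1
    res = mann_whitney_u(a, b)
    ref = stats.mannwhitneyu(a, b, method="asymptotic", use_continuity=True)
    assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-12)


# ---------------------------------------------------------------------------
# scan_thresholds
# ---------------------------------------------------------------------------

def _frame(neutro, faced, efaced=None):
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(len(neutro))],
            "neutrophils": neutro,
            "faced": faced,
            "efaced": efaced if efaced is not None else faced,
        }
    )


def test_scan_small_cohort_single_candidate():
    df = _frame([1000, 2000, 8000, 9000], [2, 2, 9, 9])
    scan = nc.scan_thresholds(df, grid=[5000])
    assert scan.n_above[0] == 2 and scan.n_below[0] == 2
    assert scan.p_faced[0] > 0.05


def test_scan_grid_beyond_observed_range_gives_null_p():
    df = _frame([1000, 2000, 3000, 4000], [1, 2, 3, 4])
    scan = nc.scan_thresholds(df, grid=[10_000, 20_000])
    assert (scan.n_above == 0).all()
    assert np.isnan(scan.p_faced).all() and np.isnan(scan.p_efaced).all()


def test_scan_missing_columns_rejected():
    df = pd.DataFrame({"patient_id": ["A"], "faced": [1.0], "efaced": [1.0]})
    with pytest.raises(ValueError, match="neutrophils"):
        nc.scan_thresholds(df)


def test_scan_group_sizes_monotone_along_grid(planted_scored):
    scan = nc.scan_thresholds(planted_scored, grid_step=100)
    assert (np.diff(scan.n_above) <= 0).all()
    assert (np.diff(scan.n_below) >= 0).all()
    ok = ~np.isnan(scan.p_faced)
    assert scan.n_above[ok].min() >= 2 and scan.n_below[ok].min() >= 2
    assert (scan.n_above + scan.n_below == scan.n_total).all()


def test_scan_pvalues_match_direct_test_per_candidate(planted_scored):
    """The vectorised sweep reproduces the per-candidate Mann-Whitney p."""
    scan = nc.scan_thresholds(planted_scored, grid_step=500)
    sub = planted_scored[["neutrophils", "faced", "efaced"]].dropna()
    for i, t in enumerate(scan.grid):
        m = sub["neutrophils"] >= t
        if min(m.sum(), (~m).sum()) < 2:
            assert np.isnan(scan.p_faced[i])
            continue
        for col, pvals in (("faced", scan.p_faced), ("efaced", scan.p_efaced)):
            ref = mann_whitney_u(sub.loc[m, col], sub.loc[~m, col]).p_value
            assert pvals[i] == pytest.approx(ref, rel=1e-12)


# ---------------------------------------------------------------------------
# select_threshold
# ---------------------------------------------------------------------------

def _scan(grid, p, n_above, n_total=100, alpha=0.05):
    grid = np.asarray(grid, float)
    p = np.asarray(p, float)
    n_above = np.asarray(n_above)
    return ThresholdScan(
        grid=grid,
        p_faced=p,
        p_efaced=p,
        n_above=n_above,
        n_below=n_total - n_above,
        alpha=alpha,
        n_total=n_total,
    )


def test_select_singleton_eligible_under_both_strategies():
    scan = _scan([3000, 4000, 5000], [0.5, 0.01, 0.8], [60, 45, 20])
    for strategy in ("most_balanced", "highest_significant"):
        assert nc.select_threshold(scan, strategy=strategy) == 4000


def test_select_most_balanced_prefers_evenest_split():
    scan = _scan([4000, 5000, 6000], [0.01, 0.01, 0.01], [40, 45, 30])
    assert nc.select_threshold(scan, strategy="most_balanced") == 5000
    assert nc.select_threshold(scan, strategy="highest_significant") == 6000


def test_select_balance_ties_break_to_higher_threshold():
    scan = _scan([4000, 5000], [0.01, 0.01], [45, 45])
    assert nc.select_threshold(scan, strategy="most_balanced") == 5000


def test_select_returns_none_when_nothing_qualifies():
    scan = _scan([4000, 5000], [0.2, 0.3], [45, 40])
    assert nc.select_threshold(scan) is None
    # significant but too unbalanced
    scan = _scan([4000], [0.001], [10])
    assert nc.select_threshold(scan, min_fraction=0.25) is None


def test_select_unknown_strategy_rejected():
    scan = _scan([4000], [0.01], [45])
    with pytest.raises(ValueError, match="strategy"):
        nc.select_threshold(scan, strategy="minimum_p")


def test_selection_invariant_to_grid_order_and_duplicates(planted_scored):
    grid = list(np.arange(3000, 6001, 250))
    base = nc.scan_thresholds(planted_scored, grid=grid)
    shuffled = nc.scan_thresholds(planted_scored, grid=grid[::-1] + grid[:5])
    assert nc.select_threshold(base) == nc.select_threshold(shuffled)


def test_null_model_rarely_selects_a_threshold():
    """Minimum-p selection bias control: with no planted effect the
    significance+balance gate should return no threshold in >= 80% of
    seeds."""
    none_count = 0
    for seed in range(50):
        cfg = nc.default_config(n_patients=1034, seed=seed, planted_threshold=None)
        scored = nc.score_cohort(nc.generate_cohort(cfg))
        scan = nc.scan_thresholds(scored, grid_step=10)
        none_count += nc.select_threshold(scan) is None
    assert none_count >= 40


def test_recovery_rate_monotone_in_effect_size():
    rates = []
    for factor in (0.1, 0.4, 1.0):
        hits = 0
        for seed in range(30):
            scored = nc.score_cohort(nc.generate_cohort(recovery_config(seed, factor)))
            scan = nc.scan_thresholds(scored, grid_step=10)
            sel = nc.select_threshold(scan)
            hits += sel is not None and abs(sel - 5000.0) <= 200.0
        rates.append(hits)
    assert rates[0] <= rates[1] <= rates[2]
    assert rates[2] >= 27  # strong effect nearly always recovered


# ---------------------------------------------------------------------------
# dichotomize / ClusterAssignment
# ---------------------------------------------------------------------------

def test_dichotomize_boundary_is_inclusive():
    df = pd.DataFrame(
        {
            "patient_id": ["A", "B", "C"],
            "neutrophils": [4990.0, 4989.9, np.nan],
        }
    )
    asg = nc.dichotomize(df, 4990.0)
    assert list(asg.labels) == ["above", "below", "unassigned"]
    assert asg.n_above == 1 and asg.n_below == 1 and asg.n_unassigned == 1


def test_dichotomize_requires_positive_threshold(planted_scored):
    with pytest.raises(ValueError):
        nc.dichotomize(planted_scored, 0.0)


# ---------------------------------------------------------------------------
# ThresholdClusterer (sklearn API)
# ---------------------------------------------------------------------------

def test_clusterer_fit_predict_roundtrip(planted_scored):
    est = nc.ThresholdClusterer(grid_step=50)
    labels = est.fit_predict(planted_scored)
    assert est.threshold_ is not None
    assert set(labels) <= {"above", "below", "unassigned"}
    again = est.predict(planted_scored)
    assert (labels == again).all()
    x = planted_scored["neutrophils"]
    assert ((labels == "above") == (x >= est.threshold_).to_numpy())[x.notna()].all()


def test_clusterer_sklearn_contract(planted_scored):
    est = nc.ThresholdClusterer(alpha=0.01, min_fraction=0.3)
    assert clone(est).get_params()["alpha"] == 0.01
    with pytest.raises(NotFittedError):
        est.predict(planted_scored)
    with pytest.raises(ValueError, match="alpha"):
        nc.ThresholdClusterer(alpha=0.0).fit(planted_scored)


def test_clusterer_null_cohort_has_no_threshold(null_scored):
    est = nc.ThresholdClusterer(grid_step=10).fit(null_scored)
    if est.threshold_ is None:  # overwhelmingly likely; labels degrade safely
        assert (est.labels_ == "unassigned").all()
        with pytest.raises(ValueError, match="no threshold"):
            est.predict(null_scored)
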