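"""Comparison tables: pooled t, chi-square, stars, exclusions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import neutroclust as nc
from neutroclust.compare import VariableSpec


def test_student_t_identical_samples():
    res = nc.student_t([1, 2, 3], [1, 2, 3])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_student_t_strong_separation():
    res = nc.student_t([0, 0, 1, 1], [10, 10, 11, 11])
    assert res.p_value < 0.001
    assert abs(res.statistic) == pytest.approx(24.49, abs=0.05)


def test_student_t_matches_scipy_pooled():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = rng.normal(size=rng.integers(3, 40))
        b = rng.normal(0.3, 1.2, size=rng.integers(3, 40))
        res = nc.student_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(float(ref.statistic), rel=1e-10)
        assert res.p_value == pytest.approx(float(ref.pvalue), rel=1e-10)


def test_student_t_zero_variance_conventions():
    assert nc.student_t([2, 2, 2], [2, 2]).p_value == 1.0
    assert nc.student_t([2, 2, 2], [3, 3]).p_value == 0.0


def test_student_t_requires_two_per_group():
    with pytest.raises(ValueError):
        nc.student_t([1.0], [1.0, 2.0])


def test_chi_square_independence_and_association():
    assert nc.chi_square([[50, 50], [50, 50]]).p_value == pytest.approx(1.0)
    res = nc.chi_square([[90, 10], [10, 90]])
    assert res.statistic == pytest.approx(128.0)
    assert res.p_value < 0.001


def test_chi_square_df_for_2x3():
    res = nc.chi_square([[10, 10, 10], [10, 10, 10]])
    assert "df=2" in res.method and res.p_value == pytest.approx(1.0)


def test_chi_square_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        nc.chi_square([[0, 10], [0, 20]])


def test_chi_square_small_expected_counts_warn():
    with pytest.warns(UserWarning, match="expected"):
        nc.chi_square([[2, 30], [3, 40]])


@pytest.mark.parametrize(
    "p, label",
    [(0.0005, "***"), (0.005, "**"), (0.03, "*"), (0.05, ""), (0.2, ""), (0.001, "**")],
)
def test_stars_thresholds(p, label):
    assert nc.stars(p) == label


def test_stars_rejects_invalid_p():
    with pytest.raises(ValueError):
        nc.stars(1.5)


# ---------------------------------------------------------------------------
# comparison_table
# ---------------------------------------------------------------------------

def _toy_cohort(n_below=697, n_above=337, seed=0):
    rng = np.random.default_rng(seed)
    n = n_below + n_above
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(n)],
            "neutrophils": np.r_[
                rng.uniform(1000, 4980, n_below), rng.uniform(5000, 12000, n_above)
            ],
            "pa_colonization": np.r_[
                np.zeros(n_below - 150), np.ones(150), np.zeros(n_above - 113), np.ones(113)
            ],
            "copd": rng.binomial(1, 0.1, n),
            "age": rng.normal(67, 14, n),
        }
    )
    return df


def test_binary_row_percent_matches_printed_style():
    df = _toy_cohort()
    asg = nc.dichotomize(df, 4990.0)
    table = nc.comparison_table(
        df, asg, [VariableSpec("pa_colonization", "binary")]
    )
    row = table.rows[0]
    assert row.above_summary == "113 (33.5)"
    assert row.below_summary == "150 (21.5)"
    assert table.n_above == 337 and table.n_below == 697


def test_exclusion_shrinks_groups_by_flag_counts():
    df = _toy_cohort(seed=3)
    asg = nc.dichotomize(df, 4990.0)
    labels = asg.label_frame(df)
    flagged_below = int(df.loc[(labels == "below").to_numpy(), "copd"].sum())
    flagged_above = int(df.loc[(labels == "above").to_numpy(), "copd"].sum())
    table = nc.comparison_table(
        df, asg, [VariableSpec("age", "continuous")], exclusion="copd"
    )
    assert table.n_below == 697 - flagged_below
    assert table.n_above == 337 - flagged_above
    assert table.exclusion == "copd"


def test_planted_large_shift_earns_three_stars():
    rng = np.random.default_rng(5)
    n = 1000
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(2 * n)],
            "neutrophils": np.r_[np.full(n, 3000.0), np.full(n, 8000.0)],
            "crp": np.r_[rng.normal(0, 1, n), rng.normal(1.5, 1, n)],
        }
    )
    asg = nc.dichotomize(df, 4990.0)
    table = nc.comparison_table(df, asg, [VariableSpec("crp", "continuous")])
    assert table.rows[0].stars == "***"


def test_absent_column_named_in_error(planted_scored, assignment):
    with pytest.raises(ValueError, match="nope"):
        nc.comparison_table(planted_scored, assignment, [VariableSpec("nope", "binary")])


def test_categorical_expands_to_per_level_rows(planted_scored, assignment):
    spec = VariableSpec(
        "smoking_status", "categorical", levels=("never", "current", "ex")
    )
    table = nc.comparison_table(planted_scored, assignment, [spec])
    assert [r.variable for r in table.rows] == [
        "smoking_status=never",
        "smoking_status=current",
        "smoking_status=ex",
    ]
    # per-level counts add up to the group sizes
    below_counts = [int(r.below_summary.split(" ")[0]) for r in table.rows]
    assert sum(below_counts) == table.rows[0].below_n


def test_count_conservation_per_variable(planted_scored, assignment):
    table = nc.comparison_table(
        planted_scored, assignment, [VariableSpec("dlco_pct", "continuous")]
    )
    row = table.rows[0]
    labels = assignment.label_frame(planted_scored)
    missing = planted_scored["dlco_pct"].isna()
    assert row.below_n == int(((labels == "below") & ~missing).sum())
    assert row.above_n == int(((labels == "above") & ~missing).sum())


def test_full_default_table_on_planted_cohort(planted_scored, assignment):
    """The registry-style table shows the planted phenotype: higher severity
    scores and inflammation above threshold, lower lung function."""
    table = nc.comparison_table(
        planted_scored, assignment, nc.default_variable_specs()
    )
    frame = table.to_frame().set_index("variable")
    for var in ("faced", "efaced", "bsi", "crp", "fibrinogen", "neutrophils"):
        assert frame.loc[var, "stars"] == "***", var
    assert "| variable |" in table.to_markdown()


def test_exclusion_of_independent_flag_keeps_direction(planted_scored):
    """Excluding COPD patients must not flip a difference planted
    independently of COPD."""
    asg = nc.dichotomize(planted_scored, 4990.0)
    spec = [VariableSpec("fibrinogen", "continuous")]
    full = nc.comparison_table(planted_scored, asg, spec)
    excl = nc.comparison_table(planted_scored, asg, spec, exclusion="copd")

    def direction(t):
        below = float(t.rows[0].below_summary.split(" ")[0])
        above = float(t.rows[0].above_summary.split(" ")[0])
        return np.sign(above - below)

    assert direction(full) == direction(excl) == 1.0
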