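"""Data-driven neutrophil cut-off discovery via a Mann-Whitney threshold sweep.

The method dichotomises a cohort at every candidate neutrophil count on a
grid, tests the separation of the FACED and EFACED severity scores between
the two groups with the Mann-Whitney U test, and selects an operating
threshold among the candidates that are significant on *both* scores while
keeping the two clusters reasonably balanced. Two selection strategies are
provided:

``most_balanced``
    among eligible candidates, maximise the smaller cluster size (ties broken
    toward the higher threshold) — the default;
``highest_significant``
    the largest eligible candidate.

P-values along the grid are raw (no multiple-testing correction): selecting a
cut-off by scanning p-values is subject to minimum-p selection bias, which the
null-model simulations in the test-suite quantify.

The sweep is exposed both as plain functions (:func:`scan_thresholds`,
:func:`select_threshold`, :func:`dichotomize`) and as a scikit-learn
compatible estimator (:class:`ThresholdClusterer`) whose ``fit`` learns
``threshold_`` and whose ``predict`` assigns above/below labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.exceptions import NotFittedError

from .cohort import Cohort

__all__ = [
    "TestResult",
    "ThresholdScan",
    "ClusterAssignment",
    "ThresholdClusterer",
    "mann_whitney_u",
    "scan_thresholds",
    "select_threshold",
    "dichotomize",
]

#: Exact Mann-Whitney enumeration is used when ``n_a * n_b`` does not exceed
#: this and the pooled sample has no ties; otherwise the normal approximation
#: with tie-corrected variance and continuity correction applies.
EXACT_LIMIT = 400


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample test."""

    statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int


def _clean(x) -> np.ndarray:
    a = pd.to_numeric(pd.Series(x), errors="coerce").to_numpy(float)
    return a[~np.isnan(a)]


def mann_whitney_u(sample_a, sample_b) -> TestResult:
    """Two-sided Mann-Whitney U test (midranks for ties).

    Exact enumeration when ``n_a * n_b <= 400`` and the pooled sample has no
    ties; otherwise the normal approximation with tie-corrected variance and
    continuity correction. The statistic reported is U for ``sample_a``.
    """
    a, b = _clean(sample_a), _clean(sample_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("Mann-Whitney U undefined for an empty sample")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(a) * len(b) <= EXACT_LIMIT) and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=f"mann-whitney-u/{method}",
        n_a=len(a),
        n_b=len(b),
    )


@dataclass
class ThresholdScan:
    """Per-candidate results of the sweep.

    ``p_faced`` / ``p_efaced`` are NaN for candidates where either side of the
    split has fewer than 2 patients (test undefined by policy).
    """

    grid: np.ndarray
    p_faced: np.ndarray
    p_efaced: np.ndarray
    n_above: np.ndarray
    n_below: np.ndarray
    alpha: float
    n_total: int
    selected: float | None = None
    strategy: str | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("scan grid must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.grid,
                "p_faced": self.p_faced,
                "p_efaced": self.p_efaced,
                "n_above": self.n_above,
                "n_below": self.n_below,
            }
        )


def _asymptotic_sweep(
    neutro_sorted: np.ndarray,
    rank_prefix: np.ndarray,
    tie_term: float,
    grid: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised tie-corrected normal-approximation p for every candidate.

    ``rank_prefix[i]`` is the sum of midranks of the ``i`` smallest neutrophil
    records. The pooled score sample (hence the tie correction) is the same at
    every split, so ranks are computed once and each candidate costs O(1).
    Matches ``scipy.stats.mannwhitneyu(method="asymptotic")`` exactly.
    """
    n = len(neutro_sorted)
    total = rank_prefix[-1]
    n_below = np.searchsorted(neutro_sorted, grid, side="left")
    n_above = n - n_below
    r_above = total - rank_prefix[n_below]
    n1, n0 = n_above.astype(float), n_below.astype(float)
    u1 = r_above - n1 * (n1 + 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.maximum(u1, n1 * n0 - u1)
        mu = n1 * n0 / 2.0
        var = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
        sd = np.sqrt(var)
        z = (u - mu - 0.5) / sd
        p = np.minimum(2.0 * stats.norm.sf(z), 1.0)
    p = np.where(sd > 0, p, 1.0)
    p = np.where(np.minimum(n_above, n_below) >= 2, p, np.nan)
    return p, n_above, n_below


def default_grid(neutrophils, step: float = 10.0, quantiles=(0.05, 0.95)) -> np.ndarray:
    """Candidate thresholds every ``step`` cells/µL across the central range."""
    x = _clean(neutrophils)
    lo, hi = np.quantile(x, quantiles)
    lo = np.ceil(lo / step) * step
    hi = np.floor(hi / step) * step
    grid = np.arange(lo, hi + step / 2, step)
    if len(grid) == 0:
        raise ValueError("empty candidate grid: neutrophil range narrower than step")
    return grid


def scan_thresholds(
    scored: Cohort | pd.DataFrame,
    grid: Sequence[float] | None = None,
    grid_step: float = 10.0,
    alpha: float = 0.05,
) -> ThresholdScan:
    """Sweep candidate cut-offs, testing FACED and EFACED separation at each.

    ``scored`` must carry ``neutrophils``, ``faced`` and ``efaced`` columns
    (see :func:`neutroclust.scores.score_cohort`). Only records with all
    three non-missing enter the sweep. Raw, unadjusted p-values are recorded.
    """
    df = scored.data if isinstance(scored, Cohort) else scored
    for col in ("neutrophils", "faced", "efaced"):
        if col not in df.columns:
            raise ValueError(f"scan requires a '{col}' column")
    sub = df[["neutrophils", "faced", "efaced"]].apply(pd.to_numeric, errors="coerce")
    sub = sub.dropna()
    if len(sub) < 4:
        raise ValueError("need at least 4 complete records to scan")
    if grid is None:
        grid_arr = default_grid(sub["neutrophils"], step=grid_step)
    else:
        grid_arr = np.unique(np.asarray(list(grid), dtype=float))
        if len(grid_arr) == 0:
            raise ValueError("empty candidate grid")

    order = np.argsort(sub["neutrophils"].to_numpy(), kind="stable")
    neutro_sorted = sub["neutrophils"].to_numpy()[order]
    n = len(sub)

    results = {}
    for name in ("faced", "efaced"):
        vals = sub[name].to_numpy(float)
        ranks = stats.rankdata(vals)
        _, counts = np.unique(vals, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts))
        exact_eligible = tie_term == 0.0
        prefix = np.concatenate([[0.0], np.cumsum(ranks[order])])
        p, n_above, n_below = _asymptotic_sweep(neutro_sorted, prefix, tie_term, grid_arr)
        if exact_eligible:
            # re-test small splits with exact enumeration
            for i, t in enumerate(grid_arr):
                na, nb = int(n_above[i]), int(n_below[i])
                if min(na, nb) >= 2 and na * nb <= EXACT_LIMIT:
                    mask = sub["neutrophils"].to_numpy() >= t
                    p[i] = mann_whitney_u(vals[mask], vals[~mask]).p_value
        results[name] = (p, n_above, n_below)

    p_faced, n_above, n_below = results["faced"]
    p_efaced = results["efaced"][0]
    return ThresholdScan(
        grid=grid_arr,
        p_faced=p_faced,
        p_efaced=p_efaced,
        n_above=n_above.astype(int),
        n_below=n_below.astype(int),
        alpha=alpha,
        n_total=n,
    )


def select_threshold(
    scan: ThresholdScan,
    strategy: str = "most_balanced",
    alpha: float | None = None,
    min_fraction: float = 0.25,
) -> float | None:
    """Pick the operating threshold from a populated scan.

    Eligible candidates have ``p_faced < alpha`` AND ``p_efaced < alpha`` AND
    a smaller-cluster fraction of at least ``min_fraction``. Returns ``None``
    when no candidate qualifies.
    """
    if strategy not in ("most_balanced", "highest_significant"):
        raise ValueError(f"unknown selection strategy '{strategy}'")
    alpha = scan.alpha if alpha is None else alpha
    n = scan.n_total
    minority = np.minimum(scan.n_above, scan.n_below) / max(n, 1)
    with np.errstate(invalid="ignore"):
        eligible = (
            ~np.isnan(scan.p_faced)
            & ~np.isnan(scan.p_efaced)
            & (scan.p_faced < alpha)
            & (scan.p_efaced < alpha)
            & (minority >= min_fraction)
        )
    if not eligible.any():
        scan.selected, scan.strategy = None, strategy
        return None
    idx = np.flatnonzero(eligible)
    if strategy == "highest_significant":
        pick = idx[-1]
    else:  # most_balanced; ties -> higher threshold (grid is increasing)
        size = np.minimum(scan.n_above, scan.n_below)[idx]
        best = size.max()
        pick = idx[size == best][-1]
    scan.selected = float(scan.grid[pick])
    scan.strategy = strategy
    return scan.selected


@dataclass
class ClusterAssignment:
    """Patient-id -> {above, below, unassigned} mapping at a threshold."""

    labels: pd.Series  # index: patient_id
    threshold: float

    def label_frame(self, df: pd.DataFrame) -> pd.Series:
        """Labels aligned to the rows of ``df`` via ``patient_id``."""
        return df["patient_id"].map(self.labels)

    @property
    def n_above(self) -> int:
        return int((self.labels == "above").sum())

    @property
    def n_below(self) -> int:
        return int((self.labels == "below").sum())

    @property
    def n_unassigned(self) -> int:
        return int((self.labels == "unassigned").sum())


def dichotomize(cohort: Cohort | pd.DataFrame, threshold: float) -> ClusterAssignment:
    """Assign each patient above (neutrophils >= threshold, boundary
    inclusive) or below; missing neutrophils are unassigned."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    x = pd.to_numeric(df["neutrophils"], errors="coerce")
    labels = pd.Series(
        np.where(x.isna(), "unassigned", np.where(x >= threshold, "above", "below")),
        index=pd.Index(df["patient_id"], name="patient_id"),
        name="cluster",
    )
    return ClusterAssignment(labels=labels, threshold=float(threshold))


class ThresholdClusterer(BaseEstimator):
    """Scikit-learn style estimator for the neutrophil cut-point sweep.

    ``fit`` expects a DataFrame with ``neutrophils``, ``faced`` and ``efaced``
    columns, runs the Mann-Whitney sweep and stores the learned cut-off;
    ``predict`` labels new records ``above`` / ``below`` / ``unassigned``.

    Parameters
    ----------
    grid : sequence of float, optional
        Explicit candidate thresholds (cells/µL). Default: every
        ``grid_step`` cells/µL between the 5th and 95th percentile of the
        observed neutrophils.
    grid_step : float
        Grid spacing when ``grid`` is not given.
    alpha : float
        Significance level for both score tests.
    strategy : {"most_balanced", "highest_significant"}
    min_fraction : float
        Minimum fraction of patients in the smaller cluster.

    Attributes
    ----------
    scan_ : ThresholdScan
    threshold_ : float or None
        Selected cut-off; ``None`` when no candidate met the criteria.
    labels_ : ndarray of str
        Cluster labels of the training records.
    """

    def __init__(
        self,
        grid=None,
        grid_step: float = 10.0,
        alpha: float = 0.05,
        strategy: str = "most_balanced",
        min_fraction: float = 0.25,
    ):
        self.grid = grid
        self.grid_step = grid_step
        self.alpha = alpha
        self.strategy = strategy
        self.min_fraction = min_fraction

    def fit(self, X: pd.DataFrame, y=None) -> "ThresholdClusterer":
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        self.scan_ = scan_thresholds(
            X, grid=self.grid, grid_step=self.grid_step, alpha=self.alpha
        )
        self.threshold_ = select_threshold(
            self.scan_,
            strategy=self.strategy,
            alpha=self.alpha,
            min_fraction=self.min_fraction,
        )
        self.n_features_in_ = X.shape[1]
        self.labels_ = self._label(X)
        return self

    def _label(self, X: pd.DataFrame) -> np.ndarray:
        if self.threshold_ is None:
            return np.full(len(X), "unassigned", dtype=object)
        x = pd.to_numeric(X["neutrophils"], errors="coerce")
        return np.where(
            x.isna(), "unassigned", np.where(x >= self.threshold_, "above", "below")
        ).astype(object)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "scan_"):
            raise NotFittedError("ThresholdClusterer is not fitted yet")
        if self.threshold_ is None:
            raise ValueError("no threshold was selected during fit")
        return self._label(X)

    def fit_predict(self, X: pd.DataFrame, y=None) -> np.ndarray:
        return self.fit(X).labels_
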