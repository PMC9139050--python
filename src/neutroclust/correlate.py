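"""Pearson correlation matrices, overall and per neutrophil cluster.

Pairwise complete-case correlations between severity scores, exacerbation
counts, lung function and neutrophil counts; entries with p > 0.05 are
flagged (reported but masked), mirroring the usual dot-matrix display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort
from .threshold import ClusterAssignment

__all__ = ["CorrelationMatrix", "pearson", "correlation_matrix", "DEFAULT_VARIABLES"]

#: Default variable list for the matrix.
DEFAULT_VARIABLES: tuple[str, ...] = (
    "neutrophils",
    "faced",
    "efaced",
    "bsi",
    "exacerbations_prior_year",
    "hospitalizations_prior_year",
    "fev1_pct",
    "fvc_pct",
    "fev1_fvc",
)


def pearson(x, y) -> tuple[float, float, int]:
    """Sample Pearson r with the two-sided t-transform p-value.

    Returns ``(r, p, n)`` over complete pairs. Raises on fewer than 3
    complete pairs or zero variance in either variable.
    """
    xs = pd.to_numeric(pd.Series(x), errors="coerce")
    ys = pd.to_numeric(pd.Series(y), errors="coerce")
    ok = xs.notna() & ys.notna()
    xa, ya = xs[ok].to_numpy(float), ys[ok].to_numpy(float)
    n = len(xa)
    if n < 3:
        raise ValueError("Pearson correlation needs >= 3 complete pairs")
    if xa.std() == 0.0 or ya.std() == 0.0:
        raise ValueError("Pearson correlation undefined for constant input")
    res = sps.pearsonr(xa, ya)
    return float(res.statistic), float(res.pvalue), n


@dataclass
class CorrelationMatrix:
    """Symmetric r/p/n matrices over a variable list for one subset."""

    variables: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    subset: str = "all"

    def nonsignificant_mask(self, alpha: float = 0.05) -> pd.DataFrame:
        """True where the correlation should be masked (p > alpha);
        the diagonal is always masked."""
        mask = self.p > alpha
        np.fill_diagonal(mask.values, True)
        return mask


def correlation_matrix(
    cohort: Cohort | pd.DataFrame,
    variables: Sequence[str] = DEFAULT_VARIABLES,
    subset: str = "all",
    assignment: ClusterAssignment | None = None,
) -> CorrelationMatrix:
    """Pairwise-complete Pearson matrix for ``subset`` in
    {"all", "above", "below"} (the latter two require ``assignment``)."""
    df = cohort.data if isinstance(cohort, Cohort) else cohort
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise ValueError(f"variables not in cohort: {missing}")
    if subset != "all":
        if assignment is None:
            raise ValueError("cluster subset requires an assignment")
        df = df[assignment.label_frame(df) == subset]
    if len(df) < 3:
        raise ValueError(f"subset '{subset}' has fewer than 3 patients")
    k = len(variables)
    r = np.eye(k)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        xi = pd.to_numeric(df[variables[i]], errors="coerce")
        n[i, i] = int(xi.notna().sum())
        for j in range(i + 1, k):
            rij, pij, nij = pearson(xi, df[variables[j]])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
            n[i, j] = n[j, i] = nij
    idx = pd.Index(variables)
    return CorrelationMatrix(
        variables=tuple(variables),
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        subset=subset,
    )
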