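"""Two-cluster characterisation tables with per-variable tests.

Continuous variables are compared with the pooled-variance Student's t test
and summarised as mean (SD); binary/categorical variables with the Pearson
chi-square test (no continuity correction by default) and summarised as
N (%). Each row uses all patients non-missing for that variable (pairwise
complete cases). Subgroup re-analyses (e.g. excluding COPD or chronically
PA-colonized patients) drop the flagged patients before any summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import Cohort
from .threshold import ClusterAssignment, TestResult

__all__ = [
    "VariableSpec",
    "ComparisonRow",
    "ComparisonTable",
    "student_t",
    "chi_square",
    "stars",
    "comparison_table",
    "default_variable_specs",
]


@dataclass(frozen=True)
class VariableSpec:
    """How one cohort variable is summarised and tested."""

    name: str
    kind: str  # continuous | binary | categorical
    units: str = ""
    section: str = ""
    levels: tuple | None = None  # categorical only

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary", "categorical"):
            raise ValueError(f"unknown variable kind '{self.kind}'")


def student_t(sample_a, sample_b) -> TestResult:
    """Two-sided pooled-variance Student's t test (df = n_a + n_b - 2).

    Degenerate convention: zero pooled variance gives p = 1 when the means
    are equal and p = 0 otherwise.
    """
    a = pd.to_numeric(pd.Series(sample_a), errors="coerce").dropna().to_numpy(float)
    b = pd.to_numeric(pd.Series(sample_b), errors="coerce").dropna().to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("Student's t requires >= 2 non-missing values per group")
    sa2 = a.var(ddof=1)
    sb2 = b.var(ddof=1)
    if sa2 == 0.0 and sb2 == 0.0:
        p = 1.0 if a.mean() == b.mean() else 0.0
        t = 0.0 if p == 1.0 else np.inf * np.sign(a.mean() - b.mean())
        return TestResult(float(t), p, "student-t/pooled", len(a), len(b))
    res = sps.ttest_ind(a, b, equal_var=True)
    return TestResult(float(res.statistic), float(res.pvalue), "student-t/pooled", len(a), len(b))


def chi_square(table) -> TestResult:
    """Pearson chi-square on a 2 x k contingency table, no continuity
    correction; df = k - 1. Warns when any expected count is below 5."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (obs < 0).any():
        raise ValueError("contingency counts must be >= 0")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined: a margin of the table is zero")
    stat, p, dof, expected = sps.chi2_contingency(obs, correction=False)
    if (expected < 5).any():
        warnings.warn(
            f"chi-square approximation questionable: {int((expected < 5).sum())} "
            "expected count(s) below 5",
            stacklevel=2,
        )
    n = obs.sum(axis=1)
    return TestResult(float(stat), float(p), f"chi-square/df={dof}", int(n[0]), int(n[-1]))


def stars(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else ''."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p-value outside [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ComparisonRow:
    variable: str
    kind: str
    below_summary: str
    above_summary: str
    below_n: int
    above_n: int
    test: TestResult | None
    section: str = ""

    @property
    def p_value(self) -> float | None:
        return None if self.test is None else self.test.p_value

    @property
    def stars(self) -> str:
        return "" if self.test is None else stars(self.test.p_value)


@dataclass
class ComparisonTable:
    rows: list[ComparisonRow]
    n_below: int
    n_above: int
    exclusion: str = "none"
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": [r.variable for r in self.rows],
                "section": [r.section for r in self.rows],
                "below": [r.below_summary for r in self.rows],
                "above": [r.above_summary for r in self.rows],
                "p": [r.p_value for r in self.rows],
                "stars": [r.stars for r in self.rows],
            }
        )

    def to_markdown(self) -> str:
        head = (
            f"| variable | below (n={self.n_below}) | above (n={self.n_above}) "
            "| p | |\n|---|---|---|---|---|"
        )
        lines = [head]
        for r in self.rows:
            p = "" if r.p_value is None else f"{r.p_value:.3g}"
            lines.append(
                f"| {r.variable} | {r.below_summary} | {r.above_summary} "
                f"| {p} | {r.stars} |"
            )
        return "\n".join(lines)


def _percent(count: int, total: int) -> float:
    return round(100.0 * count / total, 1) if total else float("nan")


def _continuous_row(name, below, above, section) -> ComparisonRow:
    b = pd.to_numeric(below, errors="coerce").dropna()
    a = pd.to_numeric(above, errors="coerce").dropna()
    test = student_t(b, a) if len(b) >= 2 and len(a) >= 2 else None
    fmt = lambda s: f"{s.mean():.1f} ({s.std(ddof=1):.1f})" if len(s) else "-"
    return ComparisonRow(name, "continuous", fmt(b), fmt(a), len(b), len(a), test, section)


def _binary_row(name, below, above, section) -> ComparisonRow:
    b = pd.to_numeric(below, errors="coerce").dropna().astype(int)
    a = pd.to_numeric(above, errors="coerce").dropna().astype(int)
    cb, ca = int(b.sum()), int(a.sum())
    tab = [[cb, len(b) - cb], [ca, len(a) - ca]]
    test = None
    if len(b) and len(a) and not (
        np.asarray(tab).sum(axis=0) == 0
    ).any():
        test = chi_square(tab)
    return ComparisonRow(
        name,
        "binary",
        f"{cb} ({_percent(cb, len(b))})",
        f"{ca} ({_percent(ca, len(a))})",
        len(b),
        len(a),
        test,
        section,
    )


def comparison_table(
    cohort: Cohort | pd.DataFrame,
    assignment: ClusterAssignment,
    specs: Sequence[VariableSpec],
    exclusion: str | None = None,
) -> ComparisonTable:
    """Variable-by-variable below vs above comparison.

    ``exclusion`` names a boolean flag column (e.g. ``"copd"`` or
    ``"pa_colonization"``); flagged patients are dropped before any summary
    and the group sizes / percent denominators shrink accordingly.
    Categorical variables are expanded to one row per level (level vs rest,
    2 x 2 chi-square), matching the registry-table layout.
    """
    df = (cohort.data if isinstance(cohort, Cohort) else cohort).copy()
    missing_cols = [s.name for s in specs if s.name not in df.columns]
    if missing_cols:
        raise ValueError(f"variable specs name absent columns: {missing_cols}")
    labels = assignment.label_frame(df)
    if exclusion is not None:
        if exclusion not in df.columns:
            raise ValueError(f"exclusion flag '{exclusion}' not in cohort")
        keep = ~(pd.to_numeric(df[exclusion], errors="coerce").fillna(0) == 1)
        df, labels = df[keep], labels[keep]
    below_df = df[labels == "below"]
    above_df = df[labels == "above"]

    rows: list[ComparisonRow] = []
    for spec in specs:
        if spec.kind == "continuous":
            rows.append(
                _continuous_row(spec.name, below_df[spec.name], above_df[spec.name], spec.section)
            )
        elif spec.kind == "binary":
            rows.append(
                _binary_row(spec.name, below_df[spec.name], above_df[spec.name], spec.section)
            )
        else:  # categorical -> one 2x2 row per level
            levels = spec.levels or tuple(
                pd.unique(df[spec.name].dropna())
            )
            for lev in levels:
                b = below_df[spec.name].dropna()
                a = above_df[spec.name].dropna()
                rows.append(
                    _binary_row(
                        f"{spec.name}={lev}",
                        (b == lev).astype(int),
                        (a == lev).astype(int),
                        spec.section,
                    )
                )
    return ComparisonTable(
        rows=rows,
        n_below=len(below_df),
        n_above=len(above_df),
        exclusion=exclusion or "none",
    )


def default_variable_specs() -> list[VariableSpec]:
    """Registry-style variable list: anthropometry, severity, smoking,
    lung function, blood analytes, comorbidities."""
    c, b = "continuous", "binary"
    return [
        VariableSpec("age", c, "years", "anthropometric"),
        VariableSpec("bmi", c, "kg/m2", "anthropometric"),
        VariableSpec("faced", c, "points", "severity"),
        VariableSpec("efaced", c, "points", "severity"),
        VariableSpec("bsi", c, "points", "severity"),
        VariableSpec("exacerbations_prior_year", c, "count", "severity"),
        VariableSpec("hospitalizations_prior_year", c, "count", "severity"),
        VariableSpec("charlson", c, "index", "severity"),
        VariableSpec("radiological_lobes", c, "lobes", "severity"),
        VariableSpec("pa_colonization", b, "", "severity"),
        VariableSpec("asthma", b, "", "severity"),
        VariableSpec("copd", b, "", "severity"),
        VariableSpec(
            "smoking_status", "categorical", "", "smoking", levels=("never", "current", "ex")
        ),
        VariableSpec("pack_years", c, "pack-years", "smoking"),
        VariableSpec("fev1_pct", c, "% pred", "lung function"),
        VariableSpec("fvc_pct", c, "% pred", "lung function"),
        VariableSpec("fev1_fvc", c, "%", "lung function"),
        VariableSpec("dlco_pct", c, "% pred", "lung function"),
        VariableSpec("leukocytes", c, "cells/uL", "blood"),
        VariableSpec("neutrophils", c, "cells/uL", "blood"),
        VariableSpec("lymphocytes", c, "cells/uL", "blood"),
        VariableSpec("eosinophils", c, "cells/uL", "blood"),
        VariableSpec("platelets", c, "cells/uL", "blood"),
        VariableSpec("crp", c, "mg/dL", "blood"),
        VariableSpec("esr", c, "mm/h", "blood"),
        VariableSpec("fibrinogen", c, "mg/dL", "blood"),
        VariableSpec("total_protein", c, "g/dL", "blood"),
        VariableSpec("albumin", c, "g/dL", "blood"),
        VariableSpec("myocardial_infarction", b, "", "comorbidity"),
        VariableSpec("heart_failure", b, "", "comorbidity"),
        VariableSpec("dementia", b, "", "comorbidity"),
        VariableSpec("diabetes", b, "", "comorbidity"),
        VariableSpec("kidney_failure", b, "", "comorbidity"),
    ]
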