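"""Table-driven bronchiectasis severity scores: FACED, EFACED, and BSI.

The scoring engine evaluates ordered band rules over patient fields, so the
point assignments live in data (serialisable to YAML), not in code. Shipped
default tables follow the original index publications:

* FACED (0-7): FEV1 < 50 % pred (2), age > 70 y (2), chronic Pseudomonas
  aeruginosa colonization (1), > 2 affected lobes (1), mMRC dyspnea 3-4 (1).
* EFACED (0-9): FACED plus 2 points for >= 1 hospitalization for exacerbation
  in the prior year.
* BSI (0-26): age, BMI, FEV1, prior hospitalization, exacerbation frequency,
  dyspnea, colonization, and radiological-severity bands.

.. note:: Provenance
   The default point values are shipped as a convenience transcription of the
   original severity-index publications (Martinez-Garcia et al. for FACED and
   E-FACED; Chalmers et al. for the BSI). Verify them against those sources
   before clinical use; corrections are configuration-only. In the shipped BSI
   table, colonization is scored as two additive items (P. aeruginosa: 3;
   other organisms: 1) and the hospital-admission item uses a one-year
   lookback by default (``bsi_lookback_years``), matching registry variables
   that record the previous year only.

A component whose inputs are missing contributes no points and is listed in
``missing_components``; the total is reported only when every component could
be evaluated (no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort

__all__ = [
    "Condition",
    "Rule",
    "Component",
    "PointTable",
    "ScoreBreakdown",
    "ScoreError",
    "faced_table",
    "efaced_table",
    "bsi_table",
    "default_tables",
    "score",
    "score_frame",
    "score_cohort",
    "categorize",
    "categorize_frame",
    "dichotomize_score",
    "save_table",
    "load_table",
    "CATEGORY_BOUNDS",
]


class ScoreError(ValueError):
    """Invalid point table, out-of-range input, or out-of-range total."""


#: Hard validity domains for score inputs (inclusive bounds, NaN allowed).
_FIELD_DOMAINS: dict[str, tuple[float, float]] = {
    "dyspnea_mmrc": (0, 4),
    "age": (0, 130),
    "bmi": (5, 100),
    "fev1_pct": (0, 300),
    "radiological_lobes": (0, 6),
    "exacerbations_prior_year": (0, np.inf),
    "hospitalizations_prior_year": (0, np.inf),
}


@dataclass(frozen=True)
class Condition:
    """Atomic predicate over one patient field."""

    field: str
    op: str  # lt | le | gt | ge | eq | is_true | is_false
    value: Any = None

    def mask(self, col: pd.Series) -> np.ndarray:
        x = pd.to_numeric(col, errors="coerce").to_numpy(float)
        if self.op == "lt":
            return x < self.value
        if self.op == "le":
            return x <= self.value
        if self.op == "gt":
            return x > self.value
        if self.op == "ge":
            return x >= self.value
        if self.op == "eq":
            return x == self.value
        if self.op == "is_true":
            return x == 1
        if self.op == "is_false":
            return x == 0
        raise ScoreError(f"unknown condition op '{self.op}'")


@dataclass(frozen=True)
class Rule:
    """One band: points awarded when the conditions hold.

    ``mode`` is ``"all"`` (conjunction, the default) or ``"any"``
    (disjunction, e.g. ">= 3 lobes OR cystic disease").
    An empty condition list is the catch-all band.
    """

    points: int
    conditions: tuple[Condition, ...] = ()
    mode: str = "all"

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        if not self.conditions:
            return np.ones(len(df), dtype=bool)
        masks = [c.mask(df[c.field]) for c in self.conditions]
        return np.logical_and.reduce(masks) if self.mode == "all" else np.logical_or.reduce(masks)


@dataclass(frozen=True)
class Component:
    """Named score component: ordered bands, first match wins."""

    name: str
    rules: tuple[Rule, ...]

    @property
    def fields(self) -> tuple[str, ...]:
        seen: list[str] = []
        for r in self.rules:
            for c in r.conditions:
                if c.field not in seen:
                    seen.append(c.field)
        return tuple(seen)

    @property
    def max_points(self) -> int:
        return max(r.points for r in self.rules)

    def evaluate(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised points + missing mask for every row of ``df``."""
        for f in self.fields:
            if f not in df.columns:
                raise ScoreError(f"component '{self.name}' needs absent column '{f}'")
            dom = _FIELD_DOMAINS.get(f)
            if dom is not None:
                x = pd.to_numeric(df[f], errors="coerce").to_numpy(float)
                bad = (x < dom[0]) | (x > dom[1])
                if bad.any():
                    raise ScoreError(
                        f"field '{f}' out of range [{dom[0]}, {dom[1]}] "
                        f"in {int(bad.sum())} record(s)"
                    )
        missing = np.zeros(len(df), dtype=bool)
        for f in self.fields:
            missing |= pd.to_numeric(df[f], errors="coerce").isna().to_numpy()
        pts = np.zeros(len(df), dtype=float)
        unmatched = np.ones(len(df), dtype=bool)
        for rule in self.rules:
            hit = rule.mask(df) & unmatched
            pts[hit] = rule.points
            unmatched &= ~hit
        pts[missing] = np.nan
        return pts, missing


@dataclass(frozen=True)
class PointTable:
    """A full severity index: ordered components and the scale maximum."""

    scale: str
    components: tuple[Component, ...]
    max_total: int
    notes: str = ""

    def __post_init__(self) -> None:
        for comp in self.components:
            if any(r.points < 0 for r in comp.rules):
                raise ScoreError(f"component '{comp.name}': negative points")
            if comp.rules[-1].conditions:
                raise ScoreError(
                    f"component '{comp.name}': last rule must be a catch-all "
                    "(exhaustiveness)"
                )
        total = sum(c.max_points for c in self.components)
        if total != self.max_total:
            raise ScoreError(
                f"{self.scale}: component maxima sum to {total}, "
                f"declared max_total is {self.max_total}"
            )

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "scale": self.scale,
            "max_total": self.max_total,
            "notes": self.notes,
            "components": [
                {
                    "name": c.name,
                    "rules": [
                        {
                            "points": r.points,
                            "mode": r.mode,
                            "conditions": [
                                {"field": q.field, "op": q.op, "value": q.value}
                                for q in r.conditions
                            ],
                        }
                        for r in c.rules
                    ],
                }
                for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PointTable":
        comps = tuple(
            Component(
                name=c["name"],
                rules=tuple(
                    Rule(
                        points=int(r["points"]),
                        mode=r.get("mode", "all"),
                        conditions=tuple(
                            Condition(q["field"], q["op"], q.get("value"))
                            for q in r.get("conditions", [])
                        ),
                    )
                    for r in c["rules"]
                ),
            )
            for c in d["components"]
        )
        return cls(
            scale=d["scale"],
            components=comps,
            max_total=int(d["max_total"]),
            notes=d.get("notes", ""),
        )


@dataclass
class ScoreBreakdown:
    """Per-component points and total for one patient on one scale."""

    scale: str
    points: dict[str, int | None]
    missing_components: list[str] = field(default_factory=list)

    @property
    def total(self) -> int | None:
        """Sum of component points; ``None`` unless all components scored."""
        if self.missing_components:
            return None
        return int(sum(v for v in self.points.values() if v is not None))


# --------------------------------------------------------------------------
# Shipped default tables
# --------------------------------------------------------------------------

_PROVENANCE = (
    "Default bands transcribed from the original severity-index publications; "
    "verify against those sources before clinical use. Table-driven: "
    "corrections are configuration-only."
)


def _band(field_: str, *pairs: tuple[str, Any, int], default: int = 0) -> tuple[Rule, ...]:
    rules = [Rule(points=p, conditions=(Condition(field_, op, v),)) for op, v, p in pairs]
    rules.append(Rule(points=default))
    return tuple(rules)


def faced_table() -> PointTable:
    """FACED: FEV1, Age, Colonization, Extension, Dyspnea; 0-7."""
    return PointTable(
        scale="FACED",
        max_total=7,
        notes=_PROVENANCE,
        components=(
            Component("fev1", _band("fev1_pct", ("lt", 50, 2))),
            Component("age", _band("age", ("gt", 70, 2))),
            Component("pa_colonization", _band("pa_colonization", ("is_true", None, 1))),
            Component("extension", _band("radiological_lobes", ("gt", 2, 1))),
            Component("dyspnea", _band("dyspnea_mmrc", ("ge", 3, 1))),
        ),
    )


def efaced_table() -> PointTable:
    """E-FACED: FACED + 2 points for >= 1 hospitalization in the prior year."""
    faced = faced_table()
    exac = Component(
        "exacerbation",
        _band("hospitalizations_prior_year", ("ge", 1, 2)),
    )
    return PointTable(
        scale="EFACED",
        max_total=9,
        notes=_PROVENANCE,
        components=(exac,) + faced.components,
    )


def bsi_table(lookback_years: int = 1) -> PointTable:
    """Bronchiectasis Severity Index; 0-26.

    ``lookback_years`` documents the hospital-admission window the input
    variable covers (the original index used 2 years; registries recording
    the previous year only use 1). The scoring rule itself is unchanged:
    >= 1 admission in the window scores 5 points.
    """
    return PointTable(
        scale="BSI",
        max_total=26,
        notes=_PROVENANCE + f" Hospital-admission lookback: {lookback_years} year(s).",
        components=(
            Component(
                "age",
                _band("age", ("ge", 80, 6), ("ge", 70, 4), ("ge", 50, 2)),
            ),
            Component("bmi", _band("bmi", ("lt", 18.5, 2))),
            Component(
                "fev1",
                _band("fev1_pct", ("lt", 30, 3), ("lt", 50, 2), ("le", 80, 1)),
            ),
            Component(
                "hospitalization",
                _band("hospitalizations_prior_year", ("ge", 1, 5)),
            ),
            Component(
                "exacerbations",
                _band("exacerbations_prior_year", ("ge", 3, 2)),
            ),
            Component(
                "dyspnea",
                _band("dyspnea_mmrc", ("ge", 4, 3), ("ge", 3, 2)),
            ),
            Component("pa_colonization", _band("pa_colonization", ("is_true", None, 3))),
            Component("other_colonization", _band("other_colonization", ("is_true", None, 1))),
            Component(
                "radiology",
                (
                    Rule(
                        points=1,
                        mode="any",
                        conditions=(
                            Condition("radiological_lobes", "ge", 3),
                            Condition("cystic_bronchiectasis", "is_true"),
                        ),
                    ),
                    Rule(points=0),
                ),
            ),
        ),
    )


def default_tables() -> dict[str, PointTable]:
    return {"FACED": faced_table(), "EFACED": efaced_table(), "BSI": bsi_table()}


def save_table(table: PointTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(table.to_dict(), fh, sort_keys=False)


def load_table(path) -> PointTable:
    with open(path, encoding="utf-8") as fh:
        return PointTable.from_dict(yaml.safe_load(fh))


# --------------------------------------------------------------------------
# Scoring
# --------------------------------------------------------------------------

def score_frame(df: pd.DataFrame, table: PointTable) -> tuple[pd.Series, pd.DataFrame]:
    """Score every row of ``df``.

    Returns
    -------
    totals
        Float series; ``NaN`` where any component input was missing.
    points
        One column per component (``NaN`` = missing input).
    """
    pts = {}
    for comp in table.components:
        p, _missing = comp.evaluate(df)
        pts[comp.name] = p
    points = pd.DataFrame(pts, index=df.index)
    totals = points.sum(axis=1, skipna=False)
    return totals, points


def score(record: Mapping[str, Any] | pd.Series, table: PointTable) -> ScoreBreakdown:
    """Score a single patient record (mapping or Series)."""
    df = pd.DataFrame([dict(record)])
    _, points = score_frame(df, table)
    row = points.iloc[0]
    missing = [c for c in points.columns if pd.isna(row[c])]
    vals = {c: (None if pd.isna(row[c]) else int(row[c])) for c in points.columns}
    return ScoreBreakdown(scale=table.scale, points=vals, missing_components=missing)


#: Inclusive category boundaries per scale: (mild hi, moderate hi); severe is
#: the remainder up to max_total.
CATEGORY_BOUNDS: dict[str, tuple[int, int]] = {
    "FACED": (2, 4),  # mild 0-2, moderate 3-4, severe 5-7
    "EFACED": (3, 6),  # mild 0-3, moderate 4-6, severe 7-9
    "BSI": (4, 8),  # mild 0-4, moderate 5-8, severe >= 9
}

_MAX_TOTAL = {"FACED": 7, "EFACED": 9, "BSI": 26}
CATEGORIES = ("mild", "moderate", "severe")


def categorize(total: int, scale: str) -> str:
    """Map an integer total to mild / moderate / severe for the scale."""
    if scale not in CATEGORY_BOUNDS:
        raise ScoreError(f"unknown scale '{scale}'")
    hi = _MAX_TOTAL[scale]
    if not 0 <= total <= hi:
        raise ScoreError(f"{scale} total {total} outside [0, {hi}]")
    mild_hi, mod_hi = CATEGORY_BOUNDS[scale]
    if total <= mild_hi:
        return "mild"
    if total <= mod_hi:
        return "moderate"
    return "severe"


def categorize_frame(totals: pd.Series, scale: str) -> pd.Series:
    """Vectorised :func:`categorize`; NaN totals stay NaN."""
    if scale not in CATEGORY_BOUNDS:
        raise ScoreError(f"unknown scale '{scale}'")
    hi = _MAX_TOTAL[scale]
    x = pd.to_numeric(totals, errors="coerce")
    finite = x.dropna()
    if ((finite < 0) | (finite > hi)).any():
        raise ScoreError(f"{scale} totals outside [0, {hi}]")
    mild_hi, mod_hi = CATEGORY_BOUNDS[scale]
    out = pd.Series(
        np.select(
            [x <= mild_hi, x <= mod_hi, x <= hi],
            ["mild", "moderate", "severe"],
            default=None,
        ),
        index=totals.index,
        dtype=object,
    )
    out[x.isna()] = None
    return out


def dichotomize_score(total: int, scale: str, cutoff: int) -> bool:
    """True iff ``total >= cutoff`` (e.g. FACED >= 5, EFACED >= 7)."""
    if scale not in _MAX_TOTAL:
        raise ScoreError(f"unknown scale '{scale}'")
    hi = _MAX_TOTAL[scale]
    if not 0 <= cutoff <= hi:
        raise ScoreError(f"cutoff {cutoff} outside {scale} range [0, {hi}]")
    if not 0 <= total <= hi:
        raise ScoreError(f"{scale} total {total} outside [0, {hi}]")
    return total >= cutoff


def score_cohort(
    cohort: Cohort | pd.DataFrame,
    tables: Mapping[str, PointTable] | None = None,
) -> pd.DataFrame:
    """Return a copy of the cohort frame with score and category columns.

    Adds ``faced``, ``efaced``, ``bsi`` (float; NaN when incomplete) and
    ``faced_cat``, ``efaced_cat``, ``bsi_cat``.
    """
    df = cohort.data.copy() if isinstance(cohort, Cohort) else cohort.copy()
    tables = dict(tables) if tables is not None else default_tables()
    for scale, col in (("FACED", "faced"), ("EFACED", "efaced"), ("BSI", "bsi")):
        totals, _ = score_frame(df, tables[scale])
        df[col] = totals
        df[f"{col}_cat"] = categorize_frame(totals, scale)
    return df
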