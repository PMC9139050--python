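"""Config-driven orchestration of the full cluster-phenotyping analysis.

Stage order: load/generate cohort -> severity scoring -> threshold scan ->
threshold selection -> dichotomisation -> comparison tables (with subgroup
exclusions) -> severity-category histograms -> correlation matrices ->
confounder-adjusted logistic associations -> report bundle with a
machine-readable manifest. Every artifact is a pure function of
(input, config, seed); when no threshold qualifies, the pipeline halts after
the scan stage and reports that no downstream tables were produced.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .associate import SCORE_CUTOFFS, LogisticFit, adjusted_association
from .cohort import Cohort, read_cohort, write_cohort
from .compare import ComparisonTable, chi_square, comparison_table, default_variable_specs, stars
from .correlate import DEFAULT_VARIABLES, CorrelationMatrix, correlation_matrix
from .scores import CATEGORIES, score_cohort
from .simulate import GeneratorConfig, generate_cohort
from .threshold import (
    ClusterAssignment,
    ThresholdScan,
    dichotomize,
    scan_thresholds,
    select_threshold,
)

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "CategoryHistogram",
    "run_pipeline",
    "percentage",
    "category_histogram",
]


def percentage(count: int, total: int, decimals: int = 1) -> float:
    """``100 * count / total`` with half-up rounding to ``decimals``."""
    if total <= 0:
        raise ValueError("total must be a positive integer")
    if not 0 <= count <= total:
        raise ValueError("count must satisfy 0 <= count <= total")
    exact = Decimal(100) * Decimal(count) / Decimal(total)
    q = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CategoryHistogram:
    """Mild/moderate/severe proportions per cluster for one scale."""

    scale: str
    proportions: pd.DataFrame  # index: below/above; columns: mild/moderate/severe
    counts: pd.DataFrame
    p_value: float
    stars: str

    def to_frame(self) -> pd.DataFrame:
        out = self.proportions.copy()
        out["p"] = self.p_value
        out["stars"] = self.stars
        return out


def category_histogram(
    scored: Cohort | pd.DataFrame,
    assignment: ClusterAssignment,
    scale: str,
) -> CategoryHistogram:
    """Per-cluster severity-category proportions plus a 2 x 3 chi-square."""
    df = scored.data if isinstance(scored, Cohort) else scored
    cat_col = f"{scale.lower()}_cat"
    if cat_col not in df.columns:
        raise ValueError(f"column '{cat_col}' missing; score the cohort first")
    labels = assignment.label_frame(df)
    counts = {}
    for grp in ("below", "above"):
        cats = df.loc[(labels == grp).to_numpy(), cat_col].dropna()
        if len(cats) == 0:
            raise ValueError(f"cluster '{grp}' has no complete-score patients")
        counts[grp] = [int((cats == c).sum()) for c in CATEGORIES]
    cnt = pd.DataFrame(counts, index=list(CATEGORIES)).T
    props = cnt.div(cnt.sum(axis=1), axis=0)
    # drop all-zero category columns before the chi-square (zero margins)
    tab = cnt.loc[:, cnt.sum(axis=0) > 0]
    test = chi_square(tab.to_numpy())
    return CategoryHistogram(
        scale=scale.upper(),
        proportions=props,
        counts=cnt,
        p_value=test.p_value,
        stars=stars(test.p_value),
    )


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one analysis run.

    Exactly one of ``input_path`` / ``generator`` must be set.
    """

    input_path: str | None = None
    generator: GeneratorConfig | None = None
    grid: list[float] | None = None
    grid_step: float = 10.0
    alpha: float = 0.05
    strategy: str = "most_balanced"
    min_fraction: float = 0.25
    cutoffs: dict[str, int] = field(default_factory=lambda: dict(SCORE_CUTOFFS))
    exclusions: list[str] = field(default_factory=lambda: ["copd", "pa_colonization"])
    correlation_variables: list[str] = field(default_factory=lambda: list(DEFAULT_VARIABLES))
    outdir: str = "neutroclust_out"
    seed: int = 0
    make_plots: bool = True

    def validate(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly inside (0, 1)")
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one of input_path / generator must be set")
        if not 0.0 <= self.min_fraction < 0.5:
            raise ValueError("min_fraction must lie in [0, 0.5)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        cfg = cls(**raw)
        if gen is not None:
            cfg.generator = GeneratorConfig(**gen)
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(dataclasses.asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class ReportBundle:
    """All pipeline outputs plus the manifest written to disk."""

    config: PipelineConfig
    cohort: Cohort
    scored: pd.DataFrame
    scan: ThresholdScan
    selected_threshold: float | None
    assignment: ClusterAssignment | None = None
    tables: dict[str, ComparisonTable] = field(default_factory=dict)
    histograms: dict[str, CategoryHistogram] = field(default_factory=dict)
    correlations: dict[str, CorrelationMatrix] = field(default_factory=dict)
    fits: dict[str, LogisticFit] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    @property
    def halted(self) -> bool:
        return self.selected_threshold is None


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all stages and write the report bundle under ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": [],
        "warnings": [],
        "stages": [],
    }

    def _write(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        manifest["outputs"].append(name)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # stage: input
        if config.generator is not None:
            gen = dataclasses.replace(config.generator, seed=config.seed)
            cohort = generate_cohort(gen)
        else:
            cohort = read_cohort(config.input_path)
        manifest["stages"].append({"stage": "input", "n_patients": len(cohort)})
        _write("cohort.csv", lambda p: write_cohort(cohort, p))

        # stage: scoring
        scored = score_cohort(cohort)
        _write(
            "scored.csv",
            lambda p: scored.to_csv(p, index=False, float_format="%.12g"),
        )
        manifest["stages"].append(
            {"stage": "score", "n_complete_faced": int(scored["faced"].notna().sum())}
        )

        # stage: scan + selection
        scan = scan_thresholds(
            scored, grid=config.grid, grid_step=config.grid_step, alpha=config.alpha
        )
        selected = select_threshold(
            scan,
            strategy=config.strategy,
            alpha=config.alpha,
            min_fraction=config.min_fraction,
        )
        _write("scan.csv", lambda p: scan.to_frame().to_csv(p, index=False))
        manifest["stages"].append(
            {
                "stage": "scan",
                "n_candidates": int(len(scan.grid)),
                "selected_threshold": selected,
                "strategy": config.strategy,
            }
        )
        bundle = ReportBundle(
            config=config,
            cohort=cohort,
            scored=scored,
            scan=scan,
            selected_threshold=selected,
            manifest=manifest,
        )
        if config.make_plots:
            from . import plots

            _write("scan.png", lambda p: plots.plot_scan(scan, p))

        if selected is None:
            manifest["halted"] = True
            manifest["reason"] = "no threshold met the significance/balance criteria"
            _write_manifest(outdir, manifest, caught)
            return bundle
        manifest["halted"] = False

        # stage: dichotomise + comparisons
        assignment = dichotomize(scored, selected)
        bundle.assignment = assignment
        specs = default_variable_specs()
        for excl in [None] + list(config.exclusions):
            key = excl or "none"
            table = comparison_table(scored, assignment, specs, exclusion=excl)
            bundle.tables[key] = table
            _write(
                f"comparison_{key}.csv",
                lambda p, t=table: t.to_frame().to_csv(p, index=False),
            )
        manifest["stages"].append(
            {
                "stage": "compare",
                "n_above": assignment.n_above,
                "n_below": assignment.n_below,
                "above_percent": percentage(assignment.n_above, assignment.n_above + assignment.n_below, 1),
            }
        )

        # stage: category histograms
        for scale in ("FACED", "EFACED", "BSI"):
            hist = category_histogram(scored, assignment, scale)
            bundle.histograms[scale] = hist
            _write(
                f"categories_{scale.lower()}.csv",
                lambda p, h=hist: h.to_frame().to_csv(p),
            )
        if config.make_plots:
            _write(
                "categories.png",
                lambda p: plots.plot_category_histograms(bundle.histograms, p),
            )

        # stage: correlations
        for subset in ("all", "above", "below"):
            cm = correlation_matrix(
                scored,
                variables=config.correlation_variables,
                subset=subset,
                assignment=assignment,
            )
            bundle.correlations[subset] = cm
            _write(f"correlation_r_{subset}.csv", lambda p, c=cm: c.r.to_csv(p))
            _write(f"correlation_p_{subset}.csv", lambda p, c=cm: c.p.to_csv(p))
            if config.make_plots:
                _write(
                    f"correlation_{subset}.png",
                    lambda p, c=cm: plots.plot_correlation(c, p),
                )

        # stage: adjusted associations
        for scale, cutoff in config.cutoffs.items():
            fit = adjusted_association(scored, assignment, scale, cutoff=cutoff)
            bundle.fits[scale] = fit
            _write(
                f"logistic_{scale.lower()}.csv",
                lambda p, f=fit: f.summary().to_csv(p, index=False),
            )
            if config.make_plots:
                _write(
                    f"forest_{scale.lower()}.png",
                    lambda p, f=fit, s=scale: plots.plot_forest(f, p, title=f"{s} >= {cutoff}"),
                )
        manifest["stages"].append(
            {
                "stage": "associate",
                "headline_or": {
                    s: float(f.term("neutrophils_above")["or"]) for s, f in bundle.fits.items()
                },
                "separation_flags": {s: f.separation for s, f in bundle.fits.items()},
            }
        )

        _write_manifest(outdir, manifest, caught)
    return bundle


def _write_manifest(outdir: Path, manifest: dict, caught) -> None:
    manifest["warnings"] = sorted({str(w.message) for w in caught})
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(manifest), fh, indent=2)
    manifest["outputs"].append("manifest.json")
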