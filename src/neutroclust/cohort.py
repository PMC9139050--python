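"""Patient-level cohort container and CSV round-trip.

A cohort is a thin wrapper around a :class:`pandas.DataFrame` with one row per
patient and a fixed, documented column schema. All downstream stages (scoring,
threshold scanning, comparison tables, regression) consume this frame; missing
clinical values are plain ``NaN`` / ``NA`` cells and are never imputed.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical column order. Unknown columns in an input file are preserved
#: (appended after these) and passed through untouched.
COLUMNS: tuple[str, ...] = (
    "patient_id",
    "age",
    "bmi",
    "fev1_pct",
    "fvc_pct",
    "fev1_fvc",
    "dlco_pct",
    "neutrophils",
    "leukocytes",
    "lymphocytes",
    "eosinophils",
    "platelets",
    "crp",
    "esr",
    "fibrinogen",
    "total_protein",
    "albumin",
    "exacerbations_prior_year",
    "hospitalizations_prior_year",
    "dyspnea_mmrc",
    "radiological_lobes",
    "cystic_bronchiectasis",
    "pa_colonization",
    "other_colonization",
    "copd",
    "asthma",
    "smoking_status",
    "pack_years",
    "charlson",
    "myocardial_infarction",
    "heart_failure",
    "dementia",
    "diabetes",
    "kidney_failure",
)

#: Columns holding 0/1 flags.
BOOLEAN_COLUMNS: tuple[str, ...] = (
    "cystic_bronchiectasis",
    "pa_colonization",
    "other_colonization",
    "copd",
    "asthma",
    "myocardial_infarction",
    "heart_failure",
    "dementia",
    "diabetes",
    "kidney_failure",
)

#: Integer-valued columns (counts and ordinal grades).
INTEGER_COLUMNS: tuple[str, ...] = (
    "exacerbations_prior_year",
    "hospitalizations_prior_year",
    "dyspnea_mmrc",
    "radiological_lobes",
    "charlson",
)

SMOKING_LEVELS: tuple[str, ...] = ("never", "current", "ex")

#: Columns added by downstream stages; recognised on re-import.
DERIVED_COLUMNS: tuple[str, ...] = (
    "faced",
    "faced_cat",
    "efaced",
    "efaced_cat",
    "bsi",
    "bsi_cat",
    "lymphocytes_pct",
    "eosinophils_pct",
)


class CohortError(ValueError):
    """Malformed cohort data (duplicate ids, invalid values, bad rows)."""


@dataclass
class Cohort:
    """An ordered collection of patient records.

    Parameters
    ----------
    data
        One row per patient. Must contain a unique ``patient_id`` column.
    provenance
        Free-text label describing where the cohort came from (file path,
        generator config hash, ...).
    """

    data: pd.DataFrame
    provenance: str = field(default="unspecified")

    def __post_init__(self) -> None:
        if "patient_id" not in self.data.columns:
            raise CohortError("cohort frame must contain a 'patient_id' column")
        ids = self.data["patient_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique()[:5].tolist()
            raise CohortError(f"duplicate patient_id values: {dupes}")
        both = self.data.get("neutrophils"), self.data.get("leukocytes")
        if both[0] is not None and both[1] is not None:
            bad = (both[0] > both[1]).fillna(False)
            if bad.any():
                raise CohortError(
                    f"{int(bad.sum())} records have neutrophils > leukocytes"
                )

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        a, b = self.data, other.data
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            xa, xb = a[col], b[col]
            if xa.dtype.kind == "f" or xb.dtype.kind == "f":
                fa = pd.to_numeric(xa, errors="coerce").to_numpy(float)
                fb = pd.to_numeric(xb, errors="coerce").to_numpy(float)
                if not np.allclose(fa, fb, rtol=1e-12, atol=0.0, equal_nan=True):
                    return False
            else:
                if not (xa.fillna("__na__") == xb.fillna("__na__")).all():
                    return False
        return True

    def config_hash(self) -> str:
        """Short content hash of the cohort frame (column-order sensitive)."""
        h = hashlib.sha256()
        h.update(",".join(self.data.columns).encode())
        h.update(self.data.to_csv(index=False).encode())
        return h.hexdigest()[:12]


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort to CSV (UTF-8, header row, empty cell = missing).

    Floats are written with 12 significant digits so that a read/write cycle
    round-trips values.
    """
    cohort.data.to_csv(path, index=False, float_format="%.12g", encoding="utf-8")


def read_cohort(path, provenance: str | None = None) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort` (or hand-made).

    Unknown columns trigger a warning but are kept; malformed rows (wrong
    number of fields) raise :class:`CohortError` with the line number.
    """
    try:
        df = pd.read_csv(path, encoding="utf-8", on_bad_lines="error")
    except pd.errors.ParserError as exc:  # pandas reports the line number
        raise CohortError(f"malformed cohort CSV {path}: {exc}") from exc
    unknown = [c for c in df.columns if c not in COLUMNS + DERIVED_COLUMNS]
    if unknown:
        warnings.warn(
            f"unknown cohort columns preserved as pass-through: {unknown}",
            stacklevel=2,
        )
    for col in BOOLEAN_COLUMNS + INTEGER_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return Cohort(df, provenance=provenance or str(path))
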