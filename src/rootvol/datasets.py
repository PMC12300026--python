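"""Cohort table I/O, the bundled 27-molar reference cohort, and consistency checks.

CSV schema (RFC 4180, dot decimal, UTF-8), one row per case:

required
    ``case_id`` and the eight linear measurements (mm)
    ``{pr,cbct}_{mesial,distal}_{length,width}_mm``
optional
    ``cbct_mesial_depth_mm``, ``cbct_distal_depth_mm`` (bucco-lingual depth,
    CBCT only), ``true_volume_mm3`` (segmentation ground truth) and the
    derived columns ``pr_surface_mm2``, ``cbct_surface_mm2``,
    ``projection_factor``, ``applied_volume_pr_mm3``,
    ``cuboid_volume_cbct_mm3`` carried for cross-validation of a published
    table.

The bundled cohort is the published 27-case reference table.  Its per-case
depths were never published, so the CBCT cuboid-volume column is carried as
data and flagged non-recomputable; every other derived column re-derives from
the base measurements to print precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import geometry
from .calibration import CaseRecord
from .errors import SchemaError
from .geometry import (
    Modality,
    RootMeasurement2D,
    RootMeasurement3D,
    ToothMeasurement,
)

__all__ = [
    "BASE_COLUMNS",
    "OPTIONAL_COLUMNS",
    "CohortTable",
    "ColumnValidationReport",
    "load_cohort",
    "write_cohort",
    "validate_columns",
    "summary_stats",
]

BASE_COLUMNS = (
    "case_id",
    "pr_mesial_length_mm",
    "pr_mesial_width_mm",
    "pr_distal_length_mm",
    "pr_distal_width_mm",
    "cbct_mesial_length_mm",
    "cbct_mesial_width_mm",
    "cbct_distal_length_mm",
    "cbct_distal_width_mm",
)

OPTIONAL_COLUMNS = (
    "cbct_mesial_depth_mm",
    "cbct_distal_depth_mm",
    "true_volume_mm3",
    "pr_surface_mm2",
    "cbct_surface_mm2",
    "projection_factor",
    "applied_volume_pr_mm3",
    "cuboid_volume_cbct_mm3",
)

_MEASUREMENT_COLUMNS = BASE_COLUMNS[1:] + OPTIONAL_COLUMNS[:3]


@dataclass
class CohortTable:
    """A validated cohort of molar cases backed by a pandas DataFrame."""

    df: pd.DataFrame
    provenance: str = "unknown"

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_cases(self) -> int:
        return len(self.df)

    def has_column(self, name: str) -> bool:
        return name in self.df.columns

    def pr_surfaces(self) -> np.ndarray:
        """Total PR elliptical surfaces recomputed from the linear columns."""
        d = self.df
        return geometry.ellipse_surface(
            d["pr_mesial_length_mm"].to_numpy(), d["pr_mesial_width_mm"].to_numpy()
        ) + geometry.ellipse_surface(
            d["pr_distal_length_mm"].to_numpy(), d["pr_distal_width_mm"].to_numpy()
        )

    def cbct_surfaces(self) -> np.ndarray:
        d = self.df
        return geometry.ellipse_surface(
            d["cbct_mesial_length_mm"].to_numpy(), d["cbct_mesial_width_mm"].to_numpy()
        ) + geometry.ellipse_surface(
            d["cbct_distal_length_mm"].to_numpy(), d["cbct_distal_width_mm"].to_numpy()
        )

    def to_case_records(self) -> list[CaseRecord]:
        records = []
        has_depth = self.has_column("cbct_mesial_depth_mm") and self.has_column(
            "cbct_distal_depth_mm"
        )
        for _, row in self.df.iterrows():
            pr = ToothMeasurement(
                mesial=RootMeasurement2D(row["pr_mesial_length_mm"], row["pr_mesial_width_mm"]),
                distal=RootMeasurement2D(row["pr_distal_length_mm"], row["pr_distal_width_mm"]),
                modality=Modality.PR,
            )
            if has_depth:
                cbct = ToothMeasurement(
                    mesial=RootMeasurement3D(
                        row["cbct_mesial_length_mm"],
                        row["cbct_mesial_width_mm"],
                        row["cbct_mesial_depth_mm"],
                    ),
                    distal=RootMeasurement3D(
                        row["cbct_distal_length_mm"],
                        row["cbct_distal_width_mm"],
                        row["cbct_distal_depth_mm"],
                    ),
                    modality=Modality.CBCT,
                )
            else:
                cbct = ToothMeasurement(
                    mesial=RootMeasurement2D(
                        row["cbct_mesial_length_mm"], row["cbct_mesial_width_mm"]
                    ),
                    distal=RootMeasurement2D(
                        row["cbct_distal_length_mm"], row["cbct_distal_width_mm"]
                    ),
                    modality=Modality.CBCT,
                )
            true_vol = row.get("true_volume_mm3")
            records.append(
                CaseRecord(
                    case_id=str(row["case_id"]),
                    pr=pr,
                    cbct=cbct,
                    true_volume_mm3=None if pd.isna(true_vol) else float(true_vol),
                )
            )
        return records


def _bundled_path():
    return resources.files("rootvol.data") / "molar_cohort.csv"


def load_cohort(source: Union[str, Path, None] = None) -> CohortTable:
    """Load and validate a cohort CSV; ``None`` or "bundled" loads the reference cohort.

    Raises :class:`SchemaError` with row/column context on any violation.
    """
    if source is None or source == "bundled":
        path = _bundled_path()
        provenance = "bundled 27-molar reference cohort"
    else:
        path = Path(source)
        provenance = str(path)
        if not path.exists():
            raise SchemaError(f"cohort file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{provenance}: file is empty") from None
    _validate_schema(df, provenance)
    return CohortTable(df=df, provenance=provenance)


def _validate_schema(df: pd.DataFrame, provenance: str) -> None:
    missing = [c for c in BASE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{provenance}: missing required column(s) {missing}")
    if len(df) == 0:
        raise SchemaError(f"{provenance}: no data rows")
    unknown = [c for c in df.columns if c not in BASE_COLUMNS + OPTIONAL_COLUMNS]
    if unknown:
        raise SchemaError(f"{provenance}: unknown column(s) {unknown}")
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise SchemaError(f"{provenance}: duplicate case_id(s) {dupes}")
    for col in df.columns:
        if col == "case_id":
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{provenance}: non-numeric value in column {col!r}, row {bad[0] + 1}"
            )
        df[col] = numeric
    for col in _MEASUREMENT_COLUMNS:
        if col not in df.columns:
            continue
        vals = df[col]
        bad = df.index[vals.notna() & (vals <= 0)]
        if len(bad):
            raise SchemaError(
                f"{provenance}: non-positive value in column {col!r}, row {bad[0] + 1}"
            )


def write_cohort(table: CohortTable, path: Union[str, Path]) -> None:
    """Write a cohort back to CSV (full precision; round-trips load_cohort)."""
    table.df.to_csv(path, index=False)


@dataclass
class ColumnValidationReport:
    """Recomputation check of a cohort's derived columns.

    ``max_abs_error`` maps each checked derived column to its worst absolute
    deviation from recomputation; ``flagged`` lists (column, row, error)
    triplets beyond the print-rounding tolerance; ``skipped`` names derived
    columns that cannot be recomputed from the available base columns.
    """

    max_abs_error: dict[str, float] = field(default_factory=dict)
    flagged: list[tuple[str, int, float]] = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)
    applied_constant: Optional[float] = None
    applied_constant_spread: Optional[float] = None
    tolerance: float = 0.02

    @property
    def ok(self) -> bool:
        return not self.flagged

    def to_dict(self) -> dict:
        return {
            "max_abs_error": self.max_abs_error,
            "flagged": [
                {"column": c, "row": int(r), "abs_error": e} for c, r, e in self.flagged
            ],
            "skipped": self.skipped,
            "applied_constant": self.applied_constant,
            "applied_constant_spread": self.applied_constant_spread,
            "tolerance": self.tolerance,
        }


def validate_columns(table: CohortTable, tolerance: float = 0.02) -> ColumnValidationReport:
    """Recompute every derivable printed column and report deviations.

    Report-only: nothing raises.  The CBCT cuboid-volume column needs
    per-case depths; without them it is listed under ``skipped``.
    """
    report = ColumnValidationReport(tolerance=tolerance)
    df = table.df

    def check(col: str, recomputed: np.ndarray) -> None:
        printed = df[col].to_numpy(dtype=float)
        err = np.abs(printed - recomputed)
        report.max_abs_error[col] = float(np.max(err))
        for idx in np.nonzero(err > tolerance)[0]:
            report.flagged.append((col, int(idx) + 1, float(err[idx])))

    pr_surface = table.pr_surfaces()
    if table.has_column("pr_surface_mm2"):
        check("pr_surface_mm2", pr_surface)
    if table.has_column("cbct_surface_mm2"):
        check("cbct_surface_mm2", table.cbct_surfaces())
    if table.has_column("projection_factor") and table.has_column("true_volume_mm3"):
        check(
            "projection_factor",
            df["true_volume_mm3"].to_numpy(dtype=float) / pr_surface,
        )
    if table.has_column("applied_volume_pr_mm3") and table.has_column("pr_surface_mm2"):
        # recover the single constant the printed volume column applied
        quotients = df["applied_volume_pr_mm3"].to_numpy(dtype=float) / df[
            "pr_surface_mm2"
        ].to_numpy(dtype=float)
        report.applied_constant = float(np.median(quotients))
        report.applied_constant_spread = float(np.max(quotients) - np.min(quotients))
    if table.has_column("cuboid_volume_cbct_mm3"):
        if table.has_column("cbct_mesial_depth_mm") and table.has_column(
            "cbct_distal_depth_mm"
        ):
            d = df
            recomputed = geometry.ellipse_surface(
                d["cbct_mesial_length_mm"].to_numpy(), d["cbct_mesial_width_mm"].to_numpy()
            ) * d["cbct_mesial_depth_mm"].to_numpy() + geometry.ellipse_surface(
                d["cbct_distal_length_mm"].to_numpy(), d["cbct_distal_width_mm"].to_numpy()
            ) * d["cbct_distal_depth_mm"].to_numpy()
            check("cuboid_volume_cbct_mm3", recomputed)
        else:
            report.skipped.append("cuboid_volume_cbct_mm3")
    return report


def summary_stats(table: CohortTable) -> pd.DataFrame:
    """Mean and sample SD (n-1) of every numeric column, as printed tables do."""
    numeric = table.df.select_dtypes(include=[np.number])
    return pd.DataFrame({"mean": numeric.mean(), "sd": numeric.std(ddof=1)})


def summary_stats_json(table: CohortTable) -> str:
    stats = summary_stats(table)
    return json.dumps(
        {col: {"mean": row["mean"], "sd": row["sd"]} for col, row in stats.iterrows()},
        indent=2,
    )
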