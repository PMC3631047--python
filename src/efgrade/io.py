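"""Reading, validating and writing reader-study tables and reports.

Two CSV schemas are supported:

* quadrant schema -- one row per patient/reader/occasion/slice with the four
  quadrant grades::

      patient_id, reader_id, occasion, slice_index, grade_A, grade_B, grade_C, grade_D

* condensed schema -- one row per patient/reader/occasion carrying a
  pre-summed per-segment total score (the form in which the bundled
  validation study records its data)::

      patient_id, reader_id, occasion, score

The aggregation writer emits a per-segment report::

    patient_id, reader_id, occasion, n_slices, total_score, segment_percent
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .grading import QUADRANTS, SegmentAssessment, SliceAssessment
from .reliability import ReaderStudyTable

__all__ = [
    "StudyConfig",
    "ParseError",
    "read_grade_table",
    "write_grade_table",
    "aggregate_quadrant_table",
    "write_segment_report",
]

QUADRANT_COLUMNS = [
    "patient_id", "reader_id", "occasion", "slice_index",
    "grade_A", "grade_B", "grade_C", "grade_D",
]
CONDENSED_COLUMNS = ["patient_id", "reader_id", "occasion", "score"]


class ParseError(ValueError):
    """Malformed grade-table input; messages carry the offending row."""


@dataclass
class StudyConfig:
    """Run configuration shared by the CLI subcommands.

    ``n_slices_expected`` defaults to 5, the protocol's slice count per
    operative level (one through the disc, two above, two below);
    aggregation warns/errors when a segment deviates.
    """

    n_slices_expected: int = 5
    trace_threshold: float = 0.005
    icc_form: str = "icc2k"
    icc_occasion: str = "first"
    ttest_flavor: str = "pooled"
    occasion_order: tuple[str, ...] | None = None
    output_precision: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices_expected < 1:
            raise ValueError("n_slices_expected must be >= 1")
        if self.output_precision < 0:
            raise ValueError("output_precision must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        """Load from TOML or YAML; keys mirror the field names."""
        path = Path(path)
        if path.suffix.lower() == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        else:
            import yaml

            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "occasion_order" in raw and raw["occasion_order"] is not None:
            raw["occasion_order"] = tuple(str(o) for o in raw["occasion_order"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["occasion_order"] is not None:
            d["occasion_order"] = list(d["occasion_order"])
        return d


def _detect_schema(columns: Iterable[str]) -> str:
    cols = set(columns)
    if cols == set(QUADRANT_COLUMNS):
        return "quadrant"
    if cols == set(CONDENSED_COLUMNS):
        return "condensed"
    raise ParseError(
        f"columns {sorted(cols)} match neither the quadrant schema "
        f"{QUADRANT_COLUMNS} nor the condensed schema {CONDENSED_COLUMNS}"
    )


def read_grade_table(
    path: str | Path,
    schema: str | None = None,
    occasion_order: tuple[str, ...] | None = None,
):
    """Read and validate a grade-table CSV.

    Returns a :class:`~efgrade.reliability.ReaderStudyTable` for the
    condensed schema, or a validated per-slice DataFrame for the quadrant
    schema.  ``schema=None`` auto-detects from the header.  Errors name the
    offending data row (1-based, excluding the header).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: file is empty") from None
    df.columns = [c.strip() for c in df.columns]
    detected = _detect_schema(df.columns)
    if schema is not None and schema != detected:
        raise ParseError(f"{path}: expected {schema} schema but header is {detected}")
    if df.empty:
        raise ParseError(f"{path}: no data rows")

    for col in ("patient_id", "reader_id", "occasion"):
        blank = df[col].isna() | (df[col].str.strip() == "")
        if blank.any():
            raise ParseError(f"{path}: row {blank.idxmax() + 1}: empty {col}")

    if detected == "condensed":
        df["score"] = _numeric(df, "score", path, integer=False)
        dup = df.duplicated(["patient_id", "reader_id", "occasion"])
        if dup.any():
            raise ParseError(
                f"{path}: row {int(dup.idxmax()) + 1}: duplicate patient/reader/occasion"
            )
        return ReaderStudyTable(df, occasion_order=occasion_order)

    df["slice_index"] = _numeric(df, "slice_index", path, integer=True)
    for q in QUADRANTS:
        col = f"grade_{q}"
        vals = _numeric(df, col, path, integer=True)
        bad = (vals < 0) | (vals > 4)
        if bad.any():
            raise ParseError(
                f"{path}: row {int(bad.idxmax()) + 1}: {col}={vals[bad.idxmax()]} "
                "outside the 0-4 scale"
            )
        df[col] = vals
    dup = df.duplicated(["patient_id", "reader_id", "occasion", "slice_index"])
    if dup.any():
        raise ParseError(
            f"{path}: row {int(dup.idxmax()) + 1}: duplicate patient/reader/occasion/slice"
        )
    return df


def _numeric(df: pd.DataFrame, col: str, path, integer: bool) -> pd.Series:
    raw = df[col]
    vals = pd.to_numeric(raw, errors="coerce")
    if vals.isna().any():
        row = int(vals.isna().idxmax())
        raise ParseError(f"{path}: row {row + 1}: {col}={raw.iloc[row]!r} is not numeric")
    if integer and not (vals % 1 == 0).all():
        row = int((vals % 1 != 0).idxmax())
        raise ParseError(f"{path}: row {row + 1}: {col}={raw.iloc[row]!r} is not an integer")
    return vals.astype(int) if integer else vals.astype(float)


def write_grade_table(table, path: str | Path) -> None:
    """Write a table back to CSV in its native schema (round-trip safe)."""
    path = Path(path)
    if isinstance(table, ReaderStudyTable):
        df = table.data[CONDENSED_COLUMNS].copy()
        score = df["score"]
        if (score % 1 == 0).all():
            df["score"] = score.astype(int)
    else:
        df = table[QUADRANT_COLUMNS]
    df.to_csv(path, index=False)


def aggregate_quadrant_table(
    df: pd.DataFrame,
    n_slices_expected: int | None = None,
) -> pd.DataFrame:
    """Collapse a per-slice quadrant table into per-segment summaries.

    Each patient/reader/occasion group becomes one row with ``n_slices``,
    ``total_score`` (condensed study score) and ``segment_percent``.  When
    ``n_slices_expected`` is given, groups with a different slice count are
    rejected — comparability across groups requires a fixed slice count.
    """
    rows = []
    for (pid, rid, occ), grp in df.groupby(
        ["patient_id", "reader_id", "occasion"], sort=True
    ):
        slices = [
            SliceAssessment.from_grades(
                {q: int(rec[f"grade_{q}"]) for q in QUADRANTS}
            )
            for rec in grp.sort_values("slice_index").to_dict("records")
        ]
        if n_slices_expected is not None and len(slices) != n_slices_expected:
            raise ParseError(
                f"patient {pid} reader {rid} occasion {occ}: "
                f"{len(slices)} slices, expected {n_slices_expected}"
            )
        seg = SegmentAssessment(slices=tuple(slices))
        rows.append(
            {
                "patient_id": pid,
                "reader_id": rid,
                "occasion": occ,
                "n_slices": seg.n_slices,
                "total_score": seg.total_score,
                "segment_percent": seg.segment_percent,
            }
        )
    return pd.DataFrame(rows)


def write_segment_report(report: pd.DataFrame, path: str | Path, precision: int = 2) -> None:
    out = report.copy()
    out["segment_percent"] = out["segment_percent"].round(precision)
    out.to_csv(path, index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
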