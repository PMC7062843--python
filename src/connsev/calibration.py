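"""Proxy calibrated severity scores (CSS) from ADOS totals.

ADOS raw totals are module- and age-dependent, so raw scores from different
modules are not directly comparable.  The calibrated severity score maps a
raw total onto a 1-10 scale via a published lookup keyed by module, age band
and raw-score range.  The *proxy* CSS substitutes the social+communication
ADOS total for the item-weighted sum before matching, making the score
computable from commonly shared phenotype fields.

This module implements the matching procedure against a pluggable CSV table.
The published calibration itself is external and not redistributed here; the
packaged ``synthetic_calibration_table.csv`` is an invented, structurally
valid stand-in used for testing and demos.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

REQUIRED_COLUMNS = ["module", "age_min", "age_max", "raw_min", "raw_max", "css"]


class CalibrationError(ValueError):
    """The calibration table violates its structural invariants."""


class UncalibratableError(LookupError):
    """No calibration row matches the subject; carries the offending record."""

    def __init__(self, record: "AdosRecord"):
        self.record = record
        super().__init__(
            f"uncalibratable subject {record.subject_id}: module={record.module}, "
            f"age={record.age}, ados_total={record.ados_total} matches no row"
        )


@dataclass(frozen=True)
class AdosRecord:
    """One subject's ADOS assessment: social+communication total, module, age."""

    subject_id: str
    ados_total: int
    module: int
    age: float

    def __post_init__(self):
        if self.ados_total < 0:
            raise ValueError(f"{self.subject_id}: ados_total must be >= 0")
        if self.module not in (1, 2, 3, 4):
            raise ValueError(f"{self.subject_id}: module must be in 1..4")
        if self.age <= 0:
            raise ValueError(f"{self.subject_id}: age must be positive")


@dataclass(frozen=True)
class CalibrationTable:
    """Validated lookup table: (module, age band, raw range) -> css 1-10.

    Age bands and raw-score ranges are closed intervals (both endpoints
    included); within one module the age bands must not overlap, and within
    one (module, age band) cell the raw ranges must be non-overlapping and
    jointly cover the cell's raw-score domain without gaps.
    """

    frame: pd.DataFrame

    @property
    def n_rows(self) -> int:
        return len(self.frame)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        raise CalibrationError("no calibration rows")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CalibrationError(f"missing columns: {missing}")
    df = df[REQUIRED_COLUMNS].copy()
    for col in ("module", "raw_min", "raw_max", "css"):
        try:
            df[col] = df[col].astype(int)
        except (TypeError, ValueError) as exc:
            raise CalibrationError(f"column {col!r} is not integer-valued: {exc}") from exc
    df["age_min"] = df["age_min"].astype(float)
    df["age_max"] = df["age_max"].astype(float)

    problems = []
    for row in df.itertuples():
        if row.css < 1 or row.css > 10:
            problems.append(f"row {row.Index}: css {row.css} outside 1-10")
        if row.module not in (1, 2, 3, 4):
            problems.append(f"row {row.Index}: module {row.module} outside 1-4")
        if row.raw_min > row.raw_max:
            problems.append(f"row {row.Index}: raw_min > raw_max")
        if row.age_min > row.age_max:
            problems.append(f"row {row.Index}: age_min > age_max")
    if problems:
        raise CalibrationError("; ".join(problems))

    # Age bands within a module must not overlap.
    for module, grp in df.groupby("module"):
        bands = sorted(grp.groupby(["age_min", "age_max"]).groups)
        for (a0, a1), (b0, b1) in zip(bands, bands[1:]):
            if b0 <= a1:
                raise CalibrationError(
                    f"module {module}: age bands [{a0}, {a1}] and [{b0}, {b1}] overlap"
                )

    # Raw ranges within a (module, age band) cell: disjoint and gap-free.
    for (module, a0, a1), grp in df.groupby(["module", "age_min", "age_max"]):
        grp = grp.sort_values("raw_min")
        rows = list(grp.itertuples())
        for prev, cur in zip(rows, rows[1:]):
            if cur.raw_min <= prev.raw_max:
                raise CalibrationError(
                    f"module {module}, ages {a0}-{a1}: rows {prev.Index} and "
                    f"{cur.Index} overlap on raw score {cur.raw_min}"
                )
            if cur.raw_min != prev.raw_max + 1:
                raise CalibrationError(
                    f"module {module}, ages {a0}-{a1}: gap between raw scores "
                    f"{prev.raw_max} and {cur.raw_min} (rows {prev.Index}, {cur.Index})"
                )
    return df.reset_index(drop=True)


def load_calibration_table(path) -> CalibrationTable:
    """Load a calibration CSV and validate its invariants.

    Violations raise :class:`CalibrationError` with row-level diagnostics.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CalibrationError("no calibration rows") from exc
    return CalibrationTable(_validate(df))


def synthetic_calibration_table() -> CalibrationTable:
    """The packaged synthetic (invented) calibration table used for demos."""
    with resources.files("connsev.data").joinpath("synthetic_calibration_table.csv").open() as fh:
        return CalibrationTable(_validate(pd.read_csv(fh)))


def proxy_css(record: AdosRecord, table: CalibrationTable) -> int:
    """Calibrated severity (1-10) of the unique row containing the record.

    Pure function of (module, age, ados_total); raises
    :class:`UncalibratableError` when no row matches.
    """
    df = table.frame
    hit = df[
        (df["module"] == record.module)
        & (df["age_min"] <= record.age)
        & (record.age <= df["age_max"])
        & (df["raw_min"] <= record.ados_total)
        & (record.ados_total <= df["raw_max"])
    ]
    if hit.empty:
        raise UncalibratableError(record)
    if len(hit) > 1:  # impossible after validation; guard anyway
        raise CalibrationError(f"ambiguous rows {hit.index.tolist()} for {record}")
    return int(hit["css"].iloc[0])


def score_cohort(phenotypes: pd.DataFrame, table: CalibrationTable):
    """Score every subject in a phenotype table.

    Returns ``(scores, exclusions)`` where ``scores`` is a DataFrame with
    columns subject_id, css (calibratable subjects only, input order) and
    ``exclusions`` lists (subject_id, reason) for subjects that matched no
    calibration row.  Nothing is silently dropped.
    """
    required = ["subject_id", "ados_total", "module", "age"]
    missing = [c for c in required if c not in phenotypes.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    rows, exclusions = [], []
    for t in phenotypes.itertuples():
        record = AdosRecord(str(t.subject_id), int(t.ados_total), int(t.module), float(t.age))
        try:
            rows.append({"subject_id": record.subject_id, "css": proxy_css(record, table)})
        except UncalibratableError as exc:
            exclusions.append((record.subject_id, str(exc)))
    return pd.DataFrame(rows, columns=["subject_id", "css"]), exclusions
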