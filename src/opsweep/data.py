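"""Cephalometric domain types and tabular I/O.

A :class:`CephRecord` holds the sixteen numeric indicators measured on one
lateral cephalogram plus identity and sex.  Cohorts are plain ordered
collections of records; CSV is the exchange format, with one header row and
canonical column names (hyphens and slashes of the printed abbreviations
replaced by underscores, ``S-Go/N-Me`` exposed as ``FHR``, ``NPo-FH`` as
``FA``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from . import tables
from .exceptions import SchemaError, ValidationError

__all__ = [
    "CephRecord", "SkeletalClass", "Cohort", "Violation",
    "read_cohort", "write_cohort", "validate_record",
    "CANONICAL_COLUMNS", "COLUMN_ALIASES",
]

#: default tolerance (degrees) for the ANB = SNA - SNB identity on imported
#: data; synthetic data satisfies it to 1e-9
DEFAULT_ANB_TOLERANCE = 0.5

#: plausibility window half-width, in pooled total SDs of each indicator
PLAUSIBILITY_SDS = 5.0

CANONICAL_COLUMNS: tuple[str, ...] = ("id", "sex") + tables.ALL_FIELDS

#: accepted spellings for imported headers (case-insensitive lookup on top)
COLUMN_ALIASES: dict[str, str] = {
    "N-ANS": "N_ANS", "S-N": "S_N", "Ptm-A": "Ptm_A", "NA-FH": "NA_FH",
    "PP-FH": "PP_FH", "Go-Po": "Go_Po", "Go-Co": "Go_Co", "S-Go": "S_Go",
    "SN-OP": "SN_OP", "S-Go/N-Me": "FHR", "S_Go/N_Me": "FHR",
    "P-A face height": "FHR", "NPo-FH": "FA", "FH-NPo": "FA",
    "facial angle": "FA", "FMA": "FH_MP", "FH-MP": "FH_MP", "SN-MP": "SN_MP",
}


@dataclass(frozen=True)
class SkeletalClass:
    """Sagittal (I/II/III) x vertical (hypo/nor/hyper) skeletal label."""

    sagittal: str
    vertical: str

    def __post_init__(self):
        if self.sagittal not in tables.SAGITTAL:
            raise ValueError(f"unknown sagittal class {self.sagittal!r}")
        if self.vertical not in tables.VERTICAL + ("unclassified",):
            raise ValueError(f"unknown vertical class {self.vertical!r}")

    @property
    def cell(self) -> tuple[str, str]:
        return (self.sagittal, self.vertical)

    def __str__(self) -> str:  # e.g. "III/hyper"
        return f"{self.sagittal}/{self.vertical}"

    @classmethod
    def parse(cls, text: str) -> "SkeletalClass":
        sag, _, vert = text.partition("/")
        return cls(sag, vert)


@dataclass
class CephRecord:
    """One patient's cephalometric measurement set.

    Linear measures in mm, angles in degrees, FHR in percent.
    """

    id: str
    sex: str
    N_ANS: float
    S_N: float
    Ptm_A: float
    SNA: float
    NA_FH: float
    PP_FH: float
    Go_Po: float
    Go_Co: float
    S_Go: float
    SN_OP: float
    FHR: float
    FA: float
    SNB: float
    ANB: float
    FH_MP: float
    SN_MP: float

    @property
    def N_Me(self) -> float:
        """Anterior face height implied by FHR = 100 * S_Go / N_Me."""
        return self.S_Go / (self.FHR / 100.0)

    def inputs(self) -> np.ndarray:
        """The ten surrogate input features, SN_OP last."""
        return np.array([getattr(self, f) for f in tables.INPUT_FEATURES])

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class Violation:
    field: str
    value: float
    bound: str

    def as_dict(self) -> dict:
        return {"field": self.field, "value": self.value, "bound": self.bound}


def _plausibility_windows() -> dict[str, tuple[float, float]]:
    wins = {}
    for f in tables.ALL_FIELDS:
        mu, sd = tables.pooled_moments(f)
        wins[f] = (mu - PLAUSIBILITY_SDS * sd, mu + PLAUSIBILITY_SDS * sd)
    return wins


_DEFAULT_WINDOWS = _plausibility_windows()


def validate_record(
    record: CephRecord,
    tolerance: float = DEFAULT_ANB_TOLERANCE,
    windows: dict[str, tuple[float, float]] | None = None,
) -> list[Violation]:
    """Report every invariant violation of one record (empty list = valid).

    Checks positivity of linear measures, the ANB = SNA - SNB identity at
    the given tolerance, 0 < FHR < 100, and a per-field plausibility window
    (default: pooled reference mean +/- 5 total SDs).
    """
    windows = _DEFAULT_WINDOWS if windows is None else windows
    out: list[Violation] = []
    if record.sex not in ("F", "M"):
        out.append(Violation("sex", float("nan"), "sex must be F or M"))
    for f in tables.MM_FIELDS:
        v = getattr(record, f)
        if not np.isfinite(v) or v <= 0:
            out.append(Violation(f, v, "> 0 (linear measure)"))
    gap = record.SNA - record.SNB - record.ANB
    if not np.isfinite(gap) or abs(gap) > tolerance:
        out.append(Violation(
            "ANB", record.ANB,
            f"|SNA - SNB - ANB| <= {tolerance} (got {gap:+.4f})"))
    if not (0.0 < record.FHR < 100.0):
        out.append(Violation("FHR", record.FHR, "0 < FHR < 100"))
    for f, (lo, hi) in windows.items():
        v = getattr(record, f)
        if not np.isfinite(v) or v < lo or v > hi:
            out.append(Violation(f, v, f"plausibility [{lo:.2f}, {hi:.2f}]"))
    return out


@dataclass
class Cohort:
    """Ordered collection of records with optional generator truth labels."""

    records: list[CephRecord]
    labels: list[SkeletalClass] | None = None
    provenance: str = "imported"
    seed: int | None = None

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate record ids in cohort")
        if self.labels is not None and len(self.labels) != len(self.records):
            raise ValidationError("labels do not align 1:1 with records")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CephRecord]:
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([r.as_dict() for r in self.records],
                          columns=list(CANONICAL_COLUMNS))
        if self.labels is not None:
            df["sagittal"] = [l.sagittal for l in self.labels]
            df["vertical"] = [l.vertical for l in self.labels]
        return df

    def inputs(self) -> pd.DataFrame:
        """n x 10 surrogate input table in canonical feature order."""
        return self.to_frame()[list(tables.INPUT_FEATURES)]

    def outcome(self, name: str) -> np.ndarray:
        if name not in ("FHR", "FA"):
            raise ValueError("outcome must be 'FHR' or 'FA'")
        return np.array([getattr(r, name) for r in self.records])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "imported",
                   seed: int | None = None,
                   anb_tolerance: float = DEFAULT_ANB_TOLERANCE) -> "Cohort":
        records, labels = [], None
        numeric = [c for c in CANONICAL_COLUMNS if c not in ("id", "sex")]
        for idx, row in df.iterrows():
            try:
                vals = {c: float(row[c]) for c in numeric}
            except (TypeError, ValueError) as e:
                raise SchemaError(f"non-numeric cell in row {idx}: {e}") from e
            rec = CephRecord(id=str(row["id"]), sex=str(row["sex"]), **vals)
            viol = validate_record(rec, tolerance=anb_tolerance)
            if viol:
                raise ValidationError(
                    f"record {rec.id!r} (row {idx}) fails validation: "
                    + "; ".join(f"{v.field}={v.value} not {v.bound}" for v in viol),
                    violations=viol)
            records.append(rec)
        if {"sagittal", "vertical"}.issubset(df.columns):
            labels = [SkeletalClass(s, v)
                      for s, v in zip(df["sagittal"], df["vertical"])]
        return cls(records, labels=labels, provenance=provenance, seed=seed)


def _canonicalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    lower_alias = {k.lower(): v for k, v in COLUMN_ALIASES.items()}
    rename = {}
    for col in df.columns:
        c = str(col).strip()
        if c in CANONICAL_COLUMNS:
            rename[col] = c
        elif c in COLUMN_ALIASES:
            rename[col] = COLUMN_ALIASES[c]
        elif c.lower() in lower_alias:
            rename[col] = lower_alias[c.lower()]
        elif c.replace("-", "_").replace("/", "_") in CANONICAL_COLUMNS:
            rename[col] = c.replace("-", "_").replace("/", "_")
    return df.rename(columns=rename)


def read_cohort(path: str | Path,
                anb_tolerance: float = DEFAULT_ANB_TOLERANCE) -> Cohort:
    """Read a cohort CSV, mapping printed header variants onto canonical names.

    Raises :class:`SchemaError` naming the first missing required column,
    or :class:`ValidationError` for the first invalid record.
    """
    path = Path(path)
    df = _canonicalize_columns(pd.read_csv(path))
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r} in {path}")
    return Cohort.from_frame(df, provenance="imported",
                             anb_tolerance=anb_tolerance)


def write_cohort(cohort: Cohort, path: str | Path) -> int:
    """Write the canonical CSV (6-decimal floats); returns the row count."""
    path = Path(path)
    df = cohort.to_frame()
    df.to_csv(path, index=False, float_format="%.6f")
    return len(df)


def write_validation_report(records: Iterable[CephRecord], path: str | Path,
                            tolerance: float = DEFAULT_ANB_TOLERANCE) -> dict:
    """JSON validation report: per-record violations plus a summary."""
    report = {"records": {}, "n": 0, "n_invalid": 0}
    for rec in records:
        report["n"] += 1
        viol = validate_record(rec, tolerance=tolerance)
        if viol:
            report["n_invalid"] += 1
            report["records"][rec.id] = [v.as_dict() for v in viol]
    Path(path).write_text(json.dumps(report, indent=2))
    return report
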