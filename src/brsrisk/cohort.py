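"""Cohort domain model: patient records, CSV I/O and ECG derived quantities.

A cohort is one row per patient with demographics, clinical flags (syncope,
atrial fibrillation, initial spontaneous type 1 pattern, programmed
ventricular stimulation, ICD), ECG measurements (QRS duration, QT/RR, QTc)
and the binary outcome: spontaneous ventricular tachycardia / ventricular
fibrillation (VT/VF).

CSV dialect: comma-separated UTF-8 with a header row; booleans serialized as
0/1; absent optional values as empty cells. ``read_cohort`` after
``write_cohort`` is the identity on valid cohorts.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from ._base import DomainError, SchemaError, ValidationError

__all__ = [
    "PatientRecord",
    "Cohort",
    "RowReport",
    "bazett_qtc",
    "read_cohort",
    "read_cohort_with_report",
    "write_cohort",
    "CANONICAL_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Canonical cohort CSV columns, in file order.
CANONICAL_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "syncope",
    "initial_type1",
    "af",
    "pvs_performed",
    "pvs_positive",
    "icd",
    "qrs_ms",
    "qt_ms",
    "rr_s",
    "qtc_ms",
    "vtvf",
)

_REQUIRED_COLUMNS = tuple(
    c for c in CANONICAL_COLUMNS if c not in ("pvs_positive", "qt_ms", "rr_s", "qtc_ms")
)

_BOOL_FIELDS = ("syncope", "initial_type1", "af", "pvs_performed", "icd", "vtvf")


def bazett_qtc(qt_ms: float, rr_s: float) -> float:
    """Heart-rate corrected QT interval (Bazett): ``QTc = QT / sqrt(RR)``.

    Parameters
    ----------
    qt_ms : QT interval in milliseconds, > 0.
    rr_s : RR interval in seconds, > 0.

    Returns
    -------
    QTc in milliseconds.
    """
    if not (qt_ms > 0):
        raise DomainError(f"qt_ms must be positive, got {qt_ms!r}")
    if not (rr_s > 0):
        raise DomainError(f"rr_s must be positive, got {rr_s!r}")
    return qt_ms / math.sqrt(rr_s)


@dataclass(frozen=True)
class PatientRecord:
    """One study subject.

    ``pvs_positive`` is defined only when ``pvs_performed`` is true; ``qt_ms``
    and ``rr_s`` are optional raw measurements from which ``qtc_ms`` may be
    derived via :func:`bazett_qtc`.
    """

    patient_id: str
    age_years: float
    sex: str  # "male" | "female"
    syncope: bool
    initial_type1: bool
    af: bool
    pvs_performed: bool
    icd: bool
    qrs_ms: float
    qtc_ms: float
    vtvf: bool
    pvs_positive: Optional[bool] = None
    qt_ms: Optional[float] = None
    rr_s: Optional[float] = None

    def __post_init__(self) -> None:
        problems = []
        if not self.patient_id:
            problems.append("patient_id must be nonempty")
        if self.sex not in ("male", "female"):
            problems.append(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not (0 <= self.age_years < 120):
            problems.append(f"age_years must be in [0, 120), got {self.age_years}")
        if not (40 < self.qrs_ms < 300):
            problems.append(f"qrs_ms must be in (40, 300) ms, got {self.qrs_ms}")
        if not (250 < self.qtc_ms < 700):
            problems.append(f"qtc_ms must be in (250, 700) ms, got {self.qtc_ms}")
        if self.qt_ms is not None and not (self.qt_ms > 0):
            problems.append(f"qt_ms must be positive, got {self.qt_ms}")
        if self.rr_s is not None and not (self.rr_s > 0):
            problems.append(f"rr_s must be positive, got {self.rr_s}")
        if self.pvs_performed and self.pvs_positive is None:
            problems.append("pvs_positive must be set when pvs_performed is true")
        if not self.pvs_performed and self.pvs_positive is not None:
            problems.append("pvs_positive must be absent when pvs_performed is false")
        if problems:
            raise ValidationError(
                f"invalid record {self.patient_id!r}: " + "; ".join(problems)
            )


@dataclass(frozen=True)
class Cohort:
    """Ordered, id-unique collection of :class:`PatientRecord`."""

    records: tuple[PatientRecord, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id values: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_cases(self) -> int:
        return sum(r.vtvf for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame with canonical columns; absent values as NA."""
        rows = []
        for r in self.records:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "age_years": r.age_years,
                    "sex": r.sex,
                    "syncope": int(r.syncope),
                    "initial_type1": int(r.initial_type1),
                    "af": int(r.af),
                    "pvs_performed": int(r.pvs_performed),
                    "pvs_positive": (
                        None if r.pvs_positive is None else int(r.pvs_positive)
                    ),
                    "icd": int(r.icd),
                    "qrs_ms": r.qrs_ms,
                    "qt_ms": r.qt_ms,
                    "rr_s": r.rr_s,
                    "qtc_ms": r.qtc_ms,
                    "vtvf": int(r.vtvf),
                }
            )
        df = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
        return df


@dataclass(frozen=True)
class RowReport:
    """Why a CSV row was rejected."""

    row_index: int
    patient_id: str
    reason: str


def _parse_bool(value: str, column: str):
    v = value.strip()
    if v in ("0", "1"):
        return bool(int(v))
    if v.lower() in ("true", "false"):
        return v.lower() == "true"
    raise ValueError(f"column {column!r}: cannot parse boolean from {value!r}")


def _parse_float(value: str, column: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValueError(f"column {column!r}: cannot parse number from {value!r}")


def _load_schema(schema) -> Mapping[str, str]:
    """Schema maps canonical column name -> actual CSV header."""
    if schema is None:
        return {}
    if isinstance(schema, Mapping):
        return dict(schema)
    path = Path(schema)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return dict(yaml.safe_load(text))
    return dict(json.loads(text))


def read_cohort_with_report(
    path, schema=None, label: str = ""
) -> tuple[Cohort, list[RowReport]]:
    """Read a cohort CSV; invalid rows are dropped and reported.

    Parameters
    ----------
    path : CSV file with a header row.
    schema : optional mapping (or JSON/YAML file) from canonical column names
        to the file's actual headers.
    label : cohort label (e.g. ``"training"``).

    Returns
    -------
    (cohort, reports) where ``reports`` lists every rejected row with its
    0-based data-row index and the violated invariant.

    Raises
    ------
    SchemaError : a required column is missing after mapping.
    ValidationError : duplicate patient ids among the accepted rows.
    """
    mapping = _load_schema(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {actual: canonical for canonical, actual in mapping.items()}
    df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    records: list[PatientRecord] = []
    reports: list[RowReport] = []
    for i, row in enumerate(df.itertuples(index=False)):
        raw = dict(zip(df.columns, row))
        pid = raw.get("patient_id", "").strip()
        try:
            records.append(_record_from_raw(raw))
        except (ValueError, ValidationError) as exc:
            reports.append(RowReport(row_index=i, patient_id=pid, reason=str(exc)))
    if reports:
        logger.warning(
            "read_cohort: rejected %d of %d rows (%s)",
            len(reports),
            len(df),
            "; ".join(f"row {r.row_index}: {r.reason}" for r in reports[:5]),
        )
    return Cohort(records=tuple(records), label=label), reports


def _record_from_raw(raw: Mapping[str, str]) -> PatientRecord:
    def opt(name):
        v = raw.get(name, "")
        return None if v is None or str(v).strip() == "" else str(v)

    kwargs = {
        "patient_id": str(raw["patient_id"]).strip(),
        "age_years": _parse_float(raw["age_years"], "age_years"),
        "sex": str(raw["sex"]).strip().lower(),
        "qrs_ms": _parse_float(raw["qrs_ms"], "qrs_ms"),
    }
    for b in _BOOL_FIELDS:
        kwargs[b] = _parse_bool(raw[b], b)

    pvs_positive = opt("pvs_positive")
    kwargs["pvs_positive"] = (
        None if pvs_positive is None else _parse_bool(pvs_positive, "pvs_positive")
    )
    qt = opt("qt_ms")
    rr = opt("rr_s")
    kwargs["qt_ms"] = None if qt is None else _parse_float(qt, "qt_ms")
    kwargs["rr_s"] = None if rr is None else _parse_float(rr, "rr_s")

    qtc = opt("qtc_ms")
    if qtc is not None:
        kwargs["qtc_ms"] = _parse_float(qtc, "qtc_ms")
        if kwargs["qt_ms"] is not None and kwargs["rr_s"] is not None:
            derived = bazett_qtc(kwargs["qt_ms"], kwargs["rr_s"])
            if abs(derived - kwargs["qtc_ms"]) > 1.0:
                # supplied value wins; flag the conflict
                logger.warning(
                    "record %s: supplied qtc_ms=%.1f differs from Bazett-derived "
                    "%.1f; keeping the supplied value",
                    kwargs["patient_id"],
                    kwargs["qtc_ms"],
                    derived,
                )
    elif kwargs["qt_ms"] is not None and kwargs["rr_s"] is not None:
        kwargs["qtc_ms"] = bazett_qtc(kwargs["qt_ms"], kwargs["rr_s"])
    else:
        raise ValueError(
            "column 'qtc_ms': value absent and not derivable (need qt_ms and rr_s)"
        )
    return PatientRecord(**kwargs)


def read_cohort(path, schema=None, label: str = "") -> Cohort:
    """Read and validate a cohort CSV; see :func:`read_cohort_with_report`."""
    cohort, _ = read_cohort_with_report(path, schema=schema, label=label)
    return cohort


def write_cohort(cohort: Cohort, path) -> None:
    """Write the canonical cohort CSV (booleans as 0/1, absents as empty)."""
    df = cohort.to_frame()
    for col in ("pvs_positive",):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    for col in ("qt_ms", "rr_s"):
        df[col] = df[col].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    for col in ("age_years", "qrs_ms", "qtc_ms"):
        df[col] = df[col].map(lambda v: repr(float(v)))
    df.to_csv(path, index=False)
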