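"""Intermediate-database data model: record types, CSV I/O, config validation.

All downstream stages (era construction, the ALT rule engine, screening,
rate statistics) consume the four flat tables defined here — prescription
orders, laboratory results, ICD-10 diagnoses and surgeries — mirroring the
intermediate database a hospital would populate from its CPOE/EMR system.
Dates are calendar dates (day granularity, ISO-8601 in files); prescriptions
nominally cover the closed interval ``[start_date, start_date +
days_supply - 1]``.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "RowError",
    "ConfigError",
    "PrescriptionOrder",
    "LabResult",
    "DiagnosisRecord",
    "SurgeryRecord",
    "MedicationHistoryRecord",
    "StudyConfig",
    "QUANTITATIVE_TESTS",
    "SEROLOGY_TESTS",
    "ALLOWED_TEST_CODES",
    "read_table",
    "write_table",
    "validate_config",
    "load_config",
]


class SchemaError(ValueError):
    """A table is missing a required column or has the wrong shape."""


class RowError(ValueError):
    """A row failed to parse; carries the offending 0-based row index."""

    def __init__(self, row_index: int, message: str):
        self.row_index = row_index
        super().__init__(f"row {row_index}: {message}")


class ConfigError(ValueError):
    """A configuration value violates its invariant; names the key."""


QUANTITATIVE_TESTS = ("ALT", "ALP")
SEROLOGY_TESTS = ("HAV_IGM", "HBS_AG", "HCV_CORE_AG", "CMV", "EBV")
ALLOWED_TEST_CODES = QUANTITATIVE_TESTS + SEROLOGY_TESTS


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.date) and not isinstance(value, dt.datetime):
        return value
    if isinstance(value, dt.datetime):
        return value.date()
    return dt.date.fromisoformat(str(value).strip())


@dataclass(frozen=True)
class PrescriptionOrder:
    """One CPOE prescription order: who, what, when, and for how many days."""

    patient_id: str
    medicine_code: str
    medicine_name: str
    start_date: dt.date
    days_supply: int

    def __post_init__(self):
        if int(self.days_supply) < 1:
            raise ValueError(f"days_supply must be >= 1, got {self.days_supply}")

    @property
    def nominal_end(self) -> dt.date:
        """Last day nominally covered: a 1-day supply covers its start day."""
        return self.start_date + dt.timedelta(days=int(self.days_supply) - 1)


@dataclass(frozen=True)
class LabResult:
    """A dated lab measurement: quantitative (ALT/ALP, IU/L) or a serology flag."""

    patient_id: str
    test_code: str
    date: dt.date
    value: Optional[float] = None
    qualitative: Optional[str] = None  # "positive" | "negative" for serologies

    def __post_init__(self):
        if self.test_code not in ALLOWED_TEST_CODES:
            raise ValueError(
                f"unknown test_code {self.test_code!r}; allowed: {list(ALLOWED_TEST_CODES)}"
            )
        if self.test_code in QUANTITATIVE_TESTS:
            if self.value is None:
                raise ValueError(f"{self.test_code} requires a numeric value")
            if self.value < 0:
                raise ValueError("quantitative lab values must be non-negative")
        else:
            if self.qualitative not in ("positive", "negative"):
                raise ValueError(
                    f"serology {self.test_code} requires qualitative positive/negative"
                )

    @property
    def is_positive(self) -> bool:
        return self.qualitative == "positive"


@dataclass(frozen=True)
class DiagnosisRecord:
    """A dated ICD-10 coded diagnosis (letter + two digits, optional sub-code)."""

    patient_id: str
    icd10_code: str
    date: dt.date

    def __post_init__(self):
        code = self.icd10_code
        ok = (
            len(code) >= 3
            and code[0].isalpha()
            and code[0].isupper()
            and code[1:3].isdigit()
        )
        if not ok:
            raise ValueError(f"malformed ICD-10 code: {code!r}")


@dataclass(frozen=True)
class SurgeryRecord:
    patient_id: str
    date: dt.date


@dataclass(frozen=True)
class MedicationHistoryRecord:
    """A merged medication era for one patient and one medicine.

    ``start_date``/``end_date`` come from nominal order dates only; the
    estimated unconsumed supply at ``end_date`` is bookkept in
    ``surplus_days`` and never extends the era.
    """

    patient_id: str
    medicine_code: str
    start_date: dt.date
    end_date: dt.date
    n_orders_combined: int
    total_days_supply: int
    surplus_days: float

    def __post_init__(self):
        if self.end_date < self.start_date:
            raise ValueError("end_date precedes start_date")
        if self.n_orders_combined < 1:
            raise ValueError("n_orders_combined must be >= 1")
        if self.surplus_days < 0:
            raise ValueError("surplus_days must be non-negative")

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


# Exclusion code prefixes: alcohol dependence (F10), liver disease (K70-K77),
# gallbladder and bile duct disease (K80-K87).
_DEFAULT_EXCLUSION_PREFIXES = tuple(
    ["F10"] + [f"K{n}" for n in range(70, 78)] + [f"K{n}" for n in range(80, 88)]
)


@dataclass(frozen=True)
class StudyConfig:
    """Every tunable constant of the detection pipeline.

    Defaults reflect the published study settings: UMI 1.4, ALT/ALP upper
    limits of normal 40/200 IU/L, a 90-day peak-search window, a 30-day
    post-cessation window, a 14-day surgery look-back, severity cut points
    80/200 IU/L, and the hepatocellular screen ALT > 200 with R > 5.
    """

    umi: float = 1.4
    uln_alt: float = 40.0
    uln_alp: float = 200.0
    peak_window_days: int = 90
    post_cessation_window_days: int = 30
    surgery_lookback_days: int = 14
    moderate_threshold: float = 80.0
    severe_threshold: float = 200.0
    rucam_alt_threshold: float = 200.0
    rucam_r_threshold: float = 5.0
    exclusion_icd10_prefixes: tuple = _DEFAULT_EXCLUSION_PREFIXES
    serology_codes: tuple = SEROLOGY_TESTS
    alpha: float = 0.05
    baseline_multiplier: float = 2.0
    recovery_fraction_after: float = 0.5
    recovery_fraction_during: float = 0.25

    def __post_init__(self):
        if self.umi < 1:
            raise ConfigError(f"umi must be >= 1, got {self.umi}")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        for key in (
            "uln_alt",
            "uln_alp",
            "peak_window_days",
            "post_cessation_window_days",
            "surgery_lookback_days",
            "moderate_threshold",
            "severe_threshold",
            "rucam_alt_threshold",
            "rucam_r_threshold",
            "baseline_multiplier",
            "recovery_fraction_after",
            "recovery_fraction_during",
        ):
            if getattr(self, key) <= 0:
                raise ConfigError(f"{key} must be positive, got {getattr(self, key)}")
        object.__setattr__(
            self, "exclusion_icd10_prefixes", tuple(self.exclusion_icd10_prefixes)
        )
        object.__setattr__(self, "serology_codes", tuple(self.serology_codes))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclusion_icd10_prefixes"] = list(d["exclusion_icd10_prefixes"])
        d["serology_codes"] = list(d["serology_codes"])
        return d


def validate_config(raw: Optional[dict] = None) -> StudyConfig:
    """Build a :class:`StudyConfig` from a key-value mapping.

    Unspecified keys take the study defaults; unknown keys are rejected so
    typos do not silently fall back to a default. Idempotent on the dict
    form of an already-valid config.
    """
    raw = dict(raw or {})
    known = {f.name for f in dataclasses.fields(StudyConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return StudyConfig(**raw)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(str(exc)) from exc


def load_config(path: Union[str, Path]) -> StudyConfig:
    """Load a YAML or JSON config file mirroring StudyConfig field names."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text) if text.strip() else {}
    else:
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return validate_config(raw)


# ---------------------------------------------------------------------------
# Flat-file tables

_TABLE_SPECS = {
    "orders": {
        "type": PrescriptionOrder,
        "columns": ("patient_id", "medicine_code", "medicine_name", "start_date", "days_supply"),
        "dates": ("start_date",),
    },
    "labs": {
        "type": LabResult,
        "columns": ("patient_id", "test_code", "date", "value", "qualitative"),
        "dates": ("date",),
    },
    "diagnoses": {
        "type": DiagnosisRecord,
        "columns": ("patient_id", "icd10_code", "date"),
        "dates": ("date",),
    },
    "surgeries": {
        "type": SurgeryRecord,
        "columns": ("patient_id", "date"),
        "dates": ("date",),
    },
    "history": {
        "type": MedicationHistoryRecord,
        "columns": (
            "patient_id",
            "medicine_code",
            "start_date",
            "end_date",
            "n_orders_combined",
            "total_days_supply",
            "surplus_days",
        ),
        "dates": ("start_date", "end_date"),
    },
}

_TYPE_TO_KIND = {spec["type"]: kind for kind, spec in _TABLE_SPECS.items()}

_INT_FIELDS = {"days_supply", "n_orders_combined", "total_days_supply"}
_FLOAT_FIELDS = {"value", "surplus_days"}


def _row_to_record(kind: str, row: dict, idx: int):
    spec = _TABLE_SPECS[kind]
    kwargs = {}
    for col in spec["columns"]:
        val = row.get(col)
        is_missing = val is None or (isinstance(val, float) and pd.isna(val)) or (
            isinstance(val, str) and val.strip() == ""
        )
        try:
            if col in spec["dates"]:
                if is_missing:
                    raise ValueError(f"missing date in column {col}")
                kwargs[col] = _parse_date(val)
            elif col in _INT_FIELDS:
                if is_missing:
                    raise ValueError(f"missing integer in column {col}")
                kwargs[col] = int(val)
            elif col in _FLOAT_FIELDS:
                kwargs[col] = None if is_missing else float(val)
            else:
                kwargs[col] = None if is_missing else str(val).strip()
        except (ValueError, TypeError) as exc:
            raise RowError(idx, f"column {col!r}: {exc}") from exc
    if kind == "history" and kwargs.get("surplus_days") is None:
        kwargs["surplus_days"] = 0.0
    try:
        return spec["type"](**kwargs)
    except RowError:
        raise
    except ValueError as exc:
        raise RowError(idx, str(exc)) from exc


def read_table(path: Union[str, Path], table_kind: str) -> list:
    """Read one flat-file table into a list of typed records.

    Row order is preserved; extra unknown columns are accepted and ignored.
    A missing required column raises :class:`SchemaError` naming it; a bad
    value raises :class:`RowError` carrying the row index.
    """
    if table_kind not in _TABLE_SPECS:
        raise ValueError(
            f"unknown table_kind {table_kind!r}; expected one of {sorted(_TABLE_SPECS)}"
        )
    spec = _TABLE_SPECS[table_kind]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{table_kind} table {path} is missing required column(s): {missing}"
        )
    records = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        records.append(_row_to_record(table_kind, row, idx))
    return records


def write_table(records: Sequence, path: Union[str, Path], table_kind: Optional[str] = None) -> None:
    """Write a homogeneous list of records to CSV (dates ISO-8601).

    ``read_table(write_table(x))`` reproduces ``x`` field-for-field. An
    empty list requires ``table_kind`` so the header can be emitted.
    """
    if records:
        types = {type(r) for r in records}
        if len(types) > 1:
            raise ValueError(f"records not homogeneous: {sorted(t.__name__ for t in types)}")
        kind = _TYPE_TO_KIND.get(next(iter(types)))
        if kind is None:
            raise ValueError(f"unsupported record type: {next(iter(types)).__name__}")
        if table_kind is not None and table_kind != kind:
            raise ValueError(f"records are {kind!r}, not {table_kind!r}")
    else:
        if table_kind is None:
            raise ValueError("table_kind is required to write an empty table")
        kind = table_kind
    spec = _TABLE_SPECS[kind]
    rows = []
    for rec in records:
        row = {}
        for col in spec["columns"]:
            val = getattr(rec, col)
            if isinstance(val, dt.date):
                val = val.isoformat()
            row[col] = "" if val is None else val
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(spec["columns"]))
    df.to_csv(path, index=False)
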