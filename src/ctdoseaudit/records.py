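"""Data model, file I/O, cohort filtering, and cross-system series matching.

One :class:`SeriesRecord` describes a single irradiation event (scout, axial,
helical, or bolus-tracking acquisition) with its scanner-reported dose indices
and geometry.  A :class:`StudyRecord` groups the series of one examination
together with the patient-level attributes (age, sex, weight) that the
size-corrected dose metrics need.

All quantities are stored in fixed units: CTDIvol in mGy, DLP in mGy.cm,
lengths and diameters in cm, weight in kg.  Readers are expected to convert
at ingest time; nothing downstream rescales.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import (
    DuplicateUidError,
    RowValidationError,
    SchemaError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class Scanner(str, enum.Enum):
    CT1 = "CT1"
    CT2 = "CT2"
    OTHER = "other"


class SeriesRegion(str, enum.Enum):
    """Series-level anatomical label (the vocabulary radiographers assign)."""

    HEAD = "head"
    NECK = "neck"
    CHEST = "chest"
    ABDOMEN_PELVIS = "abdomen_pelvis"
    TRUNK = "trunk"
    UNDEFINED = "undefined"


class StudyAlias(str, enum.Enum):
    """Study-level anatomical label (coarser than the series vocabulary)."""

    HEAD = "head"
    NECK = "neck"
    CHEST = "chest"
    ABDOMEN = "abdomen"
    PELVIS = "pelvis"
    UNDEFINED = "undefined"


class AcquisitionType(str, enum.Enum):
    SCOUT = "scout"
    AXIAL = "axial"
    HELICAL = "helical"
    BOLUS_TRACKING = "bolus_tracking"


class Phantom(str, enum.Enum):
    HEAD16 = "head16"
    BODY32 = "body32"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"
    UNKNOWN = "unknown"


# ---------------------------------------------------------------------------
# Records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeriesRecord:
    """One irradiation event with dose indices and geometry."""

    study_id: str
    series_uid: str
    scanner_id: Scanner
    protocol_name: str
    series_region: SeriesRegion
    acquisition_type: AcquisitionType
    ctdi_vol: float          # mGy
    phantom: Phantom
    dlp: float               # mGy.cm
    scan_length: float       # cm
    d_eff: float | None = None    # cm
    d_water: float | None = None  # cm

    def __post_init__(self) -> None:
        if not self.series_uid:
            raise ValueError("series_uid must be non-empty")
        if self.ctdi_vol < 0:
            raise ValueError(f"ctdi_vol must be >= 0, got {self.ctdi_vol}")
        if self.dlp < 0:
            raise ValueError(f"dlp must be >= 0, got {self.dlp}")
        if self.scan_length < 0:
            raise ValueError(f"scan_length must be >= 0, got {self.scan_length}")
        if self.d_eff is not None and self.d_eff <= 0:
            raise ValueError(f"d_eff must be > 0 when present, got {self.d_eff}")

    @property
    def is_scout(self) -> bool:
        return self.acquisition_type is AcquisitionType.SCOUT


@dataclass
class StudyRecord:
    """Patient-level grouping of series; series order = acquisition order."""

    study_id: str
    patient_age: float                 # years
    patient_sex: Sex = Sex.UNKNOWN
    patient_weight: float | None = None   # kg
    study_alias: StudyAlias = StudyAlias.UNDEFINED
    series: list[SeriesRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.patient_age < 0:
            raise ValueError(f"patient_age must be >= 0, got {self.patient_age}")
        if self.patient_weight is not None and self.patient_weight <= 0:
            raise ValueError(
                f"patient_weight must be > 0 when present, got {self.patient_weight}"
            )
        for s in self.series:
            if s.study_id != self.study_id:
                raise ValueError(
                    f"series {s.series_uid} has study_id {s.study_id!r}, "
                    f"expected {self.study_id!r}"
                )

    def diagnostic_series(self) -> list[SeriesRecord]:
        """Series that are not scouts (order preserved)."""
        return [s for s in self.series if not s.is_scout]

    def replace_series(self, series: Sequence[SeriesRecord]) -> "StudyRecord":
        return dataclasses.replace(self, series=list(series))


@dataclass(frozen=True)
class MatchedPair:
    """The same irradiation event as seen by two monitoring systems."""

    dms_view: SeriesRecord
    dw_view: SeriesRecord

    def __post_init__(self) -> None:
        if self.dms_view.series_uid != self.dw_view.series_uid:
            raise ValueError("matched pair must share series_uid")


# ---------------------------------------------------------------------------
# Table dialect (column mapping) and I/O
# ---------------------------------------------------------------------------

#: Canonical field -> default CSV column name.
DEFAULT_COLUMNS: dict[str, str] = {
    "study_id": "study_id",
    "series_uid": "series_uid",
    "scanner_id": "scanner_id",
    "protocol_name": "protocol_name",
    "series_region": "series_region",
    "acquisition_type": "acquisition_type",
    "ctdi_vol": "ctdi_vol_mgy",
    "phantom": "phantom",
    "dlp": "dlp_mgy_cm",
    "scan_length": "scan_length_cm",
    "d_eff": "d_eff_cm",
    "d_water": "d_water_cm",
    "patient_age": "patient_age_y",
    "patient_sex": "patient_sex",
    "patient_weight": "patient_weight_kg",
    "study_alias": "study_alias",
}

MANDATORY_FIELDS = (
    "study_id",
    "series_uid",
    "ctdi_vol",
    "dlp",
    "scan_length",
    "patient_age",
)

_NUMERIC_FIELDS = ("ctdi_vol", "dlp", "scan_length", "d_eff", "d_water",
                   "patient_age", "patient_weight")


@dataclass(frozen=True)
class TableDialect:
    """Maps canonical field names onto file column names."""

    columns: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COLUMNS)
    )

    @classmethod
    def from_file(cls, path: str | Path) -> "TableDialect":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        cols = dict(DEFAULT_COLUMNS)
        cols.update(raw.get("columns", {}))
        return cls(columns=cols)


def _parse_enum(enum_cls, raw, default):
    if raw is None:
        return default
    text = str(raw).strip()
    if not text:
        return default
    try:
        return enum_cls(text)
    except ValueError:
        return default


def _parse_float(raw, *, row: int, column: str, optional: bool = False):
    if raw is None:
        if optional:
            return None
        raise RowValidationError(row, f"column {column!r} is empty")
    text = str(raw).strip()
    if not text or text.lower() == "nan":
        if optional:
            return None
        raise RowValidationError(row, f"column {column!r} is empty")
    try:
        return float(text)
    except ValueError:
        raise RowValidationError(
            row, f"column {column!r} value {text!r} is not numeric"
        ) from None


def _row_to_series(fields: Mapping[str, object], row: int) -> SeriesRecord:
    try:
        return SeriesRecord(
            study_id=str(fields["study_id"]),
            series_uid=str(fields["series_uid"]),
            scanner_id=_parse_enum(Scanner, fields.get("scanner_id"), Scanner.OTHER),
            protocol_name=str(fields.get("protocol_name") or ""),
            series_region=_parse_enum(
                SeriesRegion, fields.get("series_region"), SeriesRegion.UNDEFINED
            ),
            acquisition_type=_parse_enum(
                AcquisitionType, fields.get("acquisition_type"),
                AcquisitionType.HELICAL,
            ),
            ctdi_vol=fields["ctdi_vol"],
            phantom=_parse_enum(Phantom, fields.get("phantom"), Phantom.BODY32),
            dlp=fields["dlp"],
            scan_length=fields["scan_length"],
            d_eff=fields.get("d_eff"),
            d_water=fields.get("d_water"),
        )
    except ValueError as exc:
        raise RowValidationError(row, str(exc)) from exc


def _group_rows(parsed: list[tuple[SeriesRecord, Mapping[str, object]]]) -> list[StudyRecord]:
    studies: dict[str, StudyRecord] = {}
    for series, fields in parsed:
        sid = series.study_id
        if sid not in studies:
            studies[sid] = StudyRecord(
                study_id=sid,
                patient_age=fields["patient_age"],
                patient_sex=_parse_enum(Sex, fields.get("patient_sex"), Sex.UNKNOWN),
                patient_weight=fields.get("patient_weight"),
                study_alias=_parse_enum(
                    StudyAlias, fields.get("study_alias"), StudyAlias.UNDEFINED
                ),
            )
        studies[sid].series.append(series)
    return list(studies.values())


def read_series_table(
    path: str | Path, dialect: TableDialect | None = None
) -> list[StudyRecord]:
    """Read a delimited (CSV) or JSON-lines series table into studies.

    Rows are grouped by ``study_id`` in first-appearance order; within a
    study the series keep file order (taken to be acquisition order).
    Blank or unknown region labels map to ``undefined``.

    Raises
    ------
    SchemaError
        when a mandatory column is absent (the message names it).
    RowValidationError
        when a dose field is non-numeric (the message cites the row index).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        return _read_jsonl(path)

    dialect = dialect or TableDialect()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for fld in MANDATORY_FIELDS:
        col = dialect.columns[fld]
        if col not in frame.columns:
            raise SchemaError(f"mandatory column {col!r} (field {fld!r}) is missing")

    parsed: list[tuple[SeriesRecord, Mapping[str, object]]] = []
    for i, raw_row in enumerate(frame.to_dict(orient="records")):
        fields: dict[str, object] = {}
        for fld, col in dialect.columns.items():
            if col not in frame.columns:
                fields[fld] = None
                continue
            value = raw_row[col]
            if fld in _NUMERIC_FIELDS:
                fields[fld] = _parse_float(
                    value, row=i, column=col, optional=fld not in MANDATORY_FIELDS
                )
            else:
                fields[fld] = value
        parsed.append((_row_to_series(fields, i), fields))
    return _group_rows(parsed)


def _read_jsonl(path: Path) -> list[StudyRecord]:
    parsed = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line:
                continue
            fields = json.loads(line)
            for fld in MANDATORY_FIELDS:
                if fld not in fields:
                    raise SchemaError(f"mandatory field {fld!r} missing in line {i}")
            parsed.append((_row_to_series(fields, i), fields))
    return _group_rows(parsed)


def _series_row(study: StudyRecord, series: SeriesRecord) -> dict[str, object]:
    return {
        "study_id": series.study_id,
        "series_uid": series.series_uid,
        "scanner_id": series.scanner_id.value,
        "protocol_name": series.protocol_name,
        "series_region": series.series_region.value,
        "acquisition_type": series.acquisition_type.value,
        "ctdi_vol": series.ctdi_vol,
        "phantom": series.phantom.value,
        "dlp": series.dlp,
        "scan_length": series.scan_length,
        "d_eff": series.d_eff,
        "d_water": series.d_water,
        "patient_age": study.patient_age,
        "patient_sex": study.patient_sex.value,
        "patient_weight": study.patient_weight,
        "study_alias": study.study_alias.value,
    }


def write_series_table(
    studies: Iterable[StudyRecord],
    path: str | Path,
    dialect: TableDialect | None = None,
) -> Path:
    """Write one row per series; study-level fields are denormalized.

    Floats are serialized with ``repr`` so a read-back is bit-exact.
    A ``.jsonl`` suffix selects the JSON-lines variant.
    """
    path = Path(path)
    rows = [_series_row(st, s) for st in studies for s in st.series]
    if path.suffix.lower() in {".jsonl", ".ndjson"}:
        with open(path, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
        return path

    dialect = dialect or TableDialect()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        cols = [dialect.columns[f] for f in DEFAULT_COLUMNS]
        fh.write(",".join(cols) + "\n")
        for row in rows:
            out = []
            for fld in DEFAULT_COLUMNS:
                v = row[fld]
                if v is None:
                    out.append("")
                elif isinstance(v, float):
                    out.append(repr(v))
                else:
                    out.append(str(v))
            fh.write(",".join(out) + "\n")
    return path


# ---------------------------------------------------------------------------
# Cohort filtering
# ---------------------------------------------------------------------------

#: Machine-readable exclusion reason tags.
REASON_AGE = "age"
REASON_UNDEFINED_REGION = "undefined_region"
REASON_EXTREMITY = "extremity"
REASON_WHOLE_BODY = "whole_body"
REASON_PROTOCOL_PATTERN = "protocol_pattern"


@dataclass(frozen=True)
class FilterRules:
    """Cohort inclusion rules; defaults reproduce an adult-only cohort.

    The age cutoff is expressed as "exclude age < min_age" with a default
    of 16 years (configurable).
    """

    min_age: float = 16.0
    exclude_undefined_alias: bool = True
    extremity_patterns: tuple[str, ...] = (
        "extremit", "wrist", "ankle", "knee", "elbow", "hand", "foot",
        "shoulder", "hip ",
    )
    whole_body_patterns: tuple[str, ...] = ("whole body", "wholebody", "total body")
    protocol_patterns: tuple[str, ...] = ()


@dataclass(frozen=True)
class Exclusion:
    study: StudyRecord
    reason: str


def _any_protocol_matches(study: StudyRecord, patterns: Sequence[str]) -> bool:
    for s in study.series:
        name = s.protocol_name.lower()
        if any(p.lower() in name for p in patterns):
            return True
    return False


def filter_cohort(
    studies: Sequence[StudyRecord], rules: FilterRules | None = None
) -> tuple[list[StudyRecord], list[Exclusion]]:
    """Partition ``studies`` into (kept, excluded-with-reason).

    Every input study lands in exactly one of the two outputs; the first
    matching rule supplies the reason tag.
    """
    rules = rules or FilterRules()
    kept: list[StudyRecord] = []
    excluded: list[Exclusion] = []
    for study in studies:
        reason = None
        if study.patient_age < rules.min_age:
            reason = REASON_AGE
        elif rules.exclude_undefined_alias and study.study_alias is StudyAlias.UNDEFINED:
            reason = REASON_UNDEFINED_REGION
        elif _any_protocol_matches(study, rules.extremity_patterns):
            reason = REASON_EXTREMITY
        elif _any_protocol_matches(study, rules.whole_body_patterns):
            reason = REASON_WHOLE_BODY
        elif rules.protocol_patterns and _any_protocol_matches(
            study, rules.protocol_patterns
        ):
            reason = REASON_PROTOCOL_PATTERN
        if reason is None:
            kept.append(study)
        else:
            logger.info("excluded study=%s reason=%s", study.study_id, reason)
            excluded.append(Exclusion(study, reason))
    return kept, excluded


# ---------------------------------------------------------------------------
# Series matching across monitoring systems
# ---------------------------------------------------------------------------

def match_series(
    dms: Sequence[SeriesRecord], dw: Sequence[SeriesRecord]
) -> tuple[list[MatchedPair], list[SeriesRecord], list[SeriesRecord]]:
    """Match two per-system series lists on their series UID.

    Returns ``(pairs, unmatched_dms, unmatched_dw)``; the three outputs
    partition the union of inputs.  A duplicate UID inside either list is
    an error naming the UID.
    """
    def index(records: Sequence[SeriesRecord]) -> dict[str, SeriesRecord]:
        out: dict[str, SeriesRecord] = {}
        for r in records:
            if r.series_uid in out:
                raise DuplicateUidError(r.series_uid)
            out[r.series_uid] = r
        return out

    dms_by_uid = index(dms)
    dw_by_uid = index(dw)
    pairs = [
        MatchedPair(dms_view=r, dw_view=dw_by_uid[uid])
        for uid, r in dms_by_uid.items()
        if uid in dw_by_uid
    ]
    unmatched_dms = [r for r in dms if r.series_uid not in dw_by_uid]
    unmatched_dw = [r for r in dw if r.series_uid not in dms_by_uid]
    for r in unmatched_dms + unmatched_dw:
        logger.info("unmatched series_uid=%s", r.series_uid)
    return pairs, unmatched_dms, unmatched_dw


def summarize_alias_counts(studies: Sequence[StudyRecord]) -> dict[str, int]:
    """Per-alias study counts; values always sum to ``len(studies)``."""
    counts: dict[str, int] = {}
    for study in studies:
        counts[study.study_alias.value] = counts.get(study.study_alias.value, 0) + 1
    return counts
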