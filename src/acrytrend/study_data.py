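"""Typed data model and CSV I/O for aggregated biomonitoring study records.

The analysis unit is one study × sampling-year × smoking-stratum × analyte
report, as published (a ``StudyRecord``).  Individual paired blood/urine
measurements used to derive trans-matrix conversion factors are
``DualMatrixRecord``s, and the filtered, unit-unified table entering the
trend models is a list of ``HarmonizedRecord``s (a "harmonized panel").

Missing values are a first-class state: absent cells in the CSV map to
``None`` in memory and back to empty cells on write.  Zero is always a real
measurement, never a stand-in for "missing".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


# --------------------------------------------------------------------------
# errors

class SchemaError(ValueError):
    """The CSV header does not match the documented schema."""


class ParseError(ValueError):
    """A cell could not be parsed; message names the row and column."""


class ValidationError(ValueError):
    """A record violates a domain invariant."""


# --------------------------------------------------------------------------
# enums

class Matrix(str, enum.Enum):
    BLOOD = "blood"
    SPOT_URINE = "spot_urine"
    MORNING_URINE = "morning_urine"
    URINE_24H = "urine_24h"
    URINE_12H = "urine_12h"


class Smoking(str, enum.Enum):
    NONSMOKER = "nonsmoker"
    SMOKER = "smoker"
    MIXED = "mixed"


class Analyte(str, enum.Enum):
    AAMA = "AAMA"          # urinary acrylamide mercapturic acid, ug/L
    GAMA = "GAMA"          # urinary glycidamide mercapturic acid, ug/L
    AAVAL = "AAVal"        # hemoglobin acrylamide-valine adduct, pmol/g Hb
    GAVAL = "GAVal"        # hemoglobin glycidamide-valine adduct, pmol/g Hb


class Unit(str, enum.Enum):
    UG_PER_L = "ug_per_L"
    PMOL_PER_G_HB = "pmol_per_g_Hb"
    PMOL_PER_L = "pmol_per_L"
    UG_PER_G_CREATININE = "ug_per_g_creatinine"
    NMOL_PER_DAY = "nmol_per_day"


class Region(str, enum.Enum):
    NORTH = "north"
    CENTRAL_WEST = "central_west"
    SOUTH = "south"


class Source(str, enum.Enum):
    PUBLISHED = "published"
    ALIGNED = "aligned"


class Provenance(str, enum.Enum):
    """How a harmonized mean was obtained (color/pattern code of the overview)."""

    MEASURED_MEAN = "measured_mean"
    MEAN_FROM_MEDIAN_RANGE = "mean_from_median_range"
    MEAN_FROM_QUARTILES = "mean_from_quartiles"
    TRANS_MATRIX = "trans_matrix"
    TRANS_MATRIX_PLUS_MEDIAN = "trans_matrix_plus_median"


class AnalytePair(str, enum.Enum):
    AAVAL_AAMA = "AAVal_AAMA"
    GAVAL_GAMA = "GAVal_GAMA"


#: blood analyte measured in pmol/g Hb -> urinary metabolite in ug/L
PAIR_OF_BLOOD_ANALYTE = {Analyte.AAVAL: AnalytePair.AAVAL_AAMA,
                         Analyte.GAVAL: AnalytePair.GAVAL_GAMA}
URINE_ANALYTE_OF_PAIR = {AnalytePair.AAVAL_AAMA: Analyte.AAMA,
                         AnalytePair.GAVAL_GAMA: Analyte.GAMA}


# --------------------------------------------------------------------------
# records

@dataclass
class StudyRecord:
    """One aggregated study-year-stratum-analyte report, as published.

    Any subset of the summary statistics (mean, median, quartiles, range, sd)
    may be present; absent fields are ``None``.  ``lod_unknown`` marks ranges
    printed as "LOD–x" where the numeric detection limit was not given (the
    minimum is then stored absent).
    """

    study_id: str
    country: str
    matrix: Matrix
    smoking: Smoking
    analyte: Analyte
    n: int
    unit: Unit
    year_start: int | None = None
    year_end: int | None = None
    region: Region | None = None
    mean: float | None = None
    median: float | None = None
    q1: float | None = None
    q3: float | None = None
    min: float | None = None
    max: float | None = None
    sd: float | None = None
    lod: float | None = None
    lod_unknown: bool = False
    mean_age: float | None = None
    pct_male: float | None = None
    source: Source = Source.PUBLISHED
    excluded_flag: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"{self.study_id}: n must be >= 1, got {self.n}")
        if (self.year_start is not None and self.year_end is not None
                and self.year_start > self.year_end):
            raise ValidationError(
                f"{self.study_id}: year_start {self.year_start} > year_end {self.year_end}")
        if self.mean is None and self.median is None:
            raise ValidationError(
                f"{self.study_id}: at least one of mean/median must be present")
        if self.pct_male is not None and not 0.0 <= self.pct_male <= 100.0:
            raise ValidationError(
                f"{self.study_id}: pct_male {self.pct_male} outside [0, 100]")
        # order statistics, where simultaneously present, must be sorted
        chain = [self.min, self.q1, self.median, self.q3, self.max]
        present = [v for v in chain if v is not None]
        if any(lo > hi for lo, hi in zip(present, present[1:])):
            raise ValidationError(
                f"{self.study_id}: order statistics not sorted: "
                f"min={self.min} q1={self.q1} median={self.median} "
                f"q3={self.q3} max={self.max}")


@dataclass
class DualMatrixRecord:
    """One individual's simultaneously sampled blood adduct and urine metabolite."""

    subject_id: str
    blood_value: float      # pmol/g Hb
    urine_value: float      # ug/L
    analyte_pair: AnalytePair
    smoking: Smoking

    def __post_init__(self) -> None:
        if self.blood_value < 0 or self.urine_value < 0:
            raise ValidationError(
                f"{self.subject_id}: biomarker values must be non-negative")


@dataclass
class HarmonizedRecord:
    """One yearly mean after harmonization: ug/L, decimal year, provenance-tagged."""

    study_id: str
    year: float
    analyte: Analyte
    smoking: Smoking
    mean_ugL: float
    n: int
    provenance: Provenance
    sd_ugL: float | None = None
    mean_age: float | None = None
    pct_male: float | None = None
    multi_year: bool = False
    low_confidence: bool = False

    def __post_init__(self) -> None:
        if self.mean_ugL < 0:
            raise ValidationError(f"{self.study_id}: mean_ugL must be >= 0")
        if not 2000.0 <= self.year <= 2025.0:
            raise ValidationError(
                f"{self.study_id}: year {self.year} outside [2000, 2025]")


# --------------------------------------------------------------------------
# CSV schemas

_STUDY_COLUMNS = [
    "study_id", "country", "region", "year_start", "year_end", "matrix",
    "smoking", "analyte", "n", "mean", "median", "q1", "q3", "min", "max",
    "sd", "lod", "lod_unknown", "unit", "mean_age", "pct_male", "source",
    "excluded_flag", "exclusion_reason",
]
_STUDY_MANDATORY = {"study_id", "country", "matrix", "smoking", "analyte",
                    "n", "unit"}

_PANEL_COLUMNS = [
    "study_id", "year", "analyte", "smoking", "mean_ugL", "sd_ugL", "n",
    "mean_age", "pct_male", "provenance", "multi_year", "low_confidence",
]

_DUAL_COLUMNS = ["subject_id", "blood_value", "urine_value", "analyte_pair",
                 "smoking"]

_INT_FIELDS = {"year_start", "year_end", "n"}
_FLOAT_FIELDS = {"mean", "median", "q1", "q3", "min", "max", "sd", "lod",
                 "mean_age", "pct_male", "year", "mean_ugL", "sd_ugL",
                 "blood_value", "urine_value"}
_BOOL_FIELDS = {"lod_unknown", "excluded_flag", "multi_year", "low_confidence"}
_ENUM_FIELDS = {"matrix": Matrix, "smoking": Smoking, "analyte": Analyte,
                "unit": Unit, "source": Source, "provenance": Provenance,
                "region": Region, "analyte_pair": AnalytePair}


def _parse_cell(name: str, raw: object, row: int):
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return None
    text = str(raw).strip()
    if text == "":
        return None
    try:
        if name in _INT_FIELDS:
            return int(text)
        if name in _FLOAT_FIELDS:
            return float(text)
        if name in _BOOL_FIELDS:
            if text.lower() in ("true", "1"):
                return True
            if text.lower() in ("false", "0"):
                return False
            raise ValueError(text)
        if name in _ENUM_FIELDS:
            return _ENUM_FIELDS[name](text)
    except ValueError as exc:
        raise ParseError(
            f"row {row}: column '{name}': cannot parse {text!r}") from exc
    return text


def _read_table(path: str | Path, columns: Sequence[str],
                mandatory: set[str], cls):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = mandatory - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s): {sorted(missing)}")
    unknown = set(df.columns) - set(columns)
    if unknown:
        raise SchemaError(f"{path.name}: unknown column(s): {sorted(unknown)}")
    records, errors = [], []
    field_names = {f.name for f in fields(cls)}
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        kwargs = {}
        try:
            for name in df.columns:
                if name in field_names:
                    value = _parse_cell(name, getattr(row, name), i)
                    if value is not None or name in _BOOL_FIELDS:
                        if value is not None:
                            kwargs[name] = value
            records.append(cls(**kwargs))
        except (ParseError, ValidationError, TypeError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ParseError(f"{path.name}: {len(errors)} malformed row(s):\n"
                         + "\n".join(errors))
    return records


def _to_frame(records: Iterable, columns: Sequence[str]) -> pd.DataFrame:
    rows = []
    for rec in records:
        d = asdict(rec)
        row = {}
        for col in columns:
            v = d.get(col)
            if isinstance(v, enum.Enum):
                v = v.value
            if isinstance(v, bool):
                v = str(v)
            row[col] = "" if v is None else v
        rows.append(row)
    return pd.DataFrame(rows, columns=columns)


# --------------------------------------------------------------------------
# public I/O

def read_studies(path: str | Path) -> list[StudyRecord]:
    """Read aggregated study records from CSV; absent cells become ``None``."""
    return _read_table(path, _STUDY_COLUMNS, _STUDY_MANDATORY, StudyRecord)


def write_studies(records: Iterable[StudyRecord], path: str | Path) -> None:
    _to_frame(records, _STUDY_COLUMNS).to_csv(path, index=False)


def read_panel(path: str | Path) -> list[HarmonizedRecord]:
    """Read a harmonized panel written by :func:`write_panel`."""
    return _read_table(path, _PANEL_COLUMNS,
                       {"study_id", "year", "analyte", "smoking", "mean_ugL",
                        "n", "provenance"}, HarmonizedRecord)


def write_panel(panel: Iterable[HarmonizedRecord], path: str | Path) -> None:
    """Write a harmonized panel to CSV; read(write(panel)) is lossless."""
    _to_frame(panel, _PANEL_COLUMNS).to_csv(path, index=False)


def read_dual_matrix(path: str | Path) -> list[DualMatrixRecord]:
    return _read_table(path, _DUAL_COLUMNS, set(_DUAL_COLUMNS),
                       DualMatrixRecord)


def write_dual_matrix(records: Iterable[DualMatrixRecord],
                      path: str | Path) -> None:
    _to_frame(records, _DUAL_COLUMNS).to_csv(path, index=False)


# --------------------------------------------------------------------------
# packaged fixtures (hand-transcribed published-study overview tables)

def fixture_path(name: str) -> Path:
    """Path of a packaged fixture CSV (e.g. ``table2_aligned.csv``)."""
    return Path(resources.files("acrytrend").joinpath("fixtures", name))


def load_published_studies() -> list[StudyRecord]:
    """Aggregated European biomonitoring reports, 2001–2017 literature."""
    return read_studies(fixture_path("table1_published.csv"))


def load_aligned_studies() -> list[StudyRecord]:
    """HBM4EU Aligned Studies yearly means (2014–2021 surveys)."""
    return read_studies(fixture_path("table2_aligned.csv"))


def load_all_studies() -> list[StudyRecord]:
    return load_published_studies() + load_aligned_studies()
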