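"""Harmonization of heterogeneous study reports into a comparable panel.

Three computations bring published summaries onto a single scale:

1. *Mean/SD estimation from order statistics* (Hozo/Wan estimators).
   When only a median m with range [a, b] or quartiles (q1, q3) is
   published, the arithmetic mean is approximated by

       X1 = (a + 2m + b) / 4        (median + range)
       X2 = (q1 + m + q3) / 3       (median + quartiles)

   and the standard deviation by the sample-size-dependent rules
   S1 (n <= 15, small-sample formula), S2 = (b - a)/4 (15 < n <= 70) and
   S3 = (b - a)/6 (n > 70).

2. *Trans-matrix conversion.* Hemoglobin-adduct means (pmol/g Hb) are
   converted to urinary-metabolite equivalents (ug/L) through a
   zero-intercept proportionality factor fitted on paired individual
   blood/urine measurements (slope k = sum(u*b) / sum(b^2)); at zero
   exposure both biomarkers vanish, hence no intercept.

3. *Inclusion rules and year assignment*, applied in a fixed order, with
   every dropped record written to an exclusion log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .study_data import (
    Analyte,
    AnalytePair,
    DualMatrixRecord,
    HarmonizedRecord,
    Matrix,
    PAIR_OF_BLOOD_ANALYTE,
    Provenance,
    Smoking,
    StudyRecord,
    Unit,
    URINE_ANALYTE_OF_PAIR,
)


class DomainError(ValueError):
    """Input violates a mathematical precondition (ordering, sign)."""


class SingularFitError(ValueError):
    """The zero-intercept fit is undefined (all predictor values zero)."""


# --------------------------------------------------------------------------
# mean / SD estimators from order statistics

def estimate_mean_from_range(m: float, a: float, b: float) -> float:
    """Mean estimate (a + 2m + b)/4 from median m and range [a, b]."""
    if not a <= m <= b:
        raise DomainError(f"need a <= m <= b, got a={a}, m={m}, b={b}")
    return (a + 2.0 * m + b) / 4.0


def estimate_mean_from_quartiles(q1: float, m: float, q3: float) -> float:
    """Mean estimate (q1 + m + q3)/3 from median and quartiles."""
    if not q1 <= m <= q3:
        raise DomainError(f"need q1 <= m <= q3, got q1={q1}, m={m}, q3={q3}")
    return (q1 + m + q3) / 3.0


def estimate_sd(m: float, a: float, b: float, n: int) -> float:
    """SD estimate from median, range and sample size.

    n <= 15 uses the small-sample formula
    sqrt((1/12) * ((a - 2m + b)^2 / 4 + (b - a)^2)); larger samples use
    range/4 (n <= 70) or range/6 (n > 70).
    """
    if not a <= m <= b:
        raise DomainError(f"need a <= m <= b, got a={a}, m={m}, b={b}")
    if n < 1:
        raise DomainError(f"need n >= 1, got {n}")
    if n <= 15:
        return math.sqrt(((a - 2.0 * m + b) ** 2 / 4.0 + (b - a) ** 2) / 12.0)
    if n <= 70:
        return (b - a) / 4.0
    return (b - a) / 6.0


# --------------------------------------------------------------------------
# trans-matrix conversion

@dataclass(frozen=True)
class ConversionFactor:
    """Fitted blood -> urine proportionality: urine (ug/L) = slope * blood."""

    analyte_pair: AnalytePair
    slope: float                    # ug/L urine per pmol/g Hb blood
    se_slope: float | None = None
    n_fit: int | None = None
    r_squared: float | None = None
    fit_population: str = "smokers_included"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise DomainError(f"slope must be positive, got {self.slope}")
        if self.r_squared is not None and not 0.0 <= self.r_squared <= 1.0:
            raise DomainError(f"r_squared {self.r_squared} outside [0, 1]")


#: the two-decimal factors used for the worked validation arithmetic
PRINTED_FACTORS: Mapping[AnalytePair, ConversionFactor] = {
    AnalytePair.AAVAL_AAMA: ConversionFactor(AnalytePair.AAVAL_AAMA, 1.64),
    AnalytePair.GAVAL_GAMA: ConversionFactor(AnalytePair.GAVAL_GAMA, 0.35),
}


def fit_conversion_factor(records: Iterable[DualMatrixRecord],
                          pair: AnalytePair) -> ConversionFactor:
    """Zero-intercept least squares of urine on blood for one analyte pair.

    slope = sum(u*b)/sum(b^2); the SE and (uncentered) R^2 come from the
    no-intercept model with df = n - 1.
    """
    sub = [r for r in records if r.analyte_pair == pair]
    b = np.array([r.blood_value for r in sub], dtype=float)
    u = np.array([r.urine_value for r in sub], dtype=float)
    if b.size < 2:
        raise DomainError(f"need >= 2 records for {pair.value}, got {b.size}")
    sbb = float(b @ b)
    if sbb == 0.0:
        raise SingularFitError("all blood values are zero")
    slope = float(u @ b) / sbb
    resid = u - slope * b
    df = b.size - 1
    sigma2 = float(resid @ resid) / df
    se = math.sqrt(sigma2 / sbb)
    suu = float(u @ u)
    r2 = 1.0 - float(resid @ resid) / suu if suu > 0 else 0.0
    return ConversionFactor(pair, slope, se_slope=se, n_fit=b.size,
                            r_squared=max(0.0, min(1.0, r2)))


def blood_to_urine(value: float, factor: ConversionFactor) -> float:
    """Convert a blood adduct mean (pmol/g Hb) to a urinary mean (ug/L)."""
    if value < 0:
        raise DomainError(f"blood value must be >= 0, got {value}")
    return factor.slope * value


def relative_error(estimate: float, reference: float) -> float:
    """Signed percent deviation of an estimate from a reference value."""
    if reference <= 0:
        raise DomainError(f"reference must be > 0, got {reference}")
    return 100.0 * (estimate - reference) / reference


# --------------------------------------------------------------------------
# inclusion rules and panel assembly

@dataclass(frozen=True)
class HarmonizationRules:
    """Inclusion/exclusion and year-assignment policy for panel assembly."""

    min_n: int = 6
    allowed_urine_matrices: frozenset = frozenset(
        {Matrix.SPOT_URINE, Matrix.MORNING_URINE})
    require_smoking_stratified: bool = True
    multi_year_policy: str = "midpoint"           # or "exclude"
    apply_gama_trans_matrix: bool = False

    def __post_init__(self) -> None:
        if self.min_n < 1:
            raise DomainError(f"min_n must be >= 1, got {self.min_n}")
        if self.multi_year_policy not in ("midpoint", "exclude"):
            raise DomainError(
                f"unknown multi_year_policy {self.multi_year_policy!r}")


@dataclass(frozen=True)
class Exclusion:
    study_id: str
    analyte: str
    smoking: str
    rule: int
    reason: str


RULE_DESCRIPTIONS = {
    1: "smoking status not stratified (mixed population)",
    2: "fewer participants than the minimum sample size",
    3: "no assignable sampling year",
    4: "matrix/unit not harmonizable (24 h / 12 h urine, creatinine or per-day units)",
    5: "multi-year sampling window under 'exclude' policy",
    6: "no mean and no order statistics to estimate one",
    7: "blood record without applicable conversion factor",
    8: "flagged excluded in the source overview",
}


def _exclude(log: list[Exclusion], rec: StudyRecord, rule: int,
             extra: str = "") -> None:
    reason = RULE_DESCRIPTIONS[rule] + (f" ({extra})" if extra else "")
    log.append(Exclusion(rec.study_id, rec.analyte.value, rec.smoking.value,
                         rule, reason))


def harmonize(
    studies: Iterable[StudyRecord],
    rules: HarmonizationRules | None = None,
    factors: Mapping[AnalytePair, ConversionFactor] | None = None,
) -> tuple[list[HarmonizedRecord], list[Exclusion]]:
    """Apply inclusion rules, estimate missing means, convert blood records.

    Rules are applied in a fixed order (1 mixed-smoking, 2 minimum n,
    3 missing year, 4 matrix/unit, 5 year assignment, 6 mean estimation,
    7 trans-matrix conversion, 8 source-flagged exclusions); every dropped
    record is logged with its rule number.  The result is independent of
    input ordering.
    """
    rules = rules or HarmonizationRules()
    factors = PRINTED_FACTORS if factors is None else factors
    panel: list[HarmonizedRecord] = []
    log: list[Exclusion] = []

    for rec in studies:
        # 1. smoking stratification
        if rules.require_smoking_stratified and rec.smoking is Smoking.MIXED:
            _exclude(log, rec, 1)
            continue
        # 2. minimum sample size
        if rec.n < rules.min_n:
            _exclude(log, rec, 2, f"n={rec.n} < {rules.min_n}")
            continue
        # 3. assignable sampling year
        if rec.year_start is None or rec.year_end is None:
            _exclude(log, rec, 3)
            continue
        # 4. harmonizable matrix and unit
        if rec.matrix is Matrix.BLOOD:
            if rec.unit is not Unit.PMOL_PER_G_HB:
                _exclude(log, rec, 4, f"blood unit {rec.unit.value}")
                continue
        else:
            if rec.matrix not in rules.allowed_urine_matrices:
                _exclude(log, rec, 4, f"matrix {rec.matrix.value}")
                continue
            if rec.unit is not Unit.UG_PER_L:
                _exclude(log, rec, 4, f"urine unit {rec.unit.value}")
                continue
        # 5. year assignment
        multi_year = rec.year_end > rec.year_start
        if multi_year and rules.multi_year_policy == "exclude":
            _exclude(log, rec, 5)
            continue
        year = (rec.year_start + rec.year_end) / 2.0

        # 6. mean (and SD) estimation where no mean was published
        low_confidence = False
        sd = rec.sd
        if rec.mean is not None:
            mean = rec.mean
            provenance = Provenance.MEASURED_MEAN
        elif rec.q1 is not None and rec.q3 is not None:
            mean = estimate_mean_from_quartiles(rec.q1, rec.median, rec.q3)
            provenance = Provenance.MEAN_FROM_QUARTILES
        elif rec.max is not None and (rec.min is not None or rec.lod_unknown):
            # "LOD-x" ranges with unknown LOD: conservative a = 0, flagged
            a = rec.min if rec.min is not None else 0.0
            low_confidence = rec.min is None
            mean = estimate_mean_from_range(rec.median, a, rec.max)
            provenance = Provenance.MEAN_FROM_MEDIAN_RANGE
            if sd is None:
                sd = estimate_sd(rec.median, a, rec.max, rec.n)
        else:
            _exclude(log, rec, 6)
            continue

        # 7. trans-matrix conversion of blood adduct means
        analyte = rec.analyte
        if rec.matrix is Matrix.BLOOD:
            pair = PAIR_OF_BLOOD_ANALYTE.get(rec.analyte)
            if pair is None:
                _exclude(log, rec, 7, f"analyte {rec.analyte.value}")
                continue
            if (pair is AnalytePair.GAVAL_GAMA
                    and not rules.apply_gama_trans_matrix):
                _exclude(log, rec, 7,
                         "GAVal->GAMA conversion disabled (regional factors)")
                continue
            factor = factors.get(pair)
            if factor is None:
                _exclude(log, rec, 7, f"no factor for {pair.value}")
                continue
            mean = blood_to_urine(mean, factor)
            if sd is not None:
                sd = factor.slope * sd
            analyte = URINE_ANALYTE_OF_PAIR[pair]
            provenance = (Provenance.TRANS_MATRIX_PLUS_MEDIAN
                          if provenance is not Provenance.MEASURED_MEAN
                          else Provenance.TRANS_MATRIX)
        # 8. source-flagged exclusions (overlapping/invalid datasets)
        if rec.excluded_flag:
            _exclude(log, rec, 8, rec.exclusion_reason or "")
            continue

        panel.append(HarmonizedRecord(
            study_id=rec.study_id, year=year, analyte=analyte,
            smoking=rec.smoking, mean_ugL=mean, sd_ugL=sd, n=rec.n,
            mean_age=rec.mean_age, pct_male=rec.pct_male,
            provenance=provenance, multi_year=multi_year,
            low_confidence=low_confidence))

    panel.sort(key=lambda r: (r.year, r.study_id, r.analyte.value,
                              r.smoking.value))
    log.sort(key=lambda e: (e.study_id, e.analyte, e.smoking, e.rule))
    return panel, log


def panel_to_studies(panel: Iterable[HarmonizedRecord]) -> list[StudyRecord]:
    """View a harmonized panel as study records (for idempotence checks)."""
    out = []
    for rec in panel:
        year = int(round(rec.year))
        out.append(StudyRecord(
            study_id=rec.study_id, country="", region=None,
            year_start=year, year_end=year, matrix=Matrix.SPOT_URINE,
            smoking=rec.smoking, analyte=rec.analyte, n=rec.n,
            unit=Unit.UG_PER_L, mean=rec.mean_ugL, sd=rec.sd_ugL,
            mean_age=rec.mean_age, pct_male=rec.pct_male))
    return out


def select_panel(panel: Sequence[HarmonizedRecord],
                 analyte: Analyte | None = None,
                 smoking: Smoking | None = None) -> list[HarmonizedRecord]:
    """Subset a panel by analyte and/or smoking stratum."""
    out = list(panel)
    if analyte is not None:
        out = [r for r in out if r.analyte is analyte]
    if smoking is not None:
        out = [r for r in out if r.smoking is smoking]
    return out
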