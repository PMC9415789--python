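"""Synthetic data emulating every input the analysis assumes.

Biomarker concentrations are non-negative and right-skewed, so individual
exposure levels are drawn log-normal.  Three generators cover the three
input kinds:

* :func:`gen_dual_matrix` — paired individual blood-adduct / urinary-
  metabolite records with a proportional blood-urine relationship and
  multiplicative log-normal noise, stratified into smokers (higher
  exposure location) and non-smokers.
* :func:`gen_individual_study` — an individual-level exposure sample
  summarized as published order statistics (median, range, quartiles)
  with the true mean returned separately for estimator validation.
* :func:`gen_panel` — an aggregated yearly study panel with an injected
  linear or broken-line time trend, age and sex covariate effects, and
  between-study noise whose standard deviation scales as 1/sqrt(n/100),
  so that weighting trend fits by study size is efficient.

All randomness flows through ``numpy.random.default_rng`` (PCG64);
identical seeds give identical output across runs and platforms.  Truth
values are returned in separate sidecar objects and never appear in the
emitted record tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .study_data import (
    Analyte,
    AnalytePair,
    DualMatrixRecord,
    HarmonizedRecord,
    Matrix,
    Provenance,
    Smoking,
    StudyRecord,
    Unit,
)


class ConfigError(ValueError):
    """A scenario parameter is outside its admissible range."""


# --------------------------------------------------------------------------
# dual-matrix records (conversion-factor derivation)

@dataclass(frozen=True)
class DualMatrixScenario:
    """Paired blood/urine sampling with constant individual exposure.

    Defaults mirror the factor-derivation population: 24 subjects of whom
    13 smoke, true conversion slopes 1.64 (AAVal->AAMA) and 0.35
    (GAVal->GAMA), and 20% multiplicative noise.  Blood adduct levels are
    log-normal per stratum with a higher location for smokers
    (non-smokers ~27 pmol/g Hb median, smokers ~80 pmol/g Hb).
    """

    n_subjects: int = 24
    smoker_fraction: float = 13 / 24
    true_slope_aa: float = 1.64
    true_slope_ga: float = 0.35
    blood_mu: dict = field(default_factory=lambda: {
        "nonsmoker": math.log(27.0), "smoker": math.log(80.0)})
    blood_sigma: dict = field(default_factory=lambda: {
        "nonsmoker": 0.4, "smoker": 0.4})
    noise_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.smoker_fraction <= 1.0:
            raise ConfigError(
                f"smoker_fraction {self.smoker_fraction} outside [0, 1]")
        if self.noise_cv < 0:
            raise ConfigError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.true_slope_aa <= 0 or self.true_slope_ga <= 0:
            raise ConfigError("true slopes must be positive")
        if self.n_subjects < 2:
            raise ConfigError(f"need >= 2 subjects, got {self.n_subjects}")


def gen_dual_matrix(scn: DualMatrixScenario) -> list[DualMatrixRecord]:
    """Simulate paired records for both analyte pairs per subject.

    Urine = true_slope * blood * exp(eps) with eps normal, scaled so the
    multiplicative error has the requested coefficient of variation and
    mean one (E[urine | blood] = true_slope * blood exactly).
    """
    rng = np.random.default_rng(scn.seed)
    n_smokers = int(round(scn.smoker_fraction * scn.n_subjects))
    strata = ([Smoking.SMOKER] * n_smokers
              + [Smoking.NONSMOKER] * (scn.n_subjects - n_smokers))
    sigma_eps = math.sqrt(math.log(1.0 + scn.noise_cv**2))
    mu_eps = -0.5 * sigma_eps**2          # mean-one multiplicative error
    records = []
    for i, smoking in enumerate(strata):
        mu = scn.blood_mu[smoking.value]
        sig = scn.blood_sigma[smoking.value]
        for pair, slope in ((AnalytePair.AAVAL_AAMA, scn.true_slope_aa),
                            (AnalytePair.GAVAL_GAMA, scn.true_slope_ga)):
            blood = float(rng.lognormal(mu, sig))
            eps = (float(rng.normal(mu_eps, sigma_eps))
                   if sigma_eps > 0 else 0.0)
            records.append(DualMatrixRecord(
                subject_id=f"S{i + 1:03d}",
                blood_value=blood,
                urine_value=slope * blood * math.exp(eps),
                analyte_pair=pair, smoking=smoking))
    return records


# --------------------------------------------------------------------------
# individual study summarized as order statistics

def gen_individual_study(n: int, lognormal_mu: float, lognormal_sigma: float,
                         seed: int = 0, study_id: str = "SYN",
                         year: int = 2010,
                         ) -> tuple[StudyRecord, float]:
    """Draw n log-normal values and report only published-style summaries.

    Returns the record (median/quartiles/range, mean left absent) and the
    hidden sample mean for estimator validation.
    """
    if n < 6:
        raise ConfigError(
            f"n = {n} violates the minimum-sample inclusion rule (n >= 6)")
    if lognormal_sigma < 0:
        raise ConfigError("lognormal_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    values = rng.lognormal(lognormal_mu, lognormal_sigma, size=n)
    record = StudyRecord(
        study_id=study_id, country="", region=None,
        year_start=year, year_end=year,
        matrix=Matrix.SPOT_URINE, smoking=Smoking.NONSMOKER,
        analyte=Analyte.AAMA, n=n, unit=Unit.UG_PER_L,
        median=float(np.median(values)),
        q1=float(np.quantile(values, 0.25)),
        q3=float(np.quantile(values, 0.75)),
        min=float(values.min()), max=float(values.max()))
    return record, float(values.mean())


# --------------------------------------------------------------------------
# aggregated yearly panel with injected trend

@dataclass(frozen=True)
class PanelScenario:
    """Yearly study panel with a linear or one-breakpoint trend.

    Defaults encode the signal the European non-smoker data display:
    a rise of about +2.1 ug/L per year from 2001 up to a 2017 breakpoint
    with a decline of about -6 ug/L per year afterwards (the post-break
    slope the harmonized panel itself exhibits), study sizes spanning the
    reported N = 6 to N = 857, and between-study scatter of 8 ug/L for a
    100-participant study (scaled by 1/sqrt(n/100)).
    """

    years: tuple = tuple(range(2001, 2021))
    studies_per_year: int = 2
    n_range: tuple = (6, 857)
    intercept: float = 40.0           # ug/L at the first year
    slope_pre: float = 2.1            # ug/L per year
    slope_post: float = -6.0          # ug/L per year after the breakpoint
    psi: float | None = 2017.0        # true breakpoint; None = pure linear
    age_effect: float = -0.5          # ug/L per year of mean age
    sex_effect: float = 0.0           # ug/L per percent male
    age_range: tuple = (6.0, 45.0)
    pct_male_range: tuple = (35.0, 60.0)
    ref_age: float = 30.0
    between_study_sd: float = 8.0     # ug/L at n = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.years) < 2:
            raise ConfigError("need >= 2 years")
        if self.n_range[0] < 6:
            raise ConfigError(
                "minimum study size below the n >= 6 inclusion rule")
        if self.psi is not None and not (
                min(self.years) < self.psi < max(self.years)):
            raise ConfigError(
                f"psi {self.psi} outside the year range {self.years[0]}"
                f"-{self.years[-1]}")
        if self.between_study_sd < 0:
            raise ConfigError("between_study_sd must be >= 0")


def true_panel_mean(scn: PanelScenario, year: float, age: float,
                    pct_male: float) -> float:
    """Noise-free study mean under the scenario's broken-line trend."""
    t0 = min(scn.years)
    mu = scn.intercept + scn.slope_pre * (year - t0)
    if scn.psi is not None:
        mu += (scn.slope_post - scn.slope_pre) * max(year - scn.psi, 0.0)
    mu += scn.age_effect * (age - scn.ref_age)
    mu += scn.sex_effect * (pct_male - 50.0)
    return mu


def gen_panel(scn: PanelScenario,
              ) -> tuple[list[HarmonizedRecord], dict]:
    """Simulate a harmonized panel plus a truth sidecar.

    The sidecar carries the scenario parameters and per-record noise-free
    means; the panel records themselves contain no truth columns.
    Observed means are truncated at zero (concentrations are
    non-negative).
    """
    rng = np.random.default_rng(scn.seed)
    panel, truths = [], []
    idx = 0
    for year in scn.years:
        for _ in range(scn.studies_per_year):
            idx += 1
            n = int(rng.integers(scn.n_range[0], scn.n_range[1] + 1))
            age = float(rng.uniform(*scn.age_range))
            pct_male = float(rng.uniform(*scn.pct_male_range))
            mu = true_panel_mean(scn, year, age, pct_male)
            sd = scn.between_study_sd / math.sqrt(n / 100.0)
            observed = max(mu + float(rng.normal(0.0, sd)), 0.0)
            study_id = f"SYN{idx:03d}"
            panel.append(HarmonizedRecord(
                study_id=study_id, year=float(year), analyte=Analyte.AAMA,
                smoking=Smoking.NONSMOKER, mean_ugL=observed, n=n,
                mean_age=age, pct_male=pct_male,
                provenance=Provenance.MEASURED_MEAN))
            truths.append({"study_id": study_id, "year": year,
                           "true_mean": mu, "noise_sd": sd})
    sidecar = {"scenario": asdict(scn), "records": truths}
    return panel, sidecar
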