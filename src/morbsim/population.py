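"""Synthetic population generation and calibration targets.

This module is the close-to-reality stand-in for the survey, primary-care and
demographic inputs the real model consumes.  It produces:

* a cohort of simulants aged 30-100 with sex, deprivation decile (DIMD,
  1 = most deprived), fixed per-exposure normal scores (the Gaussian-copula
  ranks that persist for life), an initial smoking history, and seeded
  prevalent diseases;
* :class:`PopulationTargets` - the calibration targets (per-condition
  incidence, case fatality and initial prevalence by age/sex/deprivation with
  log-linear secular trends; an all-cause mortality envelope; year-specific
  population counts and entrants) that the disease and mortality engines
  calibrate to.

Exposure *values* are never stored at generation time: under the copula design
a simulant's exposure in any year is the stratum-year quantile function
evaluated at their fixed rank (see :mod:`morbsim.exposure`), which enforces
both lifelong quintile-group persistence and constant cross-exposure
correlations.

The generator's default parameters emulate the shape of English adult data
(survey-style exposure distributions with deprivation gradients, Gompertz-like
mortality, steeply age-graded incidence of degenerative disease); they are
synthetic and illustrative, not estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from ._streams import StreamFactory
from .registry import Registry, load_registry

__all__ = [
    "ExposureSpec",
    "SmokingConfig",
    "DiseaseTargetParams",
    "MortalityEnvelopeParams",
    "GeneratorConfig",
    "Cohort",
    "PopulationTargets",
    "default_generator_config",
    "default_rank_correlation",
    "generate_population",
    "project_population_targets",
    "verify_population_accounting",
]

#: Order of the latent normal scores in the copula (cigarettes is the
#: intensity rank of smokers; smoking is the status rank).
Z_VARS = (
    "bmi", "sbp", "total_cholesterol", "fruit", "vegetables",
    "physical_activity", "smoking", "cigarettes",
)

CONTINUOUS_EXPOSURES = (
    "bmi", "sbp", "total_cholesterol", "fruit", "vegetables", "physical_activity",
)


@dataclass(frozen=True)
class ExposureSpec:
    """Parametric stratum-year distribution of one continuous exposure.

    The location parameter evolves log-linearly in calendar time (log link for
    positive-scale exposures; logit link for the bounded active-days count).
    ``value = quantile(rank | age, sex, dimd, year)`` clamped to bounds.
    """

    name: str
    scale: str  # "continuous" | "count"
    lo: float
    hi: float
    base: float          # location at age 50, mid-deprivation, reference year
    sex_effect: float    # additive on the link scale for males
    age_slope: float     # per year of age, link scale
    dimd_slope: float    # per deprivation decile (1 most deprived), link scale
    sigma: float         # spread of the normal score on the link scale
    trend: float         # per calendar year, link scale ("log-linear trends")
    ref_year: int = 2013

    def location(self, age, sex, dimd, year):
        """Link-scale location; vectorised over simulants."""
        age = np.asarray(age, dtype=float)
        sex = np.asarray(sex, dtype=float)
        dimd = np.asarray(dimd, dtype=float)
        if self.scale == "count":
            eta0 = math.log(self.base / (self.hi - self.base))
        else:
            eta0 = math.log(self.base)
        return (
            eta0
            + self.sex_effect * sex
            + self.age_slope * (age - 50.0)
            + self.dimd_slope * (dimd - 5.5)
            + self.trend * (np.asarray(year, dtype=float) - self.ref_year)
        )

    def quantile(self, z, age, sex, dimd, year):
        """Exposure value at normal score ``z`` in the given stratum-year."""
        eta = self.location(age, sex, dimd, year) + self.sigma * np.asarray(z, float)
        if self.scale == "count":
            value = self.hi * expit(eta)
        else:
            value = np.exp(eta)
        return np.clip(value, self.lo, self.hi)


@dataclass(frozen=True)
class SmokingConfig:
    """Initial smoking states and annual transition rates."""

    p_current_base: float = 0.19   # at age 50, mid-deprivation, reference year
    p_current_age: float = -0.012  # logit per year of age
    p_current_dimd: float = 0.11   # logit per deprivation decile
    p_current_trend: float = -0.03  # logit per calendar year
    p_ex_base: float = 0.26
    p_ex_age: float = 0.02
    cigs_median: float = 12.0      # cigarettes/day among smokers
    cigs_sigma: float = 0.45
    initiation_rate: float = 0.002  # adults 30+, per year
    initiation_trend: float = -0.05  # log per calendar year
    cessation_rate: float = 0.035
    relapse_rate: float = 0.005
    ref_year: int = 2013

    def p_current(self, age, dimd, year):
        return expit(
            math.log(self.p_current_base / (1 - self.p_current_base))
            + self.p_current_age * (np.asarray(age, float) - 50.0)
            + self.p_current_dimd * (np.asarray(dimd, float) - 5.5)
            + self.p_current_trend * (np.asarray(year, float) - self.ref_year)
        )

    def p_ex(self, age):
        return expit(
            math.log(self.p_ex_base / (1 - self.p_ex_base))
            + self.p_ex_age * (np.asarray(age, float) - 50.0)
        )

    def initiation(self, year):
        return self.initiation_rate * math.exp(
            self.initiation_trend * (year - self.ref_year)
        )


@dataclass(frozen=True)
class DiseaseTargetParams:
    """Log-linear target rates for one condition.

    ``rate = base * exp(age_slope*(age-60) + dimd_slope*(dimd-5.5)
    + sex_effect*male + trend*(year-ref))`` clipped to a cap; zero below
    ``min_age`` and outside ``sex`` (for the sex-specific cancers).
    """

    inc0: float
    inc_age: float = 0.05
    inc_dimd: float = 0.03
    inc_sex: float = 0.0
    inc_trend: float = 0.0
    cf0: float = 0.01
    cf_age: float = 0.04
    prev0: float = 0.02
    prev_age: float = 0.05
    min_age: int = 30
    sex: str | None = None  # None, "m" or "f"
    ref_year: int = 2013

    def _rate(self, base, age_slope, age, sex, dimd, year, trend, cap):
        age = np.asarray(age, float)
        rate = base * np.exp(
            age_slope * (age - 60.0)
            + self.inc_dimd * (np.asarray(dimd, float) - 5.5)
            + self.inc_sex * np.asarray(sex, float)
            + trend * (np.asarray(year, float) - self.ref_year)
        )
        rate = np.where(age < self.min_age, 0.0, rate)
        if self.sex == "m":
            rate = np.where(np.asarray(sex) == 1, rate, 0.0)
        elif self.sex == "f":
            rate = np.where(np.asarray(sex) == 0, rate, 0.0)
        return np.clip(rate, 0.0, cap)

    def incidence(self, age, sex, dimd, year):
        return self._rate(self.inc0, self.inc_age, age, sex, dimd, year,
                          self.inc_trend, 0.5)

    def case_fatality(self, age, sex, dimd, year):
        return self._rate(self.cf0, self.cf_age, age, sex, dimd, year, 0.0, 0.8)

    def prevalence(self, age, sex, dimd):
        return self._rate(self.prev0, self.prev_age, age, sex, dimd,
                          self.ref_year, 0.0, 0.9)


@dataclass(frozen=True)
class MortalityEnvelopeParams:
    """All-cause mortality target (Gompertz in age, graded by deprivation)."""

    base: float = 4.5e-4   # at age 30
    age_slope: float = 0.094
    sex_effect: float = 0.3
    dimd_slope: float = 0.04
    trend: float = -0.005
    cap: float = 0.7
    ref_year: int = 2013

    def rate(self, age, sex, dimd, year):
        return np.clip(
            self.base
            * np.exp(
                self.age_slope * (np.asarray(age, float) - 30.0)
                + self.sex_effect * np.asarray(sex, float)
                + self.dimd_slope * (np.asarray(dimd, float) - 5.5)
                + self.trend * (np.asarray(year, float) - self.ref_year)
            ),
            0.0,
            self.cap,
        )


def default_rank_correlation() -> pd.DataFrame:
    """Spearman rank-correlation targets between the latent exposure ranks.

    Converted internally to normal-score correlations via the exact Gaussian
    copula relation rho_z = 2 sin(pi * rho_s / 6), so the *empirical rank*
    correlations of a generated cohort match these numbers.
    """
    r = pd.DataFrame(np.eye(len(Z_VARS)), index=Z_VARS, columns=Z_VARS)

    def set_(a, b, v):
        r.loc[a, b] = v
        r.loc[b, a] = v

    set_("bmi", "sbp", 0.30)
    set_("bmi", "total_cholesterol", 0.25)
    set_("sbp", "total_cholesterol", 0.20)
    set_("fruit", "vegetables", 0.50)
    set_("fruit", "physical_activity", 0.25)
    set_("vegetables", "physical_activity", 0.25)
    set_("bmi", "fruit", -0.15)
    set_("bmi", "physical_activity", -0.20)
    set_("smoking", "fruit", -0.20)
    set_("smoking", "physical_activity", -0.15)
    set_("smoking", "cigarettes", 0.60)
    return r


def _default_exposures() -> dict[str, ExposureSpec]:
    return {
        "bmi": ExposureSpec("bmi", "continuous", 15.0, 60.0, base=27.0,
                            sex_effect=0.01, age_slope=0.002, dimd_slope=0.008,
                            sigma=0.17, trend=0.001),
        "sbp": ExposureSpec("sbp", "continuous", 80.0, 220.0, base=126.0,
                            sex_effect=0.025, age_slope=0.0035,
                            dimd_slope=0.002, sigma=0.11, trend=-0.002),
        "total_cholesterol": ExposureSpec(
            "total_cholesterol", "continuous", 2.0, 12.0, base=5.3,
            sex_effect=0.0, age_slope=0.002, dimd_slope=0.004,
            sigma=0.18, trend=-0.004),
        "fruit": ExposureSpec("fruit", "continuous", 0.0, 1500.0, base=180.0,
                              sex_effect=-0.10, age_slope=0.006,
                              dimd_slope=-0.04, sigma=0.8, trend=0.003),
        "vegetables": ExposureSpec("vegetables", "continuous", 0.0, 1500.0,
                                   base=190.0, sex_effect=-0.05,
                                   age_slope=0.004, dimd_slope=-0.035,
                                   sigma=0.7, trend=0.002),
        "physical_activity": ExposureSpec(
            "physical_activity", "count", 0.0, 7.0, base=3.0,
            sex_effect=0.10, age_slope=-0.012, dimd_slope=-0.06,
            sigma=1.1, trend=0.002),
    }


def _default_disease_params() -> dict[str, DiseaseTargetParams]:
    p = DiseaseTargetParams
    return {
        "dementia": p(inc0=0.0018, inc_age=0.16, inc_sex=-0.05, inc_trend=0.005,
                      cf0=0.12, cf_age=0.03, prev0=0.006, prev_age=0.17,
                      min_age=55),
        "breast_cancer": p(inc0=0.0022, inc_age=0.03, cf0=0.025,
                           prev0=0.02, prev_age=0.04, sex="f"),
        "colorectal_cancer": p(inc0=0.0006, inc_age=0.07, cf0=0.05,
                               prev0=0.005, prev_age=0.06),
        "lung_cancer": p(inc0=0.0005, inc_age=0.08, inc_sex=0.3,
                         inc_trend=-0.01, cf0=0.25, prev0=0.002, prev_age=0.07),
        "prostate_cancer": p(inc0=0.002, inc_age=0.09, cf0=0.035,
                             prev0=0.015, prev_age=0.1, sex="m"),
        "other_cancers": p(inc0=0.005, inc_age=0.06, cf0=0.08,
                           prev0=0.04, prev_age=0.05),
        "copd": p(inc0=0.003, inc_age=0.07, inc_dimd=0.08, inc_sex=0.1,
                  inc_trend=-0.005, cf0=0.06, prev0=0.03, prev_age=0.08),
        "atrial_fibrillation": p(inc0=0.004, inc_age=0.09, inc_sex=0.2,
                                 cf0=0.03, prev0=0.03, prev_age=0.1),
        "heart_failure": p(inc0=0.002, inc_age=0.10, inc_sex=0.2, cf0=0.10,
                           prev0=0.012, prev_age=0.11),
        "constipation": p(inc0=0.016, inc_age=0.04, cf0=0.001,
                          prev0=0.06, prev_age=0.04),
        "epilepsy": p(inc0=0.0008, inc_age=0.01, cf0=0.01,
                      prev0=0.010, prev_age=0.0),
        "chronic_pain": p(inc0=0.020, inc_age=0.02, inc_dimd=0.06, cf0=0.0005,
                          prev0=0.12, prev_age=0.02),
        "stroke": p(inc0=0.002, inc_age=0.09, inc_sex=0.15, inc_trend=-0.01,
                    cf0=0.08, prev0=0.015, prev_age=0.09),
        "diabetes_type1": p(inc0=0.0003, inc_age=0.0, cf0=0.01,
                            prev0=0.006, prev_age=0.0),
        "diabetes_type2": p(inc0=0.006, inc_age=0.04, inc_dimd=0.06,
                            inc_sex=0.15, inc_trend=0.01, cf0=0.015,
                            prev0=0.06, prev_age=0.05),
        "alcohol_problems": p(inc0=0.003, inc_age=-0.02, inc_dimd=0.08,
                              inc_sex=0.4, cf0=0.01, prev0=0.03, prev_age=-0.02),
        "psychosis_bipolar": p(inc0=0.0008, inc_age=-0.01, inc_dimd=0.07,
                               cf0=0.005, prev0=0.012, prev_age=-0.01),
        "ckd": p(inc0=0.003, inc_age=0.09, cf0=0.02, prev0=0.025,
                 prev_age=0.10),
        "anxiety_depression": p(inc0=0.020, inc_age=-0.01, inc_dimd=0.04,
                                inc_sex=-0.4, cf0=0.0005,
                                prev0=0.14, prev_age=-0.01),
        "chd": p(inc0=0.005, inc_age=0.07, inc_dimd=0.05, inc_sex=0.4,
                 inc_trend=-0.015, cf0=0.03, prev0=0.05, prev_age=0.08),
        "rheumatoid_arthritis": p(inc0=0.0008, inc_age=0.02, inc_sex=-0.3,
                                  cf0=0.005, prev0=0.010, prev_age=0.03),
        "other_connective_tissue": p(inc0=0.001, inc_age=0.02, cf0=0.003,
                                     prev0=0.015, prev_age=0.03),
        "ibs": p(inc0=0.004, inc_age=-0.02, inc_sex=-0.3, cf0=0.0002,
                 prev0=0.05, prev_age=-0.02),
        "asthma": p(inc0=0.003, inc_age=-0.01, cf0=0.002,
                    prev0=0.08, prev_age=-0.01),
        "hearing_loss": p(inc0=0.004, inc_age=0.08, cf0=0.0001,
                          prev0=0.04, prev_age=0.09),
        "hypertension": p(inc0=0.015, inc_age=0.04, inc_dimd=0.03,
                          inc_trend=-0.005, cf0=0.002, prev0=0.22,
                          prev_age=0.05),
    }


@dataclass
class GeneratorConfig:
    """Everything the synthetic-population generator needs."""

    n_simulants: int = 10_000
    start_year: int = 2013
    end_year: int = 2043
    min_age: int = 30
    max_age: int = 100
    entrants_per_year: int | None = None  # default ~1.3% of the cohort
    exposures: dict[str, ExposureSpec] = field(default_factory=_default_exposures)
    rank_correlation: pd.DataFrame = field(default_factory=default_rank_correlation)
    smoking: SmokingConfig = field(default_factory=SmokingConfig)
    disease_params: dict[str, DiseaseTargetParams] = field(
        default_factory=_default_disease_params
    )
    mortality: MortalityEnvelopeParams = field(
        default_factory=MortalityEnvelopeParams
    )
    ets_coupling: float = 0.9  # ETS exposure probability per unit smoking prevalence
    max_backdate_years: int = 15  # longest pre-existing disease duration at seeding

    def __post_init__(self) -> None:
        if self.entrants_per_year is None:
            self.entrants_per_year = max(1, round(0.013 * self.n_simulants))

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    def normal_score_correlation(self) -> np.ndarray:
        """Convert Spearman targets to the copula's normal-score correlation."""
        rho_s = self.rank_correlation.loc[list(Z_VARS), list(Z_VARS)].to_numpy(float)
        rho_z = 2.0 * np.sin(np.pi * rho_s / 6.0)
        np.fill_diagonal(rho_z, 1.0)
        eig = np.linalg.eigvalsh(rho_z)
        if eig.min() < -1e-10:
            raise ValueError(
                "infeasible correlation matrix (not positive semi-definite "
                f"after copula conversion; min eigenvalue {eig.min():.3g})"
            )
        return rho_z


def default_generator_config(registry: Registry | None = None,
                             **overrides) -> GeneratorConfig:
    cfg = GeneratorConfig(**overrides)
    registry = registry or load_registry()
    missing = set(registry.conditions) - set(cfg.disease_params)
    if missing:
        raise ValueError(f"no disease target parameters for: {sorted(missing)}")
    return cfg


@dataclass
class Cohort:
    """Vectorised simulant attributes (one entry per roster member,
    including future entrants flagged by ``entry_year``)."""

    ids: np.ndarray
    sex: np.ndarray          # 0 female, 1 male
    age_entry: np.ndarray    # age at entry year
    dimd: np.ndarray         # deprivation decile, 1 = most deprived
    entry_year: np.ndarray
    z: np.ndarray            # (n, len(Z_VARS)) fixed normal scores
    smk_status: np.ndarray   # 0 never, 1 current, 2 ex (state at entry)
    cigs_per_day: np.ndarray
    pack_years: np.ndarray
    years_since_quit: np.ndarray
    disease_state: dict[str, np.ndarray]   # 0 free, 1 active, 2 recovered
    onset_year: dict[str, np.ndarray]
    ever_had: dict[str, np.ndarray]

    @property
    def n(self) -> int:
        return self.ids.size

    @property
    def quintile(self) -> np.ndarray:
        """IMD quintile group 1-5 (1 = most deprived); deciles pair up."""
        return (self.dimd + 1) // 2

    def age_at(self, year: int) -> np.ndarray:
        return self.age_entry + (year - self.entry_year)

    def z_of(self, name: str) -> np.ndarray:
        return self.z[:, Z_VARS.index(name)]

    def rank_of(self, name: str) -> np.ndarray:
        from scipy.special import ndtr

        return ndtr(self.z_of(name))

    def entered(self, year: int) -> np.ndarray:
        return self.entry_year <= year

    def copy(self) -> "Cohort":
        return Cohort(
            ids=self.ids.copy(), sex=self.sex.copy(),
            age_entry=self.age_entry.copy(), dimd=self.dimd.copy(),
            entry_year=self.entry_year.copy(), z=self.z.copy(),
            smk_status=self.smk_status.copy(),
            cigs_per_day=self.cigs_per_day.copy(),
            pack_years=self.pack_years.copy(),
            years_since_quit=self.years_since_quit.copy(),
            disease_state={k: v.copy() for k, v in self.disease_state.items()},
            onset_year={k: v.copy() for k, v in self.onset_year.items()},
            ever_had={k: v.copy() for k, v in self.ever_had.items()},
        )


@dataclass
class PopulationTargets:
    """Calibration targets: rate surfaces plus the demographic accounting."""

    config: GeneratorConfig
    counts: pd.DataFrame          # year x age x sex -> target population
    entrants: dict[int, int]

    def incidence_rate(self, condition, age, sex, dimd, year):
        return self.config.disease_params[condition].incidence(age, sex, dimd, year)

    def case_fatality_rate(self, condition, age, sex, dimd, year):
        return self.config.disease_params[condition].case_fatality(
            age, sex, dimd, year)

    def initial_prevalence(self, condition, age, sex, dimd):
        return self.config.disease_params[condition].prevalence(age, sex, dimd)

    def mortality_rate(self, age, sex, dimd, year):
        return self.config.mortality.rate(age, sex, dimd, year)


# ---------------------------------------------------------------------------


def _sample_ages(rng: np.random.Generator, n: int, lo: int, hi: int) -> np.ndarray:
    """Adult age structure: slow decline to ~75, steeper after."""
    ages = np.arange(lo, hi + 1)
    w = np.exp(-0.013 * (ages - lo)) * np.exp(-0.065 * np.maximum(ages - 75, 0.0))
    w /= w.sum()
    return rng.choice(ages, size=n, p=w).astype(np.int16)


def generate_population(
    config: GeneratorConfig,
    seed: int | StreamFactory,
    registry: Registry | None = None,
) -> tuple[Cohort, PopulationTargets, dict[str, ExposureSpec]]:
    """Generate the roster (initial cohort + future entrants) and its targets.

    Reproducible given the seed; two calls with identical arguments return
    byte-identical cohorts.
    """
    registry = registry or load_registry()
    streams = seed if isinstance(seed, StreamFactory) else StreamFactory(seed)
    n0 = config.n_simulants
    years_after = list(range(config.start_year + 1, config.end_year + 1))
    n_entrants = config.entrants_per_year * len(years_after)
    n = n0 + n_entrants

    rng = streams("generate")
    sex = (rng.random(n) < 0.5).astype(np.int8)
    dimd = rng.integers(1, 11, size=n).astype(np.int8)
    age_entry = np.empty(n, dtype=np.int16)
    age_entry[:n0] = _sample_ages(rng, n0, config.min_age, config.max_age)
    age_entry[n0:] = config.min_age
    entry_year = np.full(n, config.start_year, dtype=np.int16)
    entry_year[n0:] = np.repeat(years_after, config.entrants_per_year)

    # Gaussian copula: fixed normal scores with the configured correlations.
    corr = config.normal_score_correlation()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))
    z = rng.standard_normal((n, len(Z_VARS))) @ chol.T

    cohort = Cohort(
        ids=np.arange(n, dtype=np.int64),
        sex=sex, age_entry=age_entry, dimd=dimd, entry_year=entry_year, z=z,
        smk_status=np.zeros(n, dtype=np.int8),
        cigs_per_day=np.zeros(n), pack_years=np.zeros(n),
        years_since_quit=np.zeros(n),
        disease_state={}, onset_year={}, ever_had={},
    )
    _init_smoking(cohort, config, rng)
    _seed_diseases(cohort, config, registry, streams)

    targets = build_targets(config, cohort)
    return cohort, targets, dict(config.exposures)


def _init_smoking(cohort: Cohort, config: GeneratorConfig,
                  rng: np.random.Generator) -> None:
    """Initial status from the smoking rank; intensity from the cigarettes rank."""
    from scipy.special import ndtr

    smk = config.smoking
    r = ndtr(cohort.z_of("smoking"))
    p_cur = smk.p_current(cohort.age_entry, cohort.dimd, cohort.entry_year)
    p_ex = smk.p_ex(cohort.age_entry)
    cur = r > 1.0 - p_cur
    ex = (~cur) & (r > 1.0 - p_cur - p_ex)
    cohort.smk_status[:] = 0
    cohort.smk_status[cur] = 1
    cohort.smk_status[ex] = 2
    cigs = np.exp(math.log(smk.cigs_median)
                  + smk.cigs_sigma * cohort.z_of("cigarettes"))
    cigs = np.clip(cigs, 1.0, 60.0)
    cohort.cigs_per_day[:] = np.where(cur, cigs, 0.0)
    years_smoked = np.maximum(cohort.age_entry - 20, 1).astype(float)
    ever = cur | ex
    cohort.pack_years[:] = np.where(ever, cigs / 20.0 * years_smoked * 0.8, 0.0)
    ysq = np.minimum(rng.integers(1, 21, cohort.n), np.maximum(
        cohort.age_entry - 25, 1))
    cohort.years_since_quit[:] = np.where(ex, ysq, 0.0)
    # Ex-smokers stopped accruing pack-years when they quit.
    cohort.pack_years[ex] *= 0.6


def _seed_diseases(cohort: Cohort, config: GeneratorConfig,
                   registry: Registry, streams: StreamFactory) -> None:
    """Draw initial disease states from the configured initial prevalence;
    onset years are back-dated so durations are realistic at entry."""
    for ci, name in enumerate(registry.condition_order):
        params = config.disease_params[name]
        rng = streams("seed_disease", ci)
        p = params.prevalence(cohort.age_entry, cohort.sex, cohort.dimd)
        active = rng.random(cohort.n) < p
        spec = registry.conditions[name]
        max_back = 9 if spec.is_cancer else config.max_backdate_years
        back = rng.integers(0, max_back + 1, cohort.n)
        onset = (cohort.entry_year - back).astype(np.int16)
        state = np.zeros(cohort.n, dtype=np.int8)
        state[active] = 1
        cohort.disease_state[name] = state
        cohort.onset_year[name] = np.where(active, onset, np.int16(-1)).astype(np.int16)
        cohort.ever_had[name] = active.copy()


def build_targets(config: GeneratorConfig, cohort: Cohort) -> PopulationTargets:
    """Project the year x age x sex population counts forward from the initial
    cohort under the mortality envelope and the configured entrants."""
    initial = cohort.entry_year == config.start_year
    base = (
        pd.DataFrame({
            "age": cohort.age_entry[initial],
            "sex": cohort.sex[initial],
        })
        .value_counts()
        .rename("count")
        .reset_index()
    )
    entrants = {
        year: int(np.sum(cohort.entry_year == year))
        for year in range(config.start_year + 1, config.end_year + 1)
    }
    counts = project_population_targets(
        base, entrants, config.mortality, config.years,
        min_age=config.min_age, max_age=config.max_age,
    )
    return PopulationTargets(config=config, counts=counts, entrants=entrants)


def project_population_targets(
    base_counts: pd.DataFrame,
    entrants: Mapping[int, float],
    envelope: MortalityEnvelopeParams,
    years: Iterable[int],
    min_age: int = 30,
    max_age: int = 100,
    check_tol: float = 0.005,
) -> pd.DataFrame:
    """Closed demographic accounting: counts(t+1) at age a+1 equal counts(t)
    at age a minus expected deaths, with entrants arriving at the minimum age;
    the open top age bin absorbs.  The identity is re-verified before
    returning and deviations above ``check_tol`` raise.
    """
    years = list(years)
    ages = np.arange(min_age, max_age + 1)
    table = np.zeros((len(years), ages.size, 2))
    start = {(int(r.age), int(r.sex)): float(r.count)
             for r in base_counts.itertuples(index=False)}
    for j, a in enumerate(ages):
        for s in (0, 1):
            table[0, j, s] = start.get((a, s), 0.0)
    mid_dimd = 5.5
    for t in range(1, len(years)):
        year_prev = years[t - 1]
        for s in (0, 1):
            m = envelope.rate(ages, s, mid_dimd, year_prev)
            survivors = table[t - 1, :, s] * (1.0 - m)
            table[t, 1:, s] = survivors[:-1]
            table[t, -1, s] += survivors[-1]  # open interval at the cap
            table[t, 0, s] = entrants.get(years[t], 0.0) / 2.0
    frames = []
    for t, year in enumerate(years):
        for s in (0, 1):
            frames.append(pd.DataFrame({
                "year": year, "age": ages, "sex": s, "count": table[t, :, s]}))
    counts = pd.concat(frames, ignore_index=True)
    dev = verify_population_accounting(counts, envelope, entrants,
                                       min_age=min_age, max_age=max_age)
    if dev > check_tol:
        raise ValueError(
            f"population accounting identity violated (max deviation {dev:.4f})"
        )
    return counts


def verify_population_accounting(
    counts: pd.DataFrame,
    envelope: MortalityEnvelopeParams,
    entrants: Mapping[int, float],
    min_age: int = 30,
    max_age: int = 100,
) -> float:
    """Max relative deviation of counts(t+1) from survivors(t) + entrants(t+1)."""
    years = sorted(counts["year"].unique())
    dev = 0.0
    for y0, y1 in zip(years[:-1], years[1:]):
        for s in (0, 1):
            c0 = (counts.query("year == @y0 and sex == @s")
                  .set_index("age")["count"].reindex(
                      range(min_age, max_age + 1), fill_value=0.0))
            c1 = (counts.query("year == @y1 and sex == @s")
                  .set_index("age")["count"].reindex(
                      range(min_age, max_age + 1), fill_value=0.0))
            m = envelope.rate(c0.index.to_numpy(), s, 5.5, y0)
            surv = c0.to_numpy() * (1.0 - m)
            expected = np.zeros_like(surv)
            expected[1:] = surv[:-1]
            expected[-1] += surv[-1]
            expected[0] = entrants.get(y1, 0.0) / 2.0
            total0, total1 = expected.sum(), c1.to_numpy().sum()
            if total1 > 0:
                dev = max(dev, abs(total0 - total1) / total1)
    return dev
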