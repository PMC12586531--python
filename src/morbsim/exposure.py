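"""Exposure trajectories: log-linear trends, smoking dynamics, ETS, lag buffers.

Continuous exposures are deterministic given a simulant's fixed normal score:
the value in any year is the stratum-year quantile function evaluated at the
lifelong rank (Gaussian copula).  That single mechanism delivers the two
exposure-module assumptions - simulants stay in the same exposure quintile
group for life, and cross-exposure correlations stay constant over time -
while the location parameter of each distribution drifts log-linearly.

Smoking is genuinely dynamic (initiation, cessation, relapse, pack-year
accrual) and environmental tobacco smoke (ETS) exposure is derived each year
from the stratum smoking prevalence, so both are simulated forward and stored.

:class:`Trajectories` is the lag buffer: full per-year matrices covering the
simulation horizon plus ``max_lag`` years of back-filled history, so the value
consulted for a link with lag L in year t is exactly the value produced for
year t - L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import ndtri

from ._streams import StreamFactory
from .population import (
    CONTINUOUS_EXPOSURES,
    Cohort,
    ExposureSpec,
    GeneratorConfig,
)

__all__ = [
    "project_exposure",
    "update_smoking",
    "derive_ets",
    "Trajectories",
    "simulate_base_trajectories",
]

NEVER, CURRENT, EX = 0, 1, 2


def project_exposure(spec: ExposureSpec, rank, age, sex, dimd, year):
    """Exposure value at a percentile rank in a stratum-year.

    The location of the stratum distribution evolves log-linearly (log link
    for positive-scale exposures, logit for the bounded count scale); the
    value is the distribution's quantile at ``rank``, clamped to bounds.
    """
    rank = np.asarray(rank, dtype=float)
    if np.any((rank <= 0.0) | (rank >= 1.0)):
        raise ValueError("rank must lie strictly inside (0, 1)")
    return spec.quantile(ndtri(rank), age, sex, dimd, year)


def update_smoking(
    status: np.ndarray,
    cigs_per_day: np.ndarray,
    pack_years: np.ndarray,
    years_since_quit: np.ndarray,
    initiation: float | np.ndarray,
    cessation: float | np.ndarray,
    draws: np.ndarray,
    relapse: float | np.ndarray = 0.0,
    new_cigs: np.ndarray | float = 10.0,
):
    """One annual smoking transition (pure; returns new arrays).

    never -> current with the initiation probability; current -> ex with the
    cessation probability; ex -> current with the relapse probability (resetting
    years_since_quit on relapse).  Pack-years accrue at cigarettes/20 per year
    while current; years_since_quit increments while ex.
    """
    for name, p in (("initiation", initiation), ("cessation", cessation),
                    ("relapse", relapse)):
        if np.any((np.asarray(p) < 0) | (np.asarray(p) > 1)):
            raise ValueError(f"{name} rate must lie in [0, 1]")
    status = status.copy()
    cigs = cigs_per_day.copy()
    pack = pack_years.copy()
    ysq = years_since_quit.copy()

    was_current = status == CURRENT
    was_ex = status == EX
    was_never = status == NEVER

    # pack-years accrue for the year spent smoking before any transition
    pack[was_current] += cigs[was_current] / 20.0

    start = was_never & (draws < initiation)
    stop = was_current & (draws < cessation)
    relapsed = was_ex & (draws < relapse)

    status[start] = CURRENT
    cigs[start] = np.broadcast_to(np.asarray(new_cigs, float), status.shape)[start]
    status[stop] = EX
    ysq[stop] = 0.0
    cigs[stop] = 0.0
    status[relapsed] = CURRENT
    ysq[relapsed] = 0.0

    still_ex = (status == EX) & ~stop
    ysq[still_ex] += 1.0
    return status, cigs, pack, ysq


def derive_ets(is_current_smoker, smoking_prevalence, coupling: float):
    """Probability of ETS exposure for non-smokers: ``coupling x stratum
    smoking prevalence``, truncated to [0, 1].  Current smokers carry direct
    smoking risk, never ETS."""
    if np.any(np.asarray(is_current_smoker)):
        raise ValueError("ETS exposure is defined for non-smokers only")
    prev = np.asarray(smoking_prevalence, dtype=float)
    if np.any((prev < 0) | (prev > 1)):
        raise ValueError("smoking prevalence must lie in [0, 1]")
    return np.clip(coupling * prev, 0.0, 1.0)


@dataclass
class Trajectories:
    """Per-simulant annual exposure matrices over [first_year, last_year].

    This is the lag ring made explicit: ``value(name, year - lag)`` is the
    exact value produced for that year, including the back-filled pre-start
    history that seeds the buffer.
    """

    first_year: int
    continuous: dict[str, np.ndarray]       # name -> (n, T)
    smk_status: np.ndarray                  # (n, T) int8
    smk_cigs: np.ndarray                    # (n, T)
    pack_years: np.ndarray                  # (n, T)
    years_since_quit: np.ndarray            # (n, T)
    ets: np.ndarray                         # (n, T) bool
    u_ets: np.ndarray = field(repr=False, default=None)  # shared ETS draws

    @property
    def n_years(self) -> int:
        return self.smk_status.shape[1]

    @property
    def last_year(self) -> int:
        return self.first_year + self.n_years - 1

    def col(self, year: int) -> int:
        if not (self.first_year <= year <= self.last_year):
            raise KeyError(f"year {year} outside trajectory buffer "
                           f"[{self.first_year}, {self.last_year}]")
        return year - self.first_year

    def value(self, name: str, year: int) -> np.ndarray:
        c = self.col(year)
        if name in self.continuous:
            return self.continuous[name][:, c]
        if name == "ets":
            return self.ets[:, c]
        if name == "smoking_status":
            return self.smk_status[:, c]
        if name == "cigarettes":
            return self.smk_cigs[:, c]
        raise KeyError(name)

    def lagged(self, name: str, year: int, lag: int) -> np.ndarray:
        return self.value(name, max(year - lag, self.first_year))

    def copy(self) -> "Trajectories":
        return Trajectories(
            first_year=self.first_year,
            continuous={k: v.copy() for k, v in self.continuous.items()},
            smk_status=self.smk_status.copy(),
            smk_cigs=self.smk_cigs.copy(),
            pack_years=self.pack_years.copy(),
            years_since_quit=self.years_since_quit.copy(),
            ets=self.ets.copy(),
            u_ets=self.u_ets,
        )


def _ets_prevalence_strata(cohort: Cohort) -> np.ndarray:
    """Stratum index for smoking-prevalence pooling: sex x IMD quintile."""
    return (cohort.sex.astype(np.int64) * 5 + (cohort.quintile - 1)).astype(np.int64)


def smoking_prevalence_by_stratum(status_col: np.ndarray,
                                  strata: np.ndarray) -> np.ndarray:
    """Proportion of current smokers per stratum code (returns per-simulant)."""
    n_strata = int(strata.max()) + 1
    cur = (status_col == CURRENT).astype(float)
    totals = np.bincount(strata, minlength=n_strata).astype(float)
    smokers = np.bincount(strata, weights=cur, minlength=n_strata)
    with np.errstate(invalid="ignore", divide="ignore"):
        prev = np.where(totals > 0, smokers / np.maximum(totals, 1.0), 0.0)
    return prev[strata]


def simulate_base_trajectories(
    cohort: Cohort,
    config: GeneratorConfig,
    streams: StreamFactory,
    max_lag: int,
) -> Trajectories:
    """Base-case exposure trajectories for the whole roster.

    Exposures depend only on sociodemographics (the epidemiological layering),
    so they are simulated for every roster member over the full horizon
    regardless of vital status; disease and mortality consume them later.
    History years before the simulation start are back-filled deterministically
    (ages extrapolated below the entry age, floored at 20) to seed lag buffers.
    """
    first_year = config.start_year - max_lag
    years = np.arange(first_year, config.end_year + 1)
    T = years.size
    n = cohort.n

    continuous: dict[str, np.ndarray] = {}
    for name in CONTINUOUS_EXPOSURES:
        spec = config.exposures[name]
        out = np.empty((n, T))
        z = cohort.z_of(name)
        for t, year in enumerate(years):
            age = np.clip(cohort.age_at(int(year)), 20, config.max_age)
            out[:, t] = spec.quantile(z, age, cohort.sex, cohort.dimd, int(year))
        continuous[name] = out

    # --- smoking: backfill history, then simulate forward ----------------
    status = np.empty((n, T), dtype=np.int8)
    cigs = np.zeros((n, T))
    pack = np.zeros((n, T))
    ysq = np.zeros((n, T))
    smk = config.smoking

    t0 = config.start_year - first_year  # column of the start year
    status[:, t0] = cohort.smk_status
    cigs[:, t0] = cohort.cigs_per_day
    pack[:, t0] = cohort.pack_years
    ysq[:, t0] = cohort.years_since_quit
    for k in range(1, t0 + 1):  # history: status frozen, accruals rolled back
        t = t0 - k
        status[:, t] = status[:, t0]
        cigs[:, t] = cigs[:, t0]
        was_cur = status[:, t0] == CURRENT
        pack[:, t] = np.maximum(
            pack[:, t0] - np.where(was_cur, cigs[:, t0] / 20.0 * k, 0.0), 0.0)
        ysq[:, t] = np.maximum(ysq[:, t0] - k, 0.0)

    new_cigs = np.clip(
        np.exp(np.log(smk.cigs_median) + smk.cigs_sigma * cohort.z_of("cigarettes")),
        1.0, 60.0)
    for t in range(t0 + 1, T):
        year = int(years[t])
        u = streams("smoking", year).random(n)
        s_new, c_new, p_new, q_new = update_smoking(
            status[:, t - 1], cigs[:, t - 1], pack[:, t - 1], ysq[:, t - 1],
            initiation=smk.initiation(year), cessation=smk.cessation_rate,
            draws=u, relapse=smk.relapse_rate, new_cigs=new_cigs,
        )
        # roster members who have not entered yet keep their entry state
        frozen = ~cohort.entered(year)
        for arr_new, arr_prev in ((s_new, status), (c_new, cigs),
                                  (p_new, pack), (q_new, ysq)):
            arr_new[frozen] = arr_prev[frozen, t - 1]
        status[:, t], cigs[:, t], pack[:, t], ysq[:, t] = s_new, c_new, p_new, q_new

    # --- ETS: shared uniform draws, prevalence-coupled -------------------
    strata = _ets_prevalence_strata(cohort)
    u_ets = np.empty((n, T), dtype=np.float32)
    ets = np.zeros((n, T), dtype=bool)
    for t, year in enumerate(years):
        u_ets[:, t] = streams("ets", int(year)).random(n, dtype=np.float32)
    fill_ets(ets, status, u_ets, strata, config.ets_coupling)

    return Trajectories(
        first_year=first_year, continuous=continuous,
        smk_status=status, smk_cigs=cigs, pack_years=pack,
        years_since_quit=ysq, ets=ets, u_ets=u_ets,
    )


def fill_ets(ets: np.ndarray, status: np.ndarray, u_ets: np.ndarray,
             strata: np.ndarray, coupling: float,
             from_col: int = 0) -> None:
    """(Re)compute ETS exposure columns from a smoking-status matrix.

    Uses the shared uniform draws so scenario arms that lower smoking
    prevalence monotonically lower ETS exposure.
    """
    for t in range(from_col, status.shape[1]):
        prev = smoking_prevalence_by_stratum(status[:, t], strata)
        p = np.clip(coupling * prev, 0.0, 1.0)
        nonsmoker = status[:, t] != CURRENT
        ets[:, t] = nonsmoker & (u_ets[:, t] < p)
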