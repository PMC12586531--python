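"""Disease incidence, recovery, and PAF-style baseline calibration.

Annual incidence for each condition is a calibrated baseline probability
multiplied by relative risks from lagged exposures (log-linear dose-response
above the TMREL for harmful continuous factors, below it for protective ones),
by prevalent parent conditions (read from the *previous* year's states, so
there is no same-year feedback), and by a past-history RR for conditions that
can recur.  The baseline is backed out from the stratum target rate through
the population attributable fraction: p0 = target / E[product of RRs], i.e.
p0 = target x (1 - PAF) with PAF = 1 - 1/E[RR product], so the expected
marginal incidence under the base case equals the target.

Smoking is special in two ways: its status multiplier scales with lagged
intensity (cigarettes/day relative to a 20/day reference), and for COPD and
lung, breast and colorectal cancers the effect is cumulative - an increasing
function of pack-years whose excess decays exponentially after quitting
rather than vanishing at the link's lag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exposure import CURRENT, EX, Trajectories
from .registry import (
    PROTECTIVE_EXPOSURES,
    ConditionSpec,
    Registry,
    RiskLink,
)

__all__ = [
    "compute_rr",
    "smoking_cumulative_rr",
    "condition_multiplier",
    "calibrate_baseline",
    "individual_incidence_probability",
    "simulate_incidence",
    "apply_recovery",
    "calibration_stratum",
    "N_CALIBRATION_STRATA",
]

#: Clamp on any annual event probability (Bernoulli validity).
P_MAX = 0.999

#: Reference smoking intensity (cigarettes/day) at which the tabulated
#: smoking-status RR applies.
REFERENCE_CIGS = 20.0

#: Pack-years at which the cumulative excess equals the tabulated RR - 1.
REFERENCE_PACK_YEARS = 20.0

#: Cap on the cumulative pack-year scaling (bounds the excess at heavy use).
PACK_YEAR_CAP = 2.5

#: Default half-life (years) of the cumulative smoking excess after quitting.
CUMULATIVE_HALF_LIFE = 10.0

FREE, ACTIVE, RECOVERED = 0, 1, 2

_N_AGEBANDS = 7  # 30-39 ... 90+


def calibration_stratum(age, sex, quintile) -> np.ndarray:
    """Stratum code for calibration: sex x 10-year age band x IMD quintile."""
    band = np.clip((np.asarray(age, int) - 30) // 10, 0, _N_AGEBANDS - 1)
    return ((np.asarray(sex, int) * _N_AGEBANDS + band) * 5
            + (np.asarray(quintile, int) - 1)).astype(np.int64)


N_CALIBRATION_STRATA = 2 * _N_AGEBANDS * 5


def compute_rr(link: RiskLink, exposure_lagged, tmrel,
               cigs_lagged=None) -> np.ndarray:
    """Multiplier for one risk link given the lagged exposure value.

    Continuous harmful: rr^max(x - tmrel, 0); continuous protective (fruit,
    vegetables, physical activity): rr^max(tmrel - x, 0), with rr > 1
    encoding the risk of the deficit; never below 1.  Categorical (ETS):
    table lookup on the lagged exposed flag.  Smoking status: the tabulated
    current-smoker RR scaled by lagged intensity; ex- and never smokers
    revert to 1 (full reversibility after the lag; cumulative links are
    handled by :func:`smoking_cumulative_rr`).
    """
    x = np.asarray(exposure_lagged, dtype=float)
    if link.form == "log_linear_continuous":
        if link.exposure in PROTECTIVE_EXPOSURES:
            excess = np.maximum(tmrel - x, 0.0)
        else:
            excess = np.maximum(x - tmrel, 0.0)
        return np.power(link.rr_per_unit, excess)
    if link.form == "categorical":
        return np.where(x.astype(bool), link.rr_per_unit, 1.0)
    if link.form == "smoking_status":
        status = np.asarray(exposure_lagged)
        cigs = np.asarray(
            cigs_lagged if cigs_lagged is not None else REFERENCE_CIGS, float)
        mult = 1.0 + (link.rr_per_unit - 1.0) * cigs / REFERENCE_CIGS
        return np.where(status == CURRENT, mult, 1.0)
    raise ValueError(f"unknown link form {link.form!r}")


def smoking_cumulative_rr(
    link: RiskLink,
    pack_years,
    years_since_quit,
    status,
    half_life: float = CUMULATIVE_HALF_LIFE,
) -> np.ndarray:
    """Cumulative smoking multiplier for COPD and the smoking cancers.

    Increasing in pack-years (linear up to a cap, scaled so the tabulated RR
    applies at 20 pack-years); after quitting the excess decays exponentially
    with the configured half-life toward - but never instantly reaching - 1.
    """
    if not link.cumulative:
        raise ValueError("smoking_cumulative_rr requires a cumulative link")
    pack = np.minimum(np.asarray(pack_years, float) / REFERENCE_PACK_YEARS,
                      PACK_YEAR_CAP)
    excess = (link.rr_per_unit - 1.0) * pack
    decay = np.where(
        np.asarray(status) == EX,
        np.exp(-np.log(2.0) / half_life * np.asarray(years_since_quit, float)),
        1.0,
    )
    mult = 1.0 + excess * decay
    return np.where(np.asarray(status) == NEVER_STATUS, 1.0, mult)


NEVER_STATUS = 0


def condition_multiplier(
    registry: Registry,
    condition: str,
    traj: Trajectories,
    year: int,
    tmrels: dict[str, float],
    prev_active: dict[str, np.ndarray] | None = None,
    ever_had: np.ndarray | None = None,
    links_only: bool = False,
    half_life: float = CUMULATIVE_HALF_LIFE,
) -> np.ndarray:
    """Product of all risk multipliers for one condition in one year.

    ``links_only`` restricts to the exposure links (used for case fatality,
    which shares the incidence RRs but not the parent-condition effects).
    """
    spec = registry.conditions[condition]
    n = traj.smk_status.shape[0]
    mult = np.ones(n)
    for link in registry.links_for(condition):
        if link.exposure == "smoking":
            if link.cumulative:
                mult *= smoking_cumulative_rr(
                    link, traj.pack_years[:, traj.col(year)],
                    traj.years_since_quit[:, traj.col(year)],
                    traj.smk_status[:, traj.col(year)],
                    half_life=half_life,
                )
            else:
                mult *= compute_rr(
                    link,
                    traj.lagged("smoking_status", year, link.lag_years),
                    0.0,
                    cigs_lagged=traj.lagged("cigarettes", year, link.lag_years),
                )
        elif link.exposure == "ets":
            mult *= compute_rr(link, traj.lagged("ets", year, link.lag_years),
                               tmrels.get("ets", 0.0))
        else:
            mult *= compute_rr(
                link,
                traj.lagged(link.exposure, year, link.lag_years),
                tmrels[link.exposure],
            )
    if not links_only:
        if prev_active is not None:
            for parent, rr in spec.parent_conditions:
                mult *= np.where(prev_active[parent], rr, 1.0)
        if spec.past_self_as_risk and ever_had is not None:
            mult *= np.where(ever_had, spec.past_self_rr, 1.0)
    return mult


def calibrate_baseline(
    target: np.ndarray,
    multiplier: np.ndarray,
    at_risk: np.ndarray,
    stratum: np.ndarray,
    n_strata: int = N_CALIBRATION_STRATA,
    frozen_divisor: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Back the baseline probability out of the target via the mean RR.

    p0_i = target_i / E[multiplier | stratum(i)], so the expected marginal
    incidence among the at-risk stratum equals the stratum's mean target rate
    (the PAF identity p0 = target x (1 - PAF), PAF = 1 - 1/E[RR]).

    When ``frozen_divisor`` is given (scenario arms) the stored base-case
    divisors are used instead of recomputing, so improved exposures lower
    individual probabilities rather than being re-absorbed by calibration.
    Strata with no at-risk members fall back to the overall at-risk mean.
    """
    if frozen_divisor is None:
        totals = np.bincount(stratum[at_risk], minlength=n_strata).astype(float)
        sums = np.bincount(stratum[at_risk], weights=multiplier[at_risk],
                           minlength=n_strata)
        overall = (multiplier[at_risk].mean() if at_risk.any() else 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            divisor = np.where(totals > 0, sums / np.maximum(totals, 1.0), overall)
    else:
        divisor = frozen_divisor
    p0 = target / divisor[stratum]
    return np.clip(p0, 0.0, P_MAX), divisor


def individual_incidence_probability(p0: np.ndarray,
                                     multiplier: np.ndarray) -> np.ndarray:
    """Annual probability: baseline x multiplicative risks, clamped below 1."""
    return np.clip(p0 * multiplier, 0.0, P_MAX)


def simulate_incidence(p: np.ndarray, at_risk: np.ndarray,
                       draws: np.ndarray) -> np.ndarray:
    """Bernoulli onset events among the at-risk set (common-random-number
    draws are indexed by simulant, so arms share them)."""
    return at_risk & (draws < p)


def apply_recovery(
    registry: Registry,
    state: dict[str, np.ndarray],
    onset_year: dict[str, np.ndarray],
    alive: np.ndarray,
    year: int,
    draw_fn,
) -> None:
    """Annual recovery transitions, in place.

    cancer_10yr: survival 10 years after diagnosis equals remission (recurrence
    only where the registry allows it - the at-risk logic elsewhere enforces
    that).  stochastic: recovery with the configured annual probability.
    none: no transitions, ever.
    """
    for ci, name in enumerate(registry.condition_order):
        spec = registry.conditions[name]
        if spec.recovery_rule == "none":
            continue
        active = alive & (state[name] == ACTIVE)
        if spec.recovery_rule == "cancer_10yr":
            recovered = active & (year - onset_year[name] >= 10)
        else:  # stochastic
            u = draw_fn(ci)
            recovered = active & (u < spec.recovery_prob)
        state[name][recovered] = RECOVERED
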