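"""Mortality: condition case fatality plus risk-modified other-cause deaths.

Each alive simulant faces one competing annual risk per active condition
(the stratum case-fatality target multiplied by the same exposure RRs as
incidence, unless the no-case-fatality-effect sensitivity switch is on) plus
an other-cause risk modified by SBP, smoking and physical activity and by a
configurable set of prevalent diseases (default CHD, stroke, diabetes, COPD).

Competing risks combine as 1 - prod(1 - p_k); a single cause of death is
attributed proportionally to the component hazards.  A per-stratum scalar on
the combined hazard is calibrated on the base-case arm so expected deaths
match the all-cause mortality envelope, then frozen and reused by scenario
arms - which is what lets risk improvements translate into genuine mortality
reductions instead of being re-absorbed by calibration.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.optimize import brentq

from .disease import (
    ACTIVE,
    N_CALIBRATION_STRATA,
    P_MAX,
    compute_rr,
)
from .exposure import CURRENT, Trajectories
from .registry import PROTECTIVE_EXPOSURES, Registry

__all__ = [
    "other_cause_multiplier",
    "combined_death_probability",
    "calibrate_mortality",
    "simulate_deaths",
    "FACTOR_CAP",
]

#: Cap on a calibration factor; an envelope needing more is flagged and capped.
FACTOR_CAP = 20.0

OTHER_CAUSE = "other"


def other_cause_multiplier(
    registry: Registry,
    traj: Trajectories,
    year: int,
    tmrels: dict[str, float],
    state: dict[str, np.ndarray],
) -> np.ndarray:
    """RR on mortality from causes not explicitly modelled.

    Exposure effects (SBP, smoking, physical activity) use current-year
    values; disease effects apply while the condition is active.
    """
    c = traj.col(year)
    n = traj.smk_status.shape[0]
    mult = np.ones(n)
    for risk in registry.mortality_risks:
        if risk.kind == "condition":
            if risk.source in state:
                mult *= np.where(state[risk.source] == ACTIVE,
                                 risk.rr_per_unit, 1.0)
        elif risk.form == "smoking_status":
            scaled = 1.0 + (risk.rr_per_unit - 1.0) * traj.smk_cigs[:, c] / 20.0
            mult *= np.where(traj.smk_status[:, c] == CURRENT, scaled, 1.0)
        else:
            x = traj.continuous[risk.source][:, c]
            tm = tmrels[risk.source]
            if risk.source in PROTECTIVE_EXPOSURES:
                excess = np.maximum(tm - x, 0.0)
            else:
                excess = np.maximum(x - tm, 0.0)
            mult *= np.power(risk.rr_per_unit, excess)
    return mult


def combined_death_probability(
    components: dict[str, np.ndarray], factor: np.ndarray | float = 1.0
) -> np.ndarray:
    """1 - prod(1 - p_k), with the calibration factor applied on the
    proportional-hazard scale: p = 1 - S^factor."""
    survival = np.ones_like(next(iter(components.values())))
    for p in components.values():
        survival = survival * (1.0 - np.clip(p, 0.0, P_MAX))
    return 1.0 - np.power(survival, factor)


def calibrate_mortality(
    components: dict[str, np.ndarray],
    target_rate: np.ndarray,
    alive: np.ndarray,
    stratum: np.ndarray,
    n_strata: int = N_CALIBRATION_STRATA,
) -> np.ndarray:
    """Per-stratum scalar f so that E[1 - S^f] equals the envelope rate.

    Returns the factor per stratum (1 where a stratum is empty).  Factors
    above :data:`FACTOR_CAP` trigger a warning and are capped.
    """
    survival = np.ones_like(target_rate, dtype=float)
    for p in components.values():
        survival = survival * (1.0 - np.clip(p, 0.0, P_MAX))
    survival = np.clip(survival, 1e-12, 1.0)
    factors = np.ones(n_strata)
    for code in np.unique(stratum[alive]):
        mask = alive & (stratum == code)
        s = survival[mask]
        t = float(np.mean(target_rate[mask]))
        if t <= 0:
            factors[code] = 0.0
            continue

        def gap(f):
            return float(np.mean(1.0 - np.power(s, f))) - t

        if gap(FACTOR_CAP) < 0:
            warnings.warn(
                f"mortality envelope unattainable in stratum {code}; "
                f"factor capped at {FACTOR_CAP}", RuntimeWarning, stacklevel=2)
            factors[code] = FACTOR_CAP
        elif gap(1e-9) > 0:
            factors[code] = 1e-9
        else:
            factors[code] = brentq(gap, 1e-9, FACTOR_CAP, xtol=1e-10)
    return factors


def simulate_deaths(
    components: dict[str, np.ndarray],
    factor_per_simulant: np.ndarray | float,
    alive: np.ndarray,
    u_death: np.ndarray,
    rng_cause: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw at most one death per simulant; attribute a single cause
    proportionally to the component hazards.

    Returns (died mask, cause index into the ordered component keys).
    """
    p_die = combined_death_probability(components, factor_per_simulant)
    died = alive & (u_death < p_die)
    causes = list(components)
    cause_idx = np.full(alive.shape[0], -1, dtype=np.int32)
    if not died.any():
        return died, cause_idx
    idx = np.flatnonzero(died)
    hazards = np.empty((len(causes), idx.size))
    for k, name in enumerate(causes):
        p = np.clip(components[name][idx], 0.0, P_MAX)
        hazards[k] = -np.log1p(-p)
    totals = hazards.sum(axis=0)
    totals[totals <= 0] = 1.0
    cum = np.cumsum(hazards / totals, axis=0)
    u = rng_cause.random(idx.size)
    cause_idx[idx] = (u[None, :] > cum).sum(axis=0)
    return died, cause_idx
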