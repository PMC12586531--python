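"""Counterfactual risk-factor scenarios.

Two scenario families transform base-case exposure trajectories from the
scenario start year (default 2023) onward:

* ``tmrel`` - every individual is set to the theoretical minimum risk exposure
  level (TMREL): continuous factors to the iteration's sampled TMREL, physical
  activity to 7 days/week, all current smokers become ex-smokers with the
  initiation rate set to zero, and ETS is eliminated;
* ``relative_improvement`` - a fractional improvement (default 10%) computed
  annually against that year's base-case value: biological factors lose the
  fraction of their excess over TMREL, fruit and vegetables gain the fraction,
  the fraction of smokers quit and remaining smokers cut cigarettes by the
  fraction, and the fraction of people below 7 active days gain one day.

Fruit and vegetables always move together; ETS is never set independently of
smoking (it is recomputed from the scenario's smoking prevalence).  A BMI
improvement also lowers SBP and total cholesterol through mediation for
BMI >= 25, unless the direct-effect-only sensitivity switch is on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._streams import StreamFactory
from .exposure import CURRENT, EX, NEVER, Trajectories, _ets_prevalence_strata, fill_ets
from .population import Cohort, GeneratorConfig
from .registry import MediationSpec

__all__ = [
    "Scenario",
    "SCENARIO_FACTORS",
    "apply_relative_improvement",
    "relative_excess_reduction",
    "apply_bmi_mediation",
    "build_arm_trajectories",
]

#: The six scenario factor groups (fruit and vegetables move as one; ETS is
#: derived from smoking).
SCENARIO_FACTORS = (
    "smoking", "fruit_veg", "physical_activity", "bmi", "total_cholesterol", "sbp",
)

_BIOLOGICAL = {"bmi": "bmi", "total_cholesterol": "total_cholesterol", "sbp": "sbp"}


@dataclass(frozen=True)
class Scenario:
    """A declarative counterfactual transform applied from ``start_year`` on."""

    name: str
    family: str = "baseline"  # baseline | tmrel | relative_improvement
    factors: tuple[str, ...] = ("all",)
    improvement_fraction: float = 0.10
    start_year: int = 2023
    mediation_on: bool = True
    case_fatality_effects_on: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("baseline", "tmrel", "relative_improvement"):
            raise ValueError(f"unknown scenario family {self.family!r}")
        if not 0.0 <= self.improvement_fraction <= 1.0:
            raise ValueError("improvement_fraction must lie in [0, 1]")
        expanded = self.expanded_factors
        unknown = set(expanded) - set(SCENARIO_FACTORS)
        if unknown:
            raise ValueError(f"unknown scenario factors: {sorted(unknown)}")

    @property
    def expanded_factors(self) -> tuple[str, ...]:
        if "all" in self.factors:
            return SCENARIO_FACTORS
        return tuple(self.factors)

    @classmethod
    def baseline(cls) -> "Scenario":
        return cls(name="baseline", family="baseline")


def apply_relative_improvement(base_value, tmrel, fraction: float):
    """Fractional reduction of the excess over the TMREL.

    ``base - fraction * max(base - tmrel, 0)``; never crosses below the TMREL.
    Applied annually against that year's base-case value.
    """
    if np.any(np.asarray(fraction) < 0):
        raise ValueError("improvement fraction cannot be negative")
    base_value = np.asarray(base_value, dtype=float)
    excess = np.maximum(base_value - tmrel, 0.0)
    out = base_value - fraction * excess
    return out if out.ndim else float(out)


def relative_excess_reduction(old_value: float, new_value: float,
                              tmrel: float) -> float:
    """Share of the excess over the TMREL removed by a change: (old - new) /
    (old - tmrel).  Reporting helper for scenario summaries."""
    if old_value <= tmrel:
        raise ValueError("no excess exposure above the TMREL to reduce")
    return (old_value - new_value) / (old_value - tmrel)


def apply_bmi_mediation(delta_bmi, bmi_base, spec: MediationSpec):
    """SBP and total-cholesterol decreases mediated by a BMI decrease.

    Active only for BMI >= the floor (25 kg/m2): per 1 kg/m2 of BMI decrease,
    SBP falls 2.55 mmHg and total cholesterol 0.23 mmol/L.
    """
    delta_bmi = np.asarray(delta_bmi, dtype=float)
    if np.any(delta_bmi < 0):
        raise ValueError("delta_bmi must be a non-negative decrease")
    on = np.asarray(bmi_base, dtype=float) >= spec.bmi_floor
    d_sbp = np.where(on, spec.delta_sbp_per_bmi_unit * delta_bmi, 0.0)
    d_tc = np.where(on, spec.delta_tc_per_bmi_unit * delta_bmi, 0.0)
    if d_sbp.ndim == 0:
        return float(d_sbp), float(d_tc)
    return d_sbp, d_tc


def _reduce_not_below(values: np.ndarray, delta: np.ndarray,
                      floor: float) -> np.ndarray:
    """Subtract ``delta`` without crossing ``floor``; values already at or
    below the floor are left untouched."""
    above = values > floor
    return np.where(above, np.maximum(values - delta, floor), values)


def build_arm_trajectories(
    base: Trajectories,
    scenario: Scenario,
    tmrels: dict[str, float],
    cohort: Cohort,
    config: GeneratorConfig,
    streams: StreamFactory,
    bmi_direct_only: bool = False,
) -> Trajectories:
    """Scenario-arm exposure trajectories derived from the base case.

    Every transform reads that year's base-case value (the "calculated
    annually relative to the base-case" rule), and the random streams used for
    who-quits and who-gains-a-day are dedicated so the same individuals are
    selected across single-factor and combined arms.
    """
    if scenario.family == "baseline":
        return base
    arm = base.copy()
    factors = set(scenario.expanded_factors)
    t_start = arm.col(scenario.start_year)
    T = arm.n_years
    n = cohort.n
    frac = scenario.improvement_fraction
    tm = scenario.family == "tmrel"

    # --- continuous biological factors -----------------------------------
    for factor in ("bmi", "total_cholesterol", "sbp"):
        if factor not in factors:
            continue
        mat = arm.continuous[factor]
        basemat = base.continuous[factor]
        if tm:
            mat[:, t_start:] = tmrels[factor]
        else:
            mat[:, t_start:] = apply_relative_improvement(
                basemat[:, t_start:], tmrels[factor], frac)

    # --- fruit & vegetables (always together) -----------------------------
    if "fruit_veg" in factors:
        for name in ("fruit", "vegetables"):
            mat = arm.continuous[name]
            if tm:
                mat[:, t_start:] = tmrels[name]
            else:
                hi = config.exposures[name].hi
                mat[:, t_start:] = np.clip(
                    base.continuous[name][:, t_start:] * (1.0 + frac), 0.0, hi)

    # --- physical activity -------------------------------------------------
    if "physical_activity" in factors:
        mat = arm.continuous["physical_activity"]
        if tm:
            mat[:, t_start:] = 7.0
        else:
            for t in range(t_start, T):
                year = base.first_year + t
                basecol = base.continuous["physical_activity"][:, t]
                u = streams("scenario_pa", year).random(n)
                gain = (basecol < 7.0) & (u < frac)
                mat[:, t] = np.where(gain, np.minimum(basecol + 1.0, 7.0), basecol)

    # --- smoking (and, through it, ETS) ------------------------------------
    if "smoking" in factors:
        _transform_smoking(arm, base, scenario, streams, t_start, cohort)
        strata = _ets_prevalence_strata(cohort)
        fill_ets(arm.ets, arm.smk_status, arm.u_ets, strata,
                 config.ets_coupling, from_col=t_start)
        if tm:
            arm.ets[:, t_start:] = False  # no environmental tobacco smoke

    # --- BMI mediation on SBP and total cholesterol ------------------------
    if ("bmi" in factors and scenario.mediation_on and not bmi_direct_only):
        delta = (base.continuous["bmi"][:, t_start:]
                 - arm.continuous["bmi"][:, t_start:])
        d_sbp, d_tc = apply_bmi_mediation(
            np.maximum(delta, 0.0), base.continuous["bmi"][:, t_start:],
            MediationSpec())
        arm.continuous["sbp"][:, t_start:] = _reduce_not_below(
            arm.continuous["sbp"][:, t_start:], d_sbp, tmrels["sbp"])
        arm.continuous["total_cholesterol"][:, t_start:] = _reduce_not_below(
            arm.continuous["total_cholesterol"][:, t_start:], d_tc,
            tmrels["total_cholesterol"])
    return arm


def _transform_smoking(arm: Trajectories, base: Trajectories,
                       scenario: Scenario, streams: StreamFactory,
                       t_start: int, cohort: Cohort) -> None:
    """Rewrite the smoking matrices from the scenario start column on.

    TMREL: all current smokers become ex-smokers at the start year (pack-years
    frozen, years_since_quit counting from the start year), initiation is set
    to zero, cigarettes to zero.  Relative improvement: a dedicated once-drawn
    uniform marks which base-case smokers quit (the same individuals across
    arms); remaining smokers cut cigarettes by the fraction and accrue
    pack-years at the reduced rate.
    """
    T = arm.n_years
    n = base.smk_status.shape[0]
    tm = scenario.family == "tmrel"
    frac = scenario.improvement_fraction
    if not tm:
        u_quit = streams("scenario_quit").random(n)
        quits = u_quit < frac

    never_at_start = base.smk_status[:, max(t_start - 1, 0)] == NEVER
    quit_year_col = np.full(n, -1, dtype=np.int64)  # column where forced quit
    for t in range(t_start, T):
        year = base.first_year + t
        entered = cohort.entered(year)
        b_status = base.smk_status[:, t]
        prev_pack = arm.pack_years[:, t - 1] if t > 0 else base.pack_years[:, t]

        if tm:
            candidate = (b_status == CURRENT) & ~never_at_start
        else:
            candidate = (b_status == CURRENT) & quits
        newly = candidate & (quit_year_col < 0)
        quit_year_col[newly] = t

        status = b_status.copy()
        cigs = base.smk_cigs[:, t].copy()
        pack = base.pack_years[:, t].copy()
        ysq = base.years_since_quit[:, t].copy()

        # forced quitters: ex from their quit year onwards
        fq = quit_year_col >= 0
        status[fq] = EX
        cigs[fq] = 0.0
        pack[fq] = prev_pack[fq]          # frozen at quitting
        ysq[fq] = (t - quit_year_col[fq]).astype(float)

        if tm:
            # smoke initiation rate set to zero: those never-smoking at the
            # start year remain never-smokers whatever the base case does
            status[never_at_start] = NEVER
            cigs[never_at_start] = 0.0
            pack[never_at_start] = 0.0
            ysq[never_at_start] = 0.0
            # base-case relapses among natural ex-smokers are cancelled
            relapsed = (status == CURRENT)
            status[relapsed] = EX
            cigs[relapsed] = 0.0
        else:
            # remaining smokers cut cigarettes by the fraction
            smoker = (status == CURRENT)
            cigs[smoker] = base.smk_cigs[smoker, t] * (1.0 - frac)
            # pack-years re-accrued at the reduced rate from the start year;
            # accrual pauses for roster members who have not yet entered,
            # mirroring the base case's frozen pre-entry state
            was_smoking = (arm.smk_status[:, t - 1] == CURRENT) if t > 0 else smoker
            pack[:] = np.where(
                smoker | was_smoking,
                prev_pack + np.where(was_smoking & entered,
                                     arm.smk_cigs[:, t - 1] / 20.0, 0.0),
                pack)

        arm.smk_status[:, t] = status
        arm.smk_cigs[:, t] = cigs
        arm.pack_years[:, t] = pack
        arm.years_since_quit[:, t] = ysq
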