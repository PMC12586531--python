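"""Orchestration: the `Microsimulation` model object and its results.

A :class:`Microsimulation` is built from a registry (the parameter truth
tables), a :class:`RunConfig` (horizon, scenarios, iterations, sensitivity
switches) and a generator configuration (the synthetic-population study
conditions).  ``run()`` executes the full Monte-Carlo design and returns a
:class:`SimulationResults` carrying the :class:`~morbsim.outcomes.ResultsCube`,
per-iteration TMREL draws, validation material and a ``summary()`` table.

Per iteration: TMRELs and the population are sampled once; the burn-in years
(2013-2022) are simulated a single time to grow lag buffers and calibrate;
each scenario arm then replays 2023-2043 from the common snapshot under
common random numbers.  The annual loop order is ageing/entrants ->
exposures (scenario transform) -> incidence -> recovery -> mortality ->
outcome accumulation.  Incidence calibration divisors and mortality
calibration factors are computed on the base-case arm and frozen for
scenario arms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from ._streams import StreamFactory
from . import disease as dz
from . import mortality as mt
from .exposure import simulate_base_trajectories
from .outcomes import ResultsCube, UncertaintySummary, case_years_prevented, summarise
from .population import (
    Cohort,
    GeneratorConfig,
    PopulationTargets,
    default_generator_config,
    generate_population,
)
from .registry import MAJOR_ILLNESS_THRESHOLD, Registry, load_registry
from .scenario import Scenario, build_arm_trajectories

__all__ = ["RunConfig", "Microsimulation", "SimulationResults", "validate_run"]

logger = logging.getLogger("morbsim")

FREE, ACTIVE, RECOVERED = dz.FREE, dz.ACTIVE, dz.RECOVERED


def default_scenarios() -> list[Scenario]:
    return [
        Scenario.baseline(),
        Scenario(name="tmrel_all", family="tmrel"),
        Scenario(name="improve10_all", family="relative_improvement"),
    ]


@dataclass
class RunConfig:
    """Run design: horizon, Monte-Carlo size, scenarios, switches."""

    n_simulants: int = 10_000
    n_iterations: int = 100
    start_year: int = 2013
    scenario_start: int = 2023
    end_year: int = 2043
    minimum_age: int = 30
    master_seed: int = 1
    scenarios: list[Scenario] = field(default_factory=default_scenarios)
    no_case_fatality_effect: bool = False      # sensitivity analysis 1
    cms_threshold: float = MAJOR_ILLNESS_THRESHOLD  # sensitivity analysis 2
    bmi_direct_only: bool = False              # sensitivity analysis 3
    cumulative_half_life: float = dz.CUMULATIVE_HALF_LIFE
    keep_probabilities: bool = False
    keep_person_years: bool = False

    def __post_init__(self) -> None:
        if not (self.start_year < self.scenario_start <= self.end_year):
            raise ValueError("need start_year < scenario_start <= end_year")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        names = [s.name for s in self.scenarios]
        if len(names) != len(set(names)):
            raise ValueError("scenario names must be unique")

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text())
        scenarios = [Scenario(**s) if isinstance(s, dict) else s
                     for s in raw.pop("scenarios", [])]
        cfg = cls(**raw)
        if scenarios:
            cfg.scenarios = scenarios
        return cfg

    def to_yaml(self, path) -> None:
        raw = {
            k: v for k, v in self.__dict__.items() if k != "scenarios"
        }
        raw["scenarios"] = [s.__dict__ for s in self.scenarios]
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass
class SimState:
    """Mutable per-arm simulation state."""

    state: dict[str, np.ndarray]
    onset_year: dict[str, np.ndarray]
    ever_had: dict[str, np.ndarray]
    alive: np.ndarray
    death_year: np.ndarray
    death_cause: np.ndarray
    prev_major: np.ndarray

    def copy(self) -> "SimState":
        return SimState(
            state={k: v.copy() for k, v in self.state.items()},
            onset_year={k: v.copy() for k, v in self.onset_year.items()},
            ever_had={k: v.copy() for k, v in self.ever_had.items()},
            alive=self.alive.copy(),
            death_year=self.death_year.copy(),
            death_cause=self.death_cause.copy(),
            prev_major=self.prev_major.copy(),
        )


class Microsimulation:
    """Dynamic discrete-time microsimulation of major-illness burden.

    Parameters
    ----------
    config
        The run design.  Defaults to a three-arm design (base case,
        theoretical-minimum-risk all factors, 10% improvement all factors).
    registry
        Parameter registry; defaults to the packaged tables.
    generator_config
        Synthetic-population study conditions; horizon fields are overridden
        to match ``config``.
    """

    def __init__(self, config: RunConfig | None = None,
                 registry: Registry | None = None,
                 generator_config: GeneratorConfig | None = None):
        self.config = config or RunConfig()
        self.registry = registry or load_registry()
        if generator_config is None:
            generator_config = default_generator_config(self.registry)
        generator_config.n_simulants = self.config.n_simulants
        generator_config.start_year = self.config.start_year
        generator_config.end_year = self.config.end_year
        generator_config.min_age = self.config.minimum_age
        generator_config.__post_init__()
        self.generator_config = generator_config
        scenarios = list(self.config.scenarios)
        if not scenarios or scenarios[0].family != "baseline":
            scenarios.insert(0, Scenario.baseline())
            self.config.scenarios = scenarios

    # ------------------------------------------------------------------

    def run(self) -> "SimulationResults":
        records: list[dict] = []
        tmrel_draws: list[dict] = []
        diagnostics: dict = {"probabilities": {}, "p_die": {},
                             "expected_deaths": {}}
        person_years: dict = {}
        validation_rows: list[dict] = []
        for iteration in range(self.config.n_iterations):
            logger.info("iteration %d / %d", iteration + 1,
                        self.config.n_iterations)
            self._run_iteration(iteration, records, tmrel_draws, diagnostics,
                                person_years, validation_rows)
        cube = ResultsCube.from_records(records)
        return SimulationResults(
            model=self, cube=cube, tmrels=tmrel_draws,
            diagnostics=diagnostics, person_years=person_years,
            validation_rows=validation_rows,
        )

    # ------------------------------------------------------------------

    def _run_iteration(self, iteration, records, tmrel_draws, diagnostics,
                       person_years, validation_rows) -> None:
        cfg = self.config
        registry = self.registry
        streams = StreamFactory(cfg.master_seed, iteration)
        tmrels = registry.sample_tmrels(streams("tmrel"))
        self._current_tmrels = tmrels
        tmrel_draws.append(tmrels)
        cohort, targets, _ = generate_population(
            self.generator_config, streams, registry)
        base_traj = simulate_base_trajectories(
            cohort, self.generator_config, streams, registry.max_lag)

        arm_trajs = {
            s.name: build_arm_trajectories(
                base_traj, s, tmrels, cohort, self.generator_config, streams,
                bmi_direct_only=cfg.bmi_direct_only)
            for s in cfg.scenarios
        }

        # frozen calibration: divisors per (condition, year), factors per year
        frozen_div: dict[tuple[str, int], np.ndarray] = {}
        frozen_factors: dict[int, np.ndarray] = {}

        state = self._initial_state(cohort)
        # burn-in is common to every arm (transforms start at scenario_start)
        for year in range(cfg.start_year, cfg.scenario_start):
            self._advance_year(
                iteration, "baseline", cfg.scenarios[0], cohort, targets,
                base_traj, base_traj, state, year, streams,
                frozen_div, frozen_factors, calibrate=True,
                records=records, diagnostics=diagnostics,
                person_years=None, validation_rows=validation_rows)
        snapshot = state.copy()

        for scenario in cfg.scenarios:
            arm_state = snapshot.copy()
            traj = arm_trajs[scenario.name]
            is_base = scenario.family == "baseline"
            py = None
            if cfg.keep_person_years:
                py = person_years.setdefault((iteration, scenario.name), {})
            for year in range(cfg.scenario_start, cfg.end_year + 1):
                self._advance_year(
                    iteration, scenario.name, scenario, cohort, targets,
                    traj, base_traj, arm_state, year, streams,
                    frozen_div, frozen_factors, calibrate=is_base,
                    records=records, diagnostics=diagnostics,
                    person_years=py, validation_rows=validation_rows)

    def _initial_state(self, cohort: Cohort) -> SimState:
        n = cohort.n
        return SimState(
            state={k: v.copy() for k, v in cohort.disease_state.items()},
            onset_year={k: v.copy() for k, v in cohort.onset_year.items()},
            ever_had={k: v.copy() for k, v in cohort.ever_had.items()},
            alive=cohort.entry_year == cohort.entry_year.min(),
            death_year=np.full(n, -1, dtype=np.int16),
            death_cause=np.full(n, -1, dtype=np.int32),
            prev_major=np.zeros(n, dtype=bool),
        )

    # ------------------------------------------------------------------

    def _advance_year(self, iteration, arm_name, scenario, cohort, targets,
                      traj, base_traj, sim, year, streams,
                      frozen_div, frozen_factors, calibrate,
                      records, diagnostics, person_years, validation_rows):
        cfg = self.config
        registry = self.registry
        n = cohort.n
        age = cohort.age_at(year)

        # 1. entrants join (ageing is implicit in age_at)
        entering = (cohort.entry_year == year) & (sim.death_year < 0)
        sim.alive |= entering
        alive_start = sim.alive.copy()
        stratum = dz.calibration_stratum(np.clip(age, 30, 100), cohort.sex,
                                         cohort.quintile)

        # 2./3. incidence (parent effects read last year's states)
        prev_active = {c: sim.state[c] == ACTIVE for c in registry.condition_order}
        incident_counts: dict[str, int] = {}
        for ci, cond in enumerate(registry.condition_order):
            spec = registry.conditions[cond]
            st = sim.state[cond]
            at_risk = sim.alive & (
                (st == FREE) | ((st == RECOVERED) & spec.can_recur))
            target = targets.incidence_rate(cond, age, cohort.sex,
                                            cohort.dimd, year)
            mult = dz.condition_multiplier(
                registry, cond, traj, year, self._tmrels_for(iteration),
                prev_active=prev_active, ever_had=sim.ever_had[cond],
                half_life=cfg.cumulative_half_life)
            if calibrate:
                p0, divisor = dz.calibrate_baseline(target, mult, at_risk, stratum)
                frozen_div[(cond, year)] = divisor
            else:
                p0, _ = dz.calibrate_baseline(
                    target, mult, at_risk, stratum,
                    frozen_divisor=frozen_div[(cond, year)])
            p = dz.individual_incidence_probability(p0, mult)
            if cfg.keep_probabilities:
                diagnostics["probabilities"][(iteration, arm_name, cond, year)] = \
                    np.where(at_risk, p, np.nan).astype(np.float32)
            u = streams("incidence", ci, year).random(n)
            events = dz.simulate_incidence(p, at_risk, u)
            sim.state[cond][events] = ACTIVE
            sim.onset_year[cond][events] = year
            sim.ever_had[cond][events] = True
            incident_counts[cond] = int(events.sum())

        # 4. recovery
        dz.apply_recovery(
            registry, sim.state, sim.onset_year, sim.alive, year,
            draw_fn=lambda ci: streams("recovery", ci, year).random(n))

        # 5. mortality
        cf_traj = traj
        if cfg.no_case_fatality_effect or not scenario.case_fatality_effects_on:
            cf_traj = base_traj
        components: dict[str, np.ndarray] = {}
        for cond in registry.condition_order:
            active = sim.alive & (sim.state[cond] == ACTIVE)
            if not active.any():
                continue
            cf = targets.case_fatality_rate(cond, age, cohort.sex,
                                            cohort.dimd, year)
            cf_mult = dz.condition_multiplier(
                registry, cond, cf_traj, year, self._tmrels_for(iteration),
                links_only=True, half_life=cfg.cumulative_half_life)
            # case-fatality targets are observed rates, so they are backed out
            # through the same PAF identity as incidence (divisors frozen on
            # the base-case arm)
            if calibrate:
                cf_p, divisor = dz.calibrate_baseline(cf, cf_mult, active,
                                                      stratum)
                frozen_div[("cf:" + cond, year)] = divisor
            else:
                cf_p, _ = dz.calibrate_baseline(
                    cf, cf_mult, active, stratum,
                    frozen_divisor=frozen_div.get(("cf:" + cond, year)))
            components[cond] = np.where(active, cf_p * cf_mult, 0.0)
        envelope = targets.mortality_rate(age, cohort.sex, cohort.dimd, year)
        oc_mult = mt.other_cause_multiplier(
            registry, traj, year, self._tmrels_for(iteration), sim.state)
        components[mt.OTHER_CAUSE] = envelope * oc_mult

        if calibrate:
            factors = mt.calibrate_mortality(components, envelope, sim.alive,
                                             stratum)
            frozen_factors[year] = factors
        else:
            factors = frozen_factors[year]
        f_ind = factors[stratum]
        u_death = streams("mortality", year).random(n)
        died, cause_idx = mt.simulate_deaths(
            components, f_ind, sim.alive, u_death, streams("cause", year))
        if cfg.keep_probabilities:
            p_die = mt.combined_death_probability(components, f_ind)
            diagnostics["p_die"][(iteration, arm_name, year)] = \
                np.where(sim.alive, p_die, np.nan).astype(np.float32)
        sim.alive[died] = False
        sim.death_year[died] = year
        sim.death_cause[died] = cause_idx[died]

        # 6. outcomes
        score = self._cms_scores(sim)
        major = sim.alive & (score > cfg.cms_threshold)
        crossings = alive_start & ~sim.prev_major & major
        at_risk_major = alive_start & ~sim.prev_major
        self._record(records, iteration, arm_name, year, cohort, sim, age,
                     alive_start, died, major, crossings, at_risk_major)
        if person_years is not None:
            person_years.setdefault("major", []).append(major.copy())
            person_years.setdefault("alive", []).append(sim.alive.copy())
            person_years.setdefault("alive_start", []).append(alive_start)
            person_years.setdefault("deaths", []).append(died.copy())
            person_years.setdefault("entrants", []).append(entering.copy())
            person_years.setdefault("years", []).append(year)
        sim.prev_major = np.where(sim.alive, major, sim.prev_major)
        if calibrate and year < cfg.scenario_start:
            self._validation_row(validation_rows, iteration, year, cohort,
                                 traj, targets, sim, incident_counts,
                                 alive_start, died)

    def _tmrels_for(self, iteration: int) -> dict[str, float]:
        # sampled once per iteration in _run_iteration; cached there
        return self._current_tmrels

    def _cms_scores(self, sim: SimState) -> np.ndarray:
        weights = self.registry.cms_weights
        members = self.registry.cms_members
        n = sim.alive.shape[0]
        score = np.zeros(n)
        for cms, conds in members.items():
            any_active = np.zeros(n, dtype=bool)
            for c in conds:
                any_active |= sim.state[c] == ACTIVE
            score += weights[cms] * any_active
        return score

    # ------------------------------------------------------------------

    def _record(self, records, iteration, arm, year, cohort, sim, age,
                alive_start, died, major, crossings, at_risk_major) -> None:
        cfg = self.config

        def add(stype, stratum, mask):
            alive = sim.alive & mask
            records.extend([
                dict(iteration=iteration, scenario=arm, year=year,
                     stratum_type=stype, stratum=stratum, metric=m, value=v)
                for m, v in (
                    ("population", int(alive.sum())),
                    ("count_major", int((major & mask).sum())),
                    ("count_without", int((alive & ~major).sum())),
                    ("deaths", int((died & mask).sum())),
                    ("at_risk_start", int((alive_start & mask).sum())),
                    ("major_crossings", int((crossings & mask).sum())),
                    ("major_at_risk", int((at_risk_major & mask).sum())),
                )
            ])

        everyone = np.ones(cohort.n, dtype=bool)
        add("overall", "all", everyone)
        for q in range(1, 6):
            add("quintile", str(q), cohort.quintile == q)
        for lo in range(30, 100, 10):
            hi = lo + 9 if lo < 90 else 100
            add("ageband", f"{lo}-{hi}", (age >= lo) & (age <= hi))
        # birth cohorts identified by age at the scenario start year
        age_2023 = cohort.age_at(cfg.scenario_start)
        for lo in (30, 50, 70):
            add("cohort", f"{lo}-{lo + 4}@{cfg.scenario_start}",
                (age_2023 >= lo) & (age_2023 <= lo + 4))

    def _validation_row(self, rows, iteration, year, cohort, traj, targets,
                        sim, incident_counts, alive_start, died) -> None:
        alive = alive_start
        n_alive = int(alive.sum())
        if n_alive == 0:
            return
        for name, mat in traj.continuous.items():
            rows.append(dict(iteration=iteration, year=year,
                             component=f"exposure_mean:{name}",
                             observed=float(mat[alive, traj.col(year)].mean()),
                             n=n_alive))
        age = cohort.age_at(year)
        env = targets.mortality_rate(age, cohort.sex, cohort.dimd, year)
        rows.append(dict(iteration=iteration, year=year,
                         component="mortality_rate",
                         observed=float(died[alive].mean()),
                         expected=float(env[alive].mean()), n=n_alive))
        for cond, count in incident_counts.items():
            t = targets.incidence_rate(cond, age, cohort.sex, cohort.dimd, year)
            st = sim.state[cond]
            rows.append(dict(iteration=iteration, year=year,
                             component=f"incidence:{cond}", observed=count,
                             expected=float(t[alive].sum()), n=n_alive))


@dataclass
class SimulationResults:
    """Everything a run produced, with summary helpers."""

    model: Microsimulation
    cube: ResultsCube
    tmrels: list[dict]
    diagnostics: dict
    person_years: dict
    validation_rows: list[dict]

    @property
    def config(self) -> RunConfig:
        return self.model.config

    def prevalence(self, scenario: str, year: int) -> pd.Series:
        return self.cube.table("major_prevalence", scenario)[year]

    def prevalence_difference(self, scenario: str, year: int,
                              base: str = "baseline",
                              relative: bool = False) -> UncertaintySummary:
        return summarise(self.prevalence(scenario, year),
                         comparator=self.prevalence(base, year),
                         relative=relative)

    def case_years_prevented(self, scenario: str,
                             base: str = "baseline") -> UncertaintySummary:
        return case_years_prevented(
            self.cube, scenario, base,
            horizon=(self.config.scenario_start, self.config.end_year))

    def validation_report(self) -> pd.DataFrame:
        """Burn-in discrepancies vs the calibration targets (always produced,
        whether or not anything is out of tolerance)."""
        return validate_run(self)

    def summary(self) -> str:
        cfg = self.config
        y = cfg.end_year
        lines = [
            "Microsimulation of major illness (CMS > "
            f"{cfg.cms_threshold:g})",
            f"  simulants: {cfg.n_simulants:,}  iterations: "
            f"{cfg.n_iterations}  horizon: {cfg.start_year}-{cfg.end_year} "
            f"(scenarios from {cfg.scenario_start})",
            "",
            f"{'scenario':<24}{'prev ' + str(y):>14}{'abs diff (pp)':>16}"
            f"{'rel diff (%)':>14}{'case-years prevented':>22}",
        ]
        base_prev = self.prevalence("baseline", y)
        for s in cfg.scenarios:
            prev = self.prevalence(s.name, y)
            row = f"{s.name:<24}{100 * prev.mean():>13.1f}%"
            if s.family == "baseline":
                lines.append(row)
                continue
            absd = summarise(prev, comparator=base_prev)
            reld = summarise(prev, comparator=base_prev, relative=True)
            cy = self.case_years_prevented(s.name)
            row += (f"{100 * absd.central:>16.2f}{100 * reld.central:>14.1f}"
                    f"{cy.central:>22,.0f}")
            lines.append(row)
        return "\n".join(lines)

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.cube.to_csv(path / "results_cube.csv")
        pd.DataFrame(self.tmrels).to_csv(path / "tmrels.csv", index=False)
        self.validation_report().to_csv(path / "validation.csv", index=False)


def validate_run(results: SimulationResults) -> pd.DataFrame:
    """Standardised burn-in discrepancies of the base case vs its targets.

    Reporting only: the frame is returned whether or not any check fails.
    Incidence and mortality rows carry binomial standard errors and z-scores.
    """
    df = pd.DataFrame(results.validation_rows)
    if df.empty:
        return df
    out = df.copy()
    if "expected" in out:
        has_exp = out["expected"].notna()
        exp = out["expected"].fillna(0.0)
        binom = out["component"].str.startswith("incidence")
        # incidence rows compare counts (Poisson-scale SE); rate rows compare
        # proportions (binomial SE)
        se = np.where(binom, np.sqrt(np.maximum(exp, 1e-9)),
                      np.sqrt(np.maximum(exp * (1 - exp), 0.0)
                              / out["n"].clip(lower=1)))
        out["se"] = se
        out["z"] = np.where(
            has_exp & (out["se"] > 0),
            (out["observed"] - exp) / out["se"], np.nan)
    return out
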