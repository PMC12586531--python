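"""Condition registry, risk links, TMRELs and the Cambridge Multimorbidity Score.

The registry is the static truth table the rest of the engine reads: the 26
modelled conditions mapped onto the 20 Cambridge Multimorbidity Score (CMS)
conditions with their outcome weights and recovery rules, the exposure ->
condition causal edges with their relative risks and lag times, the
theoretical-minimum-risk exposure levels (TMRELs), the BMI -> SBP / total
cholesterol mediation coefficients, and the risk effects on mortality from
causes not explicitly modelled.

All tables ship as UTF-8 tab-delimited text under ``morbsim/data`` with a
SHA-256 checksum file; :func:`load_registry` validates both the checksums and
the structural invariants (counts, cross-references, flag consistency) and
fails loudly, naming the offending row, on any violation.

The packaged relative-risk magnitudes are illustrative, not meta-analytic
estimates: they are chosen so that realistic exposure contrasts imply relative
risks of roughly 1.1-3.0, which is what the engine's correctness properties
require.  Substituting an epidemiologically estimated table of the same shape
changes no code.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ConditionSpec",
    "RiskLink",
    "TmrelSpec",
    "MediationSpec",
    "MortalityRisk",
    "Registry",
    "RegistryError",
    "load_registry",
    "cms_score",
    "is_major_illness",
    "MAJOR_ILLNESS_THRESHOLD",
]

#: CMS score above which a simulant counts as living with "major illness".
MAJOR_ILLNESS_THRESHOLD = 1.5

RECOVERY_RULES = ("none", "cancer_10yr", "stochastic")
LINK_FORMS = ("log_linear_continuous", "categorical", "smoking_status")

#: Exposures for which a *deficit* below the TMREL is harmful (the RR per unit
#: encodes the risk of being one unit short of the protective level).
PROTECTIVE_EXPOSURES = frozenset({"fruit", "vegetables", "physical_activity"})

#: Exposures allowed to act on mortality from causes not explicitly modelled.
NONMODELLED_MORTALITY_EXPOSURES = frozenset({"sbp", "smoking", "physical_activity"})


class RegistryError(ValueError):
    """Structured validation failure while loading or checking the registry."""


@dataclass(frozen=True)
class ConditionSpec:
    modelled_name: str
    cms_condition: str
    cms_weight: float
    recovery_rule: str  # none | cancer_10yr | stochastic
    can_recur: bool
    is_cancer: bool
    past_self_as_risk: bool
    past_self_rr: float | None = None
    recovery_prob: float | None = None
    has_parent_risks: bool = False
    parent_conditions: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.recovery_rule not in RECOVERY_RULES:
            raise RegistryError(
                f"{self.modelled_name}: unknown recovery_rule {self.recovery_rule!r}"
            )
        if self.cms_weight <= 0:
            raise RegistryError(f"{self.modelled_name}: cms_weight must be positive")
        if self.recovery_rule == "cancer_10yr" and not self.is_cancer:
            raise RegistryError(
                f"{self.modelled_name}: cancer_10yr recovery on a non-cancer condition"
            )
        if self.recovery_rule == "stochastic" and self.recovery_prob is None:
            raise RegistryError(
                f"{self.modelled_name}: stochastic recovery needs recovery_prob"
            )
        if self.past_self_as_risk and self.past_self_rr is None:
            raise RegistryError(
                f"{self.modelled_name}: past_self_as_risk needs past_self_rr"
            )


@dataclass(frozen=True)
class RiskLink:
    exposure: str
    condition: str
    form: str  # log_linear_continuous | categorical | smoking_status
    rr_per_unit: float
    unit: str
    lag_years: int
    cumulative: bool
    affects_case_fatality: bool
    affects_nonmodelled_mortality: bool

    def __post_init__(self) -> None:
        if self.form not in LINK_FORMS:
            raise RegistryError(
                f"link {self.exposure}->{self.condition}: unknown form {self.form!r}"
            )
        if self.lag_years <= 0:
            raise RegistryError(
                f"link {self.exposure}->{self.condition}: lag_years must be positive"
            )
        if self.rr_per_unit <= 0:
            raise RegistryError(
                f"link {self.exposure}->{self.condition}: rr_per_unit must be positive"
            )


@dataclass(frozen=True)
class TmrelSpec:
    exposure: str
    central: float
    unit: str
    support_low: float
    support_high: float
    distribution: str = "triangular"  # triangular | fixed

    def sample(self, rng: np.random.Generator) -> float:
        """One TMREL draw; redrawn per Monte-Carlo iteration, fixed within it."""
        if self.distribution == "fixed" or self.support_low == self.support_high:
            return self.central
        return float(
            rng.triangular(self.support_low, self.central, self.support_high)
        )


@dataclass(frozen=True)
class MediationSpec:
    """Indirect effect of BMI reduction on SBP and total cholesterol."""

    delta_sbp_per_bmi_unit: float = 2.55  # mmHg per kg/m2
    delta_tc_per_bmi_unit: float = 0.23  # mmol/L per kg/m2
    bmi_floor: float = 25.0  # mediation off below this BMI

    def __post_init__(self) -> None:
        if self.delta_sbp_per_bmi_unit <= 0 or self.delta_tc_per_bmi_unit <= 0:
            raise RegistryError("mediation coefficients must be strictly positive")


@dataclass(frozen=True)
class MortalityRisk:
    """A risk effect on mortality from causes not explicitly modelled."""

    source: str
    kind: str  # exposure | condition
    form: str
    rr_per_unit: float


def _data_dir() -> Path:
    return Path(resources.files("morbsim").joinpath("data"))  # type: ignore[arg-type]


def _verify_checksums(path: Path) -> None:
    checkfile = path / "checksums.sha256"
    if not checkfile.exists():
        return
    for line in checkfile.read_text().splitlines():
        digest, name = line.split()
        target = path / name
        if not target.exists():
            raise RegistryError(f"registry table missing: {name}")
        actual = hashlib.sha256(target.read_bytes()).hexdigest()
        if actual != digest:
            raise RegistryError(
                f"registry table {name} does not match its packaged checksum"
            )


@dataclass
class Registry:
    """Validated parameter registry; the static truth tables of the model."""

    conditions: dict[str, ConditionSpec]
    links: tuple[RiskLink, ...]
    tmrels: dict[str, TmrelSpec]
    mediation: MediationSpec
    mortality_risks: tuple[MortalityRisk, ...] = ()
    major_illness_threshold: float = MAJOR_ILLNESS_THRESHOLD
    _links_by_condition: dict[str, tuple[RiskLink, ...]] = field(
        init=False, repr=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        by_cond: dict[str, list[RiskLink]] = {}
        for link in self.links:
            if link.condition not in self.conditions:
                raise RegistryError(
                    f"link {link.exposure}->{link.condition}: unknown condition"
                )
            by_cond.setdefault(link.condition, []).append(link)
        self._links_by_condition = {c: tuple(ls) for c, ls in by_cond.items()}
        for cond in self.conditions.values():
            for parent, rr in cond.parent_conditions:
                if parent not in self.conditions:
                    raise RegistryError(
                        f"{cond.modelled_name}: unknown parent condition {parent!r}"
                    )
                if rr <= 0:
                    raise RegistryError(
                        f"{cond.modelled_name}: parent RR for {parent} must be positive"
                    )

    # -- lookups ---------------------------------------------------------

    @property
    def condition_order(self) -> tuple[str, ...]:
        """Fixed evaluation order (registry order; parent effects are lagged
        one year so no same-year feedback arises whatever the order)."""
        return tuple(self.conditions)

    @property
    def cms_weights(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for c in self.conditions.values():
            out.setdefault(c.cms_condition, c.cms_weight)
        return out

    @property
    def cms_members(self) -> dict[str, tuple[str, ...]]:
        out: dict[str, list[str]] = {}
        for c in self.conditions.values():
            out.setdefault(c.cms_condition, []).append(c.modelled_name)
        return {k: tuple(v) for k, v in out.items()}

    def links_for(self, condition: str) -> tuple[RiskLink, ...]:
        return self._links_by_condition.get(condition, ())

    @property
    def max_lag(self) -> int:
        return max((l.lag_years for l in self.links), default=1)

    def lifelong_cms_conditions(self) -> tuple[str, ...]:
        """CMS conditions whose member modelled conditions all have
        recovery_rule 'none' (the conditions modelled as lifelong)."""
        out = []
        for cms, members in self.cms_members.items():
            if all(self.conditions[m].recovery_rule == "none" for m in members):
                out.append(cms)
        return tuple(out)

    def sample_tmrels(self, rng: np.random.Generator) -> dict[str, float]:
        """Draw one TMREL per exposure for a Monte-Carlo iteration."""
        return {name: spec.sample(rng) for name, spec in sorted(self.tmrels.items())}

    # -- scoring ---------------------------------------------------------

    def score(self, prevalent_cms: Iterable[str]) -> float:
        return cms_score(prevalent_cms, self.cms_weights)

    def score_from_modelled(self, prevalent_modelled: Iterable[str]) -> float:
        """CMS score from modelled-condition names; each CMS condition is
        counted once however many of its members are present (e.g. both
        diabetes subtypes contribute the Diabetes weight exactly once)."""
        cms = {self.conditions[m].cms_condition for m in prevalent_modelled}
        return cms_score(cms, self.cms_weights)

    # -- validation ------------------------------------------------------

    def validate_strict(self) -> None:
        """Invariants of the packaged transcription (counts and flags)."""
        if len(self.conditions) != 26:
            raise RegistryError(
                f"expected 26 modelled conditions, found {len(self.conditions)}"
            )
        if len(self.cms_weights) != 20:
            raise RegistryError(
                f"expected 20 CMS conditions, found {len(self.cms_weights)}"
            )
        if len(self.lifelong_cms_conditions()) != 14:
            raise RegistryError(
                "expected 14 lifelong CMS conditions, found "
                f"{len(self.lifelong_cms_conditions())}"
            )
        for name in ("breast_cancer", "colorectal_cancer", "lung_cancer",
                     "prostate_cancer"):
            if self.conditions[name].recovery_rule != "cancer_10yr":
                raise RegistryError(f"{name}: expected cancer_10yr recovery")
        seen: set[tuple[str, str]] = set()
        cancer_lags, other_lags = [], []
        for link in self.links:
            key = (link.exposure, link.condition)
            if key in seen:
                raise RegistryError(f"duplicate edge {key}")
            seen.add(key)
            if link.affects_nonmodelled_mortality and (
                link.exposure not in NONMODELLED_MORTALITY_EXPOSURES
            ):
                raise RegistryError(
                    f"link {key}: affects_nonmodelled_mortality allowed only for "
                    "SBP, smoking and physical activity"
                )
            if link.cumulative and not (
                link.exposure == "smoking"
                and link.condition in {"copd", "lung_cancer", "breast_cancer",
                                       "colorectal_cancer"}
            ):
                raise RegistryError(
                    f"link {key}: cumulative effects are restricted to smoking -> "
                    "COPD / lung / breast / colorectal cancer"
                )
            (cancer_lags if self.conditions[link.condition].is_cancer
             else other_lags).append(link.lag_years)
        if other_lags and not (4.0 <= float(np.mean(other_lags)) <= 5.0):
            raise RegistryError("mean non-cancer lag outside the 4-5 year band")
        if cancer_lags and abs(float(np.mean(cancer_lags)) - 9.0) > 0.5:
            raise RegistryError("mean cancer lag is not ~9 years")
        for cond in self.conditions.values():
            if cond.parent_conditions and not cond.has_parent_risks:
                raise RegistryError(
                    f"{cond.modelled_name}: parent links present but condition is "
                    "not flagged as having pre-existing-condition risks"
                )

    # -- round-trip ------------------------------------------------------

    def to_frames(self) -> dict[str, pd.DataFrame]:
        conds = pd.DataFrame(
            [
                {
                    "modelled_name": c.modelled_name,
                    "cms_condition": c.cms_condition,
                    "cms_weight": c.cms_weight,
                    "recovery_rule": c.recovery_rule,
                    "can_recur": int(c.can_recur),
                    "is_cancer": int(c.is_cancer),
                    "past_self_as_risk": int(c.past_self_as_risk),
                    "past_self_rr": c.past_self_rr,
                    "recovery_prob": c.recovery_prob,
                    "has_parent_risks": int(c.has_parent_risks),
                }
                for c in self.conditions.values()
            ]
        )
        links = pd.DataFrame(
            [
                {
                    "exposure": l.exposure,
                    "condition": l.condition,
                    "form": l.form,
                    "rr_per_unit": l.rr_per_unit,
                    "unit": l.unit,
                    "lag_years": l.lag_years,
                    "cumulative": int(l.cumulative),
                    "affects_case_fatality": int(l.affects_case_fatality),
                    "affects_nonmodelled_mortality": int(
                        l.affects_nonmodelled_mortality
                    ),
                }
                for l in self.links
            ]
        )
        parents = pd.DataFrame(
            [
                {"condition": c.modelled_name, "parent": p, "rr": rr}
                for c in self.conditions.values()
                for p, rr in c.parent_conditions
            ]
        )
        tmrel = pd.DataFrame(
            [
                {
                    "exposure": t.exposure,
                    "central": t.central,
                    "unit": t.unit,
                    "support_low": t.support_low,
                    "support_high": t.support_high,
                    "distribution": t.distribution,
                }
                for t in self.tmrels.values()
            ]
        )
        mediation = pd.DataFrame([
            {"parameter": "delta_sbp_per_bmi_unit",
             "value": self.mediation.delta_sbp_per_bmi_unit},
            {"parameter": "delta_tc_per_bmi_unit",
             "value": self.mediation.delta_tc_per_bmi_unit},
            {"parameter": "bmi_floor", "value": self.mediation.bmi_floor},
        ])
        other = pd.DataFrame(
            [
                {"source": r.source, "kind": r.kind, "form": r.form,
                 "rr_per_unit": r.rr_per_unit}
                for r in self.mortality_risks
            ]
        )
        return {"conditions": conds, "risk_links": links,
                "parent_links": parents, "tmrel": tmrel,
                "mediation": mediation, "other_mortality": other}

    def write(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, frame in self.to_frames().items():
            if not frame.empty:
                frame.to_csv(path / f"{name}.tsv", sep="\t", index=False)


def cms_score(
    prevalent: Iterable[str], weights: Mapping[str, float] | None = None
) -> float:
    """Cambridge Multimorbidity Score: the sum of the weights of the prevalent
    CMS conditions.  Order-independent; duplicates are forbidden (scoring is
    defined on the *set* of the 20 conditions)."""
    if weights is None:
        weights = load_registry().cms_weights
    items = list(prevalent)
    if len(items) != len(set(items)):
        raise RegistryError("duplicate CMS conditions in prevalent set")
    unknown = [c for c in items if c not in weights]
    if unknown:
        raise RegistryError(f"unknown CMS condition(s): {unknown}")
    return float(sum(weights[c] for c in items))


def is_major_illness(
    score: float | np.ndarray, threshold: float = MAJOR_ILLNESS_THRESHOLD
):
    """Major illness is a CMS score *strictly* greater than the threshold
    (default 1.5; configurable for the threshold sensitivity analysis)."""
    if np.any(np.asarray(score) < 0):
        raise ValueError("CMS score cannot be negative")
    return np.asarray(score) > threshold if isinstance(score, np.ndarray) else (
        score > threshold
    )


def _read_table(path: Path, name: str) -> pd.DataFrame:
    f = path / f"{name}.tsv"
    if not f.exists():
        raise RegistryError(f"registry table missing: {f}")
    df = pd.read_csv(f, sep="\t")
    if df.empty:
        raise RegistryError(f"registry table {name} is empty")
    return df


def load_registry(path: str | Path | None = None, strict: bool = True) -> Registry:
    """Load and validate the registry from delimited-text tables.

    Parameters
    ----------
    path
        Directory with the tables; defaults to the packaged set.
    strict
        Also enforce the packaged-transcription invariants (checksums, 26/20/14
        counts, edge restrictions).  Custom experimental registries may load
        with ``strict=False``.
    """
    path = Path(path) if path is not None else _data_dir()
    if strict:
        _verify_checksums(path)

    conds_df = _read_table(path, "conditions")
    links_df = _read_table(path, "risk_links")
    tmrel_df = _read_table(path, "tmrel")
    parents_file = path / "parent_links.tsv"
    parents_df = (
        pd.read_csv(parents_file, sep="\t") if parents_file.exists() else pd.DataFrame()
    )

    parent_map: dict[str, list[tuple[str, float]]] = {}
    for row in parents_df.itertuples(index=False):
        parent_map.setdefault(row.condition, []).append((row.parent, float(row.rr)))

    conditions: dict[str, ConditionSpec] = {}
    for row in conds_df.itertuples(index=False):
        name = row.modelled_name
        if name in conditions:
            raise RegistryError(f"duplicate modelled condition {name!r}")
        conditions[name] = ConditionSpec(
            modelled_name=name,
            cms_condition=row.cms_condition,
            cms_weight=float(row.cms_weight),
            recovery_rule=row.recovery_rule,
            can_recur=bool(row.can_recur),
            is_cancer=bool(row.is_cancer),
            past_self_as_risk=bool(row.past_self_as_risk),
            past_self_rr=None if pd.isna(row.past_self_rr) else float(row.past_self_rr),
            recovery_prob=None if pd.isna(row.recovery_prob) else float(row.recovery_prob),
            has_parent_risks=bool(row.has_parent_risks),
            parent_conditions=tuple(parent_map.get(name, [])),
        )
    for cond_name in parent_map:
        if cond_name not in conditions:
            raise RegistryError(f"parent link for unknown condition {cond_name!r}")

    links = tuple(
        RiskLink(
            exposure=row.exposure,
            condition=row.condition,
            form=row.form,
            rr_per_unit=float(row.rr_per_unit),
            unit=row.unit,
            lag_years=int(row.lag_years),
            cumulative=bool(row.cumulative),
            affects_case_fatality=bool(row.affects_case_fatality),
            affects_nonmodelled_mortality=bool(row.affects_nonmodelled_mortality),
        )
        for row in links_df.itertuples(index=False)
    )

    tmrels = {
        row.exposure: TmrelSpec(
            exposure=row.exposure,
            central=float(row.central),
            unit=row.unit,
            support_low=float(row.support_low),
            support_high=float(row.support_high),
            distribution=row.distribution,
        )
        for row in tmrel_df.itertuples(index=False)
    }

    mediation = MediationSpec()
    med_file = path / "mediation.tsv"
    if med_file.exists():
        med = pd.read_csv(med_file, sep="\t").set_index("parameter")["value"]
        mediation = MediationSpec(
            delta_sbp_per_bmi_unit=float(med["delta_sbp_per_bmi_unit"]),
            delta_tc_per_bmi_unit=float(med["delta_tc_per_bmi_unit"]),
            bmi_floor=float(med["bmi_floor"]),
        )

    mortality_risks: tuple[MortalityRisk, ...] = ()
    om_file = path / "other_mortality.tsv"
    if om_file.exists():
        om = pd.read_csv(om_file, sep="\t")
        mortality_risks = tuple(
            MortalityRisk(
                source=row.source,
                kind=row.kind,
                form=row.form,
                rr_per_unit=float(row.rr_per_unit),
            )
            for row in om.itertuples(index=False)
        )

    registry = Registry(
        conditions=conditions,
        links=links,
        tmrels=tmrels,
        mediation=mediation,
        mortality_risks=mortality_risks,
    )
    if strict:
        registry.validate_strict()
    return registry
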