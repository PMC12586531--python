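"""Aggregation of simulant histories into reported metrics.

The :class:`ResultsCube` is a tidy table - one row per Monte-Carlo iteration x
scenario x year x stratum x metric - holding the counts the engine records
(alive population, counts with/without major illness, deaths, persons at
risk, threshold crossings).  All headline quantities derive from it:
prevalence of major illness among adults 30+, incidence of major illness
(new crossings of the CMS threshold per person at risk), all-cause mortality
per 10,000 at risk, case-years of major illness prevented or postponed,
age-standardised prevalence against the 2023 structure, and deprivation
gradients with across-iteration direction probabilities.

Uncertainty is summarised across iterations: mean and 2.5th-97.5th
percentiles (linear interpolation on the sorted per-iteration values), with
scenario-minus-base differences computed *within* iteration before
summarising so the common-random-number pairing is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ResultsCube",
    "UncertaintySummary",
    "COUNT_METRICS",
    "major_illness_incidence",
    "case_years_prevented",
    "standardise_to_reference",
    "inequality_gradient",
    "summarise",
    "iteration_series",
    "derived_metric",
    "plot_metric",
]

COUNT_METRICS = (
    "population",        # alive at end of year
    "count_major",       # alive with CMS score > threshold
    "count_without",     # alive without major illness
    "deaths",            # deaths during the year
    "at_risk_start",     # alive at the start of the year
    "major_crossings",   # first crossings of the threshold during the year
    "major_at_risk",     # alive at year start and not yet major-ill
)

DERIVED_METRICS = ("major_prevalence", "mortality_per_10k", "major_incidence_rate")


@dataclass(frozen=True)
class UncertaintySummary:
    """Mean and 95% interval across iterations, plus the fraction of
    iterations in which the quantity is positive."""

    central: float
    lower: float | None
    upper: float | None
    direction_probability: float | None = None
    n_iterations: int = 0

    def __str__(self) -> str:
        if self.lower is None:
            return f"{self.central:.4g}"
        return f"{self.central:.4g} ({self.lower:.4g}, {self.upper:.4g})"


@dataclass
class ResultsCube:
    """Tidy metric x year x scenario x stratum x iteration table."""

    data: pd.DataFrame  # iteration, scenario, year, stratum_type, stratum, metric, value

    REQUIRED = ("iteration", "scenario", "year", "stratum_type", "stratum",
                "metric", "value")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.data.columns)
        if missing:
            raise ValueError(f"results cube missing columns {sorted(missing)}")

    @classmethod
    def from_records(cls, records: list[dict]) -> "ResultsCube":
        return cls(pd.DataFrame.from_records(records, columns=list(cls.REQUIRED)))

    @property
    def scenarios(self) -> tuple[str, ...]:
        return tuple(self.data["scenario"].unique())

    @property
    def iterations(self) -> np.ndarray:
        return np.sort(self.data["iteration"].unique())

    def table(self, metric: str, scenario: str, stratum_type: str = "overall",
              stratum: str = "all") -> pd.DataFrame:
        """Iteration x year table for one metric (derived metrics computed
        on the fly from the counts)."""
        if metric in DERIVED_METRICS:
            return derived_metric(self, metric, scenario, stratum_type, stratum)
        sub = self.data.query(
            "metric == @metric and scenario == @scenario and "
            "stratum_type == @stratum_type and stratum == @stratum")
        return sub.pivot_table(index="iteration", columns="year",
                               values="value", aggfunc="first")

    def validate_conservation(self, atol: float = 1e-9) -> None:
        """count_major + count_without == population, exactly, everywhere."""
        wide = self.data[self.data["metric"].isin(
            ["population", "count_major", "count_without"])].pivot_table(
            index=["iteration", "scenario", "year", "stratum_type", "stratum"],
            columns="metric", values="value", aggfunc="first")
        gap = (wide["count_major"] + wide["count_without"]
               - wide["population"]).abs()
        if (gap > atol).any():
            bad = gap[gap > atol].index[0]
            raise AssertionError(f"count conservation violated at {bad}")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ResultsCube":
        return cls(pd.read_csv(path))


def derived_metric(cube: ResultsCube, metric: str, scenario: str,
                   stratum_type: str = "overall",
                   stratum: str = "all") -> pd.DataFrame:
    def tab(name):
        return cube.table(name, scenario, stratum_type, stratum)

    if metric == "major_prevalence":
        return tab("count_major") / tab("population")
    if metric == "mortality_per_10k":
        return tab("deaths") / tab("at_risk_start") * 1e4
    if metric == "major_incidence_rate":
        return tab("major_crossings") / tab("major_at_risk")
    raise KeyError(metric)


def major_illness_incidence(major: np.ndarray, alive_start: np.ndarray,
                            mask: np.ndarray | None = None) -> float | None:
    """Incidence of major illness in one year from per-simulant flags.

    ``major`` is the end-of-year major-illness flag, with column -1 the
    previous year; new crossings (score moving from <= threshold to > it)
    among persons at risk (alive at year start, not yet major-ill).  Returns
    None when the at-risk denominator is empty.
    """
    if mask is None:
        mask = np.ones(alive_start.shape[0], dtype=bool)
    prev, now = major[:, 0], major[:, 1]
    at_risk = mask & alive_start & ~prev
    if at_risk.sum() == 0:
        return None
    return float((at_risk & now).sum() / at_risk.sum())


def _percentiles(values: np.ndarray) -> tuple[float, float]:
    lo, hi = np.percentile(values, [2.5, 97.5], method="linear")
    return float(lo), float(hi)


def summarise(values: pd.Series | np.ndarray,
              comparator: pd.Series | np.ndarray | None = None,
              relative: bool = False) -> UncertaintySummary:
    """Across-iteration summary of a per-iteration quantity.

    With a comparator, the per-iteration difference comparator - value is
    summarised (positive = reduction relative to the comparator), divided by
    the comparator when ``relative``.  Differencing happens per iteration
    *before* summarising - the arms share iteration indices under common
    random numbers and must stay paired.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    if comparator is not None:
        comparator = pd.Series(np.asarray(comparator, dtype=float))
        if len(comparator) != len(values):
            raise ValueError("mismatched arms: iteration counts differ")
        diff = comparator.to_numpy() - values.to_numpy()
        if relative:
            diff = diff / comparator.to_numpy()
        values = pd.Series(diff)
    arr = values.to_numpy()
    central = float(arr.mean())
    if arr.size < 2:
        return UncertaintySummary(central, None, None, None, arr.size)
    lo, hi = _percentiles(arr)
    return UncertaintySummary(central, lo, hi,
                              float(np.mean(arr > 0)), arr.size)


def case_years_prevented(cube: ResultsCube, scenario: str,
                         base: str = "baseline",
                         horizon: tuple[int, int] = (2023, 2043),
                         stratum_type: str = "overall",
                         stratum: str = "all") -> UncertaintySummary:
    """Case-years of major illness prevented or postponed over the horizon.

    Per iteration: sum over years of (count_major_base - count_major_scenario);
    negative totals mean the scenario *increases* case-years (people living
    longer with major illness).  Arms must share iterations.
    """
    t_base = cube.table("count_major", base, stratum_type, stratum)
    t_scen = cube.table("count_major", scenario, stratum_type, stratum)
    if not t_base.index.equals(t_scen.index):
        raise ValueError("mismatched arms: iteration indices differ")
    years = [y for y in t_base.columns if horizon[0] <= y <= horizon[1]]
    per_iter = (t_base[years] - t_scen[years]).sum(axis=1)
    return summarise(-per_iter.to_numpy(), comparator=np.zeros(len(per_iter)))


def standardise_to_reference(age_specific_prevalence: pd.Series,
                             reference_counts: pd.Series) -> float:
    """Prevalence re-weighted to a fixed reference age structure.

    Removes demographic-change effects: the weighted average of age-specific
    prevalence with weights proportional to the reference population counts.
    Index supports must match exactly.
    """
    prev = age_specific_prevalence.dropna()
    missing = set(reference_counts.index) - set(prev.index)
    extra = set(prev.index) - set(reference_counts.index)
    if missing or extra:
        raise ValueError(
            f"age supports do not match (missing {sorted(missing)}, "
            f"extra {sorted(extra)})")
    w = reference_counts.reindex(prev.index).astype(float)
    w = w / w.sum()
    return float((prev * w).sum())


def inequality_gradient(cube: ResultsCube, year: int, scenario: str,
                        base: str = "baseline",
                        metric: str = "major_prevalence"
                        ) -> UncertaintySummary:
    """Most- vs least-deprived difference in the scenario's effect.

    Per iteration: (base - scenario) reduction in the metric in quintile
    group 1 (most deprived) minus the same reduction in quintile group 5.
    Positive = the scenario helps the most deprived more; the direction
    probability is the fraction of iterations with a positive difference.
    """
    def reduction(q):
        b = cube.table(metric, base, "quintile", str(q))[year]
        s = cube.table(metric, scenario, "quintile", str(q))[year]
        return b - s

    diff = reduction(1) - reduction(5)
    return summarise(-diff.to_numpy(), comparator=np.zeros(len(diff)))


def iteration_series(cube: ResultsCube, metric: str, scenario: str, year: int,
                     stratum_type: str = "overall",
                     stratum: str = "all") -> pd.Series:
    """Per-iteration values of a metric in one year (pairing-safe input for
    :func:`summarise`)."""
    return cube.table(metric, scenario, stratum_type, stratum)[year]


def plot_metric(cube: ResultsCube, metric: str, scenarios=None, base=None,
                stratum_type: str = "overall", stratum: str = "all",
                smooth: int = 1, ax=None):
    """Plot the across-iteration mean of a metric by year and scenario.

    ``smooth`` applies a centred rolling mean for display only; stored
    metrics are never smoothed.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for scen in scenarios or cube.scenarios:
        tab = cube.table(metric, scen, stratum_type, stratum)
        if base is not None:
            tab = cube.table(metric, base, stratum_type, stratum) - tab
        series = tab.mean(axis=0)
        if smooth > 1:
            series = series.rolling(smooth, center=True, min_periods=1).mean()
        ax.plot(series.index, series.to_numpy(), label=scen)
    ax.set_xlabel("year")
    ax.set_ylabel(metric)
    ax.legend()
    return ax
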