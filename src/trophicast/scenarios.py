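"""Future temperature and fishing scenarios, projection and summaries.

Temperature forcing for projections is composed additively from a deep-water
temperature (DIT) baseline, a climate-pathway anomaly, a seeded variability
term replicating the historical residual standard deviation, and a
multidecadal oscillation projected by time-reflection ("mirroring") of its
smoothed historical record.  Fishing scenarios hold per-group mortalities at
status-quo or management-target values.  Projections splice onto a hindcast
endpoint and are summarised as cumulative biomass/catch percent changes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .dynamics import (
    ArenaParameters,
    ForcingSet,
    SimOptions,
    Trajectory,
    run,
)
from .foodweb import EcopathSolution
from .thermal import ThermalNiche

__all__ = [
    "ClimateSeries",
    "ScenarioSpec",
    "ScenarioResult",
    "dit_from_sst",
    "mirror_amo",
    "build_future_temperature",
    "rcp_anomaly",
    "project",
    "cumulative_change",
    "load_fmsy_table",
]

#: surface-to-near-bottom scaling of sea surface temperature (°C)
DEFAULT_SST_OFFSET = 0.61
#: default reflection pivot for the multidecadal-oscillation projection;
#: configurable because sources disagree on the exact pivot year
DEFAULT_AMO_PIVOT = 2012
#: approximate recurrence interval of the oscillation (years), used to wrap
#: reflections that would fall before the start of the historical record
DEFAULT_AMO_RECURRENCE = 62

#: synthetic pathway intensities: total anomaly (°C) accumulated by the end
#: of an 87-year projection window, loosely shaped after the IPCC pathway
#: family ordering (weakest to strongest forcing)
RCP_TOTALS = {"2.6": 1.0, "4.5": 1.8, "6.5": 2.2, "8.5": 3.7}


@dataclass(frozen=True)
class ClimateSeries:
    """A labelled annual climate series with contiguous, increasing years."""

    values: pd.Series
    label: str = ""

    def __post_init__(self):
        years = np.asarray(self.values.index, dtype=int)
        if len(years) == 0:
            raise ValueError(f"climate series {self.label!r} is empty")
        if np.any(np.diff(years) != 1):
            raise ValueError(
                f"climate series {self.label!r} must have strictly increasing "
                "contiguous years"
            )
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"climate series {self.label!r} has non-finite values")
        object.__setattr__(
            self, "values", pd.Series(vals, index=years, name=self.label or None)
        )

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float], label: str = "") -> "ClimateSeries":
        keys = sorted(int(k) for k in mapping)
        return cls(pd.Series([float(mapping[k]) for k in keys], index=keys), label)

    @property
    def years(self) -> np.ndarray:
        return self.values.index.to_numpy()

    @property
    def start_year(self) -> int:
        return int(self.years[0])

    @property
    def end_year(self) -> int:
        return int(self.years[-1])

    def value(self, year: int) -> float:
        return float(self.values.loc[int(year)])


@dataclass
class ScenarioSpec:
    """A named projection: per-group fishing mortalities plus temperature mode."""

    name: str
    f_by_group: dict[str, float]
    temperature_mode: str = "constant_last_year"
    rcp_label: Optional[str] = None
    start_year: int = 2014
    end_year: int = 2100

    def __post_init__(self):
        if self.temperature_mode not in ("constant_last_year", "rcp"):
            raise ValueError(
                f"temperature_mode must be 'constant_last_year' or 'rcp', "
                f"got {self.temperature_mode!r}"
            )
        for group, f in self.f_by_group.items():
            if not np.isfinite(f) or f < 0:
                raise ValueError(f"scenario {self.name!r}: F for {group!r} must be >= 0")
        if self.end_year < self.start_year:
            raise ValueError(
                f"scenario {self.name!r}: end_year {self.end_year} before "
                f"start_year {self.start_year}"
            )


@dataclass
class ScenarioResult:
    """Projection output: the trajectory plus cumulative summaries."""

    spec: ScenarioSpec
    trajectory: Trajectory
    temperature: Optional[pd.Series]
    cumulative_biomass_initial: float
    cumulative_biomass_final: float
    cumulative_catch_initial: float
    cumulative_catch_final: float

    @property
    def biomass_change_pct(self) -> int:
        return cumulative_change(
            self.cumulative_biomass_initial, self.cumulative_biomass_final
        )

    @property
    def catch_change_pct(self) -> int:
        return cumulative_change(
            self.cumulative_catch_initial, self.cumulative_catch_final
        )

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("biomass", self.cumulative_biomass_initial,
                 self.cumulative_biomass_final, self.biomass_change_pct),
                ("catch", self.cumulative_catch_initial,
                 self.cumulative_catch_final, self.catch_change_pct),
            ],
            columns=["kind", "initial", "final", "decrease_pct"],
        )


def dit_from_sst(
    sst: ClimateSeries,
    offset: float = DEFAULT_SST_OFFSET,
    multiplicative: bool = False,
) -> ClimateSeries:
    """Deep-water (near-bottom) temperature from sea surface temperature.

    Default is a constant subtractive offset: DIT(y) = SST(y) − offset.
    With ``multiplicative=True`` the offset is instead a dimensionless scale
    factor, DIT(y) = SST(y) · offset.
    """
    if not np.isfinite(offset):
        raise ValueError("offset must be finite")
    if multiplicative:
        vals = sst.values * offset
    else:
        vals = sst.values - offset
    return ClimateSeries(vals, label=f"dit({sst.label})" if sst.label else "dit")


def mirror_amo(
    smoothed: ClimateSeries,
    pivot_year: int = DEFAULT_AMO_PIVOT,
    end_year: int = 2100,
    recurrence: int = DEFAULT_AMO_RECURRENCE,
) -> ClimateSeries:
    """Project a smoothed oscillation index by time-reflection at a pivot.

    projection(pivot + k) = smoothed(pivot − k) for k ≥ 1; years at or
    before the pivot keep their historical values.  Reflections that would
    fall before the start of the record wrap forward by the recurrence
    interval until they land inside it.
    """
    years = smoothed.years
    pivot_year = int(pivot_year)
    if pivot_year < years[0] or pivot_year > years[-1]:
        raise ValueError(
            f"pivot year {pivot_year} outside series "
            f"[{years[0]}, {years[-1]}]"
        )
    out_years = list(range(int(years[0]), int(end_year) + 1))
    out_vals = []
    first = int(years[0])
    last = int(years[-1])
    for y in out_years:
        if y <= pivot_year:
            if y <= last:
                out_vals.append(smoothed.value(y))
            else:  # pivot at series end with end_year beyond: unreachable
                out_vals.append(smoothed.value(last))
            continue
        src = pivot_year - (y - pivot_year)
        while src < first:
            src += recurrence
        if src > last:
            src = last
        out_vals.append(smoothed.value(src))
    return ClimateSeries(
        pd.Series(out_vals, index=out_years),
        label=f"mirror({smoothed.label})" if smoothed.label else "amo_mirror",
    )


def _historical_sigma(hist: pd.Series, window: int) -> float:
    """Moving average of the windowed historical standard deviation.

    The detrended residual SD is computed in rolling windows, its moving
    average taken with the same window, and the last available value used as
    the projection-noise scale.  The composition of window SD into
    year-specific noise is under-specified upstream; this interpretation is
    deterministic and documented.
    """
    if len(hist) < window + 1:
        return 0.0
    resid = hist - hist.rolling(window, center=True, min_periods=1).mean()
    sd = resid.rolling(window).std()
    smoothed = sd.rolling(window, min_periods=1).mean().dropna()
    if smoothed.empty:
        return 0.0
    return float(smoothed.iloc[-1])


def build_future_temperature(
    hist_dit: ClimateSeries,
    rcp_anomaly: ClimateSeries,
    amo_projection: Optional[ClimateSeries] = None,
    stdev_window: int = 3,
    seed: int = 0,
    variability_scale: float = 1.0,
) -> ClimateSeries:
    """Compose a future temperature series, exactly additively.

    T(y) = DIT_last + anomaly(y) + variability(y) + AMO(y).  The anomaly must
    be referenced to its first projection year (value 0 there).  Variability
    is a seeded normal draw scaled by the windowed historical residual
    standard deviation (``variability_scale=0`` disables it).  The AMO term
    is the projection minus its value at the first projection year, so a
    missing AMO contributes zero.
    """
    if abs(rcp_anomaly.value(rcp_anomaly.start_year)) > 1e-12:
        raise ValueError(
            "rcp_anomaly must be referenced to its first projection year "
            f"(value 0 at {rcp_anomaly.start_year})"
        )
    years = rcp_anomaly.years
    if amo_projection is not None:
        missing = [int(y) for y in years if y not in amo_projection.values.index]
        if missing:
            raise ValueError(f"AMO projection missing years {missing}")
        amo = (
            amo_projection.values.reindex(years).to_numpy()
            - amo_projection.value(int(years[0]))
        )
    else:
        amo = np.zeros(len(years))
    dit_last = hist_dit.value(hist_dit.end_year)
    sigma = _historical_sigma(hist_dit.values, stdev_window) * variability_scale
    rng = np.random.default_rng(seed)
    variability = rng.normal(0.0, 1.0, size=len(years)) * sigma
    vals = dit_last + rcp_anomaly.values.to_numpy() + variability + amo
    return ClimateSeries(pd.Series(vals, index=years), label="future_dit")


def rcp_anomaly(
    label: str,
    start_year: int,
    end_year: int,
    shape: str = "linear",
) -> ClimateSeries:
    """Synthetic climate-pathway temperature anomaly.

    ``label`` selects the total warming accumulated by ``end_year`` from the
    pathway family ("2.6", "4.5", "6.5", "8.5"); ``shape`` is "linear" or
    "convex" (accelerating, quadratic in time).  The anomaly is zero at
    ``start_year``.
    """
    if label not in RCP_TOTALS:
        raise ValueError(f"unknown pathway {label!r}; use one of {sorted(RCP_TOTALS)}")
    if shape not in ("linear", "convex"):
        raise ValueError("shape must be 'linear' or 'convex'")
    years = np.arange(int(start_year), int(end_year) + 1)
    if len(years) < 2:
        frac = np.zeros(len(years))
    else:
        frac = (years - years[0]) / (years[-1] - years[0])
    if shape == "convex":
        frac = frac**2
    vals = RCP_TOTALS[label] * frac
    return ClimateSeries(pd.Series(vals, index=years), label=f"rcp{label}")


def project(
    sol: EcopathSolution,
    arena: ArenaParameters,
    scenario: ScenarioSpec,
    niches: Optional[Mapping[str, ThermalNiche]] = None,
    start_biomass: Optional[np.ndarray] = None,
    last_temperature: Optional[float] = None,
    future_temperature: Optional[ClimateSeries] = None,
    options: Optional[SimOptions] = None,
    f_ramp_per_year: Optional[float] = None,
) -> ScenarioResult:
    """Run one scenario forward from a hindcast endpoint.

    Scenario fishing mortalities apply from ``start_year`` as a step change,
    or approach the target geometrically at ``f_ramp_per_year`` (e.g. 0.15
    for ±15% per year) when given.  Temperature is either held constant at
    ``last_temperature`` or taken from ``future_temperature``, depending on
    the scenario's mode.  Initial state defaults to the balance baseline;
    pass the hindcast's ``final_biomass`` to splice.
    """
    options = options or SimOptions()
    names = sol.names
    for group in scenario.f_by_group:
        if group not in names:
            raise KeyError(
                f"scenario {scenario.name!r}: group {group!r} not in the model"
            )
    years = list(range(scenario.start_year, scenario.end_year + 1))

    f = pd.DataFrame(np.tile(sol.f0, (len(years), 1)), index=years, columns=names)
    for group, target in scenario.f_by_group.items():
        if f_ramp_per_year is None:
            f[group] = target
        else:
            current = float(sol.f0[names.index(group)])
            vals = []
            for _ in years:
                if target > current:
                    current = min(target, current * (1.0 + f_ramp_per_year))
                else:
                    current = max(target, current * (1.0 - f_ramp_per_year))
                vals.append(current)
            f[group] = vals

    if scenario.temperature_mode == "constant_last_year":
        if last_temperature is None:
            temperature = None
        else:
            temperature = pd.Series(float(last_temperature), index=years)
    else:
        if future_temperature is None:
            raise ValueError(
                f"scenario {scenario.name!r} uses mode 'rcp' but no future "
                "temperature series was supplied"
            )
        missing = [y for y in years if y not in future_temperature.values.index]
        if missing:
            raise ValueError(f"future temperature missing years {missing}")
        temperature = future_temperature.values.reindex(years)

    forcing = ForcingSet.build(sol, years, temperature=temperature, f=f)
    traj = run(
        sol, arena, forcing, years,
        niches=niches, options=options, start_biomass=start_biomass,
    )

    living = [g.name for g in sol.model.groups if not g.is_detritus]
    first, last = years[0], years[-1]
    return ScenarioResult(
        spec=scenario,
        trajectory=traj,
        temperature=temperature,
        cumulative_biomass_initial=float(traj.biomass.loc[first, living].sum()),
        cumulative_biomass_final=float(traj.biomass.loc[last, living].sum()),
        cumulative_catch_initial=float(traj.catch.loc[first, living].sum()),
        cumulative_catch_final=float(traj.catch.loc[last, living].sum()),
    )


def cumulative_change(initial: float, final: float) -> int:
    """Percent decrease from initial to final, rounded to the nearest whole
    percent (negative values indicate an increase)."""
    if not initial > 0:
        raise ValueError("initial must be positive")
    return int(round(100.0 * (initial - final) / initial))


def load_fmsy_table() -> pd.DataFrame:
    """Packaged reference table of status-quo and MSY fishing mortalities
    (yr⁻¹) for commercially assessed West-of-Scotland stocks."""
    ref = importlib.resources.files("trophicast.data").joinpath("fmsy_table.csv")
    with ref.open("r") as fh:
        return pd.read_csv(fh)
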