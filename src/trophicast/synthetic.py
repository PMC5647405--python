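"""Synthetic food webs, forcings and observations with known ground truth.

Every downstream stage (balance, calibration, fitting, uncertainty,
validation, projection) is exercised against webs generated here: small
balanced webs with a planted top-down predator, a planted production anomaly,
a temperature series with trend + multidecadal oscillation + noise, and
noisy log-normal observation series produced by the forward model itself —
the statistical structure the log-residual objective assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dynamics import (
    ForcingSet,
    SimOptions,
    Trajectory,
    calibrate_arena,
    run,
    vulnerability_matrix,
)
from .fitting import ObservedSeries, SplineAnomaly, TimeSeriesSet
from .foodweb import EcopathSolution, FoodWebModel, Group, balance_model
from .thermal import ThermalNiche, build_niche, juvenile_offset, plankton_niche

__all__ = ["SyntheticSpec", "SyntheticTruth", "make_web", "make_niches",
           "make_temperature", "make_fishing", "make_observations"]

#: span matching a typical three-decade monitoring window
DEFAULT_YEARS = tuple(range(1985, 2014))


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic study: web size, planted truth, noise, seed."""

    n_groups: int = 6
    planted_v: dict[str, float] = field(default_factory=lambda: {"predator": 50.0})
    anomaly_values: tuple[float, ...] = (1.0, 1.2, 0.85)
    noise_cv: float = 0.1
    seed: int = 0
    years: tuple[int, ...] = DEFAULT_YEARS

    # temperature-series shape: mean level, warming trend, multidecadal
    # oscillation (°C, °C/yr, °C amplitude / yr period), observation noise
    temp_base: float = 9.5
    temp_trend: float = 0.01
    temp_osc_amp: float = 0.5
    temp_osc_period: float = 62.0
    temp_noise_sd: float = 0.15


@dataclass
class SyntheticTruth:
    """Everything needed to score recovery of the planted structure."""

    spec: SyntheticSpec
    model: FoodWebModel
    sol: EcopathSolution
    niches: dict[str, ThermalNiche]
    temperature: pd.Series
    f: pd.DataFrame
    anomaly: SplineAnomaly
    planted_v: dict[str, float]
    trajectory: Trajectory


def _web6() -> FoodWebModel:
    """Six-group shelf web: producer, detritus, zooplankton, a boreal
    planktivore, a eurythermal benthivore, and a fished top predator."""
    groups = [
        Group("producer", is_producer=True, biomass=30, pb=12),
        Group("detritus", is_detritus=True, biomass=10, pb=0),
        Group("zooplankton", biomass=15, pb=5, qb=15),
        Group("planktivore", biomass=4, pb=1.2, qb=6, catch=0.5),
        Group("benthivore", biomass=3, pb=1.0, qb=5, catch=0.3),
        Group("predator", biomass=0.8, pb=0.8, qb=3, catch=0.2),
    ]
    n = len(groups)
    diet = np.zeros((n, n))
    diet[0, 2] = 0.95
    diet[1, 2] = 0.05
    diet[2, 3] = 1.0
    diet[2, 4] = 0.5
    diet[1, 4] = 0.5
    diet[3, 5] = 0.6
    diet[4, 5] = 0.4
    return FoodWebModel(groups=groups, diet=diet)


def _web3() -> FoodWebModel:
    """Minimal producer-consumer-detritus chain."""
    groups = [
        Group("producer", is_producer=True, biomass=10, pb=10),
        Group("consumer", biomass=1, pb=1, qb=5, catch=0.1),
        Group("detritus", is_detritus=True, biomass=5, pb=0),
    ]
    diet = np.zeros((3, 3))
    diet[0, 1] = 1.0
    return FoodWebModel(groups=groups, diet=diet)


def _web12() -> FoodWebModel:
    """Larger preset with two producers and a linked juvenile/adult pair."""
    groups = [
        Group("phytoplankton", is_producer=True, biomass=25, pb=15),
        Group("kelp", is_producer=True, biomass=5, pb=4),
        Group("detritus", is_detritus=True, biomass=20, pb=0),
        Group("small_zooplankton", biomass=12, pb=6, qb=18),
        Group("large_zooplankton", biomass=6, pb=4, qb=12),
        Group("benthos", biomass=8, pb=2.5, qb=8),
        Group("planktivore", biomass=3.5, pb=1.2, qb=6, catch=0.4),
        Group("benthivore", biomass=2.5, pb=1.2, qb=5, catch=0.25),
        Group("juv_gadoid", biomass=0.6, pb=1.5, qb=5, catch=0.05,
              stanza_partner="adult_gadoid"),
        Group("adult_gadoid", biomass=1.2, pb=0.7, qb=3, catch=0.25),
        Group("large_demersal", biomass=1.0, pb=0.6, qb=2.5, catch=0.15),
        Group("seal", biomass=0.15, pb=0.1, qb=8),
    ]
    names = [g.name for g in groups]
    n = len(groups)
    diet = np.zeros((n, n))

    def d(prey, pred, frac):
        diet[names.index(prey), names.index(pred)] = frac

    d("phytoplankton", "small_zooplankton", 0.9)
    d("detritus", "small_zooplankton", 0.1)
    d("phytoplankton", "large_zooplankton", 0.5)
    d("small_zooplankton", "large_zooplankton", 0.4)
    d("detritus", "large_zooplankton", 0.1)
    d("detritus", "benthos", 0.65)
    d("kelp", "benthos", 0.25)
    d("phytoplankton", "benthos", 0.1)
    d("small_zooplankton", "planktivore", 0.6)
    d("large_zooplankton", "planktivore", 0.4)
    d("benthos", "benthivore", 0.7)
    d("detritus", "benthivore", 0.3)
    d("small_zooplankton", "juv_gadoid", 0.5)
    d("large_zooplankton", "juv_gadoid", 0.3)
    d("benthos", "juv_gadoid", 0.2)
    d("planktivore", "adult_gadoid", 0.4)
    d("benthivore", "adult_gadoid", 0.3)
    d("juv_gadoid", "adult_gadoid", 0.1)
    d("benthos", "adult_gadoid", 0.2)
    d("planktivore", "large_demersal", 0.3)
    d("benthivore", "large_demersal", 0.3)
    d("benthos", "large_demersal", 0.3)
    d("juv_gadoid", "large_demersal", 0.1)
    d("planktivore", "seal", 0.3)
    d("benthivore", "seal", 0.2)
    d("adult_gadoid", "seal", 0.3)
    d("large_demersal", "seal", 0.2)
    return FoodWebModel(
        groups=groups, diet=diet, maturation_rate={"juv_gadoid": 0.2}
    )


def make_web(spec: SyntheticSpec) -> FoodWebModel:
    """Emit a balanced web preset for the requested size (3, 6 or 12)."""
    if spec.n_groups <= 3:
        return _web3()
    if spec.n_groups <= 6:
        return _web6()
    if spec.n_groups <= 12:
        return _web12()
    raise ValueError("presets available for 3, 6 and 12 groups only")


def make_temperature(spec: SyntheticSpec) -> pd.Series:
    """Annual water temperature: trend + multidecadal oscillation + noise."""
    rng = np.random.default_rng(spec.seed + 1)
    years = np.asarray(spec.years)
    t = years - years[0]
    vals = (
        spec.temp_base
        + spec.temp_trend * t
        + spec.temp_osc_amp * np.sin(2 * np.pi * t / spec.temp_osc_period)
        + rng.normal(0.0, spec.temp_noise_sd, size=len(years))
    )
    return pd.Series(vals, index=years, name="temperature")


def make_niches(
    model: FoodWebModel, temperature: pd.Series
) -> dict[str, ThermalNiche]:
    """Thermal niches for the preset webs.

    Includes one boreal niche (low optimum, narrow warm side) and one
    eurythermal niche (high optimum, wide tolerance); plankton-type groups
    get wide niches centred on the historical mean temperature.
    """
    temps = temperature.to_numpy()
    wide = plankton_niche(temps)
    niches: dict[str, ThermalNiche] = {}
    boreal = build_niche(t_min=0.0, p10=5.5, p90=11.5, t_max=14.0)
    eurytherm = build_niche(t_min=-4.0, p10=10.0, p90=17.6, t_max=22.0)
    top = build_niche(t_min=1.0, p10=7.0, p90=11.0, t_max=15.0)
    table = {
        "producer": wide,
        "consumer": top,
        "zooplankton": wide,
        "planktivore": boreal,
        "benthivore": eurytherm,
        "predator": top,
        "phytoplankton": wide,
        "kelp": wide,
        "small_zooplankton": wide,
        "large_zooplankton": wide,
        "benthos": eurytherm,
        "juv_gadoid": juvenile_offset(top, 1.0),
        "adult_gadoid": top,
        "large_demersal": eurytherm,
        "seal": boreal,
    }
    for g in model.groups:
        if g.is_detritus:
            continue
        niches[g.name] = table[g.name]
    return niches


def make_fishing(spec: SyntheticSpec, sol: EcopathSolution) -> pd.DataFrame:
    """Mild historical effort trend: the top predator's F ramps up by half
    over the span; other fleets hold the baseline."""
    years = list(spec.years)
    f = pd.DataFrame(
        np.tile(sol.f0, (len(years), 1)), index=years, columns=sol.names
    )
    target = "predator" if "predator" in sol.names else sol.names[-1]
    ramp = np.linspace(1.0, 1.5, len(years))
    f[target] = f[target] * ramp
    return f


def make_observations(
    spec: SyntheticSpec,
    model: Optional[FoodWebModel] = None,
    options: Optional[SimOptions] = None,
) -> tuple[TimeSeriesSet, SyntheticTruth]:
    """Forward-simulate the planted truth and overlay multiplicative noise.

    Observations are trajectory values times lognormal noise with unit mean
    and coefficient of variation ``spec.noise_cv`` (zero noise reproduces the
    trajectory exactly).  Biomass series are emitted for every living group
    and catch series for every fished group, all with weight 1.
    """
    options = options or SimOptions()
    model = model or make_web(spec)
    sol = balance_model(model)
    if not sol.balanced:
        raise RuntimeError("synthetic web failed to balance")
    years = list(spec.years)
    temperature = make_temperature(spec)
    niches = make_niches(model, temperature)
    f = make_fishing(spec, sol)
    anomaly = SplineAnomaly.from_count(
        len(spec.anomaly_values), years[0], years[-1],
        values=np.asarray(spec.anomaly_values),
    )
    v = vulnerability_matrix(model, by_predator=spec.planted_v)
    arena = calibrate_arena(sol, v, literal_prey_pool=options.literal_prey_pool)
    forcing = ForcingSet.build(
        sol, years, temperature=temperature, f=f, pp=anomaly.multiplier(years)
    )
    traj = run(sol, arena, forcing, years, niches=niches, options=options)

    rng = np.random.default_rng(spec.seed + 2)
    sigma = np.sqrt(np.log(1.0 + spec.noise_cv**2))
    series: list[ObservedSeries] = []
    for g in model.groups:
        if g.is_detritus:
            continue
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(years)))
        series.append(
            ObservedSeries(g.name, "biomass", traj.biomass[g.name] * noise)
        )
        if g.catch > 0:
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=len(years)))
            series.append(
                ObservedSeries(g.name, "catch", traj.catch[g.name] * noise)
            )
    truth = SyntheticTruth(
        spec=spec, model=model, sol=sol, niches=niches, temperature=temperature,
        f=f, anomaly=anomaly, planted_v=dict(spec.planted_v), trajectory=traj,
    )
    return TimeSeriesSet(series), truth
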