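"""Future temperature composition, scenario projection, and summaries."""

import numpy as np
import pandas as pd
import pytest

from trophicast.dynamics import ForcingSet, calibrate_arena, run, vulnerability_matrix
from trophicast.scenarios import (
    ClimateSeries,
    ScenarioSpec,
    build_future_temperature,
    cumulative_change,
    dit_from_sst,
    load_fmsy_table,
    mirror_amo,
    project,
    rcp_anomaly,
)
from trophicast.thermal import build_niche


def _series(values, start=2000, label="s"):
    years = range(start, start + len(values))
    return ClimateSeries(pd.Series(list(values), index=list(years)), label)


def test_climate_series_invariants():
    with pytest.raises(ValueError):
        ClimateSeries(pd.Series([1.0, 2.0], index=[2000, 2002]))  # gap
    with pytest.raises(ValueError):
        ClimateSeries(pd.Series([], dtype=float))
    with pytest.raises(ValueError):
        ClimateSeries(pd.Series([np.nan], index=[2000]))


def test_dit_from_sst():
    sst = _series([12.0, 12.5, 13.0])
    ident = dit_from_sst(sst, offset=0.0)
    assert np.allclose(ident.values.to_numpy(), sst.values.to_numpy())
    dit = dit_from_sst(sst)
    assert dit.value(2000) == pytest.approx(11.39, abs=1e-12)
    restored = dit.values + 0.61
    assert np.allclose(restored.to_numpy(), sst.values.to_numpy())
    mult = dit_from_sst(sst, offset=0.9, multiplicative=True)
    assert mult.value(2000) == pytest.approx(12.0 * 0.9)


def test_mirror_amo_reflection():
    years = np.arange(1950, 2014)
    smoothed = ClimateSeries(
        pd.Series(np.sin(2 * np.pi * (years - 1950) / 62.0), index=years), "amo"
    )
    mirrored = mirror_amo(smoothed, pivot_year=2012, end_year=2074)
    assert mirrored.value(2012) == smoothed.value(2012)
    for k in range(1, 2013 - 1950):
        assert mirrored.value(2012 + k) == pytest.approx(
            smoothed.value(2012 - k), abs=1e-12
        )
    with pytest.raises(ValueError):
        mirror_amo(smoothed, pivot_year=1900, end_year=2100)


def test_mirror_amo_minima_spacing():
    years = np.arange(1950, 2014)
    # one historical minimum 62 yr before the pivot (at 1950) on a 62-yr cycle
    smoothed = ClimateSeries(
        pd.Series(-np.cos(2 * np.pi * (years - 1950) / 62.0), index=years), "amo"
    )
    mirrored = mirror_amo(smoothed, pivot_year=2012, end_year=2100)
    v = mirrored.values.to_numpy()
    yrs = mirrored.values.index.to_numpy()
    # plateau-tolerant local minima over the projected era
    minima = [
        int(yrs[k])
        for k in range(2, len(v) - 2)
        if yrs[k] >= 2000
        and v[k] <= v[k - 1] and v[k] <= v[k + 1]
        and v[k] < v[k - 2] and v[k] < v[k + 2]
    ]
    gaps = np.diff(minima)
    assert len(gaps) >= 1
    assert np.all((gaps >= 60) & (gaps <= 65))


def test_build_future_temperature_composition():
    hist = _series([10.0] * 29, start=1985, label="dit")
    zero_anom = ClimateSeries(pd.Series(0.0, index=range(2014, 2101)), "none")
    flat = build_future_temperature(hist, zero_anom, None, seed=0, variability_scale=0.0)
    assert np.allclose(flat.values.to_numpy(), 10.0)

    amo = ClimateSeries(
        pd.Series(np.sin(np.arange(87) / 5.0), index=range(2014, 2101)), "amo"
    )
    amo2 = ClimateSeries(amo.values * 2.0, "amo2")
    t1 = build_future_temperature(hist, zero_anom, amo, seed=4)
    t2 = build_future_temperature(hist, zero_anom, amo2, seed=4)
    delta_amo = (amo2.values - amo2.value(2014)) - (amo.values - amo.value(2014))
    assert np.allclose(
        (t2.values - t1.values).to_numpy(), delta_amo.to_numpy(), atol=1e-12
    )


def test_build_future_temperature_linear_anomaly_and_seeding():
    rng_hist = np.random.default_rng(0)
    hist = _series(10.0 + rng_hist.normal(0, 0.15, 29), start=1985)
    anom = ClimateSeries(
        pd.Series(0.03 * np.arange(87), index=range(2014, 2101)), "lin"
    )
    out = build_future_temperature(hist, anom, None, seed=9)
    rise = out.value(2100) - out.value(2014)
    assert rise == pytest.approx(0.03 * 86, abs=1.0)  # within variability bound
    again = build_future_temperature(hist, anom, None, seed=9)
    assert np.array_equal(out.values.to_numpy(), again.values.to_numpy())
    other = build_future_temperature(hist, anom, None, seed=10)
    assert not np.array_equal(out.values.to_numpy(), other.values.to_numpy())


def test_build_future_temperature_errors():
    hist = _series([10.0] * 29, start=1985)
    bad_ref = ClimateSeries(pd.Series(0.5, index=range(2014, 2020)), "bad")
    with pytest.raises(ValueError):
        build_future_temperature(hist, bad_ref)
    anom = ClimateSeries(pd.Series(0.0, index=range(2014, 2030)), "ok")
    short_amo = ClimateSeries(pd.Series(0.0, index=range(2014, 2020)), "amo")
    with pytest.raises(ValueError) as err:
        build_future_temperature(hist, anom, short_amo)
    assert "2020" in str(err.value)


def test_rcp_anomaly_generators():
    for label, total in (("2.6", 1.0), ("4.5", 1.8), ("6.5", 2.2), ("8.5", 3.7)):
        for shape in ("linear", "convex"):
            a = rcp_anomaly(label, 2014, 2100, shape=shape)
            assert a.value(2014) == 0.0
            assert a.value(2100) == pytest.approx(total, rel=1e-12)
    convex = rcp_anomaly("8.5", 2014, 2100, shape="convex").values.to_numpy()
    linear = rcp_anomaly("8.5", 2014, 2100, shape="linear").values.to_numpy()
    assert np.all(convex[1:-1] < linear[1:-1])
    with pytest.raises(ValueError):
        rcp_anomaly("9.9", 2014, 2100)


def test_cumulative_change_printed_values():
    assert cumulative_change(15.8, 13.5) == 15
    assert cumulative_change(3.04, 2.42) == 20
    assert cumulative_change(1.0, 1.0) == 0
    with pytest.raises(ValueError):
        cumulative_change(0.0, 1.0)


def test_fmsy_table_shipped():
    table = load_fmsy_table()
    assert list(table.columns) == ["species", "f_status_quo", "f_msy"]
    assert len(table) == 11
    cod = table[table.species == "Cod"].iloc[0]
    assert cod.f_status_quo == pytest.approx(0.6)
    assert cod.f_msy == pytest.approx(0.19)


@pytest.fixture(scope="module")
def toy_projection_setup(web3_sol):
    arena = calibrate_arena(web3_sol, vulnerability_matrix(web3_sol.model))
    niches = {
        "producer": build_niche(-20, -10, 30, 40),
        "consumer": build_niche(0.0, 4.0, 8.0, 10.0),  # boreal: t_opt = 6
    }
    return web3_sol, arena, niches


def test_projection_splices_exactly(toy_projection_setup):
    sol, arena, niches = toy_projection_setup
    years_all = list(range(2000, 2041))
    temp_all = pd.Series(6.0, index=years_all)
    forcing_all = ForcingSet.build(sol, years_all, temperature=temp_all)
    reference = run(sol, arena, forcing_all, years_all, niches=niches)

    hind_years = years_all[:15]
    forcing_h = ForcingSet.build(
        sol, hind_years, temperature=temp_all.loc[hind_years]
    )
    hind = run(sol, arena, forcing_h, hind_years, niches=niches)
    spec = ScenarioSpec(
        "frozen",
        {n: float(sol.f0[i]) for i, n in enumerate(sol.names) if sol.f0[i] > 0},
        start_year=years_all[15], end_year=years_all[-1],
    )
    res = project(
        sol, arena, spec, niches=niches,
        start_biomass=hind.final_biomass, last_temperature=6.0,
    )
    assert np.allclose(
        res.trajectory.biomass.to_numpy(),
        reference.biomass.loc[years_all[15]:].to_numpy(),
        rtol=0, atol=1e-12,
    )


def test_warming_scenario_lowers_boreal_predator(toy_projection_setup):
    sol, arena, niches = toy_projection_setup
    f_now = {"consumer": float(sol.f0[sol.model.index("consumer")])}
    const = ScenarioSpec("const", f_now, start_year=2014, end_year=2090)
    warm = ScenarioSpec(
        "warm", f_now, temperature_mode="rcp", rcp_label="8.5",
        start_year=2014, end_year=2090,
    )
    res_const = project(sol, arena, const, niches=niches, last_temperature=6.0)
    future = rcp_anomaly("8.5", 2014, 2090)
    future = ClimateSeries(future.values + 6.0, "warming")
    res_warm = project(
        sol, arena, warm, niches=niches, future_temperature=future
    )
    end_const = res_const.trajectory.biomass["consumer"].iloc[-1]
    end_warm = res_warm.trajectory.biomass["consumer"].iloc[-1]
    assert end_warm < end_const


def test_msy_scenario_recovers_overfished_stock(toy_projection_setup):
    sol, arena, niches = toy_projection_setup
    f0 = float(sol.f0[sol.model.index("consumer")])
    status_quo = ScenarioSpec("sq", {"consumer": f0 * 3.0}, start_year=2014, end_year=2060)
    msy = ScenarioSpec("msy", {"consumer": f0}, start_year=2014, end_year=2060)
    res_sq = project(sol, arena, status_quo, niches=niches, last_temperature=6.0)
    res_msy = project(sol, arena, msy, niches=niches, last_temperature=6.0)
    assert (
        res_msy.trajectory.biomass["consumer"].iloc[-1]
        > res_sq.trajectory.biomass["consumer"].iloc[-1]
    )
    assert res_msy.summary().shape == (2, 4)


def test_status_quo_on_equilibrated_hindcast_is_flat(web6_sol, web6_arena):
    spec = ScenarioSpec(
        "sq",
        {n: float(web6_sol.f0[i]) for i, n in enumerate(web6_sol.names)
         if web6_sol.f0[i] > 0},
        start_year=2014, end_year=2050,
    )
    res = project(web6_sol, web6_arena, spec)
    bio = res.trajectory.biomass.to_numpy()
    assert np.max(np.abs(bio / bio[0] - 1.0)) < 1e-6
    assert res.biomass_change_pct == 0


def test_unknown_group_and_invalid_spec():
    with pytest.raises(ValueError):
        ScenarioSpec("bad", {"x": -0.1})
    with pytest.raises(ValueError):
        ScenarioSpec("bad", {"x": 0.1}, start_year=2020, end_year=2010)
    with pytest.raises(ValueError):
        ScenarioSpec("bad", {"x": 0.1}, temperature_mode="weird")


def test_project_unknown_group_errors(toy_projection_setup):
    sol, arena, niches = toy_projection_setup
    spec = ScenarioSpec("bad", {"unicorn": 0.1}, start_year=2014, end_year=2020)
    with pytest.raises(KeyError) as err:
        project(sol, arena, spec, last_temperature=6.0)
    assert "unicorn" in str(err.value)


def test_f_ramp_approaches_target(toy_projection_setup):
    sol, arena, niches = toy_projection_setup
    f0 = float(sol.f0[sol.model.index("consumer")])
    spec = ScenarioSpec("ramp", {"consumer": f0 * 4.0}, start_year=2014, end_year=2060)
    step = project(sol, arena, spec, niches=niches, last_temperature=6.0)
    ramp = project(
        sol, arena, spec, niches=niches, last_temperature=6.0,
        f_ramp_per_year=0.15,
    )
    # ramped fishing removes less early on, so early biomass stays higher
    assert (
        ramp.trajectory.biomass["consumer"].iloc[0]
        > step.trajectory.biomass["consumer"].iloc[0]
    )
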