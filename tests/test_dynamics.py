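"""Foraging-arena consumption, calibration, and the integrator."""

import numpy as np
import pandas as pd
import pytest

from trophicast.dynamics import (
    ArenaParameters,
    ForcingSet,
    SimOptions,
    SimState,
    calibrate_arena,
    consumption_rate,
    run,
    vulnerability_matrix,
)
from trophicast.foodweb import balance_model
from trophicast.thermal import build_niche


def _arena(a, v, d, n=2):
    A = np.zeros((n, n))
    V = np.ones((n, n))
    D = np.full(n, np.inf)
    A[0, 1] = a
    V[0, 1] = v
    D[1] = d
    return ArenaParameters(a=A, v=V, d=D, m=np.ones((n, n)))


def _state(b, p):
    return SimState(biomass=np.array([b, p]))


def test_eq1_hand_values():
    # a=1, v=2, B=2, P=1, T=M=1, D=1 -> Q = 4/5
    q = consumption_rate(0, 1, _state(2.0, 1.0), _arena(1.0, 2.0, 1.0))
    assert q == pytest.approx(0.8, abs=1e-12)
    # v=4 -> 8/9
    q = consumption_rate(0, 1, _state(2.0, 1.0), _arena(1.0, 4.0, 1.0))
    assert q == pytest.approx(8.0 / 9.0, abs=1e-12)
    # D -> inf: handling term vanishes -> 1.0
    q = consumption_rate(0, 1, _state(2.0, 1.0), _arena(1.0, 2.0, np.inf))
    assert q == pytest.approx(1.0, abs=1e-12)


def test_eq1_zero_cases_and_errors():
    arena = _arena(1.0, 2.0, 1.0)
    assert consumption_rate(0, 1, _state(2.0, 1.0), arena, env_scale=0.0) == 0.0
    assert consumption_rate(1, 0, _state(2.0, 1.0), arena) == 0.0  # a = 0 link
    with pytest.raises(ValueError):
        consumption_rate(0, 1, _state(2.0, 1.0), arena, env_scale=1.5)
    with pytest.raises(ValueError):
        consumption_rate(0, 1, SimState(biomass=np.array([1.0, 1.0]),
                                        t_rel=np.array([-0.5, 1.0])),
                         arena)


def test_eq1_monotone_in_v_and_linear_in_env():
    rng = np.random.default_rng(7)
    for _ in range(30):
        a = rng.uniform(0.1, 5)
        b, p = rng.uniform(0.1, 10, 2)
        d = rng.uniform(0.2, 5)
        vs = np.sort(rng.uniform(0.5, 50, 4))
        qs = [
            consumption_rate(0, 1, _state(b, p), _arena(a, v, d)) for v in vs
        ]
        assert np.all(np.diff(qs) >= -1e-12)
        env = rng.uniform(0, 1)
        q1 = consumption_rate(0, 1, _state(b, p), _arena(a, vs[0], d), 1.0)
        qe = consumption_rate(0, 1, _state(b, p), _arena(a, vs[0], d), env)
        assert qe == pytest.approx(env * q1, rel=1e-12)


def test_calibrate_closed_form_rate_mode(toy2_sol):
    # Q0=1 (toy: consumer eats 5 of producer; scale using explicit numbers):
    # check a = 2 v Q0 / (P0 (v B0 - Q0/D)) directly against the solver
    arena = calibrate_arena(toy2_sol, v=2.0, d=None, v_scaling="rate")
    q0 = toy2_sol.q0[0, 1]
    b0_prey = toy2_sol.biomass[0]
    p0 = toy2_sol.biomass[1]
    expected = 2.0 * 2.0 * q0 / (p0 * (2.0 * b0_prey))
    assert arena.a[0, 1] == pytest.approx(expected, rel=1e-12)


def test_calibration_reproduces_baseline_consumption(web6_sol):
    arena = calibrate_arena(web6_sol, vulnerability_matrix(web6_sol.model))
    state = SimState(biomass=web6_sol.biomass.copy())
    n = web6_sol.model.n_groups
    for j in range(n):
        qb = web6_sol.model.groups[j].qb
        if qb == 0:
            continue
        total = sum(consumption_rate(i, j, state, arena) for i in range(n))
        assert total == pytest.approx(web6_sol.biomass[j] * qb, abs=1e-9)
        for i in range(n):
            q0 = web6_sol.q0[i, j]
            if q0 > 0:
                q = consumption_rate(i, j, state, arena)
                assert q == pytest.approx(q0, rel=1e-10)


def test_calibrate_infeasible_link_reports_feasible_v(toy2_sol):
    with pytest.raises(ValueError) as err:
        calibrate_arena(toy2_sol, v=1e-6, d=1e-3, v_scaling="rate")
    msg = str(err.value)
    assert "producer" in msg and "consumer" in msg and "needs v >" in msg


def test_equilibrium_preserved_50yr(web6_sol, web6_arena):
    years = list(range(2000, 2050))
    forcing = ForcingSet.build(web6_sol, years)
    traj = run(web6_sol, web6_arena, forcing, years)
    rel = np.abs(traj.biomass.iloc[-1].to_numpy() / web6_sol.biomass - 1.0)
    assert np.max(rel) < 1e-6


def test_doubled_f_direction(web6_sol, web6_arena):
    years = list(range(2000, 2010))
    f = pd.DataFrame(
        np.tile(web6_sol.f0, (len(years), 1)),
        index=years, columns=web6_sol.names,
    )
    f["predator"] *= 2.0
    forcing = ForcingSet.build(web6_sol, years, f=f)
    traj = run(web6_sol, web6_arena, forcing, years)
    pred = traj.biomass["predator"].to_numpy()
    base = web6_sol.biomass[web6_sol.model.index("predator")]
    # initial response is a strict decline; the web then compensates, so the
    # decade ends well below baseline without being monotone throughout
    assert np.all(np.diff(pred[:5]) < 0)
    assert pred[-1] < 0.8 * base
    prey0 = web6_sol.biomass[web6_sol.model.index("planktivore")]
    assert traj.biomass["planktivore"].iloc[-1] > prey0


def test_dt_halving_convergence(web6_sol, web6_arena):
    years = list(range(2000, 2010))
    f = pd.DataFrame(
        np.tile(web6_sol.f0 * 1.3, (len(years), 1)),
        index=years, columns=web6_sol.names,
    )
    forcing = ForcingSet.build(web6_sol, years, f=f)
    t1 = run(web6_sol, web6_arena, forcing, years, options=SimOptions(dt=1 / 24))
    t2 = run(web6_sol, web6_arena, forcing, years, options=SimOptions(dt=1 / 48))
    rel = np.abs(t2.biomass.to_numpy() / t1.biomass.to_numpy() - 1.0)
    assert np.max(rel) < 1e-3


def test_run_contract(web6_sol, web6_arena):
    years = list(range(2000, 2005))
    forcing = ForcingSet.build(web6_sol, years)
    empty = run(web6_sol, web6_arena, forcing, [])
    assert len(empty.biomass) == 0
    a = run(web6_sol, web6_arena, forcing, years)
    b = run(web6_sol, web6_arena, forcing, years)
    assert np.array_equal(a.biomass.to_numpy(), b.biomass.to_numpy())
    assert np.array_equal(a.catch.to_numpy(), b.catch.to_numpy())
    with pytest.raises(ValueError):
        run(web6_sol, web6_arena, forcing, list(range(2000, 2010)))


def test_annual_catch_quadrature(web6_sol, web6_arena):
    years = list(range(2000, 2005))
    forcing = ForcingSet.build(web6_sol, years)
    traj = run(web6_sol, web6_arena, forcing, years)
    for name in ("predator", "planktivore"):
        i = web6_sol.model.index(name)
        f0 = web6_sol.f0[i]
        approx = f0 * traj.biomass[name]
        assert np.allclose(traj.catch[name], approx, rtol=0.01)


def test_warming_lowers_boreal_predator(web3_sol):
    """Constant temperature above the consumer's optimum lowers its
    equilibrium biomass and raises its prey's."""
    arena = calibrate_arena(web3_sol, vulnerability_matrix(web3_sol.model))
    niches = {
        "producer": build_niche(-20, -10, 30, 40),  # effectively flat
        "consumer": build_niche(0.0, 4.0, 8.0, 10.0),  # t_opt = 6
    }
    years = list(range(2000, 2030))

    def end_state(temp):
        forcing = ForcingSet.build(
            web3_sol, years, temperature=pd.Series(temp, index=years)
        )
        traj = run(web3_sol, web3_sol and arena, forcing, years, niches=niches)
        return traj.biomass.iloc[-1]

    at_opt = end_state(6.0)
    warm = end_state(12.0)
    assert warm["consumer"] < at_opt["consumer"]
    assert warm["producer"] > at_opt["producer"]


def test_neutral_v_has_no_scale_dependence(web6_sol):
    """Multiplier-mode vulnerabilities are dimensionless: calibration is
    feasible on every link regardless of biomass scale."""
    arena = calibrate_arena(web6_sol, 2.0)
    assert np.all(arena.a[web6_sol.q0 > 0] > 0)
    assert arena.v_input is not None
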