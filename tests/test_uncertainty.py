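"""Monte Carlo envelopes, validation splits, and RMSD."""

import numpy as np
import pandas as pd
import pytest

from trophicast.dynamics import ForcingSet, calibrate_arena, run, vulnerability_matrix
from trophicast.fitting import ObservedSeries, TimeSeriesSet
from trophicast.uncertainty import (
    Pedigree,
    PedigreeEntry,
    monte_carlo,
    rmsd,
    validation_split,
)


@pytest.fixture(scope="module")
def mc_setup(web6_sol):
    years = list(range(2000, 2010))
    forcing = ForcingSet.build(web6_sol, years)
    v = vulnerability_matrix(web6_sol.model)
    baseline = run(web6_sol, calibrate_arena(web6_sol, v), forcing, years)
    return web6_sol, forcing, years, v, baseline


def test_pedigree_entry_bounds():
    PedigreeEntry("x", cv_b=0.8)
    with pytest.raises(ValueError):
        PedigreeEntry("x", cv_b=0.81)
    with pytest.raises(ValueError):
        PedigreeEntry("x", cv_ee=-0.1)


def test_pedigree_pb_cap():
    ped = Pedigree.fixed(0.3)
    cv_b, cv_pb, cv_qb, cv_ee = ped.cvs("anything")
    assert cv_b == 0.3 and cv_qb == 0.3 and cv_ee == 0.3
    assert cv_pb == 0.1  # capped by default
    loose = Pedigree(entries={}, default_cv=0.3, cap_pb=False)
    assert loose.cvs("anything")[1] == 0.3


def test_cv_zero_collapses_envelope(mc_setup):
    sol, forcing, years, v, baseline = mc_setup
    env = monte_carlo(sol, forcing, years, pedigree=0.0, n_trials=20, seed=1, v=v)
    assert np.allclose(env.biomass_p5.to_numpy(), baseline.biomass.to_numpy())
    assert np.allclose(env.biomass_p95.to_numpy(), baseline.biomass.to_numpy())
    assert env.n_accepted == 20


def test_envelope_contains_baseline_and_is_ordered(mc_setup):
    sol, forcing, years, v, baseline = mc_setup
    env = monte_carlo(sol, forcing, years, pedigree=0.1, n_trials=60, seed=2, v=v)
    b = baseline.biomass.to_numpy()
    assert np.all(env.biomass_p5.to_numpy() <= env.biomass_p50.to_numpy() + 1e-12)
    assert np.all(env.biomass_p50.to_numpy() <= env.biomass_p95.to_numpy() + 1e-12)
    living = [not g.is_detritus for g in sol.model.groups]
    inside = (env.biomass_p5.to_numpy() <= b) & (b <= env.biomass_p95.to_numpy())
    assert inside[:, living].mean() > 0.9


def test_seeding_contract(mc_setup):
    sol, forcing, years, v, _ = mc_setup
    e1 = monte_carlo(sol, forcing, years, pedigree=0.1, n_trials=20, seed=5, v=v)
    e2 = monte_carlo(sol, forcing, years, pedigree=0.1, n_trials=20, seed=5, v=v)
    e3 = monte_carlo(sol, forcing, years, pedigree=0.1, n_trials=20, seed=6, v=v)
    assert np.array_equal(e1.biomass_p50.to_numpy(), e2.biomass_p50.to_numpy())
    assert not np.array_equal(e1.biomass_p50.to_numpy(), e3.biomass_p50.to_numpy())


def test_envelope_width_monotone_in_cv(mc_setup):
    sol, forcing, years, v, _ = mc_setup
    widths = []
    for cv in (0.0, 0.05, 0.10):
        env = monte_carlo(sol, forcing, years, pedigree=cv, n_trials=60, seed=3, v=v)
        widths.append(
            float(np.mean(env.biomass_p95.to_numpy() - env.biomass_p5.to_numpy()))
        )
    assert widths[0] <= widths[1] <= widths[2]
    assert widths[0] == pytest.approx(0.0, abs=1e-9)


def test_low_acceptance_aborts(mc_setup):
    sol, forcing, years, v, _ = mc_setup
    with pytest.raises(RuntimeError):
        monte_carlo(
            sol, forcing, years, pedigree=0.1, n_trials=10, seed=1, v=v,
            max_draw_factor=0,
        )


def _make_obs(years, groups=("a", "b"), value=1.0):
    series = [
        ObservedSeries(g, "biomass", pd.Series(value, index=list(years)))
        for g in groups
    ]
    return TimeSeriesSet(series)


def test_validation_split_named_schemes():
    obs = _make_obs(range(1985, 2014))
    for scheme, n_fit, n_hold in (("A", 22, 7), ("B", 24, 5), ("C", 26, 3)):
        fit, hold = validation_split(obs, scheme)
        assert len(fit.years()) == n_fit
        assert len(hold.years()) == n_hold
        assert set(fit.years()) | set(hold.years()) == set(range(1985, 2014))
        assert not set(fit.years()) & set(hold.years())
        assert hold.years()[0] == 2014 - n_hold  # chronological tail


def test_validation_split_explicit_equivalence():
    obs = _make_obs(range(1985, 2014))
    fit_a, hold_a = validation_split(obs, "A")
    fit_e, hold_e = validation_split(obs, list(range(2007, 2014)))
    assert list(fit_a.years()) == list(fit_e.years())
    assert list(hold_a.years()) == list(hold_e.years())


def test_validation_split_short_span_errors():
    obs = _make_obs(range(2000, 2010))
    with pytest.raises(ValueError):
        validation_split(obs, "A")
    with pytest.raises(ValueError):
        validation_split(obs, "Z")


def test_rmsd_identities(mc_setup):
    sol, forcing, years, v, baseline = mc_setup
    same = TimeSeriesSet(
        [ObservedSeries("predator", "biomass", baseline.biomass["predator"])]
    )
    table = rmsd(baseline, same)
    assert table[table.group == "predator"]["rmsd"].iloc[0] == pytest.approx(0.0, abs=1e-14)
    offset = TimeSeriesSet(
        [ObservedSeries("predator", "biomass", baseline.biomass["predator"] + 0.25)]
    )
    table = rmsd(baseline, offset)
    assert table[table.group == "predator"]["rmsd"].iloc[0] == pytest.approx(0.25, rel=1e-12)


def test_rmsd_pooled_formula(mc_setup):
    sol, forcing, years, v, baseline = mc_setup
    obs = TimeSeriesSet(
        [
            ObservedSeries("predator", "biomass", baseline.biomass["predator"] + 0.1),
            ObservedSeries("planktivore", "biomass", baseline.biomass["planktivore"] + 0.3),
        ]
    )
    table = rmsd(baseline, obs)
    r1 = table["rmsd"].iloc[0]
    r2 = table["rmsd"].iloc[1]
    pooled = table[table.group == "(pooled)"]["rmsd"].iloc[0]
    assert pooled == pytest.approx(np.sqrt((r1**2 + r2**2) / 2.0), rel=1e-12)


def test_rmsd_empty_overlap_errors(mc_setup):
    sol, forcing, years, v, baseline = mc_setup
    obs = TimeSeriesSet(
        [ObservedSeries("predator", "biomass", pd.Series(1.0, index=[1900, 1901]))]
    )
    with pytest.raises(ValueError):
        rmsd(baseline, obs)


def test_progressive_fit_windows_never_hurt_noise_free(noise_free_study):
    """Longer fit windows (A -> B -> C) do not worsen pooled biomass RMSD on
    noise-free synthetic data."""
    from trophicast.fitting import stepwise_fit

    observed, truth = noise_free_study
    sol = truth.sol
    pooled = []
    for scheme in ("A", "B", "C"):
        fit_set, _ = validation_split(observed, scheme)
        fit_years = [int(y) for y in fit_set.years()]
        report = stepwise_fit(
            sol, fit_set, fit_years,
            max_v=1, spline_counts=(3,), temperature=truth.temperature,
            f_observed=truth.f, niches=truth.niches, seed=21, n_restarts=1,
            fatol=1e-9,
        )
        best = report.best
        all_years = [int(y) for y in truth.temperature.index]
        anomaly = best.anomaly.multiplier(all_years)
        arena = calibrate_arena(sol, {**{}, **best.vulnerabilities})
        forcing = ForcingSet.build(
            sol, all_years, temperature=truth.temperature, f=truth.f, pp=anomaly
        )
        traj = run(sol, arena, forcing, all_years, niches=truth.niches)
        bio_obs = TimeSeriesSet([s for s in observed if s.kind == "biomass"])
        table = rmsd(traj, bio_obs)
        pooled.append(float(table[table.group == "(pooled)"]["rmsd"].iloc[0]))
    assert pooled[1] <= pooled[0] * (1 + 1e-6)
    assert pooled[2] <= pooled[1] * (1 + 1e-6)
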