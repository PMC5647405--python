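"""Monte Carlo propagation of baseline-input uncertainty and hold-out validation.

Each Monte Carlo trial perturbs the basic balance inputs (B, P/B, Q/B, EE)
uniformly within per-group confidence half-widths (a fixed ±10% by default,
or a per-group data pedigree), re-solves the balance, rejects trials whose
solution is infeasible, re-runs the simulation on the fixed fitted arena and
accumulates trajectories into empirical 5/50/95 percentile envelopes.

Validation splits the observed series chronologically into a fit window and
a hold-out tail (named schemes keep 7, 5 or 3 final years out on a 29-year
record) and scores predictions on the natural scale by root mean square
deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .dynamics import ForcingSet, SimOptions, Trajectory, calibrate_arena, run
from .fitting import TimeSeriesSet
from .foodweb import BalanceError, EcopathSolution, balance_model
from .thermal import ThermalNiche

__all__ = [
    "PedigreeEntry",
    "Pedigree",
    "MCEnvelope",
    "monte_carlo",
    "validation_split",
    "rmsd",
]

#: named chronological hold-out schemes: years kept out at the end of a
#: 29-year record (fit windows of 22, 24 and 26 years respectively)
SPLIT_SCHEMES = {"A": 7, "B": 5, "C": 3}
MIN_SPAN = 29

#: default cap on the P/B half-width: wider production intervals amplify the
#: envelopes disproportionately, so the pedigree keeps P/B at 10%
PB_CV_CAP = 0.1


@dataclass
class PedigreeEntry:
    """Fractional confidence half-widths of one group's basic inputs."""

    group: str
    cv_b: float = 0.1
    cv_pb: float = 0.1
    cv_qb: float = 0.1
    cv_ee: float = 0.1

    def __post_init__(self):
        for name in ("cv_b", "cv_pb", "cv_qb", "cv_ee"):
            val = getattr(self, name)
            if not 0.0 <= val <= 0.8:
                raise ValueError(f"{name} must lie in [0, 0.8], got {val}")


@dataclass
class Pedigree:
    """Per-group input pedigree; groups without an entry use the default CV."""

    entries: dict[str, PedigreeEntry] = field(default_factory=dict)
    default_cv: float = 0.1
    cap_pb: bool = True

    @classmethod
    def fixed(cls, cv: float) -> "Pedigree":
        return cls(entries={}, default_cv=cv)

    def cvs(self, group: str) -> tuple[float, float, float, float]:
        e = self.entries.get(group)
        if e is None:
            cv_pb = min(self.default_cv, PB_CV_CAP) if self.cap_pb else self.default_cv
            return self.default_cv, cv_pb, self.default_cv, self.default_cv
        cv_pb = min(e.cv_pb, PB_CV_CAP) if self.cap_pb else e.cv_pb
        return e.cv_b, cv_pb, e.cv_qb, e.cv_ee


@dataclass
class MCEnvelope:
    """Empirical Monte Carlo envelope per group, kind and year."""

    biomass_p5: pd.DataFrame
    biomass_p50: pd.DataFrame
    biomass_p95: pd.DataFrame
    catch_p5: pd.DataFrame
    catch_p50: pd.DataFrame
    catch_p95: pd.DataFrame
    n_accepted: int
    n_drawn: int

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for kind, p5, p50, p95 in (
            ("biomass", self.biomass_p5, self.biomass_p50, self.biomass_p95),
            ("catch", self.catch_p5, self.catch_p50, self.catch_p95),
        ):
            stacked = pd.concat(
                {"p5": p5.stack(), "median": p50.stack(), "p95": p95.stack()},
                axis=1,
            ).reset_index()
            stacked.columns = ["year", "group", "p5", "median", "p95"]
            stacked.insert(1, "kind", kind)
            frames.append(stacked)
        return pd.concat(frames, ignore_index=True)


def monte_carlo(
    sol: EcopathSolution,
    forcing: ForcingSet,
    years: Sequence[int],
    pedigree: Union[Pedigree, float] = 0.1,
    n_trials: int = 200,
    seed: int = 0,
    v=None,
    niches: Optional[Mapping[str, ThermalNiche]] = None,
    options: Optional[SimOptions] = None,
    max_draw_factor: int = 50,
) -> MCEnvelope:
    """Propagate balance-input uncertainty through the simulation.

    Draws inputs uniformly within ±CV of the base values, re-balances,
    rejects infeasible draws (any living EE outside [0, 1], negative solved
    biomass, or an uncalibratable arena), re-runs the simulation with the
    fixed vulnerabilities ``v`` and accumulates ``n_trials`` accepted
    trajectories.  Aborts if acceptance falls below 1 in
    ``max_draw_factor`` draws per required trial.
    """
    options = options or SimOptions()
    if isinstance(pedigree, (int, float)):
        pedigree = Pedigree.fixed(float(pedigree))
    model = sol.model
    rng = np.random.default_rng(seed)
    years = np.asarray(list(years), dtype=int)
    names = model.names
    n = model.n_groups

    cv_b = np.zeros(n)
    cv_pb = np.zeros(n)
    cv_qb = np.zeros(n)
    cv_ee = np.zeros(n)
    for k, name in enumerate(names):
        cv_b[k], cv_pb[k], cv_qb[k], cv_ee[k] = pedigree.cvs(name)

    base_b = sol.biomass
    base_pb = np.array([g.pb for g in model.groups])
    base_qb = np.array([g.qb for g in model.groups])
    base_ee = sol.ee

    bios, cats = [], []
    n_drawn = 0
    max_draws = max_draw_factor * n_trials
    while len(bios) < n_trials:
        if n_drawn >= max_draws:
            rate = len(bios) / max(n_drawn, 1)
            raise RuntimeError(
                f"Monte Carlo acceptance rate {rate:.3%} too low after "
                f"{n_drawn} draws; loosen the pedigree or rebalance the model"
            )
        n_drawn += 1
        b = base_b * (1.0 + cv_b * rng.uniform(-1, 1, n))
        pb = base_pb * (1.0 + cv_pb * rng.uniform(-1, 1, n))
        qb = base_qb * (1.0 + cv_qb * rng.uniform(-1, 1, n))
        ee = base_ee * (1.0 + cv_ee * rng.uniform(-1, 1, n))
        try:
            trial_model = model.with_inputs(biomass=b, pb=pb, qb=qb, ee=ee)
            trial_sol = balance_model(trial_model)
        except (BalanceError, ValueError):
            continue
        if not trial_sol.balanced:
            continue
        try:
            arena = calibrate_arena(
                trial_sol,
                v if v is not None else 2.0,
                literal_prey_pool=options.literal_prey_pool,
            )
            traj = run(
                trial_sol, arena, forcing, years, niches=niches, options=options
            )
        except (ValueError, FloatingPointError):
            continue
        bios.append(traj.biomass.to_numpy())
        cats.append(traj.catch.to_numpy())

    bio_arr = np.stack(bios)  # (trials, years, groups)
    cat_arr = np.stack(cats)
    idx = pd.Index(years, name="year")

    def q(arr, p):
        return pd.DataFrame(np.percentile(arr, p, axis=0), index=idx, columns=names)

    return MCEnvelope(
        biomass_p5=q(bio_arr, 5),
        biomass_p50=q(bio_arr, 50),
        biomass_p95=q(bio_arr, 95),
        catch_p5=q(cat_arr, 5),
        catch_p50=q(cat_arr, 50),
        catch_p95=q(cat_arr, 95),
        n_accepted=len(bios),
        n_drawn=n_drawn,
    )


def validation_split(
    observed: TimeSeriesSet,
    scheme: Union[str, Sequence[int]],
) -> tuple[TimeSeriesSet, TimeSeriesSet]:
    """Chronological fit/hold-out split of the observed series.

    ``scheme`` is one of the named schemes ("A", "B", "C") or an explicit
    collection of hold-out years.  The union of the two sets is the input
    and they never overlap.
    """
    all_years = observed.years()
    if isinstance(scheme, str):
        if scheme not in SPLIT_SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}; use A, B or C")
        span = int(all_years[-1] - all_years[0] + 1)
        if span < MIN_SPAN:
            raise ValueError(
                f"named schemes need a span of at least {MIN_SPAN} years, got {span}"
            )
        n_holdout = SPLIT_SCHEMES[scheme]
        holdout_years = set(int(y) for y in all_years[-n_holdout:])
    else:
        holdout_years = set(int(y) for y in scheme)
    fit_years = [int(y) for y in all_years if int(y) not in holdout_years]
    fit_set = observed.restrict(fit_years)
    holdout_set = observed.restrict(sorted(holdout_years))
    return fit_set, holdout_set


def rmsd(
    predicted: Trajectory,
    observed: TimeSeriesSet,
    years: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Root mean square deviation per series plus a pooled row.

    Computed on the natural (untransformed) scale over the requested years;
    the pooled value pools all squared deviations across series.
    """
    rows = []
    sq_all = []
    for s in observed.active():
        table = predicted.biomass if s.kind == "biomass" else predicted.catch
        pred = table[s.group]
        common = s.values.index.intersection(pred.index)
        if years is not None:
            common = common.intersection(pd.Index(list(years)))
        if len(common) == 0:
            raise ValueError(f"series {s.label}: empty overlap for RMSD")
        diff = s.values.loc[common].to_numpy() - pred.loc[common].to_numpy()
        sq = diff**2
        sq_all.append(sq)
        rows.append((s.group, s.kind, float(np.sqrt(sq.mean())), len(common)))
    pooled = float(np.sqrt(np.concatenate(sq_all).mean()))
    out = pd.DataFrame(rows, columns=["group", "kind", "rmsd", "n"])
    out.loc[len(out)] = ("(pooled)", "all", pooled, int(sum(r[3] for r in rows)))
    return out
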