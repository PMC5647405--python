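"""Foraging-arena consumption and forward simulation of the food web.

Consumption on each predator-prey link follows the foraging-arena rate

    Q_ij = env_j * a_ij v_ij B_i P_j T_i T_j M_ij
           / (v_ij + v_ij T_i M_ij + a_ij M_ij P_j T_j / D_j)

where ``a`` is the effective search rate, ``v`` the vulnerability exchange
rate (1 = strictly bottom-up, large = top-down), ``T`` relative feeding
times, ``M`` mediation multipliers, and ``D_j`` the handling time whose only
role is to saturate the rate at high prey density (D = inf disables the
limit).  ``env_j`` is the predator's thermal response at the current water
temperature, scaling the size of the foraging arena.

Search rates are not free inputs: :func:`calibrate_arena` solves them in
closed form so that the rate equation reproduces the mass-balance baseline
consumption exactly, which makes the balanced state a fixed point of the
dynamics under baseline forcing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _kernel
from .foodweb import EcopathSolution, FoodWebModel
from .thermal import ThermalNiche

__all__ = [
    "ArenaParameters",
    "SimState",
    "SimOptions",
    "ForcingSet",
    "Trajectory",
    "consumption_rate",
    "calibrate_arena",
    "vulnerability_matrix",
    "step",
    "run",
]

DEFAULT_VULNERABILITY = 2.0


@dataclass
class ArenaParameters:
    """Per-link foraging-arena constants.

    ``a[i, j]`` search rate of predator j on prey i ((t·km⁻²)⁻¹·yr⁻¹, zero on
    absent links), ``v[i, j]`` vulnerabilities (≥ 1), ``d[j]`` handling times
    (yr; inf = no handling limit), ``m[i, j]`` mediation multipliers.
    """

    a: np.ndarray
    v: np.ndarray
    d: np.ndarray
    m: np.ndarray

    #: user-level dimensionless vulnerabilities, kept for reporting when the
    #: equation-level exchange rates in ``v`` were derived from multipliers
    v_input: Optional[np.ndarray] = None

    def __post_init__(self):
        if np.any(self.a < 0):
            raise ValueError("search rates must be non-negative")
        if np.any(self.v[self.a > 0] <= 0.0):
            raise ValueError("vulnerability exchange rates must be positive on active links")


@dataclass
class SimState:
    """Instantaneous simulation state."""

    biomass: np.ndarray
    t_rel: Optional[np.ndarray] = None
    time: float = 0.0

    def __post_init__(self):
        self.biomass = np.asarray(self.biomass, dtype=float)
        if np.any(self.biomass < 0):
            raise ValueError("biomass must be non-negative")
        if self.t_rel is None:
            self.t_rel = np.ones_like(self.biomass)
        else:
            self.t_rel = np.asarray(self.t_rel, dtype=float)


@dataclass
class SimOptions:
    """Numerical and structural switches of the integrator."""

    dt: float = 1.0 / 12.0  # yr; monthly default
    producer_cap_mult: float = 10.0  # producer ceiling as multiple of baseline
    apply_thermal_to_producers: bool = True
    feeding_alpha: float = 0.0  # 0 = fixed relative feeding times
    trel_min: float = 0.1
    trel_max: float = 2.0
    literal_prey_pool: bool = False  # prey pool in the saturation term

    @property
    def steps_per_year(self) -> int:
        spy = round(1.0 / self.dt)
        if abs(spy * self.dt - 1.0) > 1e-9:
            raise ValueError("dt must divide one year evenly")
        return spy


def consumption_rate(
    i: int,
    j: int,
    state: SimState,
    arena: ArenaParameters,
    env_scale: float = 1.0,
) -> float:
    """Reference (non-compiled) evaluation of one link's consumption rate.

    Returns t·km⁻²·yr⁻¹.  Zero when the link has no search rate or the
    environmental scale is zero.
    """
    if not (0.0 <= env_scale <= 1.0):
        raise ValueError("env_scale must lie in [0, 1]")
    b_i = float(state.biomass[i])
    p_j = float(state.biomass[j])
    t_i = float(state.t_rel[i])
    t_j = float(state.t_rel[j])
    a = float(arena.a[i, j])
    if min(b_i, p_j, t_i, t_j) < 0:
        raise ValueError("negative state input")
    if a == 0.0 or env_scale == 0.0:
        return 0.0
    v = float(arena.v[i, j])
    m = float(arena.m[i, j])
    d = float(arena.d[j])
    dinv = 0.0 if math.isinf(d) else 1.0 / d
    num = a * v * b_i * p_j * t_i * t_j * m
    den = v + v * t_i * m + a * m * p_j * t_j * dinv
    return env_scale * num / den


def vulnerability_matrix(
    model: FoodWebModel,
    default: float = DEFAULT_VULNERABILITY,
    by_predator: Optional[Mapping[str, float]] = None,
) -> np.ndarray:
    """Full vulnerability matrix from a default plus per-predator overrides.

    A per-predator value applies the same top-down/bottom-up control to all
    of that predator's prey links.
    """
    n = model.n_groups
    v = np.full((n, n), float(default))
    if by_predator:
        for name, val in by_predator.items():
            if val < 1.0:
                raise ValueError(f"vulnerability for {name!r} must be >= 1")
            v[:, model.index(name)] = float(val)
    return v


def calibrate_arena(
    sol: EcopathSolution,
    v: Union[float, np.ndarray, Mapping[str, float]] = DEFAULT_VULNERABILITY,
    d: Union[float, np.ndarray, None] = 1.0,
    m: Optional[np.ndarray] = None,
    literal_prey_pool: bool = False,
    v_scaling: str = "multiplier",
) -> ArenaParameters:
    """Solve the per-link search rates that reproduce the baseline.

    At the balanced state (all feeding times and mediation 1, environmental
    scale 1) the rate equation inverts per link to

        a = 2 v Q0 / (pool0 * (v B0 - Q0 / D))

    with pool0 the predator baseline biomass (or the prey's, in the literal
    pool convention).  Links where ``v B0 <= Q0 / D`` cannot reproduce the
    baseline at any search rate; they raise with the minimum feasible v.

    ``v_scaling`` controls how the supplied vulnerabilities are interpreted:

    * ``"multiplier"`` (default, the field convention): dimensionless values
      in (1, inf), 2 neutral; converted to exchange rates as
      ``v_rate = v * Q0 / B0_prey`` (the multiplier times the baseline
      predation mortality on the link), so v > 2 yields top-down and
      1 < v < 2 bottom-up responses for any web scale.
    * ``"rate"``: the values already are the equation-level exchange rates.

    The handling time default D = 1 yr retains the predator-interference term
    of the saturation denominator; D = inf removes it, in which case the
    dynamics become insensitive to v (mass-action limit).
    """
    model = sol.model
    n = model.n_groups
    if isinstance(v, Mapping):
        v_user = vulnerability_matrix(model, by_predator=v)
    elif np.isscalar(v):
        v_user = np.full((n, n), float(v))
    else:
        v_user = np.asarray(v, dtype=float).copy()
    if v_scaling not in ("multiplier", "rate"):
        raise ValueError("v_scaling must be 'multiplier' or 'rate'")
    if d is None:
        d_vec = np.full(n, np.inf)
    elif np.isscalar(d):
        d_vec = np.full(n, float(d))
    else:
        d_vec = np.asarray(d, dtype=float)
    m_mat = np.ones((n, n)) if m is None else np.asarray(m, dtype=float)

    a = np.zeros((n, n))
    v_rate = np.full((n, n), 1.0)
    b0 = sol.biomass
    for j in range(n):
        dinv = 0.0 if math.isinf(d_vec[j]) else 1.0 / d_vec[j]
        for i in range(n):
            q0 = sol.q0[i, j]
            if q0 <= 0:
                continue
            if v_scaling == "multiplier":
                if v_user[i, j] < 1.0:
                    raise ValueError(
                        f"vulnerability multiplier on link "
                        f"{model.names[i]}->{model.names[j]} must be >= 1"
                    )
                vij = v_user[i, j] * q0 / b0[i]
            else:
                vij = v_user[i, j]
            pool0 = b0[i] if literal_prey_pool else b0[j]
            denom = pool0 * (vij * b0[i] - q0 * dinv)
            if denom <= 0:
                if v_scaling == "multiplier":
                    v_min = dinv  # v_rate*B0 = v*q0; need v*q0 > q0/D
                else:
                    v_min = q0 * dinv / b0[i]
                raise ValueError(
                    f"infeasible link {model.names[i]}->{model.names[j]}: "
                    f"baseline consumption exceeds the handling-limited arena; "
                    f"needs v > {v_min:.6g}"
                )
            a[i, j] = 2.0 * vij * q0 / denom
            v_rate[i, j] = vij
    return ArenaParameters(a=a, v=v_rate, d=d_vec, m=m_mat, v_input=v_user)


@dataclass
class ForcingSet:
    """Time-indexed drivers over a simulation horizon.

    ``temperature`` °C per year (optional: no thermal forcing), ``f`` fishing
    mortality per year and group (yr⁻¹), ``pp`` multiplier on primary
    production per year.
    """

    years: np.ndarray
    f: pd.DataFrame
    temperature: Optional[pd.Series] = None
    pp: Optional[pd.Series] = None

    @classmethod
    def build(
        cls,
        sol: EcopathSolution,
        years: Sequence[int],
        temperature: Optional[pd.Series] = None,
        f: Optional[pd.DataFrame] = None,
        pp: Optional[pd.Series] = None,
    ) -> "ForcingSet":
        """Assemble forcing, defaulting F to the baseline and the production
        multiplier to 1 for any year/group not supplied."""
        years = np.asarray(list(years), dtype=int)
        names = sol.names
        full_f = pd.DataFrame(
            np.tile(sol.f0, (len(years), 1)), index=years, columns=names
        )
        if f is not None:
            for col in f.columns:
                if col not in names:
                    raise KeyError(f"forcing names unknown group {col!r}")
            sub = f.reindex(years)
            for col in f.columns:
                vals = sub[col]
                full_f.loc[vals.notna(), col] = vals[vals.notna()]
        full_pp = pd.Series(1.0, index=years)
        if pp is not None:
            aligned = pp.reindex(years)
            full_pp[aligned.notna()] = aligned[aligned.notna()]
        if temperature is not None:
            missing = [int(y) for y in years if y not in temperature.index]
            if missing:
                raise ValueError(f"temperature forcing missing years {missing}")
            temperature = temperature.reindex(years).astype(float)
        return cls(years=years, f=full_f, temperature=temperature, pp=full_pp)

    def check_covers(self, years: Sequence[int]) -> None:
        missing = sorted(set(int(y) for y in years) - set(self.years.tolist()))
        if missing:
            raise ValueError(f"forcing does not cover years {missing}")


@dataclass
class Trajectory:
    """Annual output of a run: mean biomass and accumulated catch per group."""

    biomass: pd.DataFrame
    catch: pd.DataFrame
    final_biomass: np.ndarray
    final_t_rel: np.ndarray

    @property
    def years(self) -> np.ndarray:
        return self.biomass.index.to_numpy()

    def to_frame(self) -> pd.DataFrame:
        """Tidy (year, group, biomass, catch) table."""
        b = self.biomass.stack().rename("biomass")
        c = self.catch.stack().rename("catch")
        out = pd.concat([b, c], axis=1).reset_index()
        out.columns = ["year", "group", "biomass", "catch"]
        return out


def _env_matrix(
    model: FoodWebModel,
    forcing: ForcingSet,
    years: np.ndarray,
    niches: Optional[Mapping[str, ThermalNiche]],
    options: SimOptions,
    steps_per_year: int,
) -> np.ndarray:
    n = model.n_groups
    n_steps = len(years) * steps_per_year
    env = np.ones((n_steps, n))
    if niches is None or forcing.temperature is None:
        return env
    temps = forcing.temperature.reindex(years).to_numpy()
    for k, grp in enumerate(model.groups):
        if grp.is_detritus:
            continue
        if grp.is_producer and not options.apply_thermal_to_producers:
            continue
        niche = niches.get(grp.name)
        if niche is None:
            continue
        annual = niche.response(temps)
        env[:, k] = np.repeat(annual, steps_per_year)
    return env


def _structural_arrays(sol: EcopathSolution, options: SimOptions):
    """Producer growth, detritus closure and stanza arrays for the kernel."""
    model = sol.model
    n = model.n_groups
    is_producer = np.array([g.is_producer for g in model.groups])
    is_detritus = np.array([g.is_detritus for g in model.groups])
    qb = np.array([g.qb for g in model.groups], dtype=float)

    r_prod = np.zeros(n)
    cap = np.ones(n)
    for k, grp in enumerate(model.groups):
        if grp.is_producer:
            cap[k] = options.producer_cap_mult * sol.biomass[k]
            r_prod[k] = grp.pb / (1.0 - 1.0 / options.producer_cap_mult)

    unassim = np.where(
        np.array([g.is_consumer for g in model.groups]),
        1.0 - model.assimilation,
        0.0,
    )

    det_idx = np.where(is_detritus)[0]
    det_share = np.zeros(n)
    det_export = np.zeros(n)
    if det_idx.size:
        inflow0 = float(
            np.sum(unassim * qb * sol.biomass)
            + np.sum(sol.m0 * sol.biomass)
        )
        out0 = sol.q0.sum(axis=1)
        basis = out0[det_idx]
        if basis.sum() <= 0:
            basis = sol.biomass[det_idx]
        shares = basis / basis.sum()
        for s, k in zip(shares, det_idx):
            det_share[k] = s
            export = s * inflow0 - out0[k]
            if export < -1e-9:
                raise ValueError(
                    f"detritus pool {model.names[k]!r} consumes more than its "
                    "inflow share; adjust the web"
                )
            det_export[k] = max(export, 0.0) / sol.biomass[k]

    m0 = sol.m0.copy()
    juv, adult, rate, comp = [], [], [], []
    for k, grp in enumerate(model.groups):
        if grp.stanza_partner is None:
            continue
        rate_k = model.maturation_rate.get(grp.name, 0.0)
        if rate_k <= 0:
            continue
        if m0[k] < rate_k - 1e-12:
            raise ValueError(
                f"maturation rate of {grp.name!r} exceeds its other mortality"
            )
        ia = model.index(grp.stanza_partner)
        m0[k] -= rate_k  # the maturation flow replaces part of other mortality
        juv.append(k)
        adult.append(ia)
        rate.append(rate_k)
        comp.append(rate_k * sol.biomass[k] / sol.biomass[ia])
    stanza_juv = np.array(juv, dtype=np.int64)
    stanza_adult = np.array(adult, dtype=np.int64)
    stanza_rate = np.array(rate, dtype=float)
    stanza_comp = np.array(comp, dtype=float)
    return (
        is_producer,
        is_detritus,
        qb,
        r_prod,
        cap,
        unassim,
        det_share,
        det_export,
        m0,
        stanza_juv,
        stanza_adult,
        stanza_rate,
        stanza_comp,
    )


def run(
    sol: EcopathSolution,
    arena: ArenaParameters,
    forcing: ForcingSet,
    years: Sequence[int],
    niches: Optional[Mapping[str, ThermalNiche]] = None,
    options: Optional[SimOptions] = None,
    start_biomass: Optional[np.ndarray] = None,
) -> Trajectory:
    """Simulate the web over ``years`` and report annual biomass and catch.

    Deterministic: identical inputs give bit-identical output.  The state is
    initialised at the mass-balance baseline unless ``start_biomass`` is
    given (e.g. to splice a scenario onto a hindcast endpoint).
    """
    options = options or SimOptions()
    model = sol.model
    years = np.asarray(list(years), dtype=int)
    names = model.names
    if years.size == 0:
        empty = pd.DataFrame(columns=names, index=pd.Index([], name="year"))
        b0 = sol.biomass if start_biomass is None else np.asarray(start_biomass)
        return Trajectory(empty, empty.copy(), b0.copy(), np.ones(model.n_groups))
    if np.any(np.diff(years) != 1):
        raise ValueError("years must be consecutive")
    forcing.check_covers(years)

    spy = options.steps_per_year
    (
        is_producer,
        is_detritus,
        qb,
        r_prod,
        cap,
        unassim,
        det_share,
        det_export,
        m0,
        stanza_juv,
        stanza_adult,
        stanza_rate,
        stanza_comp,
    ) = _structural_arrays(sol, options)

    env = _env_matrix(model, forcing, years, niches, options, spy)
    ppm = np.repeat(forcing.pp.reindex(years).to_numpy(dtype=float), spy)
    f_annual = forcing.f.reindex(years)[names].to_numpy(dtype=float)
    f_steps = np.repeat(f_annual, spy, axis=0)

    b0 = (
        sol.biomass.astype(float).copy()
        if start_biomass is None
        else np.asarray(start_biomass, dtype=float).copy()
    )

    bio, cat, b_final, trel_final, bad_step = _kernel.simulate(
        b0,
        arena.a,
        arena.v,
        arena.m,
        np.where(np.isinf(arena.d), 0.0, 1.0 / arena.d),
        sol.g,
        m0,
        is_producer,
        is_detritus,
        r_prod,
        cap,
        unassim,
        det_share,
        det_export,
        env,
        ppm,
        f_steps,
        spy,
        len(years),
        options.feeding_alpha,
        options.trel_min,
        options.trel_max,
        qb,
        stanza_juv,
        stanza_adult,
        stanza_rate,
        stanza_comp,
        options.literal_prey_pool,
    )
    if bad_step >= 0:
        t_bad = years[0] + bad_step / spy
        raise FloatingPointError(
            f"simulation state became non-finite at t = {t_bad:.3f}"
        )
    idx = pd.Index(years, name="year")
    return Trajectory(
        biomass=pd.DataFrame(bio, index=idx, columns=names),
        catch=pd.DataFrame(cat, index=idx, columns=names),
        final_biomass=b_final,
        final_t_rel=trel_final,
    )


def step(
    state: SimState,
    arena: ArenaParameters,
    sol: EcopathSolution,
    f: np.ndarray,
    dt: float,
    env: Optional[np.ndarray] = None,
    pp_multiplier: float = 1.0,
    options: Optional[SimOptions] = None,
) -> SimState:
    """Advance the state by one RK4 step of length ``dt`` (years).

    Thin single-step wrapper around the compiled right-hand side; ``env`` is
    the per-group environmental scale for this step (default all ones).
    """
    options = options or SimOptions()
    model = sol.model
    n = model.n_groups
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not np.all(np.isfinite(state.biomass)):
        raise FloatingPointError(f"non-finite state at t = {state.time}")
    env_row = np.ones(n) if env is None else np.asarray(env, dtype=float)
    f = np.asarray(f, dtype=float)
    (
        is_producer,
        is_detritus,
        qb,
        r_prod,
        cap,
        unassim,
        det_share,
        det_export,
        m0,
        stanza_juv,
        stanza_adult,
        stanza_rate,
        stanza_comp,
    ) = _structural_arrays(sol, options)
    dinv = np.where(np.isinf(arena.d), 0.0, 1.0 / arena.d)
    q_buf = np.empty((n, n))

    def rhs(b):
        return _kernel._rhs(
            b, state.t_rel, arena.a, arena.v, arena.m, dinv, sol.g, m0,
            is_producer, is_detritus, r_prod, cap, unassim, det_share,
            det_export, env_row, pp_multiplier, f, stanza_juv, stanza_adult,
            stanza_rate, stanza_comp, options.literal_prey_pool, q_buf,
        )

    b = state.biomass
    k1 = rhs(b)
    k2 = rhs(b + 0.5 * dt * k1)
    k3 = rhs(b + 0.5 * dt * k2)
    k4 = rhs(b + dt * k3)
    b_new = np.maximum(b + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
    return SimState(biomass=b_new, t_rel=state.t_rel.copy(), time=state.time + dt)
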