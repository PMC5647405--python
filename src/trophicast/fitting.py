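"""Fitting the dynamic model to observed time series.

The objective is the weighted sum of squared log-residuals between predicted
and observed biomass/catch series.  Free parameters are per-predator
vulnerabilities (one value shared by all prey links of a predator, mapped to
(1, inf) via v = 1 + exp(theta)) and the values of a primary-production
anomaly spline with knots evenly spaced over the fit window (positive via
exp(theta)).  A stepwise search over configurations — which predators'
vulnerabilities to estimate, how many spline knots — is ranked by AIC, with
Akaike weights expressing relative support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize

from .dynamics import (
    ForcingSet,
    SimOptions,
    Trajectory,
    calibrate_arena,
    run,
    vulnerability_matrix,
)
from .foodweb import EcopathSolution
from .thermal import ThermalNiche

__all__ = [
    "ObservedSeries",
    "TimeSeriesSet",
    "SplineAnomaly",
    "FitResult",
    "FitReport",
    "sum_of_squares",
    "information_criteria",
    "akaike_weights",
    "stepwise_fit",
]


@dataclass
class ObservedSeries:
    """One observed series: a group's biomass or catch by year."""

    group: str
    kind: str  # "biomass" | "catch"
    values: pd.Series  # year -> value, strictly positive
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in ("biomass", "catch"):
            raise ValueError(f"kind must be biomass or catch, got {self.kind!r}")
        if self.weight < 0:
            raise ValueError("series weight must be >= 0")
        self.values = self.values.astype(float).dropna()
        if self.weight > 0 and np.any(self.values.to_numpy() <= 0):
            raise ValueError(
                f"series ({self.group}, {self.kind}): values must be positive "
                "for log residuals"
            )

    @property
    def label(self) -> str:
        return f"{self.group}/{self.kind}"


@dataclass
class TimeSeriesSet:
    """Collection of observed series used in one fit."""

    series: list[ObservedSeries]

    def __iter__(self):
        return iter(self.series)

    def __len__(self):
        return len(self.series)

    def active(self) -> list[ObservedSeries]:
        return [s for s in self.series if s.weight > 0]

    def n_observations(self, years: Optional[Sequence[int]] = None) -> int:
        total = 0
        for s in self.active():
            vals = s.values
            if years is not None:
                vals = vals[vals.index.isin(list(years))]
            total += len(vals)
        return total

    def years(self) -> np.ndarray:
        ys: set[int] = set()
        for s in self.series:
            ys.update(int(y) for y in s.values.index)
        return np.array(sorted(ys))

    def restrict(self, years: Sequence[int]) -> "TimeSeriesSet":
        keep = set(int(y) for y in years)
        out = []
        for s in self.series:
            vals = s.values[s.values.index.isin(keep)]
            if len(vals):
                out.append(ObservedSeries(s.group, s.kind, vals, s.weight))
        return TimeSeriesSet(out)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.series:
            for year, val in s.values.items():
                rows.append((s.group, s.kind, int(year), val, s.weight))
        return pd.DataFrame(rows, columns=["group", "kind", "year", "value", "weight"])


@dataclass
class SplineAnomaly:
    """Positive production multiplier interpolated through evenly spaced knots.

    Monotone-safe cubic (PCHIP) interpolation in log space guarantees a
    positive multiplier without overshoot; zero knots means no anomaly.
    """

    knot_years: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.knot_years = np.asarray(self.knot_years, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.knot_years.shape != self.values.shape:
            raise ValueError("knot_years and values must have the same length")
        if np.any(self.values <= 0):
            raise ValueError("anomaly knot values must be positive")

    @classmethod
    def from_count(
        cls, n_points: int, year_start: int, year_end: int, values=None
    ) -> "SplineAnomaly":
        """Knots evenly spaced over [year_start, year_end] inclusive."""
        if n_points == 0:
            return cls(np.empty(0), np.empty(0))
        if n_points == 1:
            knots = np.array([(year_start + year_end) / 2.0])
        else:
            knots = np.linspace(year_start, year_end, n_points)
        vals = np.ones(n_points) if values is None else np.asarray(values, float)
        return cls(knots, vals)

    @property
    def n_points(self) -> int:
        return len(self.knot_years)

    def multiplier(self, years: Sequence[int]) -> pd.Series:
        years = np.asarray(list(years), dtype=int)
        if self.n_points == 0:
            return pd.Series(1.0, index=years)
        if self.n_points == 1:
            return pd.Series(float(self.values[0]), index=years)
        interp = PchipInterpolator(self.knot_years, np.log(self.values))
        t = np.clip(years, self.knot_years[0], self.knot_years[-1])
        return pd.Series(np.exp(interp(t)), index=years)


def sum_of_squares(predicted: Trajectory, observed: TimeSeriesSet) -> float:
    """Weighted sum of squared natural-log residuals.

    Zero-weight series are excluded; each remaining series must overlap the
    prediction and both sides must be positive over the overlap.
    """
    total = 0.0
    for s in observed.active():
        table = predicted.biomass if s.kind == "biomass" else predicted.catch
        if s.group not in table.columns:
            raise KeyError(f"series {s.label}: group not simulated")
        pred = table[s.group]
        common = s.values.index.intersection(pred.index)
        if len(common) == 0:
            raise ValueError(f"series {s.label}: no overlapping years")
        o = s.values.loc[common].to_numpy()
        p = pred.loc[common].to_numpy()
        if np.any(o <= 0) or np.any(p <= 0):
            raise ValueError(f"series {s.label}: non-positive value in overlap")
        total += s.weight * float(np.sum((np.log(o) - np.log(p)) ** 2))
    return total


def information_criteria(ss: float, n_obs: int, k_params: int) -> tuple[float, float]:
    """AIC and small-sample AICc from a least-squares fit.

    AIC = n ln(SS/n) + 2k; AICc adds the 2k(k+1)/(n-k-1) correction (NaN when
    n <= k + 1).
    """
    if ss <= 0:
        raise ValueError("SS must be positive (perfect fit is degenerate)")
    if n_obs <= 0:
        raise ValueError("need at least one observation")
    aic = n_obs * math.log(ss / n_obs) + 2 * k_params
    if n_obs > k_params + 1:
        aicc = aic + 2 * k_params * (k_params + 1) / (n_obs - k_params - 1)
    else:
        aicc = math.nan
    return aic, aicc


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Relative likelihoods exp(-ΔAIC/2), normalised to sum to one."""
    arr = np.asarray(list(aics), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one AIC value")
    if not np.all(np.isfinite(arr)):
        raise ValueError("AIC values must be finite")
    delta = arr - arr.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


@dataclass
class FitResult:
    """One fitted configuration of the stepwise search."""

    name: str
    ss: float
    n_obs: int
    n_vulnerabilities: int
    n_spline_points: int
    aic: float
    aicc: float
    vulnerabilities: dict[str, float] = field(default_factory=dict)
    anomaly: Optional[SplineAnomaly] = None
    akaike_weight: float = math.nan
    converged: bool = True
    uses_fishing: bool = True

    @property
    def k_params(self) -> int:
        return self.n_vulnerabilities + self.n_spline_points


@dataclass
class FitReport:
    """Ranked collection of fitted configurations."""

    results: list[FitResult]
    ss_baseline: float

    def __post_init__(self):
        self.results.sort(key=lambda r: r.aic)
        w = akaike_weights([r.aic for r in self.results])
        for r, wi in zip(self.results, w):
            r.akaike_weight = float(wi)

    @property
    def best(self) -> FitResult:
        return self.results[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            red = (
                (self.ss_baseline - r.ss) / self.ss_baseline
                if self.ss_baseline > 0
                else math.nan
            )
            rows.append(
                (
                    r.name,
                    r.k_params,
                    r.ss,
                    100.0 * red,
                    r.aic,
                    r.aicc,
                    r.akaike_weight,
                    r.converged,
                )
            )
        return pd.DataFrame(
            rows,
            columns=[
                "name",
                "parameters",
                "ss",
                "ss_reduction_pct",
                "aic",
                "aicc",
                "akaike_weight",
                "converged",
            ],
        )


class _FitEngine:
    """Shared state for repeated simulate-and-score evaluations.

    Pre-flattens everything that does not depend on the fitted parameters
    (environmental responses, fishing forcing, observation indices) and calls
    the compiled integrator directly, so one objective evaluation costs only
    a re-calibration plus one simulation.
    """

    def __init__(
        self,
        sol: EcopathSolution,
        observed: TimeSeriesSet,
        years: np.ndarray,
        temperature: Optional[pd.Series],
        f_observed: Optional[pd.DataFrame],
        niches: Optional[Mapping[str, ThermalNiche]],
        options: SimOptions,
    ):
        from . import _kernel
        from .dynamics import _env_matrix, _structural_arrays

        self.sol = sol
        self.observed = observed
        self.years = years
        self.options = options
        self.n_obs = observed.n_observations(years)
        self._kernel = _kernel

        spy = options.steps_per_year
        self.spy = spy
        self.n_years = len(years)
        (
            self.is_producer,
            self.is_detritus,
            self.qb,
            self.r_prod,
            self.cap,
            self.unassim,
            self.det_share,
            self.det_export,
            self.m0,
            self.stanza_juv,
            self.stanza_adult,
            self.stanza_rate,
            self.stanza_comp,
        ) = _structural_arrays(sol, options)

        forcing_probe = ForcingSet.build(sol, years, temperature=temperature)
        self.env = _env_matrix(sol.model, forcing_probe, years, niches, options, spy)
        names = sol.names
        f_base = pd.DataFrame(
            np.tile(sol.f0, (len(years), 1)), index=years, columns=names
        )
        self.f_baseline = np.repeat(f_base.to_numpy(dtype=float), spy, axis=0)
        if f_observed is not None:
            fobs = ForcingSet.build(sol, years, f=f_observed).f
            self.f_observed = np.repeat(
                fobs[names].to_numpy(dtype=float), spy, axis=0
            )
        else:
            self.f_observed = self.f_baseline

        # observation index structures for array-level scoring
        self._obs_idx = []
        year_pos = {int(y): k for k, y in enumerate(years)}
        for s in observed.active():
            col = sol.model.index(s.group)
            mask = [int(y) in year_pos for y in s.values.index]
            if not any(mask):
                raise ValueError(f"series {s.label}: no overlapping years")
            rows = np.array(
                [year_pos[int(y)] for y, m in zip(s.values.index, mask) if m]
            )
            logobs = np.log(s.values.to_numpy()[np.asarray(mask)])
            self._obs_idx.append((s.kind, col, rows, logobs, s.weight))

    def evaluate(
        self,
        v_by_pred: Mapping[str, float],
        anomaly: Optional[SplineAnomaly],
        use_fishing: bool,
    ) -> float:
        arena = calibrate_arena(
            self.sol,
            vulnerability_matrix(self.sol.model, by_predator=dict(v_by_pred)),
            literal_prey_pool=self.options.literal_prey_pool,
        )
        if anomaly is None:
            ppm = np.ones(self.n_years * self.spy)
        else:
            ppm = np.repeat(anomaly.multiplier(self.years).to_numpy(), self.spy)
        f = self.f_observed if use_fishing else self.f_baseline
        bio, cat, _, _, bad = self._kernel.simulate(
            self.sol.biomass.copy(),
            arena.a,
            arena.v,
            arena.m,
            np.where(np.isinf(arena.d), 0.0, 1.0 / arena.d),
            self.sol.g,
            self.m0,
            self.is_producer,
            self.is_detritus,
            self.r_prod,
            self.cap,
            self.unassim,
            self.det_share,
            self.det_export,
            self.env,
            ppm,
            f,
            self.spy,
            self.n_years,
            self.options.feeding_alpha,
            self.options.trel_min,
            self.options.trel_max,
            self.qb,
            self.stanza_juv,
            self.stanza_adult,
            self.stanza_rate,
            self.stanza_comp,
            self.options.literal_prey_pool,
        )
        if bad >= 0:
            return 1e12
        total = 0.0
        for kind, col, rows, logobs, w in self._obs_idx:
            pred = (bio if kind == "biomass" else cat)[rows, col]
            if np.any(pred <= 0):
                return 1e12
            total += w * float(np.sum((logobs - np.log(pred)) ** 2))
        return total


def _optimize_config(
    engine: _FitEngine,
    predators: Sequence[str],
    n_spline: int,
    rng: np.random.Generator,
    n_restarts: int,
    fatol: float,
    maxiter: Optional[int],
    warm_start: Optional[np.ndarray] = None,
    fixed_anomaly_theta: Optional[np.ndarray] = None,
) -> tuple[float, dict[str, float], Optional[SplineAnomaly], bool, np.ndarray]:
    """Minimise SS over log-transformed parameters of one configuration.

    Vulnerability multipliers are 1 + exp(theta) (domain (1, inf), start at
    the neutral 2); spline knot values exp(theta) (start 1).  Derivative-free
    Nelder-Mead with seeded restarts; ``warm_start`` adds an informed start.
    ``fixed_anomaly_theta`` freezes the anomaly at given knot values so only
    vulnerabilities are searched (used by the greedy predator scoring).
    """
    years = engine.years
    n_v = len(predators)
    free_spline = n_spline if fixed_anomaly_theta is None else 0
    dim = n_v + free_spline

    def unpack(theta):
        v = {p: 1.0 + math.exp(th) for p, th in zip(predators, theta[:n_v])}
        anomaly = None
        if n_spline:
            sp_theta = (
                theta[n_v:] if fixed_anomaly_theta is None else fixed_anomaly_theta
            )
            anomaly = SplineAnomaly.from_count(
                n_spline, int(years[0]), int(years[-1]), values=np.exp(sp_theta)
            )
        return v, anomaly

    def objective(theta):
        if np.any(np.abs(theta) > 12):  # keep exp() in a sane range
            return 1e12
        v, anomaly = unpack(theta)
        try:
            return engine.evaluate(v, anomaly, use_fishing=True)
        except (FloatingPointError, ValueError):
            return 1e12

    if dim == 0:
        v, anomaly = unpack(np.empty(0))
        ss = engine.evaluate(v, anomaly, use_fishing=True)
        return ss, v, anomaly, True, np.empty(0)

    starts = [np.zeros(dim)]  # neutral: v = 2, multiplier = 1
    if warm_start is not None:
        starts.insert(0, np.asarray(warm_start, dtype=float))
    for _ in range(max(n_restarts - 1, 0)):
        starts.append(rng.normal(scale=0.8, size=dim))
    best = None
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "fatol": fatol,
                "xatol": 1e-6,
                "maxiter": maxiter or 300 * dim,
                "maxfev": maxiter or 300 * dim,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
    v, anomaly = unpack(best.x)
    return float(best.fun), v, anomaly, bool(best.success), best.x


def stepwise_fit(
    sol: EcopathSolution,
    observed: TimeSeriesSet,
    years: Sequence[int],
    max_v: int = 3,
    max_spline: int = 3,
    spline_counts: Optional[Sequence[int]] = None,
    temperature: Optional[pd.Series] = None,
    f_observed: Optional[pd.DataFrame] = None,
    niches: Optional[Mapping[str, ThermalNiche]] = None,
    options: Optional[SimOptions] = None,
    seed: int = 0,
    n_restarts: int = 3,
    fatol: float = 1e-8,
    maxiter: Optional[int] = None,
    exhaustive: bool = False,
) -> FitReport:
    """Stepwise search over vulnerability/anomaly configurations.

    Predators whose vulnerability to estimate are chosen greedily by the SS
    reduction each achieves alone (``exhaustive=True`` scores every predator
    subset instead, practical only for small webs); spline-point counts are
    crossed with the nested predator sets.  Every configuration is retained
    — non-convergent ones flagged, not dropped — and ranked by AIC alongside
    the no-driver baseline and fishing-only rows.
    """
    options = options or SimOptions()
    years = np.asarray(list(years), dtype=int)
    rng = np.random.default_rng(seed)
    engine = _FitEngine(sol, observed, years, temperature, f_observed, niches, options)
    n_obs = engine.n_obs
    if n_obs == 0:
        raise ValueError("no observations in the fit window")
    if spline_counts is None:
        spline_counts = list(range(0, max_spline + 1))
    spline_counts = sorted(set(int(c) for c in spline_counts))

    results: list[FitResult] = []

    def add(name, ss, v, anomaly, converged, uses_fishing=True):
        n_vv = len(v)
        n_sp = 0 if anomaly is None else anomaly.n_points
        ss_safe = max(ss, 1e-300)
        aic, aicc = information_criteria(ss_safe, n_obs, n_vv + n_sp)
        results.append(
            FitResult(
                name=name, ss=ss, n_obs=n_obs, n_vulnerabilities=n_vv,
                n_spline_points=n_sp, aic=aic, aicc=aicc,
                vulnerabilities=dict(v), anomaly=anomaly, converged=converged,
                uses_fishing=uses_fishing,
            )
        )

    ss_baseline = engine.evaluate({}, None, use_fishing=False)
    add("baseline", ss_baseline, {}, None, True, uses_fishing=False)
    ss_fishing = engine.evaluate({}, None, use_fishing=True)
    add("fishing", ss_fishing, {}, None, True)

    # anomaly-only rows; the largest fitted count also conditions the greedy
    # predator scoring below, so confounding between the production anomaly
    # and trophic-control signals does not corrupt the ordering
    anomaly_theta: dict[int, np.ndarray] = {}
    for n_sp in spline_counts:
        if n_sp == 0:
            continue
        ss, v, anom, conv, theta = _optimize_config(
            engine, [], n_sp, rng, n_restarts, fatol, maxiter
        )
        add(f"fishing + {n_sp} PP_anomaly", ss, v, anom, conv)
        anomaly_theta[n_sp] = theta

    cond_n_sp = max(anomaly_theta) if anomaly_theta else 0
    cond_theta = anomaly_theta.get(cond_n_sp)

    # greedy predator ordering by single-predator SS reduction
    candidates = [g.name for g in sol.model.groups if g.is_consumer]
    scores = []
    v_theta: dict[str, float] = {}
    for name in candidates:
        ss, v, _, _, theta = _optimize_config(
            engine, [name], cond_n_sp, rng, n_restarts=1, fatol=1e-4,
            maxiter=80, fixed_anomaly_theta=cond_theta,
        )
        scores.append((ss, name))
        v_theta[name] = float(theta[0])
    scores.sort()
    ordered = [name for _, name in scores]

    if exhaustive:
        if len(candidates) > 8:
            raise ValueError("exhaustive mode limited to <= 8 predators")
        from itertools import combinations

        subsets = [
            list(c)
            for size in range(1, max_v + 1)
            for c in combinations(ordered, size)
        ]
    else:
        subsets = [ordered[:k] for k in range(1, min(max_v, len(ordered)) + 1)]

    for preds in subsets:
        for n_sp in spline_counts:
            label = f"fishing + {len(preds)} Vs"
            if n_sp:
                label += f" + {n_sp} PP_anomaly"
            warm = np.concatenate(
                [
                    np.array([v_theta.get(p, 0.0) for p in preds]),
                    anomaly_theta.get(n_sp, np.zeros(n_sp)),
                ]
            )
            ss, v, anom, conv, _ = _optimize_config(
                engine, preds, n_sp, rng, n_restarts, fatol, maxiter,
                warm_start=warm,
            )
            add(label, ss, v, anom, conv)

    return FitReport(results=results, ss_baseline=ss_baseline)
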