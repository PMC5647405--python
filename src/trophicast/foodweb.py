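"""Food-web model definition and the static mass-balance baseline.

A food web is a set of functional groups (producers, consumers, detritus)
linked by a diet-composition matrix.  The baseline solver enforces, for each
living group *i*, the master balance

    B_i * (P/B)_i * EE_i = sum_j B_j * (Q/B)_j * DC_ij + Y_i

where the right-hand side is predation on *i* plus fisheries catch Y_i.
Exactly one of {biomass, ecotrophic efficiency} may be unknown per group;
unknown biomasses are obtained by linear elimination and unknown EEs by
direct evaluation.  Biomass accumulation and net migration are fixed at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "Group",
    "FoodWebModel",
    "EcopathSolution",
    "BalanceError",
    "balance_model",
    "mortality_budget",
]

_EPS_DIET = 1e-9
_EPS_BALANCE = 1e-8


class BalanceError(ValueError):
    """Raised when the mass-balance system cannot be solved."""


@dataclass
class Group:
    """One functional group of the web.

    Parameters use the field's conventional units: biomass in t·km⁻²,
    P/B and Q/B in yr⁻¹, catch in t·km⁻²·yr⁻¹.  ``biomass`` or ``ee`` may be
    None (at most one), in which case the balance solver estimates it.
    """

    name: str
    is_producer: bool = False
    is_detritus: bool = False
    biomass: Optional[float] = None
    pb: float = 0.0
    qb: float = 0.0
    ee: Optional[float] = None
    catch: float = 0.0
    stanza_partner: Optional[str] = None  # adult pool fed by this juvenile

    def __post_init__(self) -> None:
        if self.is_producer and self.is_detritus:
            raise ValueError(f"group {self.name!r} cannot be both producer and detritus")
        if (self.is_producer or self.is_detritus) and self.qb != 0:
            raise ValueError(f"group {self.name!r}: producers/detritus must have qb = 0")
        if self.catch < 0:
            raise ValueError(f"group {self.name!r}: catch must be >= 0")
        if not self.is_detritus and self.pb <= 0:
            raise ValueError(f"group {self.name!r}: living groups need pb > 0")
        if self.biomass is None and self.ee is None:
            raise BalanceError(
                f"group {self.name!r}: at most one of biomass/ee may be missing"
            )

    @property
    def is_living(self) -> bool:
        return not self.is_detritus

    @property
    def is_consumer(self) -> bool:
        return not (self.is_producer or self.is_detritus)


@dataclass
class FoodWebModel:
    """Static web definition: groups plus a prey-by-predator diet matrix.

    ``diet[i, j]`` is the fraction of predator *j*'s diet made of prey *i*.
    Consumer columns must sum to one; producer/detritus columns are zero.
    """

    groups: list[Group]
    diet: np.ndarray
    assimilation: float = 0.8  # assimilated fraction of consumption
    maturation_rate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.groups)
        self.diet = np.asarray(self.diet, dtype=float)
        if self.diet.shape != (n, n):
            raise ValueError(f"diet matrix must be {n}x{n}, got {self.diet.shape}")
        if np.any(self.diet < 0):
            raise ValueError("diet fractions must be non-negative")
        names = [g.name for g in self.groups]
        if len(set(names)) != n:
            raise ValueError("group names must be unique")
        for j, g in enumerate(self.groups):
            col = self.diet[:, j].sum()
            if g.is_consumer:
                if abs(col - 1.0) > _EPS_DIET:
                    raise ValueError(
                        f"diet column of consumer {g.name!r} sums to {col}, expected 1"
                    )
            elif col > _EPS_DIET:
                raise ValueError(f"non-consumer {g.name!r} has a non-zero diet column")
        for g in self.groups:
            if g.stanza_partner is not None and g.stanza_partner not in names:
                raise ValueError(
                    f"stanza partner {g.stanza_partner!r} of {g.name!r} not in model"
                )

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no group named {name!r}") from None

    def living_mask(self) -> np.ndarray:
        return np.array([g.is_living for g in self.groups])

    def with_inputs(
        self,
        biomass: Optional[np.ndarray] = None,
        pb: Optional[np.ndarray] = None,
        qb: Optional[np.ndarray] = None,
        ee: Optional[np.ndarray] = None,
    ) -> "FoodWebModel":
        """Copy of the model with perturbed basic inputs (Monte Carlo support).

        Only values that were provided in the original model are replaced;
        estimated (None) slots remain estimated.
        """
        new_groups = []
        for k, g in enumerate(self.groups):
            kw = {}
            if biomass is not None and g.biomass is not None:
                kw["biomass"] = float(biomass[k])
            if pb is not None and g.is_living:
                kw["pb"] = float(pb[k])
            if qb is not None and g.is_consumer:
                kw["qb"] = float(qb[k])
            if ee is not None and g.ee is not None:
                kw["ee"] = float(np.clip(ee[k], 0.0, 1.0))
            new_groups.append(replace(g, **kw) if kw else replace(g))
        return FoodWebModel(
            groups=new_groups,
            diet=self.diet.copy(),
            assimilation=self.assimilation,
            maturation_rate=dict(self.maturation_rate),
        )


@dataclass
class EcopathSolution:
    """Balanced baseline state of the web.

    ``q0[i, j]`` is baseline consumption of prey *i* by predator *j*
    (t·km⁻²·yr⁻¹); ``m0`` is non-predation, non-fishing mortality (yr⁻¹);
    ``g`` is gross food-conversion efficiency P/Q; ``f0`` the baseline
    fishing mortality Y/B.
    """

    model: FoodWebModel
    biomass: np.ndarray
    ee: np.ndarray
    q0: np.ndarray
    m0: np.ndarray
    g: np.ndarray
    f0: np.ndarray
    balanced: bool

    @property
    def names(self) -> list[str]:
        return self.model.names

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "biomass": self.biomass,
                "ee": self.ee,
                "other_mortality": self.m0,
                "baseline_f": self.f0,
                "gross_efficiency": self.g,
            },
            index=pd.Index(self.names, name="group"),
        )

    def residuals(self) -> np.ndarray:
        """Master-equation residual per living group (zero for detritus)."""
        model = self.model
        res = np.zeros(model.n_groups)
        predation = self.q0.sum(axis=1)
        for i, grp in enumerate(model.groups):
            if grp.is_living:
                res[i] = (
                    self.biomass[i] * grp.pb * self.ee[i]
                    - predation[i]
                    - grp.catch
                )
        return res


def balance_model(model: FoodWebModel) -> EcopathSolution:
    """Solve the static mass balance of the web.

    Unknown biomasses are solved by linear elimination over the master
    equations of groups whose EE is given; unknown EEs are then evaluated
    directly.  A solution with any living EE outside [0, 1] is returned
    flagged ``balanced=False`` rather than raised, so that diagnostics can
    be reported; a negative solved biomass or a singular system is an error.
    """
    n = model.n_groups
    groups = model.groups
    b = np.array(
        [np.nan if g.biomass is None else g.biomass for g in groups], dtype=float
    )
    qb = np.array([g.qb for g in groups], dtype=float)
    pb = np.array([g.pb for g in groups], dtype=float)
    catch = np.array([g.catch for g in groups])
    dc = model.diet

    unknown_b = [i for i, g in enumerate(groups) if g.biomass is None]
    if unknown_b:
        for i in unknown_b:
            if groups[i].ee is None:
                raise BalanceError(
                    f"group {groups[i].name!r}: both biomass and ee unknown"
                )
            if groups[i].is_detritus:
                raise BalanceError(
                    f"detritus group {groups[i].name!r} needs an explicit biomass"
                )
        # Linear system over the unknown biomasses x:
        #   x_i*pb_i*ee_i - sum_{j unknown} x_j*qb_j*dc_ij = Y_i + sum_{j known} b_j*qb_j*dc_ij
        idx = {i: k for k, i in enumerate(unknown_b)}
        m = len(unknown_b)
        A = np.zeros((m, m))
        rhs = np.zeros(m)
        for i in unknown_b:
            k = idx[i]
            A[k, k] += pb[i] * groups[i].ee
            rhs[k] = catch[i]
            for j in range(n):
                if qb[j] == 0 or dc[i, j] == 0:
                    continue
                if j in idx:
                    A[k, idx[j]] -= qb[j] * dc[i, j]
                else:
                    rhs[k] += b[j] * qb[j] * dc[i, j]
        try:
            x = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError:
            names = [groups[i].name for i in unknown_b]
            raise BalanceError(
                "singular mass-balance system over unknown biomasses of groups "
                f"{names}: circular unknowns"
            ) from None
        bad = [groups[i].name for i, xi in zip(unknown_b, x) if xi <= 0]
        if bad:
            raise BalanceError(f"solved biomass non-positive for groups {bad}")
        for i, xi in zip(unknown_b, x):
            b[i] = xi

    if np.any(~np.isfinite(b)):
        missing = [g.name for g, bi in zip(groups, b) if not np.isfinite(bi)]
        raise BalanceError(f"biomass undetermined for groups {missing}")

    # Baseline consumption matrix and EE evaluation.
    q0 = dc * (b * qb)[None, :]
    predation = q0.sum(axis=1)
    ee = np.zeros(n)
    for i, grp in enumerate(groups):
        if grp.is_living:
            if grp.biomass is None:
                ee[i] = grp.ee  # EE was the input that let us solve B
            else:
                # EE evaluated from the master equation (any supplied value is
                # a prior estimate; the balance defines the realised one).
                ee[i] = (predation[i] + catch[i]) / (b[i] * pb[i])
        else:
            # Detritus EE: consumed fraction of the inflow (diagnostic only).
            inflow = _detritus_inflow(model, b, qb, pb, q0)
            ee[i] = predation[i] / inflow if inflow > 0 else 0.0

    living = model.living_mask()
    balanced = bool(np.all((ee[living] >= -1e-12) & (ee[living] <= 1.0 + 1e-12)))
    m0 = np.where(living, pb * (1.0 - ee), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(qb > 0, pb / qb, 0.0)
    f0 = catch / b
    return EcopathSolution(
        model=model, biomass=b, ee=ee, q0=q0, m0=m0, g=g, f0=f0, balanced=balanced
    )


def _detritus_inflow(model, b, qb, pb, q0) -> float:
    """Total flow into detritus: unassimilated consumption + other-mortality."""
    unassim = 0.0
    for j, grp in enumerate(model.groups):
        if grp.is_consumer:
            unassim += (1.0 - model.assimilation) * b[j] * qb[j]
    other = 0.0
    for i, grp in enumerate(model.groups):
        if grp.is_living:
            predation = q0[i, :].sum()
            other += b[i] * pb[i] - predation - grp.catch  # = m0_i * b_i at balance
    return unassim + max(other, 0.0)


def mortality_budget(sol: EcopathSolution) -> pd.DataFrame:
    """Decompose total mortality (= P/B) of each living group.

    Columns: predation (yr⁻¹), fishing (yr⁻¹), other (yr⁻¹); the three sum
    to P/B for every living group of a balanced web.
    """
    model = sol.model
    if np.any(sol.biomass <= 0):
        bad = [n for n, b in zip(sol.names, sol.biomass) if b <= 0]
        raise ValueError(f"zero/negative biomass for groups {bad}")
    rows = []
    for i, grp in enumerate(model.groups):
        if not grp.is_living:
            continue
        pred = sol.q0[i, :].sum() / sol.biomass[i]
        fishing = grp.catch / sol.biomass[i]
        rows.append((grp.name, pred, fishing, sol.m0[i]))
    return pd.DataFrame(
        rows, columns=["group", "predation", "fishing", "other"]
    ).set_index("group")
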