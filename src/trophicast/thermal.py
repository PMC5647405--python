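"""Species thermal response functions.

Each group's sensitivity to water temperature is a two-sided Gaussian niche
centred on its optimum temperature: the consumption (or production) scaling
factor is exactly 1 at the optimum and decays as exp(-(T - t_opt)^2 / 2 sigma^2)
with separate standard deviations below and above the optimum, so that
asymmetric tolerance envelopes (t_min .. t_opt .. t_max) are honoured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ThermalNiche",
    "build_niche",
    "aggregate_niches",
    "juvenile_offset",
    "plankton_niche",
]

#: envelope edges sit this many standard deviations from the optimum
DEFAULT_K_SIGMA = 2.0
#: floor (°C) for a degenerate zero-width niche side
SIGMA_FLOOR = 0.5


@dataclass(frozen=True)
class ThermalNiche:
    """Asymmetric Gaussian thermal niche of one group.

    ``sigma_lower`` applies below the optimum, ``sigma_upper`` at or above it.
    ``t_min``/``t_max`` and the 10th/90th preference percentiles are retained
    so niches can be aggregated or shifted without losing the envelope.
    """

    t_opt: float
    sigma_lower: float
    sigma_upper: float
    t_min: Optional[float] = None
    t_max: Optional[float] = None
    p10: Optional[float] = None
    p90: Optional[float] = None
    symmetric: bool = False

    def __post_init__(self):
        if self.sigma_lower <= 0 or self.sigma_upper <= 0:
            raise ValueError("niche standard deviations must be > 0")
        if self.t_min is not None and self.t_min > self.t_opt + 1e-12:
            raise ValueError("t_min must not exceed t_opt")
        if self.t_max is not None and self.t_max < self.t_opt - 1e-12:
            raise ValueError("t_max must not be below t_opt")

    def response(self, temperature):
        """Scaling factor in (0, 1] at the given temperature(s) in °C."""
        t = np.asarray(temperature, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("temperature must be finite")
        if self.symmetric:
            sigma = 0.5 * (self.sigma_lower + self.sigma_upper)
            out = np.exp(-((t - self.t_opt) ** 2) / (2.0 * sigma**2))
        else:
            sigma = np.where(t < self.t_opt, self.sigma_lower, self.sigma_upper)
            out = np.exp(-((t - self.t_opt) ** 2) / (2.0 * sigma**2))
        if np.isscalar(temperature) or np.ndim(temperature) == 0:
            return float(out)
        return out


def response(niche: ThermalNiche, temperature):
    """Functional alias for :meth:`ThermalNiche.response`."""
    return niche.response(temperature)


def build_niche(
    t_min: float,
    p10: float,
    p90: float,
    t_max: float,
    k_sigma: float = DEFAULT_K_SIGMA,
    sigma_floor: float = SIGMA_FLOOR,
) -> ThermalNiche:
    """Construct a niche from an observed tolerance envelope.

    The optimum is the mean of the 10th and 90th preference percentiles; the
    side standard deviations place the envelope edges ``k_sigma`` standard
    deviations from the optimum.  Degenerate (zero-width) sides get the floor.
    """
    if not (t_min <= p10 <= p90 <= t_max):
        raise ValueError(
            f"envelope ordering violated: need t_min <= p10 <= p90 <= t_max, "
            f"got {t_min}, {p10}, {p90}, {t_max}"
        )
    t_opt = 0.5 * (p10 + p90)
    sigma_lower = max((t_opt - t_min) / k_sigma, sigma_floor)
    sigma_upper = max((t_max - t_opt) / k_sigma, sigma_floor)
    return ThermalNiche(
        t_opt=t_opt,
        sigma_lower=sigma_lower,
        sigma_upper=sigma_upper,
        t_min=t_min,
        t_max=t_max,
        p10=p10,
        p90=p90,
    )


def _weighted_geomean(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted geometric mean with a shift to a positive scale if needed."""
    offset = 0.0
    vmin = values.min()
    if vmin <= 0:
        offset = 1.0 - vmin
    shifted = values + offset
    logmean = float(np.sum(weights * np.log(shifted)) / np.sum(weights))
    return math.exp(logmean) - offset


def aggregate_niches(
    niches: Sequence[ThermalNiche],
    weights: Sequence[float],
    k_sigma: float = DEFAULT_K_SIGMA,
) -> ThermalNiche:
    """Aggregate species niches into one functional-group niche.

    Each envelope parameter is the biomass- (or catch-) weighted geometric
    mean of the species values; the optimum and widths are then rebuilt from
    the aggregated envelope.  All input niches must carry a full envelope.
    """
    if len(niches) == 0:
        raise ValueError("need at least one niche")
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(niches),) or np.any(w < 0):
        raise ValueError("weights must be non-negative, one per niche")
    if not np.any(w > 0):
        raise ValueError("at least one weight must be positive")
    keep = w > 0
    if keep.sum() == 1:
        return niches[int(np.argmax(keep))]
    for nch in niches:
        if None in (nch.t_min, nch.t_max, nch.p10, nch.p90):
            raise ValueError("aggregation needs full envelopes (t_min, p10, p90, t_max)")
    sub = [n for n, k in zip(niches, keep) if k]
    wsub = w[keep]
    params = {}
    for name in ("t_min", "p10", "p90", "t_max"):
        vals = np.array([getattr(n, name) for n in sub], dtype=float)
        params[name] = _weighted_geomean(vals, wsub)
    return build_niche(k_sigma=k_sigma, **params)


def juvenile_offset(niche: ThermalNiche, delta: float = 1.0) -> ThermalNiche:
    """Shift the whole envelope by ``delta`` °C (widths unchanged).

    Used for juvenile stages assumed to occupy shallower, warmer water than
    the adults whose envelope was observed; the conventional shift is +1 °C.
    """
    return replace(
        niche,
        t_opt=niche.t_opt + delta,
        t_min=None if niche.t_min is None else niche.t_min + delta,
        t_max=None if niche.t_max is None else niche.t_max + delta,
        p10=None if niche.p10 is None else niche.p10 + delta,
        p90=None if niche.p90 is None else niche.p90 + delta,
    )


def plankton_niche(temperature_series, sigma: float = 10.0) -> ThermalNiche:
    """Wide niche for plankton-type groups without tolerance data.

    The optimum is the mean of the supplied historical temperature series and
    both sides get a wide standard deviation (default 10 °C), so the response
    stays close to 1 across the historical range.
    """
    t = np.asarray(temperature_series, dtype=float)
    if t.size == 0 or not np.all(np.isfinite(t)):
        raise ValueError("need a finite, non-empty temperature series")
    t_opt = float(t.mean())
    return ThermalNiche(
        t_opt=t_opt,
        sigma_lower=sigma,
        sigma_upper=sigma,
        t_min=t_opt - 2 * sigma,
        t_max=t_opt + 2 * sigma,
        p10=t_opt,
        p90=t_opt,
    )
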