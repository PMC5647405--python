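"""JIT-compiled forward integrator for the foraging-arena dynamics.

Plain-array kernel kept free of Python objects so numba can compile it; all
model structure is flattened by :mod:`trophicast.dynamics` before the call.
The integrator is fixed-step classical Runge-Kutta (4th order) with forcing
held constant within each sub-annual step, which keeps runs bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _rhs(
    b,
    trel,
    a,
    v,
    med,
    dinv,
    g,
    m0,
    is_producer,
    is_detritus,
    r_prod,
    cap,
    unassim,
    det_share,
    det_export,
    env_row,
    ppm,
    f_row,
    stanza_juv,
    stanza_adult,
    stanza_rate,
    stanza_comp,
    literal_prey_pool,
    q_buf,
):
    """Time derivative of biomass; fills q_buf with link consumptions."""
    n = b.shape[0]
    # consumption matrix
    for j in range(n):
        if g[j] <= 0.0:  # not a consumer
            for i in range(n):
                q_buf[i, j] = 0.0
            continue
        pj = b[j]
        for i in range(n):
            aij = a[i, j]
            if aij <= 0.0:
                q_buf[i, j] = 0.0
                continue
            pool = b[i] if literal_prey_pool else pj
            num = aij * v[i, j] * b[i] * pj * trel[i] * trel[j] * med[i, j]
            den = (
                v[i, j]
                + v[i, j] * trel[i] * med[i, j]
                + aij * med[i, j] * pool * trel[j] * dinv[j]
            )
            q_buf[i, j] = env_row[j] * num / den

    db = np.zeros(n)
    det_inflow = 0.0
    for j in range(n):
        if is_detritus[j]:
            continue
        if is_producer[j]:
            prod = r_prod[j] * ppm * env_row[j] * b[j] * (1.0 - b[j] / cap[j])
        else:
            qin = 0.0
            for i in range(n):
                qin += q_buf[i, j]
            prod = g[j] * qin
            det_inflow += unassim[j] * qin
        qout = 0.0
        for k in range(n):
            qout += q_buf[j, k]
        db[j] = prod - qout - m0[j] * b[j] - f_row[j] * b[j]
        det_inflow += m0[j] * b[j]

    for j in range(n):
        if is_detritus[j]:
            qout = 0.0
            for k in range(n):
                qout += q_buf[j, k]
            db[j] = det_share[j] * det_inflow - qout - det_export[j] * b[j]

    for p in range(stanza_juv.shape[0]):
        ju = stanza_juv[p]
        ad = stanza_adult[p]
        flow = stanza_rate[p] * b[ju]
        db[ju] -= flow
        db[ad] += flow - stanza_comp[p] * b[ad]
    return db


@njit(cache=True)
def simulate(
    b0,
    a,
    v,
    med,
    dinv,
    g,
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
    f,
    steps_per_year,
    n_years,
    alpha,
    trel_min,
    trel_max,
    qb,
    stanza_juv,
    stanza_adult,
    stanza_rate,
    stanza_comp,
    literal_prey_pool,
):
    """Integrate ``n_years`` at ``steps_per_year`` RK4 steps per year.

    Returns annual-mean biomass, annual accumulated catch, the final state,
    the final relative feeding times, and the index of the first step at
    which the state became non-finite (-1 if the run completed).
    """
    n = b0.shape[0]
    b = b0.copy()
    trel = np.ones(n)
    dt = 1.0 / steps_per_year
    bio = np.zeros((n_years, n))
    cat = np.zeros((n_years, n))
    q_buf = np.empty((n, n))
    for y in range(n_years):
        for s in range(steps_per_year):
            step = y * steps_per_year + s
            env_row = env[step]
            f_row = f[step]
            ppm_s = ppm[step]
            k1 = _rhs(b, trel, a, v, med, dinv, g, m0, is_producer, is_detritus,
                      r_prod, cap, unassim, det_share, det_export, env_row, ppm_s,
                      f_row, stanza_juv, stanza_adult, stanza_rate, stanza_comp,
                      literal_prey_pool, q_buf)
            if alpha > 0.0:
                # first-order relaxation of feeding time toward the effort that
                # restores the baseline per-biomass ration, using stage-1 rates
                for j in range(n):
                    if qb[j] > 0.0 and b[j] > 0.0:
                        qreal = 0.0
                        for i in range(n):
                            qreal += q_buf[i, j]
                        qreal /= b[j]
                        if qreal > 0.0:
                            tnew = trel[j] * (1.0 - alpha + alpha * qb[j] / qreal)
                            trel[j] = min(max(tnew, trel_min), trel_max)
            b2 = b + 0.5 * dt * k1
            k2 = _rhs(b2, trel, a, v, med, dinv, g, m0, is_producer, is_detritus,
                      r_prod, cap, unassim, det_share, det_export, env_row, ppm_s,
                      f_row, stanza_juv, stanza_adult, stanza_rate, stanza_comp,
                      literal_prey_pool, q_buf)
            b3 = b + 0.5 * dt * k2
            k3 = _rhs(b3, trel, a, v, med, dinv, g, m0, is_producer, is_detritus,
                      r_prod, cap, unassim, det_share, det_export, env_row, ppm_s,
                      f_row, stanza_juv, stanza_adult, stanza_rate, stanza_comp,
                      literal_prey_pool, q_buf)
            b4 = b + dt * k3
            k4 = _rhs(b4, trel, a, v, med, dinv, g, m0, is_producer, is_detritus,
                      r_prod, cap, unassim, det_share, det_export, env_row, ppm_s,
                      f_row, stanza_juv, stanza_adult, stanza_rate, stanza_comp,
                      literal_prey_pool, q_buf)
            b_new = b + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            for i in range(n):
                if b_new[i] < 0.0:
                    b_new[i] = 0.0
                cat[y, i] += 0.5 * dt * f_row[i] * (b[i] + b_new[i])
                bio[y, i] += b_new[i] / steps_per_year
            b = b_new
            for i in range(n):
                if not np.isfinite(b[i]):
                    return bio, cat, b, trel, step
    return bio, cat, b, trel, -1
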