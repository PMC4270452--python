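"""Compiled right-hand side for network integration.

The numpy implementation in :mod:`astrofilter.gchi` is the reference; this
module provides a numba-compiled equivalent used by the simulator to keep
per-step callback cost low (the adaptive solver evaluates the RHS tens of
thousands of times per run).  Equivalence of the two paths is asserted in the
test suite.
"""

from __future__ import annotations

import numpy as np

from .params import GChIParams, GJCParams

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


def pack_params(gchi: GChIParams, gjc: GJCParams | None) -> np.ndarray:
    g = gjc if gjc is not None else GJCParams(0.0, 1.0, 1.0)
    return np.array([
        gchi.r_c, gchi.r_l, gchi.v_er, gchi.k_er, gchi.c_tot, gchi.rho_er,
        gchi.d1, gchi.d2, gchi.d3, gchi.d5, gchi.o2,
        gchi.o_beta, gchi.k_r, gchi.k_p, gchi.k_pi, gchi.n_glu,
        gchi.o_delta, gchi.kappa_delta, gchi.k_delta,
        gchi.o_3k, gchi.k_d, gchi.k_3, gchi.omega_5p,
        g.f_gjc, g.i_theta, g.omega_i,
    ], dtype=np.float64)


@njit(cache=True)
def _glut_at(t, spike_times, g_after, omega_c):
    n = spike_times.size
    if n == 0:
        return 0.0
    # find last spike <= t
    lo, hi = 0, n
    while lo < hi:
        mid = (lo + hi) // 2
        if spike_times[mid] <= t:
            lo = mid + 1
        else:
            hi = mid
    k = lo - 1
    if k < 0:
        return 0.0
    return g_after[k] * np.exp(-omega_c * (t - spike_times[k]))


@njit(cache=True)
def rhs_kernel(t, y, stim_mask, spike_times, g_after, omega_c,
               edge_i, edge_j, p):
    n = stim_mask.size
    g_now = _glut_at(t, spike_times, g_after, omega_c)
    (r_c, r_l, v_er, k_er, c_tot, rho_er, d1, d2, d3, d5, o2,
     o_beta, k_r, k_p, k_pi, n_glu, o_delta, kappa_delta, k_delta,
     o_3k, k_d, k_3, omega_5p, f_gjc, i_theta, omega_i) = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9], p[10],
        p[11], p[12], p[13], p[14], p[15], p[16], p[17], p[18],
        p[19], p[20], p[21], p[22], p[23], p[24], p[25])
    dy = np.empty_like(y)
    for i in range(n):
        C = y[i]
        h = y[n + i]
        I = y[2 * n + i]
        er_drive = c_tot - (1.0 + rho_er) * C
        m_inf = I / (I + d1)
        n_inf = C / (C + d5)
        gate = m_inf * n_inf * h
        j_c = r_c * gate * gate * gate * er_drive
        j_l = r_l * er_drive
        j_p = v_er * C * C / (C * C + k_er * k_er)
        q2 = d2 * (I + d1) / (I + d3)
        dh = o2 * (q2 * (1.0 - h) - C * h)
        G = g_now if stim_mask[i] else 0.0
        if G > 0.0:
            k_gamma = k_r * (1.0 + (k_p / k_r) * C / (C + k_pi))
            gn = G ** n_glu
            j_beta = o_beta * gn / (gn + k_gamma ** n_glu)
        else:
            j_beta = 0.0
        j_delta = o_delta / (1.0 + I / kappa_delta) * C * C / (C * C + k_delta * k_delta)
        c4 = C ** 4
        j_3k = o_3k * c4 / (c4 + k_d ** 4) * I / (I + k_3)
        j_5p = omega_5p * I
        dy[i] = j_c + j_l - j_p
        dy[n + i] = dh
        dy[2 * n + i] = j_beta + j_delta - j_3k - j_5p
    tail = np.tanh(i_theta / omega_i)
    for e in range(edge_i.size):
        a = edge_i[e]
        b = edge_j[e]
        delta = y[2 * n + b] - y[2 * n + a]
        mag = 0.5 * f_gjc * (np.tanh((abs(delta) - i_theta) / omega_i) + tail)
        flux = mag if delta > 0 else (-mag if delta < 0 else 0.0)
        dy[2 * n + a] += flux
        dy[2 * n + b] -= flux
    return dy
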