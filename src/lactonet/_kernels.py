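"""Compiled inner loop of the fixed-step integrator.

The RK4 stepper and the model right-hand side are fused into one numba
kernel operating on a (4, n_cells, K) state array (K = batched trials).
The gap-junction current is accumulated edge-wise over voltage
*differences*, so that on the synchronous manifold (all cells equal)
every edge contributes exactly zero and the manifold is invariant to
machine precision.  Falls back to pure numpy when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _rhs(x, out, Ic, ea, eb, p):
    """dx/dt into ``out``; ``p`` is the packed parameter vector.

    Layout of p: [g_Kdr, g_Ca, g_SK, g_BK, g_L, g_c, V_K, V_Ca, V_L,
    v_n, v_m, v_b, l_n, l_m, l_b, inv_tau_n, inv_tau_b, f_c, alpha,
    k_c, k_SK, inv_C_m].
    """
    n = x.shape[1]
    K = x.shape[2]
    (g_Kdr, g_Ca, g_SK, g_BK, g_L, g_c, V_K, V_Ca, V_L,
     v_n, v_m, v_b, l_n, l_m, l_b, inv_tau_n, inv_tau_b,
     f_c, alpha, k_c, k_SK, inv_C_m) = (
        p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8], p[9], p[10],
        p[11], p[12], p[13], p[14], p[15], p[16], p[17], p[18], p[19],
        p[20], p[21])
    for i in range(n):
        for k in range(K):
            Ic[i, k] = 0.0
    for e in range(ea.shape[0]):
        a = ea[e]
        b = eb[e]
        for k in range(K):
            d = x[0, a, k] - x[0, b, k]
            Ic[a, k] += d
            Ic[b, k] -= d
    kSK2 = k_SK * k_SK
    for i in range(n):
        for k in range(K):
            V = x[0, i, k]
            ca = x[1, i, k]
            nn = x[2, i, k]
            bb = x[3, i, k]
            m_inf = 1.0 / (1.0 + np.exp((v_m - V) / l_m))
            n_inf = 1.0 / (1.0 + np.exp((v_n - V) / l_n))
            b_inf = 1.0 / (1.0 + np.exp((v_b - V) / l_b))
            c2 = ca * ca
            s_inf = c2 / (c2 + kSK2)
            dV_K = V - V_K
            I_Ca = g_Ca * m_inf * (V - V_Ca)
            I_sum = ((g_Kdr * nn + g_BK * bb + g_SK * s_inf) * dV_K
                     + I_Ca + g_L * (V - V_L) + g_c * Ic[i, k])
            out[0, i, k] = -I_sum * inv_C_m
            out[1, i, k] = -f_c * (alpha * I_Ca + k_c * ca)
            out[2, i, k] = (n_inf - nn) * inv_tau_n
            out[3, i, k] = (b_inf - bb) * inv_tau_b


@njit(cache=True)
def rk4_run(x, ea, eb, p, dt, n_steps, window_first,
            V_win, c_win, n_win, b_win, store_full,
            stride, trans_V, check_stride):
    """Advance ``x`` in place by ``n_steps`` classical RK4 steps.

    Voltages (and, if ``store_full``, the other variables) are recorded
    every step from ``window_first`` on, and every ``stride`` steps
    before that (if ``stride > 0``).  Returns 0 on success, or the step
    index at which the state was found non-finite (checked every
    ``check_stride`` steps).
    """
    k1 = np.empty_like(x)
    k2 = np.empty_like(x)
    k3 = np.empty_like(x)
    k4 = np.empty_like(x)
    xt = np.empty_like(x)
    n = x.shape[1]
    K = x.shape[2]
    Ic = np.empty((n, K))
    half = dt / 2.0
    sixth = dt / 6.0
    flat_x = x.reshape(-1)
    flat_xt = xt.reshape(-1)
    f1 = k1.reshape(-1)
    f2 = k2.reshape(-1)
    f3 = k3.reshape(-1)
    f4 = k4.reshape(-1)
    m = flat_x.shape[0]
    ti = 0
    for step in range(1, n_steps + 1):
        _rhs(x, k1, Ic, ea, eb, p)
        for q in range(m):
            flat_xt[q] = flat_x[q] + half * f1[q]
        _rhs(xt, k2, Ic, ea, eb, p)
        for q in range(m):
            flat_xt[q] = flat_x[q] + half * f2[q]
        _rhs(xt, k3, Ic, ea, eb, p)
        for q in range(m):
            flat_xt[q] = flat_x[q] + dt * f3[q]
        _rhs(xt, k4, Ic, ea, eb, p)
        for q in range(m):
            flat_x[q] += sixth * (f1[q] + 2.0 * (f2[q] + f3[q]) + f4[q])
        if step >= window_first:
            w = step - window_first
            for i in range(n):
                for k in range(K):
                    V_win[w, i, k] = x[0, i, k]
            if store_full:
                for i in range(n):
                    for k in range(K):
                        c_win[w, i, k] = x[1, i, k]
                        n_win[w, i, k] = x[2, i, k]
                        b_win[w, i, k] = x[3, i, k]
        elif stride > 0 and step % stride == 0:
            for i in range(n):
                for k in range(K):
                    trans_V[ti, i, k] = x[0, i, k]
            ti += 1
        if step % check_stride == 0 or step == n_steps:
            for i in range(n):
                for k in range(K):
                    if not np.isfinite(x[0, i, k]):
                        return step
    return 0


def pack_params(params) -> np.ndarray:
    """Pack a CellParams into the flat vector ``_rhs`` expects."""
    return np.array([
        params.g_Kdr, params.g_Ca, params.g_SK, params.g_BK, params.g_L,
        params.g_c, params.V_K, params.V_Ca, params.V_L,
        params.v_n, params.v_m, params.v_b,
        params.l_n, params.l_m, params.l_b,
        1.0 / params.tau_n, 1.0 / params.tau_b,
        params.f_c, params.alpha, params.k_c, params.k_SK,
        1.0 / params.C_m,
    ])
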