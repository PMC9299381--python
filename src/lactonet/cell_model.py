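"""Right-hand side of the coupled lactotroph network model.

Each cell carries four state variables (V, c, n, b).  The membrane
currents are a delayed-rectifier K+ current, an L-type Ca2+ current with
instantaneous activation m = m_inf(V), BK and SK K+ currents, a leak, and
an ohmic gap-junction coupling current summed over structural neighbors:

    C_m dV/dt = -(I_Kdr + I_Ca + I_BK + I_SK + I_L + I_c)
    tau_n dn/dt = n_inf(V) - n
    dc/dt = -f_c (alpha * I_Ca + k_c * c)
    tau_b db/dt = b_inf(V) - b

A network state is a flat vector of length 4*n ordered as
``[V_0..V_{n-1}, c_0..c_{n-1}, n_0..n_{n-1}, b_0..b_{n-1}]``; a batch of
K states is the (4n, K) array whose columns are independent states.
"""

from __future__ import annotations

import numpy as np

from .network_builder import StructuralNetwork
from .params import CellParams

__all__ = [
    "gating_equilibrium",
    "sk_activation",
    "ionic_currents",
    "coupling_currents",
    "network_rhs",
    "make_network_rhs",
    "pack_state",
    "unpack_state",
]


def gating_equilibrium(V, v_half: float, slope: float):
    """Voltage-dependent equilibrium activation 1 / (1 + exp((v_half - V)/slope)).

    Strictly increasing in V for positive ``slope``, with value 0.5 at
    ``V = v_half``.
    """
    if slope == 0:
        raise ValueError("slope factor must be nonzero")
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite membrane potential")
    with np.errstate(over="ignore"):  # saturates cleanly to 0
        out = 1.0 / (1.0 + np.exp((v_half - V) / slope))
    return float(out) if out.ndim == 0 else out


def sk_activation(c, k_SK: float):
    """Ca2+-dependent SK-channel activation c^2 / (c^2 + k_SK^2)."""
    if k_SK <= 0:
        raise ValueError("k_SK must be positive")
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("calcium concentration must be non-negative")
    c2 = c * c
    out = c2 / (c2 + k_SK * k_SK)
    return float(out) if out.ndim == 0 else out


def ionic_currents(V, c, n, b, params: CellParams):
    """The five membrane currents (pA) of each cell.

    Returns ``(I_Kdr, I_Ca, I_BK, I_SK, I_L)``; inputs may be scalars or
    arrays of a common shape.  m and s are algebraic (quasi-equilibrium).
    """
    p = params
    m_inf = gating_equilibrium(V, p.v_m, p.l_m)
    s_inf = sk_activation(c, p.k_SK)
    dV_K = np.asarray(V, dtype=float) - p.V_K
    I_Kdr = p.g_Kdr * np.asarray(n, float) * dV_K
    I_Ca = p.g_Ca * m_inf * (np.asarray(V, float) - p.V_Ca)
    I_BK = p.g_BK * np.asarray(b, float) * dV_K
    I_SK = p.g_SK * s_inf * dV_K
    I_L = p.g_L * (np.asarray(V, float) - p.V_L)
    return I_Kdr, I_Ca, I_BK, I_SK, I_L


def coupling_currents(voltages, network: StructuralNetwork, g_c: float):
    """Gap-junction current I_c,i = sum_{j in N_i} g_c (V_i - V_j) per cell.

    Accumulated edge-wise over voltage differences, so each edge's two
    contributions cancel antisymmetrically: the total over all cells
    vanishes, and equal voltages give exactly zero current.
    """
    V = np.asarray(voltages, dtype=float)
    if V.shape[0] != network.n_nodes:
        raise ValueError(
            f"voltage vector length {V.shape[0]} != node count {network.n_nodes}"
        )
    ea, eb = network.edge_arrays()
    out = np.zeros_like(V)
    d = V[ea] - V[eb]
    np.add.at(out, ea, d)
    np.add.at(out, eb, -d)
    return g_c * out


def pack_state(V, c, n, b) -> np.ndarray:
    """Stack per-cell variables into the flat [V | c | n | b] ordering."""
    return np.concatenate([np.atleast_1d(np.asarray(a, float)) for a in (V, c, n, b)])


def unpack_state(x: np.ndarray, n_cells: int):
    """Split a flat state (or (4n, K) batch) into V, c, n, b blocks."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != 4 * n_cells:
        raise ValueError(f"state length {x.shape[0]} != 4 * {n_cells}")
    s = x.reshape(4, n_cells, -1) if x.ndim > 1 else x.reshape(4, n_cells)
    return s[0], s[1], s[2], s[3]


def make_network_rhs(network: StructuralNetwork, params: CellParams):
    """Compile a fast dx/dt closure for one (network, params) pair.

    The returned callable accepts a flat state of shape (4n,) or a batch
    (4n, K) and returns derivatives of the same shape.  No validation is
    performed inside the closure (the integrator checks for blow-up).
    """
    p = params
    n_cells = network.n_nodes
    ea, eb = network.edge_arrays()
    k_SK2 = p.k_SK * p.k_SK
    inv_Cm = 1.0 / p.C_m
    inv_tau_n = 1.0 / p.tau_n
    inv_tau_b = 1.0 / p.tau_b

    def rhs(x: np.ndarray) -> np.ndarray:
        s = x.reshape(4, n_cells, -1)
        V, ca, nn, bb = s[0], s[1], s[2], s[3]
        m_inf = 1.0 / (1.0 + np.exp((p.v_m - V) / p.l_m))
        n_inf = 1.0 / (1.0 + np.exp((p.v_n - V) / p.l_n))
        b_inf = 1.0 / (1.0 + np.exp((p.v_b - V) / p.l_b))
        c2 = ca * ca
        s_inf = c2 / (c2 + k_SK2)
        dV_K = V - p.V_K
        I_Ca = p.g_Ca * m_inf * (V - p.V_Ca)
        I_sum = (p.g_Kdr * nn + p.g_BK * bb + p.g_SK * s_inf) * dV_K
        I_sum += I_Ca
        I_sum += p.g_L * (V - p.V_L)
        Ic = np.zeros_like(V)
        if len(ea):
            d = V[ea] - V[eb]
            np.add.at(Ic, ea, d)
            np.add.at(Ic, eb, -d)
        I_sum += p.g_c * Ic
        out = np.empty_like(x)
        o = out.reshape(4, n_cells, -1)
        o[0] = I_sum * (-inv_Cm)
        o[1] = -p.f_c * (p.alpha * I_Ca + p.k_c * ca)
        o[2] = (n_inf - nn) * inv_tau_n
        o[3] = (b_inf - bb) * inv_tau_b
        return out

    return rhs


def network_rhs(state: np.ndarray, network: StructuralNetwork,
                params: CellParams) -> np.ndarray:
    """Validated time derivative of a full network state (flat or batched)."""
    x = np.asarray(state, dtype=float)
    if x.shape[0] != 4 * network.n_nodes:
        raise ValueError(
            f"state length {x.shape[0]} != 4 * {network.n_nodes} cells"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite network state")
    return make_network_rhs(network, params)(x).reshape(x.shape)
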