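"""Fixed-step integration of the coupled network and initial-condition sampling.

The study protocol is: draw random initial states, integrate the network
with classical 4th-order Runge-Kutta at a fixed step (0.5 ms), discard a
long transient, and analyze only the final window (10 s) during which the
system is taken to be on its asymptotic state.  Everything downstream
(burst detection, similarity, functional networks) reads that window.

Batching: a bank of K initial conditions for the *same* network and
parameters is integrated as one (4n, K) array, which is how the
100/1000-trial experiments stay fast.  Column k of a batch evolves
bit-identically to a separate single run of the same initial state.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ._kernels import HAVE_NUMBA, pack_params, rk4_run
from .cell_model import make_network_rhs
from .network_builder import StructuralNetwork
from .params import CellParams

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "sample_initial_conditions",
    "rk4_integrate",
    "run_trial",
]

# sampling box for random initial conditions: V spans the K+ reversal up
# to above the burst plateau; c spans the oscillation range of the model
IC_V_RANGE = (-75.0, -10.0)   # mV
IC_C_RANGE = (0.0, 1.0)       # uM
_BLOWUP_CHECK_STRIDE = 2000   # steps between finiteness checks


@dataclass
class SimulationConfig:
    """Integration protocol.

    ``t_total`` includes the transient; only the final ``t_analysis`` is
    stored sample-by-sample and analyzed.  The default transient (390 s
    discarded of 400 s total) is chosen so that the slow, Ca2+-mediated
    phase dynamics of weakly coupled cells (coupling conductances of a
    few pS) have demonstrably reached their asymptotic state: by then a
    coupled pair classifies cleanly as synchronized or antiphase, with no
    trials left in transit between the attractors.  ``record_stride``
    thins the transient portion of stored trajectories (it never affects
    the analysis window); 0 drops the transient entirely.
    """

    dt: float = 0.5               # ms
    t_total: float = 400_000.0    # ms
    t_analysis: float = 10_000.0  # ms
    seed: int | None = None
    record_stride: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_analysis > self.t_total:
            raise ValueError("t_analysis cannot exceed t_total")
        if self.record_stride < 0:
            raise ValueError("record_stride must be >= 0")

    @property
    def n_steps(self) -> int:
        return round(self.t_total / self.dt)

    @property
    def n_window(self) -> int:
        return round(self.t_analysis / self.dt)


@dataclass
class Trajectory:
    """Sampled states of every cell over the analysis window.

    ``t`` has one entry per stored sample; ``V``, ``c``, ``n``, ``b`` are
    (n_samples, n_cells) arrays (``c``/``n``/``b`` may be absent when only
    voltages were recorded).  ``transient_t`` / ``transient_V`` hold the
    thinned pre-window voltage record, if any.
    """

    t: np.ndarray
    V: np.ndarray
    c: np.ndarray | None = None
    n: np.ndarray | None = None
    b: np.ndarray | None = None
    transient_t: np.ndarray | None = None
    transient_V: np.ndarray | None = None
    final_state: np.ndarray | None = None
    config: SimulationConfig | None = None
    seed: int | None = None

    @property
    def n_cells(self) -> int:
        return self.V.shape[1]

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time, cell, V [, c, n, b]."""
        n_s, n_c = self.V.shape
        data = {
            "time": np.repeat(self.t, n_c),
            "cell": np.tile(np.arange(n_c), n_s),
            "V": self.V.ravel(),
        }
        for name in ("c", "n", "b"):
            arr = getattr(self, name)
            if arr is not None:
                data[name] = arr.ravel()
        return pd.DataFrame(data)

    def write_csv(self, path: str | Path) -> None:
        """Columnar table plus a JSON provenance sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if self.config is not None:
            sidecar = path.with_suffix(path.suffix + ".json")
            meta = asdict(self.config)
            meta["seed"] = self.seed
            sidecar.write_text(json.dumps(meta, indent=2) + "\n")


def sample_initial_conditions(n_cells: int, seed, size: int | None = None) -> np.ndarray:
    """Uniform random initial network states.

    Per cell: V ~ U(-75, -10) mV, c ~ U(0, 1) uM, n ~ U(0, 1), b ~ U(0, 1).
    Returns a flat (4n,) state, or an IC bank of shape (4n, size) whose
    columns are independent states — the bank is what a coupling-strength
    sweep reuses so every g_c value sees bit-identical initial states.
    Deterministic given ``seed`` (an int or a numpy SeedSequence/Generator).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    k = 1 if size is None else size
    V = rng.uniform(*IC_V_RANGE, size=(n_cells, k))
    c = rng.uniform(*IC_C_RANGE, size=(n_cells, k))
    n = rng.uniform(0.0, 1.0, size=(n_cells, k))
    b = rng.uniform(0.0, 1.0, size=(n_cells, k))
    bank = np.concatenate([V, c, n, b], axis=0)
    return bank[:, 0] if size is None else bank


def rk4_integrate(
    initial: np.ndarray,
    network: StructuralNetwork,
    params: CellParams,
    config: SimulationConfig,
    rhs: Callable[[np.ndarray], np.ndarray] | None = None,
    record: str = "full",
) -> Trajectory:
    """Classical fixed-step 4th-order Runge-Kutta over ``t_total``.

    ``initial`` is a flat (4n,) state or a (4n, K) batch.  ``record`` is
    ``"full"`` (store V, c, n, b over the analysis window) or ``"V"``
    (voltages only, which is all the synchrony analysis needs).  A ``rhs``
    override exists as a test hook; by default the lactotroph network
    right-hand side is compiled from (network, params).

    Raises ``FloatingPointError`` naming the approximate time if the
    state stops being finite.
    """
    x = np.array(initial, dtype=float)
    batched = x.ndim == 2
    n_cells = network.n_nodes
    if x.shape[0] != 4 * n_cells:
        raise ValueError(f"state length {x.shape[0]} != 4 * {n_cells}")
    dt = config.dt
    n_steps = config.n_steps
    n_window = config.n_window
    window_first = n_steps - n_window + 1  # first recorded step index

    k_batch = x.shape[1] if batched else 1
    store_full = record == "full"
    if record not in ("full", "V"):
        raise ValueError("record must be 'full' or 'V'")
    xb = np.ascontiguousarray(x.reshape(4, n_cells, k_batch))
    V_win = np.empty((n_window, n_cells, k_batch))
    empty = np.empty((0, 0, 0))
    c_win = np.empty_like(V_win) if store_full else empty
    n_win = np.empty_like(V_win) if store_full else empty
    b_win = np.empty_like(V_win) if store_full else empty
    stride = int(config.record_stride)
    n_trans = (window_first - 1) // stride if stride else 0
    trans_V = np.empty((n_trans, n_cells, k_batch)) if stride else empty
    x0_V = xb[0].copy() if stride else None

    if rhs is None and HAVE_NUMBA:
        ea, eb = network.edge_arrays()
        status = rk4_run(xb, ea, eb, pack_params(params), dt, n_steps,
                         window_first, V_win, c_win, n_win, b_win,
                         store_full, stride, trans_V, _BLOWUP_CHECK_STRIDE)
        if status:
            raise FloatingPointError(
                f"state became non-finite by t = {status * dt:g} ms")
    else:
        if rhs is None:
            rhs = make_network_rhs(network, params)
        _rk4_python(xb, rhs, dt, n_steps, window_first, V_win, c_win, n_win,
                    b_win, store_full, stride, trans_V)

    t = np.arange(window_first, n_steps + 1) * dt
    tail = (n_cells, k_batch) if batched else (n_cells,)
    final = xb.reshape(4 * n_cells, k_batch)
    trans_arrays = None
    if stride:
        trans_arrays = np.concatenate([x0_V[None], trans_V], axis=0)
        trans_t = np.concatenate([[0.0], (np.arange(1, n_trans + 1) * stride) * dt])
    return Trajectory(
        t=t,
        V=V_win if batched else V_win[:, :, 0],
        c=c_win[:, :, 0] if store_full and not batched else (c_win if store_full else None),
        n=n_win[:, :, 0] if store_full and not batched else (n_win if store_full else None),
        b=b_win[:, :, 0] if store_full and not batched else (b_win if store_full else None),
        transient_t=trans_t if stride else None,
        transient_V=(trans_arrays if batched else trans_arrays[:, :, 0]) if stride else None,
        final_state=final if batched else final[:, 0],
        config=config,
        seed=config.seed,
    )


def _rk4_python(xb: np.ndarray, rhs, dt: float, n_steps: int, window_first: int,
                V_win, c_win, n_win, b_win, store_full: bool,
                stride: int, trans_V) -> None:
    """Pure-numpy RK4 loop (fallback path and test hook for rhs overrides)."""
    n_cells, k_batch = xb.shape[1], xb.shape[2]
    x = xb.reshape(4 * n_cells, k_batch)
    half, sixth = dt / 2.0, dt / 6.0
    ti = 0
    for step in range(1, n_steps + 1):
        k1 = rhs(x)
        k2 = rhs(x + half * k1)
        k3 = rhs(x + half * k2)
        k4 = rhs(x + dt * k3)
        x += sixth * (k1 + 2.0 * (k2 + k3) + k4)
        if step >= window_first:
            i = step - window_first
            V_win[i] = xb[0]
            if store_full:
                c_win[i] = xb[1]
                n_win[i] = xb[2]
                b_win[i] = xb[3]
        elif stride and step % stride == 0:
            trans_V[ti] = xb[0]
            ti += 1
        if step % _BLOWUP_CHECK_STRIDE == 0 or step == n_steps:
            if not np.all(np.isfinite(xb[0])):
                raise FloatingPointError(
                    f"state became non-finite by t = {step * dt:g} ms")


def run_trial(
    network: StructuralNetwork,
    params: CellParams,
    config: SimulationConfig,
    initial: np.ndarray | None = None,
    record: str = "full",
) -> Trajectory:
    """One simulation: optional IC sampling, transient, analysis window.

    If ``initial`` is omitted it is drawn with ``config.seed``.  The
    returned trajectory's per-sample arrays cover exactly the final
    ``t_analysis`` window used by all downstream statistics.
    """
    if initial is None:
        initial = sample_initial_conditions(network.n_nodes, config.seed)
    return rk4_integrate(initial, network, params, config, record=record)
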