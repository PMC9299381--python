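"""Parameter set of the pituitary lactotroph model.

The model describes a single pituitary lactotroph with four state
variables: membrane potential ``V`` (mV), free cytosolic calcium ``c``
(uM), delayed-rectifier K+ activation ``n`` and BK-channel activation
``b``.  Cells in a network are identical; the only inter-cell parameter
is the gap-junctional coupling conductance ``g_c``.

Units follow the pF / mV / ms / nS / pA / uM convention, under which all
terms of the right-hand side are dimensionally consistent (nS x mV = pA;
pA / pF = mV/ms).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["CellParams", "load_params", "save_params"]

_POSITIVE_FIELDS = (
    "C_m", "g_Kdr", "g_Ca", "g_SK", "g_BK", "g_L",
    "tau_n", "tau_b", "f_c", "alpha", "k_c", "k_SK",
)


@dataclass(frozen=True)
class CellParams:
    """All constants of the lactotroph model.

    Defaults are the published reference parameter set for a
    pseudo-plateau bursting lactotroph.  ``l_m`` is 12 mV (a widely used
    slope for the fast Ca2+ activation function in this model family) and
    ``k_c`` is a plasma-membrane Ca2+ pump rate with units of 1/ms.
    """

    C_m: float = 5.0        # membrane capacitance, pF
    g_Kdr: float = 2.5      # delayed-rectifier K+ conductance, nS
    g_Ca: float = 2.1       # L-type Ca2+ conductance, nS
    g_SK: float = 2.0       # SK K+ conductance, nS
    g_BK: float = 1.0       # BK K+ conductance, nS
    g_L: float = 0.2        # leak conductance, nS
    g_c: float = 0.002      # gap-junction coupling conductance, nS (= 2 pS)
    V_K: float = -75.0      # K+ Nernst potential, mV
    V_Ca: float = 60.0      # Ca2+ Nernst potential, mV
    V_L: float = -50.0      # leak reversal potential, mV
    v_n: float = -5.0       # half-activation voltage of n, mV
    v_m: float = -20.0      # half-activation voltage of m, mV
    v_b: float = -5.0       # half-activation voltage of b, mV
    # The reference table's l_n/l_m rows carry a displaced zero ("1 mV" /
    # "12 0mV"); the consistent reading is l_n = 10 mV, l_m = 12 mV — the
    # standard slopes for n_inf and m_inf in this lactotroph model family,
    # and the only reading under which the model reproduces the published
    # network behavior (see docs/methods.md).
    l_n: float = 10.0       # slope factor of n, mV
    l_m: float = 12.0       # slope factor of m, mV
    l_b: float = 2.0        # slope factor of b, mV
    tau_n: float = 30.0     # activation time constant of n, ms
    tau_b: float = 5.0      # activation time constant of b, ms
    f_c: float = 0.005      # fraction of cytosolic Ca2+ that is free
    alpha: float = 0.0015   # Ca2+ current-to-concentration conversion, uM/fC
    k_c: float = 0.12       # Ca2+ pump rate, 1/ms
    k_SK: float = 0.4       # SK half-activation Ca2+ concentration, uM

    def __post_init__(self) -> None:
        for name in _POSITIVE_FIELDS:
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.g_c < 0:
            raise ValueError(f"g_c must be non-negative, got {self.g_c!r}")
        for name in ("l_n", "l_m", "l_b"):
            if getattr(self, name) == 0:
                raise ValueError(f"{name} must be nonzero")

    @property
    def g_c_pS(self) -> float:
        """Coupling conductance in pS (the reporting unit; stored in nS)."""
        return self.g_c * 1000.0

    def with_coupling(self, *, g_c: float | None = None,
                      g_c_pS: float | None = None) -> "CellParams":
        """Return a copy with a different coupling conductance."""
        if (g_c is None) == (g_c_pS is None):
            raise ValueError("give exactly one of g_c (nS) or g_c_pS (pS)")
        if g_c_pS is not None:
            g_c = g_c_pS / 1000.0
        return dataclasses.replace(self, g_c=g_c)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, float]) -> "CellParams":
        field_names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - field_names
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        missing = field_names - set(data)
        if missing:
            raise ValueError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in data.items()})


def load_params(path: str | Path) -> CellParams:
    """Load a complete parameter set from a JSON or YAML file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key/value mapping")
    return CellParams.from_dict(data)


def save_params(params: CellParams, path: str | Path) -> None:
    """Write a parameter set as JSON or YAML depending on the suffix."""
    path = Path(path)
    data = params.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
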