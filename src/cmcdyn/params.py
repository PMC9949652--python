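"""Model parameters for the canonical microcircuit (CMC) neural mass model.

The CMC describes a cortical column as four interacting neuronal populations.
Each population *i* is a damped-free oscillator with angular frequency
``omega_i`` whose potential ``q_i`` and current ``p_i = dq_i/dt`` are coupled
to the other populations through a connectivity gain matrix ``G`` and two
nonlinear coupling functions:

* ``S`` maps presynaptic *potential* to postsynaptic drive (a sigmoid),
* ``P`` maps presynaptic *current* to postsynaptic drive (spike-rate
  variability).

Two scalar perturbation scales, ``epsilon`` (potential coupling) and ``mu``
(current coupling), control the departure from the uncoupled harmonic system.
A lead field ``a`` maps population potentials to the measured EEG signal, and
``sigma`` is the standard deviation of the noise driving the slow amplitude
dynamics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = ["CouplingFunction", "CMCParameters", "load_config", "save_config"]


@dataclass(frozen=True)
class CouplingFunction:
    """A centered, odd, bounded coupling nonlinearity.

    Parameters
    ----------
    kind : {"tanh", "tanh_sum", "linear"}
        Functional form.  ``tanh`` is ``gain * tanh(slope * x)``;
        ``tanh_sum`` is ``sum_k w_k * tanh(s_k * x)`` over ``components``;
        ``linear`` is ``gain * x`` (the small-signal idealization, the one
        form that is not bounded).
    gain : float
        Dimensionless scale (ignored for ``tanh_sum``).
    slope : float
        Dimensionless steepness at the origin (ignored for ``tanh_sum``).
    components : tuple of (weight, slope) pairs
        Only used for ``tanh_sum``.  A signed mixture of saturating terms;
        physiologically, parallel excitatory/inhibitory subpopulation gains
        with different sensitivities.

    Notes
    -----
    Every kind satisfies f(0) = 0 and f(-x) = -f(x); these properties are what
    make the origin a fixed point of the full model and restrict the drift
    expansion to odd powers.
    """

    kind: str = "tanh"
    gain: float = 1.0
    slope: float = 1.0
    components: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self):
        if self.kind not in ("tanh", "tanh_sum", "linear"):
            raise ValueError(f"unknown coupling kind {self.kind!r}")
        if self.kind == "tanh_sum":
            if not self.components:
                raise ValueError("tanh_sum coupling requires components")
            object.__setattr__(
                self, "components", tuple((float(w), float(s)) for w, s in self.components)
            )

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return self.gain * x
        if self.kind == "tanh":
            return self.gain * np.tanh(self.slope * x)
        out = np.zeros_like(x)
        for w, s in self.components:
            out += w * np.tanh(s * x)
        return out

    @property
    def bound(self) -> float:
        """Supremum of |f|; ``inf`` for the linear idealization."""
        if self.kind == "linear":
            return np.inf
        if self.kind == "tanh":
            return abs(self.gain)
        return sum(abs(w) for w, _ in self.components)

    def slope_at_zero(self) -> float:
        if self.kind == "linear":
            return self.gain
        if self.kind == "tanh":
            return self.gain * self.slope
        return sum(w * s for w, s in self.components)

    def to_dict(self) -> dict:
        d = {"kind": self.kind}
        if self.kind == "tanh_sum":
            d["components"] = [list(c) for c in self.components]
        else:
            d["gain"] = self.gain
            d["slope"] = self.slope
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CouplingFunction":
        if d.get("kind") == "tanh_sum":
            return cls(kind="tanh_sum", components=tuple(tuple(c) for c in d["components"]))
        return cls(
            kind=d.get("kind", "tanh"),
            gain=float(d.get("gain", 1.0)),
            slope=float(d.get("slope", 1.0)),
        )


def _as_array(x, n=None, name="array") -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if n is not None and a.shape != (n,):
        raise ValueError(f"{name} must have shape ({n},), got {a.shape}")
    return a


@dataclass(frozen=True)
class CMCParameters:
    """All constants of the CMC model and its amplitude-level noise.

    The lead field is rescaled on construction so that ``sum(a_i**2) == n``
    (with ``n`` the number of populations); with that normalization the
    constant-amplitude surfaces ``sum(a_i**2 R_i**2) = n R_s**2`` reduce to
    spheres when all ``a_i`` are equal, and ``R_s`` equals the common
    per-population envelope in the symmetric case.
    """

    omegas: np.ndarray = field(
        default_factory=lambda: np.array([2 * np.pi, 4 * np.pi, 6 * np.pi, 8 * np.pi])
    )
    G: np.ndarray = field(default_factory=lambda: np.zeros((4, 4)))
    epsilon: float = 0.0
    mu: float = 0.0
    S: CouplingFunction = field(default_factory=lambda: CouplingFunction("tanh"))
    P: CouplingFunction = field(default_factory=lambda: CouplingFunction("tanh"))
    leadfield: np.ndarray = field(default_factory=lambda: np.ones(4))
    sigma: float = 0.0

    def __post_init__(self):
        omegas = _as_array(self.omegas, None, "omegas")
        n = omegas.size
        if n < 2:
            raise ValueError("need at least two populations")
        if np.any(omegas <= 0):
            raise ValueError("all omegas must be positive")
        if len(np.unique(omegas)) != n and len(np.unique(omegas)) != 1:
            # identical frequencies are allowed only if *all* coincide
            # (envelope separation needs pairwise-distinct bands otherwise)
            raise ValueError("omegas must be pairwise distinct (or all equal)")
        G = np.asarray(self.G, dtype=float)
        if G.shape != (n, n):
            raise ValueError(f"G must be {n}x{n}, got {G.shape}")
        lf = _as_array(self.leadfield, n, "leadfield")
        ss = float(np.sum(lf**2))
        if ss <= 0:
            raise ValueError("leadfield must have at least one nonzero weight")
        lf = lf * np.sqrt(n / ss)
        for nm, v in (("epsilon", self.epsilon), ("mu", self.mu), ("sigma", self.sigma)):
            if v < 0:
                raise ValueError(f"{nm} must be non-negative")
        object.__setattr__(self, "omegas", omegas)
        object.__setattr__(self, "G", G)
        object.__setattr__(self, "leadfield", lf)
        object.__setattr__(self, "epsilon", float(self.epsilon))
        object.__setattr__(self, "mu", float(self.mu))
        object.__setattr__(self, "sigma", float(self.sigma))

    @property
    def n_populations(self) -> int:
        return self.omegas.size

    def replace(self, **kw) -> "CMCParameters":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "omegas": self.omegas.tolist(),
            "G": self.G.tolist(),
            "epsilon": self.epsilon,
            "mu": self.mu,
            "S": self.S.to_dict(),
            "P": self.P.to_dict(),
            "leadfield": self.leadfield.tolist(),
            "sigma": self.sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CMCParameters":
        kw = dict(d)
        if "S" in kw:
            kw["S"] = CouplingFunction.from_dict(kw["S"])
        if "P" in kw:
            kw["P"] = CouplingFunction.from_dict(kw["P"])
        for key in ("omegas", "G", "leadfield"):
            if key in kw:
                kw[key] = np.asarray(kw[key], dtype=float)
        return cls(**kw)


def load_config(path) -> CMCParameters:
    """Read a YAML or JSON model configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return CMCParameters.from_dict(data)


def save_config(params: CMCParameters, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(params.to_dict(), indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))
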