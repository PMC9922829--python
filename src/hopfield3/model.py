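"""Three-neuron Hopfield network with bias current: vector fields and Jacobians.

The base model is the continuous-time Hopfield network

    C_i dx_i/dt = -x_i / R_i + sum_j w_ij tanh(beta_j x_j) + I_i

with three neurons, C_i = R_i = 1, and an external bias current ``i1``
injected into the first neuron only.  With the default synaptic weights the
system reads

    dx1/dt = -x1 + 2 tanh(b1 x1) - 1.2 tanh(b2 x2) + 0.48 tanh(b3 x3) + i1
    dx2/dt = -x2 + 3.6 tanh(b1 x1) + 1.7 tanh(b2 x2) + 1.076 tanh(b3 x3)
    dx3/dt = -x3 - 9 tanh(b1 x1)

For ``i1 = 0`` the vector field is odd (equivariant under x -> -x), so
attractors occur in mirror pairs unless self-symmetric; a nonzero bias
breaks that symmetry.

Two Jacobian variants are provided.  :func:`jacobian_true` is the analytic
derivative of the vector field and drives all simulation-side computations
(tangent dynamics for Lyapunov exponents, dissipativity checks).
:func:`jacobian_printed` is a historical variant whose (2,2) entry carries
the opposite sign on the recurrent synaptic term; it is retained because
published eigenvalue tables for this model follow it, and it is used only
for reproducing those stability classifications.

A four-dimensional extension implements linear-augmentation control: an
auxiliary variable x4 with linear decay ``eps`` and offset ``gamma`` is
coupled into neuron 2 with strength ``phi``,

    dx2/dt += phi * x4,      dx4/dt = -eps * x4 - phi * (x2 - gamma).

Increasing ``phi`` from zero progressively destroys coexisting attractors
until a single one survives (monostability).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DEFAULT_W",
    "DEFAULT_BETA",
    "ModelParams",
    "ControlParams",
    "vector_field",
    "jacobian_true",
    "jacobian_printed",
    "augmented_field",
    "mirror",
    "write_config",
    "read_config",
]

#: Default synaptic weight matrix w[i][j] (row = postsynaptic neuron).
DEFAULT_W = ((2.0, -1.2, 0.48), (3.6, 1.7, 1.076), (-9.0, 0.0, 0.0))

#: Default activation gradients (beta1, beta2, beta3).  beta2 is the usual
#: bifurcation parameter and is varied freely; 1.7 is the stability-analysis
#: value.
DEFAULT_BETA = (0.9, 1.7, 1.4)


def _as_state(s, dim: int) -> np.ndarray:
    arr = np.asarray(s, dtype=float)
    if arr.shape != (dim,):
        raise ValueError(f"state must have shape ({dim},), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"state contains non-finite values: {arr}")
    return arr


@dataclass(frozen=True)
class ModelParams:
    """All constants of the three-neuron network.

    Parameters
    ----------
    w : (3, 3) array-like
        Synaptic weights; ``w[i, j]`` couples neuron ``j``'s activation into
        neuron ``i``.  Dimensionless.
    beta : length-3 array-like
        Activation gradients (slopes of the tanh nonlinearity), all > 0.
    i1 : float
        Bias current into neuron 1.  ``i1 = 0`` gives the odd-symmetric
        regime.
    c, r : float
        Membrane capacitance and resistance, fixed to 1 in the dimensionless
        form; kept as explicit fields for completeness.
    """

    w: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_W))
    beta: np.ndarray = field(default_factory=lambda: np.array(DEFAULT_BETA))
    i1: float = 0.0
    c: float = 1.0
    r: float = 1.0

    def __post_init__(self):
        w = np.array(self.w, dtype=float)
        beta = np.array(self.beta, dtype=float)
        if w.shape != (3, 3):
            raise ValueError(f"w must be 3x3, got {w.shape}")
        if beta.shape != (3,):
            raise ValueError(f"beta must have 3 components, got {beta.shape}")
        if not np.all(np.isfinite(w)) or not np.all(np.isfinite(beta)):
            raise ValueError("w and beta must be finite")
        if np.any(beta <= 0):
            raise ValueError(f"beta components must be strictly positive, got {beta}")
        w.setflags(write=False)
        beta.setflags(write=False)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "i1", float(self.i1))

    def updated(self, **kwargs) -> "ModelParams":
        """Return a copy with scalar overrides.

        Accepts the dataclass fields plus the flat names ``beta1..beta3``
        and ``w11..w33`` (1-based indices, row = postsynaptic neuron), so
        the modified-weight regimes (e.g. ``w11=2.33`` bursting) are plain
        configuration.
        """
        w = np.array(self.w)
        beta = np.array(self.beta)
        plain = {}
        for key, val in kwargs.items():
            if len(key) == 3 and key.startswith("w") and key[1:].isdigit():
                i, j = int(key[1]) - 1, int(key[2]) - 1
                if not (0 <= i < 3 and 0 <= j < 3):
                    raise KeyError(key)
                w[i, j] = val
            elif len(key) == 5 and key.startswith("beta") and key[4].isdigit():
                j = int(key[4]) - 1
                if not 0 <= j < 3:
                    raise KeyError(key)
                beta[j] = val
            elif key in ("w", "beta", "i1", "c", "r"):
                plain[key] = val
            else:
                raise KeyError(f"unknown parameter {key!r}")
        return dataclasses.replace(self, w=w, beta=beta, **plain)

    @property
    def beta2(self) -> float:
        return float(self.beta[1])


@dataclass(frozen=True)
class ControlParams:
    """Linear-augmentation control constants.

    ``phi`` is the coupling strength swept in [0, ~0.3]; ``eps`` the decay
    of the auxiliary variable; ``gamma`` its target offset.  Defaults follow
    the standard control experiment (eps=0.5, gamma=8).
    """

    phi: float = 0.0
    eps: float = 0.5
    gamma: float = 8.0

    def __post_init__(self):
        if self.phi < 0:
            raise ValueError(f"phi must be >= 0, got {self.phi}")


def vector_field(s, p: ModelParams) -> np.ndarray:
    """Time derivative (dx1, dx2, dx3) of the base network at state ``s``."""
    x = _as_state(s, 3)
    act = np.tanh(p.beta * x)
    dx = -x + p.w @ act
    dx[0] += p.i1
    return dx


def jacobian_true(s, p: ModelParams) -> np.ndarray:
    """Analytic Jacobian of :func:`vector_field`.

    Entry (j, k) is ``-delta_jk + w[j, k] * beta[k] * sech^2(beta[k] x[k])``.
    Because w32 = w33 = 0 by default, the last row depends on x1 only.
    """
    x = _as_state(s, 3)
    sech2 = 1.0 - np.tanh(p.beta * x) ** 2
    return p.w * (p.beta * sech2)[np.newaxis, :] - np.eye(3)


def jacobian_printed(s, p: ModelParams) -> np.ndarray:
    """Historical Jacobian variant used for the published stability table.

    Identical to :func:`jacobian_true` except that the (2,2) entry is
    ``-w22 * beta2 * sech^2(beta2 x2) - 1``: the recurrent self-synapse term
    of neuron 2 enters with flipped sign.  The difference from the analytic
    Jacobian is ``2 * w22 * beta2 * sech^2(beta2 x2)`` in that single entry.
    Use only to reproduce the tabulated eigenvalue classifications; the
    tangent dynamics of the simulated flow follow :func:`jacobian_true`.
    """
    jac = jacobian_true(s, p)
    x = _as_state(s, 3)
    sech2_2 = 1.0 - np.tanh(p.beta[1] * x[1]) ** 2
    jac[1, 1] = -p.w[1, 1] * p.beta[1] * sech2_2 - 1.0
    return jac


def augmented_field(s, p: ModelParams, c: ControlParams) -> np.ndarray:
    """Derivative of the 4D control system (x1, x2, x3, x4).

    The first three components equal :func:`vector_field` with
    ``phi * x4`` added to dx2/dt; the fourth is
    ``-eps * x4 - phi * (x2 - gamma)``.  At ``phi = 0`` the network
    decouples from the control variable.
    """
    x = _as_state(s, 4)
    dx = np.empty(4)
    dx[:3] = vector_field(x[:3], p)
    dx[1] += c.phi * x[3]
    dx[3] = -c.eps * x[3] - c.phi * (x[1] - c.gamma)
    return dx


def mirror(s) -> np.ndarray:
    """Point reflection x -> -x (any dimension).

    For ``i1 = 0`` the base vector field is equivariant under this map:
    ``f(mirror(s)) == -f(s)``, so trajectories, attractors and basins come
    in mirror pairs.
    """
    return -np.asarray(s, dtype=float)


# ---------------------------------------------------------------------------
# flat key-value config serialization

_W_KEYS = [f"w{i+1}{j+1}" for i in range(3) for j in range(3)]


def write_config(path, p: ModelParams, c: ControlParams | None = None) -> None:
    """Write parameters as flat ``key = value`` lines (w11..w33, beta1..beta3,
    i1, and optionally phi/eps/gamma)."""
    lines = ["# hopfield3 model configuration"]
    for i in range(3):
        for j in range(3):
            lines.append(f"w{i+1}{j+1} = {float(p.w[i, j])!r}")
    for j in range(3):
        lines.append(f"beta{j+1} = {float(p.beta[j])!r}")
    lines.append(f"i1 = {float(p.i1)!r}")
    if c is not None:
        lines.append(f"phi = {float(c.phi)!r}")
        lines.append(f"eps = {float(c.eps)!r}")
        lines.append(f"gamma = {float(c.gamma)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path) -> tuple[ModelParams, ControlParams | None]:
    """Read a config written by :func:`write_config`.

    Returns ``(ModelParams, ControlParams or None)``; the control block is
    present iff any of phi/eps/gamma appears in the file.
    """
    values: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {raw!r}")
        key, _, val = line.partition("=")
        values[key.strip()] = float(val)
    w = np.array(DEFAULT_W)
    beta = np.array(DEFAULT_BETA)
    for key, val in values.items():
        if key in _W_KEYS:
            w[int(key[1]) - 1, int(key[2]) - 1] = val
        elif key.startswith("beta") and len(key) == 5:
            beta[int(key[4]) - 1] = val
    p = ModelParams(w=w, beta=beta, i1=values.get("i1", 0.0))
    if {"phi", "eps", "gamma"} & values.keys():
        c = ControlParams(
            phi=values.get("phi", 0.0),
            eps=values.get("eps", 0.5),
            gamma=values.get("gamma", 8.0),
        )
        return p, c
    return p, None
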