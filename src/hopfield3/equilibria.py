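"""Fixed points of the network and their linear stability.

Setting the three derivatives to zero and eliminating x2, x3 reduces the
fixed-point problem to one transcendental equation in x1.  From the third
equation x3 = -9 tanh(b1 x1) (the third neuron has no recurrent or lateral
synapse); substituting into the first gives

    tanh(b2 x2) = (1/1.2) * (-x1 + 2 tanh(b1 x1) + 0.48 tanh(b3 x3) + i1)

which is solvable for x2 only while the right-hand side lies strictly in
(-1, 1).  Outside that strip no real equilibrium exists (the analytic
continuation picks up the artanh branch offset i*pi/(2 b2), producing
complex "equilibria" that are excluded here and reported as inadmissible
intervals).  The residual of the second equation after both substitutions
is the scalar function whose real roots are the network's equilibria.

Stability is classified from the eigenvalues of either Jacobian variant;
see :mod:`hopfield3.model` for why two variants exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model import ModelParams, jacobian_printed, jacobian_true, vector_field

__all__ = [
    "ReductionDomainError",
    "EquilibriumRecord",
    "scalar_residual",
    "reduce_coordinates",
    "find_equilibria",
    "inadmissible_intervals",
    "classify",
]

#: Real parts within this band of zero are classified "marginal".
MARGINAL_TOL = 1e-9

#: Default x1 scan range; covers every real root of the default model with
#: wide margin (|x1| of all known equilibria is below 4).
X1_RANGE_DEFAULT = (-6.0, 6.0)
N_SCAN_DEFAULT = 10_000


class ReductionDomainError(ValueError):
    """artanh argument left (-1, 1): no real equilibrium at this x1."""

    def __init__(self, x1e: float, argument: float):
        self.x1e = x1e
        self.argument = argument
        super().__init__(
            f"equilibrium reduction undefined at x1 = {x1e:g}: "
            f"artanh argument {argument:g} outside (-1, 1)"
        )


@dataclass(frozen=True)
class EquilibriumRecord:
    """A real fixed point with its spectrum under one Jacobian variant."""

    x: np.ndarray
    eigvals: np.ndarray
    variant: str  # "true" | "printed"
    stability: str  # "stable" | "unstable" | "marginal"
    charpoly: np.ndarray  # monic cubic coefficients (alpha1..alpha4)

    @property
    def stable(self) -> bool:
        return self.stability == "stable"


def _reduction_argument(x1e: float, p: ModelParams) -> tuple[float, float]:
    """(artanh argument, x3) of the scalar reduction at ``x1e``."""
    b1, _, b3 = p.beta
    x3 = p.w[2, 0] * np.tanh(b1 * x1e)
    arg = (
        -x1e + p.w[0, 0] * np.tanh(b1 * x1e) + p.w[0, 2] * np.tanh(b3 * x3) + p.i1
    ) / (-p.w[0, 1])
    return arg, x3


def reduce_coordinates(x1e: float, p: ModelParams) -> np.ndarray:
    """Full equilibrium coordinates (x1, x2, x3) implied by ``x1e``."""
    arg, x3 = _reduction_argument(x1e, p)
    if not -1.0 < arg < 1.0:
        raise ReductionDomainError(x1e, arg)
    x2 = np.arctanh(arg) / p.beta[1]
    return np.array([x1e, x2, x3])


def scalar_residual(x1e: float, p: ModelParams) -> float:
    """Residual of the second fixed-point equation after the reduction.

    Zero iff ``x1e`` is the first coordinate of a real equilibrium.  For
    ``i1 = 0`` the function is odd in ``x1e``.  Raises
    :class:`ReductionDomainError` where no real x2 exists.
    """
    x = reduce_coordinates(x1e, p)
    return float(vector_field(x, p)[1])


def _scan_values(p: ModelParams, x1_range, n_scan: int):
    xs = np.linspace(x1_range[0], x1_range[1], n_scan)
    vals = np.full(n_scan, np.nan)
    for i, x1 in enumerate(xs):
        try:
            vals[i] = scalar_residual(x1, p)
        except ReductionDomainError:
            pass
    return xs, vals


def inadmissible_intervals(
    p: ModelParams, x1_range=X1_RANGE_DEFAULT, n_scan: int = N_SCAN_DEFAULT
) -> list[tuple[float, float]]:
    """x1 intervals (at scan resolution) where the reduction has no real x2.

    These are where the tabulated complex-coordinate points live; the real
    root finder skips them by construction.
    """
    xs, vals = _scan_values(p, x1_range, n_scan)
    bad = ~np.isfinite(vals)
    out: list[tuple[float, float]] = []
    i = 0
    while i < n_scan:
        if bad[i]:
            j = i
            while j + 1 < n_scan and bad[j + 1]:
                j += 1
            out.append((float(xs[i]), float(xs[j])))
            i = j + 1
        else:
            i += 1
    return out


def find_equilibria(
    p: ModelParams,
    x1_range=X1_RANGE_DEFAULT,
    n_scan: int = N_SCAN_DEFAULT,
    variant: str = "true",
    residual_tol: float = 1e-10,
) -> list[EquilibriumRecord]:
    """All real equilibria in ``x1_range``, classified and sorted by x1.

    A dense scan of the scalar residual locates sign changes; each bracket
    is refined with Brent's method until |S| < ``residual_tol``.  Only real
    equilibria are returned; intervals where the reduction leaves its
    domain are available from :func:`inadmissible_intervals`.
    """
    if n_scan < 100:
        raise ValueError("n_scan must be at least 100 for a reliable scan")
    xs, vals = _scan_values(p, x1_range, n_scan)
    finite = np.isfinite(vals)
    if not finite.any():
        warnings.warn("equilibrium reduction admissible nowhere in range; no roots")
        return []
    roots: list[float] = []
    for i in range(n_scan - 1):
        if not (finite[i] and finite[i + 1]):
            continue
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(xs[i]))
        elif a * b < 0:
            roots.append(brentq(lambda x: scalar_residual(x, p), xs[i], xs[i + 1], xtol=1e-14))
    if finite[-1] and vals[-1] == 0.0:
        roots.append(float(xs[-1]))
    records = []
    for x1e in sorted(roots):
        if abs(scalar_residual(x1e, p)) > residual_tol:
            continue
        records.append(classify(reduce_coordinates(x1e, p), p, variant=variant))
    return records


def classify(eq_coords, p: ModelParams, variant: str = "true") -> EquilibriumRecord:
    """Eigenvalue classification of a fixed point.

    ``variant`` selects the Jacobian: "true" (analytic, used for dynamics)
    or "printed" (the historical variant behind the published stability
    table).  Stability requires all real parts negative; real parts within
    ±1e-9 of zero yield the label "marginal".
    """
    x = np.asarray(eq_coords, dtype=float)
    res = np.linalg.norm(vector_field(x, p))
    if res > 1e-6:
        raise ValueError(f"not an equilibrium: |f(x)| = {res:g} > 1e-6")
    if variant == "true":
        jac = jacobian_true(x, p)
    elif variant == "printed":
        jac = jacobian_printed(x, p)
    else:
        raise ValueError(f"unknown Jacobian variant {variant!r}")
    eig = np.linalg.eigvals(jac)
    order = np.argsort(-eig.real)
    eig = eig[order]
    re = eig.real
    if np.any(re > MARGINAL_TOL):
        stability = "unstable"
    elif np.all(re < -MARGINAL_TOL):
        stability = "stable"
    else:
        stability = "marginal"
    charpoly = np.real(np.poly(jac))
    return EquilibriumRecord(x=x, eigvals=eig, variant=variant,
                             stability=stability, charpoly=charpoly)
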