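"""Bifurcation sweeps with hysteresis and period-bubbling detection.

A sweep integrates the network at every value of a parameter grid and
records the set of post-transient local maxima of x1 (the classic
peak-based bifurcation diagram).  Two seeding conventions are supported:

* ``reset`` — every grid point starts from the same initial condition,
  probing the basin of that one point;
* ``follow`` — each grid point starts from the final state of the previous
  one (attractor continuation), so the branch tracks an attractor through
  parameter space and exposes hysteresis when swept in both directions.

Running several protocols (up/down, different seeds, reset/follow) and
comparing the branches is how coexisting attractors show up in these
diagrams: wherever two protocols disagree, at least two attractors coexist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .integrate import (
    DT_DEFAULT,
    TRANSIENT_DEFAULT,
    DivergenceError,
    extract_peaks,
    integrate_fixed,
)
from .lyapunov import CHAOS_THRESHOLD, lyapunov_spectrum
from .model import ModelParams

__all__ = [
    "SweepProtocol",
    "BifurcationBranch",
    "sweep",
    "cluster_levels",
    "count_levels",
    "detect_bubbles",
    "hysteresis_windows",
    "WINDOW_SWEEP_DEFAULT",
]

#: Post-transient window per grid point; shorter than the census window
#: because a sweep needs only the peak-level structure, not attractor
#: identity.
WINDOW_SWEEP_DEFAULT = 300.0

#: Absolute tolerance for clustering peak levels into periodic "levels".
LEVEL_TOL_DEFAULT = 1e-2

#: More distinct levels than this is labeled chaotic.
MAX_PERIODIC_LEVELS = 32


@dataclass(frozen=True)
class SweepProtocol:
    """One row of a sweep plan.

    ``values`` must be strictly monotone and agree with ``direction``
    ("upward" increasing, "downward" decreasing).  ``ic_mode`` is "reset"
    or "follow" (see module docstring); ``ic`` seeds the first (reset:
    every) grid point.
    """

    param_name: str
    values: np.ndarray
    direction: str
    ic_mode: str
    ic: np.ndarray
    label: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        ic = np.asarray(self.ic, dtype=float)
        diffs = np.diff(values)
        if self.direction == "upward":
            ok = np.all(diffs > 0)
        elif self.direction == "downward":
            ok = np.all(diffs < 0)
        else:
            raise ValueError(f"direction must be upward|downward, got {self.direction!r}")
        if len(values) > 1 and not ok:
            raise ValueError("values must be strictly monotone matching direction")
        if self.ic_mode not in ("reset", "follow"):
            raise ValueError(f"ic_mode must be reset|follow, got {self.ic_mode!r}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ic", ic)


@dataclass(frozen=True)
class BifurcationBranch:
    """Sweep output, grid-aligned with the protocol."""

    values: np.ndarray
    peak_sets: list  # one ndarray of x1 peak values per grid point; None if divergent
    period_counts: np.ndarray  # -1 where divergent
    largest_le: np.ndarray | None = None
    label: str = ""

    def chaotic_mask(self) -> np.ndarray:
        mask = self.period_counts > MAX_PERIODIC_LEVELS
        if self.largest_le is not None:
            mask |= self.largest_le > CHAOS_THRESHOLD
        return mask


def cluster_levels(peaks: np.ndarray, tol: float = LEVEL_TOL_DEFAULT) -> np.ndarray:
    """Cluster peak values into distinct levels (gap > ``tol`` splits).

    Returns the sorted level representatives (cluster means).  A period-n
    limit cycle yields n point clusters; chaos yields wide clusters (bands).
    """
    if len(peaks) == 0:
        return np.empty(0)
    s = np.sort(np.asarray(peaks, dtype=float))
    splits = np.flatnonzero(np.diff(s) > tol) + 1
    return np.array([c.mean() for c in np.split(s, splits)])


def count_levels(peaks: np.ndarray, tol: float = LEVEL_TOL_DEFAULT) -> int:
    """Number of peak levels resolved at tolerance ``tol``.

    A point cluster counts once; a band (the peak continuum of a chaotic
    orbit) counts once per ``tol`` of its width, so the count stays large
    no matter how densely the band is sampled.  A period-n limit cycle
    gives exactly n.
    """
    if len(peaks) == 0:
        return 0
    s = np.sort(np.asarray(peaks, dtype=float))
    splits = np.flatnonzero(np.diff(s) > tol) + 1
    return int(sum(1 + int((c[-1] - c[0]) / tol) for c in np.split(s, splits)))


def sweep(
    proto: SweepProtocol,
    p: ModelParams,
    dt: float = DT_DEFAULT,
    transient: float = TRANSIENT_DEFAULT,
    window: float = WINDOW_SWEEP_DEFAULT,
    level_tol: float = LEVEL_TOL_DEFAULT,
    compute_lyapunov: bool = False,
    lyapunov_t: float = 1000.0,
) -> BifurcationBranch:
    """Run one sweep protocol and collect the peak-based branch.

    A divergent grid point is recorded as missing (peak set ``None``,
    period count -1) and the sweep continues; in follow mode the seed then
    falls back to the protocol's initial condition.
    """
    ic = np.asarray(proto.ic, dtype=float)
    seed = ic.copy()
    peak_sets: list = []
    counts = np.empty(len(proto.values), dtype=int)
    les = np.full(len(proto.values), np.nan) if compute_lyapunov else None
    for k, val in enumerate(proto.values):
        pk = p.updated(**{proto.param_name: float(val)})
        x0 = ic if proto.ic_mode == "reset" else seed
        try:
            tr = integrate_fixed(x0, pk, transient + window, dt=dt, transient=transient)
        except DivergenceError:
            peak_sets.append(None)
            counts[k] = -1
            seed = ic.copy()
            continue
        peaks = extract_peaks(tr, coord=0)
        peak_sets.append(peaks.peak_values)
        counts[k] = count_levels(peaks.peak_values, tol=level_tol)
        if proto.ic_mode == "follow":
            seed = tr.final_state()
        if compute_lyapunov:
            les[k] = lyapunov_spectrum(
                tr.final_state(), pk, t_total=lyapunov_t, dt=dt, transient=0.0
            ).largest
    return BifurcationBranch(
        values=proto.values.copy(),
        peak_sets=peak_sets,
        period_counts=counts,
        largest_le=les,
        label=proto.label or f"{proto.param_name} {proto.direction} {proto.ic_mode}",
    )


def detect_bubbles(branch: BifurcationBranch) -> list[tuple[float, float]]:
    """Parameter intervals where the period count rises then falls back.

    A "bubble" (antimonotonicity) is a maximal interval over which the
    period-count sequence is unimodal — it increases from some base count,
    peaks strictly above it, and returns to the base count.  A monotone
    cascade that never reverses is not a bubble.
    """
    seq = branch.period_counts
    n = len(seq)
    if n < 20:
        raise ValueError("need at least 20 grid points to detect bubbles")
    out: list[tuple[float, float]] = []
    s = 0
    while s < n - 2:
        if seq[s] < 0:
            s += 1
            continue
        base = seq[s]
        # ascend (allowing plateaus)
        t = s
        while t + 1 < n and seq[t + 1] >= seq[t] and seq[t + 1] >= 0:
            t += 1
        if t == s or seq[t] <= base:
            s += 1
            continue
        # descend until back at (or below) base
        u = t
        e = -1
        while u + 1 < n and 0 <= seq[u + 1] <= seq[u]:
            u += 1
            if seq[u] <= base:
                e = u
                break
        if e > s:
            out.append((float(branch.values[s]), float(branch.values[e])))
            s = e
        else:
            s = t + 1
    return out


def _hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two finite point sets on the line."""
    if len(a) == 0 and len(b) == 0:
        return 0.0
    if len(a) == 0 or len(b) == 0:
        return np.inf
    d = np.abs(a[:, None] - b[None, :])
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()))


def hysteresis_windows(
    b_up: BifurcationBranch,
    b_down: BifurcationBranch,
    tol: float = 0.05,
) -> list[tuple[float, float]]:
    """Parameter intervals where two branches disagree (coexistence flags).

    The branches must cover the same grid (the downward one reversed).
    Disagreement at a grid point means the Hausdorff distance between the
    two x1 peak sets exceeds ``tol``; consecutive disagreeing points merge
    into one interval.
    """
    v_up = b_up.values
    v_dn = b_down.values[::-1]
    if len(v_up) != len(v_dn) or not np.allclose(v_up, v_dn):
        raise ValueError("branch grids do not match")
    peaks_dn = b_down.peak_sets[::-1]
    flagged = np.zeros(len(v_up), dtype=bool)
    for k in range(len(v_up)):
        a, b = b_up.peak_sets[k], peaks_dn[k]
        if a is None or b is None:
            flagged[k] = True
            continue
        flagged[k] = _hausdorff(np.asarray(a), np.asarray(b)) > tol
    out: list[tuple[float, float]] = []
    k = 0
    while k < len(flagged):
        if flagged[k]:
            j = k
            while j + 1 < len(flagged) and flagged[j + 1]:
                j += 1
            out.append((float(v_up[k]), float(v_up[j])))
            k = j + 1
        else:
            k += 1
    return out
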