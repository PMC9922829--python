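"""Attractor census, basins of attraction, and multistability control.

The unit of comparison is the :class:`AttractorFingerprint`: a compact,
deterministic descriptor of a post-transient orbit (time-averaged state,
bounding box, clustered x1 peak levels, and an equilibrium/cycle/chaotic
kind label).  Two orbits belong to the same attractor when their
fingerprints are closer than a merge tolerance under

    d(f, g) = max( |mean_f - mean_g|_2 , Hausdorff(peaks_f, peaks_g) )

Mirror-related attractors of the symmetric (i1 = 0) regime have distinct
fingerprints and are counted separately, matching the usual convention of
counting "eight coexisting attractors" from four +/- seed pairs.

Basins are rasterized on the (x1(0), x3(0)) initial-condition plane with
x2(0) fixed (default 0), labeling each cell by the attractor its orbit
converges to.  The linear-augmentation control sweep runs the census on
the 4D system over a grid of coupling strengths and reports the attractor
count as a function of phi, locating the onset of monostability.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .bifurcation import MAX_PERIODIC_LEVELS, cluster_levels, count_levels, _hausdorff
from .integrate import (
    DT_DEFAULT,
    TRANSIENT_DEFAULT,
    DivergenceError,
    Trajectory,
    extract_peaks,
    integrate_fixed,
)
from .model import ControlParams, ModelParams

__all__ = [
    "AttractorFingerprint",
    "CensusResult",
    "BasinGrid",
    "ControlSweepResult",
    "fingerprint",
    "fingerprint_distance",
    "census",
    "basin_grid",
    "basin_line",
    "control_sweep",
    "MERGE_TOL_DEFAULT",
    "WINDOW_CENSUS_DEFAULT",
]

#: Census merge tolerance in state units.
MERGE_TOL_DEFAULT = 0.05

#: Post-transient window used for censuses and basins.
WINDOW_CENSUS_DEFAULT = 1500.0

#: Bounding-box diameter below which an orbit is an equilibrium.
EQUILIBRIUM_DIAMETER = 1e-4


@dataclass(frozen=True)
class AttractorFingerprint:
    """Comparable descriptor of a settled orbit."""

    kind: str  # "equilibrium" | "cycle" | "chaotic"
    mean_state: np.ndarray
    peak_signature: np.ndarray  # sorted distinct x1 peak levels
    bounding_box: np.ndarray  # (2, d): per-coordinate min / max
    largest_le: float | None = None

    def mirrored(self) -> "AttractorFingerprint":
        """Fingerprint of the point-reflected orbit (x -> -x).

        x1 peaks of the mirrored orbit are the negated x1 *minima* of the
        original; the bounding box supplies them exactly only for the box
        corners, so the signature is rebuilt from the reflected peaks when
        comparing mirror pairs — here we negate means and boxes and leave
        signature matching to the census distance on actual orbits.
        """
        return AttractorFingerprint(
            kind=self.kind,
            mean_state=-self.mean_state,
            peak_signature=self.peak_signature.copy(),
            bounding_box=-self.bounding_box[::-1].copy(),
            largest_le=self.largest_le,
        )


@dataclass(frozen=True)
class CensusResult:
    """Grouping of initial conditions by attractor."""

    count: int
    groups: list  # list of member-index lists
    fingerprints: list  # one representative fingerprint per group
    members: np.ndarray  # group index per IC; -1 for divergent/excluded
    merge_tol: float


@dataclass(frozen=True)
class BasinGrid:
    """Raster of attractor labels over an IC plane.

    ``labels[i, j]`` is the legend index of the cell at
    (axis0_values[i], axis1_values[j]); -1 marks escaping orbits.
    """

    axes: tuple[str, str]
    axis_values: tuple[np.ndarray, np.ndarray]
    fixed_coords: dict
    labels: np.ndarray
    legend: list  # AttractorFingerprint per label


@dataclass(frozen=True)
class ControlSweepResult:
    phis: np.ndarray
    counts: np.ndarray
    onset_phi: float | None  # smallest phi with a single surviving attractor


def fingerprint(
    tr: Trajectory,
    level_tol: float = 1e-2,
    largest_le: float | None = None,
) -> AttractorFingerprint:
    """Descriptor of the post-transient part of ``tr``.

    Requires a reasonably long window (>= ~1000 time units recommended) so
    time averages and peak sets are stationary; fingerprints of different
    sub-windows of the same settled orbit then agree within the census
    tolerance.
    """
    post = tr.post[:, :3]
    if len(post) < 2:
        raise ValueError("trajectory has no post-transient window")
    box = np.vstack([post.min(axis=0), post.max(axis=0)])
    diameter = float(np.linalg.norm(box[1] - box[0]))
    mean_state = post.mean(axis=0)
    if diameter < EQUILIBRIUM_DIAMETER:
        return AttractorFingerprint(
            kind="equilibrium",
            mean_state=mean_state,
            peak_signature=np.empty(0),
            bounding_box=box,
            largest_le=largest_le,
        )
    peaks = extract_peaks(tr, coord=0)
    signature = cluster_levels(peaks.peak_values, tol=level_tol)
    n_levels = count_levels(peaks.peak_values, tol=level_tol)
    if n_levels > MAX_PERIODIC_LEVELS or (largest_le is not None and largest_le > 1e-2):
        kind = "chaotic"
    else:
        kind = "cycle"
    return AttractorFingerprint(
        kind=kind,
        mean_state=mean_state,
        peak_signature=signature,
        bounding_box=box,
        largest_le=largest_le,
    )


def fingerprint_distance(f: AttractorFingerprint, g: AttractorFingerprint) -> float:
    """Census metric: max of mean-state distance and peak-set Hausdorff.

    An equilibrium (empty peak signature) is infinitely far from any
    oscillating orbit, so kinds never merge across the
    equilibrium/oscillation divide.
    """
    d_mean = float(np.linalg.norm(f.mean_state - g.mean_state))
    d_peaks = _hausdorff(f.peak_signature, g.peak_signature)
    return max(d_mean, d_peaks)


def _single_linkage(fps: list, merge_tol: float) -> tuple[np.ndarray, int]:
    """Union-find single-linkage grouping under the census metric."""
    n = len(fps)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if fingerprint_distance(fps[i], fps[j]) <= merge_tol:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    roots = {}
    labels = np.empty(n, dtype=int)
    for i in range(n):
        r = find(i)
        labels[i] = roots.setdefault(r, len(roots))
    return labels, len(roots)


def census(
    p: ModelParams,
    ics,
    merge_tol: float = MERGE_TOL_DEFAULT,
    dt: float = DT_DEFAULT,
    transient: float = TRANSIENT_DEFAULT,
    window: float = WINDOW_CENSUS_DEFAULT,
    control: ControlParams | None = None,
) -> CensusResult:
    """Count the distinct attractors reached from a list of ICs.

    Each IC is integrated past the transient, fingerprinted over the
    analysis window, and the fingerprints are merged by single linkage at
    ``merge_tol``.  With ``control`` given, ICs are 4-vectors integrated in
    the augmented system and fingerprinted on their (x1, x2, x3)
    projection.  Divergent ICs are excluded with a warning.
    """
    ics = [np.asarray(ic, dtype=float) for ic in ics]
    if len(ics) == 0:
        raise ValueError("need at least one initial condition")
    fps = []
    ok_idx = []
    for i, ic in enumerate(ics):
        try:
            tr = integrate_fixed(ic, p, transient + window, dt=dt,
                                 transient=transient, control=control)
        except DivergenceError as err:
            warnings.warn(f"IC {ic} diverged ({err}); excluded from census")
            continue
        fps.append(fingerprint(tr))
        ok_idx.append(i)
    members = np.full(len(ics), -1, dtype=int)
    if not fps:
        return CensusResult(0, [], [], members, merge_tol)
    labels, count = _single_linkage(fps, merge_tol)
    for pos, i in enumerate(ok_idx):
        members[i] = labels[pos]
    groups = [[] for _ in range(count)]
    reps: list = [None] * count
    for pos, i in enumerate(ok_idx):
        groups[labels[pos]].append(i)
        if reps[labels[pos]] is None:
            reps[labels[pos]] = fps[pos]
    return CensusResult(count, groups, reps, members, merge_tol)


def _label_against_legend(fp, legend: list, merge_tol: float) -> int:
    best, best_d = -1, np.inf
    for k, ref in enumerate(legend):
        d = fingerprint_distance(fp, ref)
        if d < best_d:
            best, best_d = k, d
    if best_d <= merge_tol:
        return best
    legend.append(fp)
    return len(legend) - 1


def basin_grid(
    p: ModelParams,
    x1_range=(-3.0, 3.0),
    x3_range=(-6.0, 6.0),
    resolution: int = 200,
    x2_fixed: float = 0.0,
    merge_tol: float = MERGE_TOL_DEFAULT,
    dt: float = DT_DEFAULT,
    transient: float = TRANSIENT_DEFAULT,
    window: float = WINDOW_CENSUS_DEFAULT,
    legend: list | None = None,
) -> BasinGrid:
    """Rasterize basins of attraction on the (x1(0), x3(0)) plane.

    Each cell's orbit is fingerprinted and matched to the nearest legend
    entry within ``merge_tol`` (the legend grows when nothing matches, and
    may be pre-seeded with census fingerprints so labels align with a
    census).  Deterministic for a given grid.  Escaping orbits get -1.
    """
    if resolution < 16:
        raise ValueError("resolution must be at least 16 per axis")
    x1s = np.linspace(*x1_range, resolution)
    x3s = np.linspace(*x3_range, resolution)
    legend = list(legend) if legend is not None else []
    labels = np.full((resolution, resolution), -1, dtype=int)
    for i, x1 in enumerate(x1s):
        for j, x3 in enumerate(x3s):
            try:
                tr = integrate_fixed((x1, x2_fixed, x3), p, transient + window,
                                     dt=dt, transient=transient)
            except DivergenceError:
                continue
            labels[i, j] = _label_against_legend(fingerprint(tr), legend, merge_tol)
    return BasinGrid(
        axes=("x1", "x3"),
        axis_values=(x1s, x3s),
        fixed_coords={"x2": x2_fixed},
        labels=labels,
        legend=legend,
    )


def basin_line(
    p: ModelParams,
    x3_range=(-2.0, 2.0),
    resolution: int = 64,
    x1_fixed: float = 0.0,
    x2_fixed: float = 0.0,
    merge_tol: float = MERGE_TOL_DEFAULT,
    dt: float = DT_DEFAULT,
    transient: float = TRANSIENT_DEFAULT,
    window: float = WINDOW_CENSUS_DEFAULT,
) -> tuple[np.ndarray, np.ndarray, list]:
    """1D basin slice along x3(0) at fixed x1(0), x2(0).

    Returns ``(x3_values, labels, legend)``; label changes along the line
    count basin boundaries crossed.
    """
    if resolution < 64:
        raise ValueError("resolution must be at least 64 for a 1D slice")
    x3s = np.linspace(*x3_range, resolution)
    legend: list = []
    labels = np.full(resolution, -1, dtype=int)
    for j, x3 in enumerate(x3s):
        try:
            tr = integrate_fixed((x1_fixed, x2_fixed, x3), p, transient + window,
                                 dt=dt, transient=transient)
        except DivergenceError:
            continue
        labels[j] = _label_against_legend(fingerprint(tr), legend, merge_tol)
    return x3s, labels, legend


def control_sweep(
    p: ModelParams,
    phis,
    ics,
    eps: float = 0.5,
    gamma: float = 8.0,
    merge_tol: float = MERGE_TOL_DEFAULT,
    dt: float = DT_DEFAULT,
    transient: float = TRANSIENT_DEFAULT,
    window: float = WINDOW_CENSUS_DEFAULT,
) -> ControlSweepResult:
    """Attractor count vs coupling strength for linear-augmentation control.

    The 3-component ICs are augmented with x4(0) = 0; for each phi the
    census runs on the 4D system (fingerprinted on the network projection).
    Reports count(phi) and the smallest phi at which a single attractor
    survives, if monostability is reached on the grid.
    """
    phis = np.asarray(phis, dtype=float)
    ics4 = [np.append(np.asarray(ic, dtype=float), 0.0) for ic in ics]
    counts = np.empty(len(phis), dtype=int)
    onset = None
    for k, phi in enumerate(phis):
        c = ControlParams(phi=float(phi), eps=eps, gamma=gamma)
        res = census(p, ics4, merge_tol=merge_tol, dt=dt, transient=transient,
                     window=window, control=c)
        counts[k] = res.count
        if onset is None and res.count == 1:
            onset = float(phi)
    return ControlSweepResult(phis=phis, counts=counts, onset_phi=onset)
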