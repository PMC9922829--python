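# Methods

## Model and conventions

The package studies the three-neuron continuous-time Hopfield network

    C_i dx_i/dt = −x_i/R_i + Σ_j w_ij tanh(β_j x_j) + I_i,   C_i = R_i = 1,

with weight matrix w = [[2, −1.2, 0.48], [3.6, 1.7, 1.076], [−9, 0, 0]],
activation gradients β = (β1, β2, β3) = (0.9, β2, 1.4), and bias current
I = (i1, 0, 0).  All quantities are dimensionless; "time" means the model
time of these equations.  β2 is the principal bifurcation parameter
(typically scanned over [1, 2]); the weights w11 and w23 are exposed as
configuration because the bursting and bubbling regimes modify them
(w11 ∈ {2, 2.33}, w23 ∈ {1, 1.076}).  For i1 = 0 the field is odd, so
every statement about an attractor applies equally to its mirror image
x → −x; mirror partners are counted as separate attractors throughout,
which is the convention behind "eight coexisting attractors".

Because each tanh is bounded and every state carries a −x leak, all
trajectories enter an absorbing ball: the system is dissipative
(trace J = Σ w_jj β_j sech² − 3 ≤ 2β1 + 1.7β2 − 3 for the default signs)
and cannot diverge.  The integrator nevertheless guards against blow-up
(bound 1e6) so that misconfigured weight sets fail loudly.

## Two Jacobian variants

`jacobian_true` is the analytic derivative of the vector field,
J_jk = −δ_jk + w_jk β_k sech²(β_k x_k).  It drives everything dynamical:
tangent evolution for Lyapunov spectra, dissipativity checks, stability of
equilibria under the actual flow.

`jacobian_printed` differs in the single entry (2,2), where the recurrent
synaptic term of neuron 2 enters with flipped sign:
J_22 = −w22 β2 sech²(β2 x2) − 1.  Published stability tables for this
model follow that variant (its origin eigenvalues 0.0182, −2.0541 ±
2.8082i are reproduced here to four decimals; the analytic variant gives
different values and, at the nontrivial equilibria, the opposite stability
verdict — a saddle-focus with eigenvalues 1.20 ± 2.30i, −0.998 instead of
a stable point).  The variant is therefore kept strictly for reproducing
those classifications and is never used in simulation-side computations.
Likewise, in its third row the coefficient is taken as 9β1 (not 9β3): only
that reading reproduces the tabulated origin eigenvalue.

## Equilibria

Fixed points satisfy x3 = −9 tanh(β1 x1) (the third neuron receives no
lateral or recurrent input) and tanh(β2 x2) = (−x1 + 2 tanh(β1 x1)
+ 0.48 tanh(β3 x3) + i1)/1.2.  The second relation is solvable for real
x2 only while its right-hand side lies strictly inside (−1, 1); outside,
the analytic continuation picks up the artanh branch offset iπ/(2β2)
(= 0.9240i for β2 = 1.7), which is where complex-coordinate "equilibria"
live.  The solver scans the residual of the remaining equation on a
10⁴-point grid over x1 ∈ [−6, 6] (covering every real root with wide
margin), refines each sign-change bracket with Brent's method to
|S| < 1e−10, and reports inadmissible intervals separately rather than
continuing into the complex domain.  Eigenvalue real parts within 1e−9 of
zero are labeled "marginal" instead of stable/unstable.

## Integration and analysis windows

Classic fixed-step RK4 at dt = 0.005 reproduces an adaptive DOP853
reference (rtol 1e−10) to better than 1e−3 at t = 20 across random initial
conditions and to ~1e−4 on smooth orbits at t = 100; the observed
Richardson convergence order exceeds 3.5.  Defaults for statistics: the
first 500 time units are discarded as transient (the slowest equilibrium
decay rates are O(1e−2), so this leaves two orders of magnitude of
margin); analysis windows are 1500 time units for censuses and basins and
300 for bifurcation scans, where only the peak-level structure matters.
All are configurable; the test suite uses shorter windows where a
structural property (not attractor identity) is being checked.

Peak extraction takes strict local maxima (plateaus count once, at their
first sample) with optional parabolic refinement through the three samples
around each peak.

## Peak levels and chaos labeling

Peak values are clustered with absolute gap tolerance 1e−2.  The number of
*levels* is counted at that resolution: a point cluster counts once, a
band of width W counts 1 + floor(W/tol) times.  (Counting clusters alone
is not stable: a chaotic band looks like many clusters when sparsely
sampled and like one wide cluster once the window fills it in.)  An orbit
is labeled chaotic when it resolves more than 32 levels or when its
largest Lyapunov exponent exceeds 1e−2; the labels are descriptive only
and never enter any reported number.

## Lyapunov spectra

Benettin's method: the 3×3 tangent frame is co-integrated with the flow
(variational equation with the analytic Jacobian, same RK4 step) and
re-orthonormalized by QR every 1.0 time units, accumulating log |R_ii|.
Averaging starts after the standard transient and runs for a few thousand
time units.  Consistency checks built into the tests: at a flow-stable
equilibrium the exponents equal the Jacobian eigenvalue real parts (to
5e−2 over a 2000-unit average); on any bounded orbit the exponent sum
equals the time-averaged Jacobian trace (Liouville, to 2%); on a limit
cycle the largest exponent vanishes (|λ1| < 5e−3); estimates move by less
than max(10%, 5e−3) when the renormalization interval is halved or
doubled.

## Bifurcation sweeps

A sweep integrates the network at each grid value and records the set of
post-transient x1 peaks.  Two seeding conventions are supported and both
are needed to expose coexistence: *reset* (same initial condition at every
grid point — probes one basin) and *follow* (each point seeded with the
previous endpoint — attractor continuation).  Hysteresis windows are grid
intervals where the upward and downward branches differ by more than 0.05
in Hausdorff distance between peak sets.  Period bubbles
(antimonotonicity) are maximal intervals where the level-count sequence
rises from a base value and returns to (or below) it; the relaxation "or
below" absorbs off-by-one clustering at the reclosing edge.  Default
sweep resolution is 500 points; structural tests use coarser grids since
the detected features (windows, bubbles) are interval-valued, not
point-valued.

## Attractor census, basins, control

An orbit's fingerprint is (kind, time-averaged state, clustered x1 peak
levels, bounding box).  Census distance is the maximum of the
mean-state Euclidean distance and the symmetric Hausdorff distance of the
peak-level sets; an equilibrium (empty peak set) is infinitely far from
any oscillating orbit.  Fingerprints are merged by single linkage at
tolerance 0.05 (state units); the count is the number of groups.  The
count is non-increasing in the merge tolerance, and duplicated seed lists
cannot change it.

Basins are rasterized on the (x1(0), x3(0)) plane with x2(0) = 0 (the
plane the seed lists live in); default extents x1(0) ∈ [−3, 3],
x3(0) ∈ [−6, 6] cover all preset seeds.  Cells are labeled against a
growing legend (optionally pre-seeded with census fingerprints so labels
align); escaping orbits would receive −1.

The control sweep appends x4(0) = 0 to each seed, integrates the 4D
augmented system for each coupling strength φ on a grid in [0, 0.29]
(ε = 0.5, γ = 8), fingerprints the (x1, x2, x3) projection, and reports
count(φ) plus the smallest φ with a single surviving attractor.  At the
standard eight-attractor condition (β2 = 1.182) the computed count falls
monotonically and reaches monostability at φ ≈ 0.05.

## Synthetic data and what the tests show

There is no external data; the "study conditions" are named presets
holding exact parameter values and seed lists (censuses at β2 ∈ {1.182,
1.183, 1.206, 1.636} with i1 = 0 and β2 ∈ {1.114, 1.173, 1.175} with
i1 = 0.001; bursting at (β2, w23) = (1.41, 1), (β2, w11) = (1.78, 2),
(1.05, 2.33); the control condition; bias values i1 ∈ {0, 0.4, 0.8}).
Seeded uniform initial-condition sampling supports property tests.
Passing tests demonstrate properties of this deterministic model under
these conditions — they say nothing about robustness to noise,
parameter mismatch, or unmodeled dynamics, none of which the generator
emulates.

## Bursting detection

The bursting seen in this network is amplitude-modulated spiking: the
spike amplitude swells and collapses cyclically but the quiescent phase
is not silent.  The detector therefore works on the modulation of the
envelope (moving peak-to-peak amplitude over two spike periods, the spike
period being the median inter-peak interval): a trace is bursting when
the envelope's modulation depth 1 − env_min/env_max exceeds 0.5 *and*
lower-band epochs (envelope in the lower 30% of its range) alternate with
high-amplitude epochs at least twice each, every epoch at least one spike
period long.  Sinusoids and plain limit cycles (near-constant envelope,
depth ≲ 0.3 in this model) are never flagged; a single transient dip
fails the recurrence requirement.  The depth and band thresholds are
conventions of this package; the measured depths in the bursting regimes
(0.57–0.81) sit well clear of the 0.5 threshold.

## Known limitations and deliberate scope

- Fixed 3-neuron topology (plus one control variable); no general N-neuron
  network, no stiff/implicit solvers, no continuation of cycles, no
  fractal basin-boundary measures, and no Kaplan–Yorke dimension.
- Equilibria are computed at discrete bias values; no branch tracking in
  i1.
- Seed-to-attractor assignment near intertwined basin boundaries is
  sensitive to integrator details.  At β2 = 1.175, i1 = 0.001 the seeds
  (0, 0, 0.55) and (0, 0, 0.7) both converge to the same period-15 cycle
  (confirmed by the adaptive reference integrator), so the census from
  that seven-seed list yields six distinct attractors even though a
  seventh attractor (a period-7 cycle nearby in state space) exists and
  is reachable from the same seed at finer step sizes.  The census
  reports what the prescribed protocol actually finds.
- The φ-boundaries between intermediate multistability regimes in the
  control sweep are reported as computed; only the qualitative
  8-to-1 collapse and its onset are treated as conclusions.
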