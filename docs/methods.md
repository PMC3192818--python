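# Methods

This note documents the models and numerical procedures implemented in
`cmenoise`, the choices made where the design was genuinely open, and
what the shipped tests do and do not establish.

## State spaces and truncation

All computations live on a rectangular integer lattice `[0, upper_i]`
per species.  Transitions that would leave the box are assigned zero
rate.  This reflecting truncation keeps every column of the rate matrix
summing to zero, so probability is conserved exactly and the truncation
error is controlled purely by the bounds.  The toggle-switch default is
`(60, 60)`, chosen so that the boundary mass is below 1e−8; doubling the
bounds moves the reported statistics by less than 1e−4 (tested).  The T7
circuit uses `t7 ≤ 60` against an ON mode near 29 ± 5.  A hard guard
refuses to enumerate more than 5·10⁶ lattice points and points the user
at scaling or sampling instead.

## The steady-state solve

The generator `M` accumulates `a_j(x)·kernel_j(x→x′)` per reaction;
fixed-change reactions are degenerate kernels.  The steady state is the
one-dimensional null space of `M`, computed by replacing the last
balance row with the normalization row `Σ P = 1` and solving the sparse
system with `scipy.sparse.linalg.spsolve`.  This is deterministic and
needs no eigensolver tuning.  Safeguards: a singular factorization or a
negative entry below −1e−12 (relative) raises with a bounds-check hint
(the usual cause is a chain disconnected by the truncation); entries in
(−1e−12, 0) are clipped and the vector renormalized; the residual
`max|M P|` must be ≤ 1e−9.

## Rescaled CME

For large copy numbers the lattice is coarsened to multiples of an
integer scale factor `S`: each fixed-change reaction moves a coarse
point `x` to `x + S·v_j` at its original propensity `a_j(x)` (evaluated
at the source point, not a midpoint).  Jump-kernel reactions are
rejected for `S > 1` since their destinations need not lie on the coarse
lattice.  Properties that pin this construction down:

* at `S = 1` it reproduces the unscaled generator bit-exactly (same
  assembly code path);
* for the birth–death chain the coarse detailed-balance ratio is
  `P(n)/P(n−S) = k_s/(k_d n)`, which crosses 1 at `n = k_s/k_d`, so the
  peak stays at the rate ratio for every `S`.  At that crossing the two
  neighbouring coarse points tie exactly, so "the peak" is a two-point
  plateau up to roundoff — tests assert near-equality with the maximum
  rather than an argmax index.

The solved coarse vector is exposed in two views: `mass` (the aggregated
probability of the `S^d` fine states a coarse point stands for, summing
to 1) and `density` (`mass/S^d`, the per-fine-state view).  The
aggregation premise is slow variation of `P` between neighbouring coarse
points; accordingly the coarse solution converges to the bin-aggregated
exact distribution as copy numbers grow at fixed `S` (tested on Poisson
targets, λ ∈ {100, 400, 1600} at S = 4, monotone).  Growing `S`
proportionally to λ does *not* converge — the lattice spacing then grows
faster than the peak width (∝ √λ) and under-resolves it.  A single
global `S` is supported; region-dependent scales are out of scope.

## Modified Gibbs sampling

**Conditionals.** The conditional along an ordered lattice line is built
by chaining ratios between consecutive points.  Each inter-point step is
decomposed into unit axis moves in fixed species order (first species
axis first); a unit up-move in species `i` at state `x` contributes the
factor `a_s,i(x)/a_d,i(x + e_i)`, where `a_s,i`/`a_d,i` sum the
propensities of reactions changing species `i` by exactly +1/−1.  For a
1-D birth–death chain this is the exact stationary distribution; in
general it is the detailed-balance approximation, and for rotated lines
the decomposition is additionally path-ordered (the path dependence is
part of the method's approximation error).  Accumulation is in log
space.  Degenerate rates: zero degradation against positive synthesis
sends the log-ratio to +∞, i.e. the mass accumulates at the line's
boundary point; both channels zero terminates the line (zero mass
beyond).

**Rotation.** Each cycle draws an angle φ uniform on (−90°, 90°) and
uses slope `m = tan φ` and its perpendicular `−1/m` to build two rounded
lattice lines through the current point (the second re-anchored at the
point sampled from the first).  `m = 0` reproduces the coordinate axes;
|m| beyond 1e9 is treated as the swapped axis-aligned pair.  In more
than two dimensions one random species pair is rotated per cycle and the
remaining coordinates are sampled axis-aligned.  Lines span the full box
(bounds here are ≤ a few hundred points, so no outward-walk cutoff is
needed).

**Stationarity.** The rotation makes the proposal symmetric, so a sample
from the target distribution remains one after a cycle *provided the
conditionals are exact*.  That premise holds for product-form networks
(e.g. two independent birth–death species), where a one-cycle chi-square
test at n = 50,000 shows no detectable drift (p ≈ 0.3).  On the toggle
switch the conditionals are approximate — the package's
`detailed_balance_error` diagnostic (the P-weighted mean of
`|r_DB − r_true|/r_true` per species over states where both ratios are
defined, weights renormalized) is 0.25 for U and 0.58 for V on the
asymmetric set — so the sampler's stationary law differs measurably from
the exact solution; its sum of squared deviations against the direct
solve is ~1.3e−2 at 10,000 samples, while two independent runs agree at
~6e−4.  This mirrors the accuracy/efficiency trade the method makes.

**Defaults.** Burn-in 1000 cycles; initialization at a stable fixed
point of the deterministic rate equations (found by damped iteration of
the drift `Σ a_j(x)·v_j` from the box corners and centre, filtered by the
Jacobian's eigenvalues; jump-kernel reactions do not contribute to the
drift).  Separate per-mode chains pooled by user-supplied weights are
available for systems whose modes are effectively disconnected.

**Mixing.** On the symmetric toggle the rotated sampler crosses between
modes roughly eight times as often as axis-aligned Gibbs (ratio ~0.12;
~0.015 for a deeper-valley variant at r = 20), and it occupies the two
modes 0.50 ± 0.05 at 20,000 samples.  At these modest copy numbers
axis-aligned Gibbs still equilibrates eventually; the advantage of
rotation grows with mode separation.

## Extrinsic noise

`convolve_grid` computes `(1 − a)·(P * M₀) + a·B`.  The kernel is the
multivariate normal density evaluated at integer offsets over ±⌈6σ⌉,
normalized to sum 1, and *boundary-renormalized per source state*: the
output is `conv(P/Z, K)` with `Z = corr(1, K)`, which conserves mass
exactly on the truncated box.  Direct summation and an FFT path agree to
1e−10 and are both exposed.  Per-mode covariances partition the grid by
nearest mode centre (Euclidean distance in molecule units) before
convolving.  The background `B` defaults to uniform over the box.

`shift_samples` adds an independent zero-mean normal shift per sample,
clips negative components to zero, and (optionally) rounds; with
background weight `a`, `round(n·a/(1−a))` extra background draws are
appended.  Clipping and kernel renormalization treat the boundary
differently by construction: for distributions hugging an axis the two
routes diverge as σ grows (SSD ≈ 3e−3 at σ = 2 on the toggle, ≈ 1e−3 at
σ = 1, ≈ 1e−5 for interior-supported distributions).  This is a
documented modeling choice, not a numerical defect.

`gamma_mixed_birth_death` is the closed-form gamma–Poisson
(negative-binomial) mixture, mean `αθ` and variance `αθ(1 + θ)`, checked
against direct quadrature to 1e−8.  `fit_extrinsic_sigma` minimizes the
unweighted least-squares distance between `convolve_grid(P, σ)` and a
target (bounded scalar search; optionally a Nelder–Mead co-fit of a
scalar mean shift, initialized from moment matching).  Unweighted least
squares is a declared choice; fitted widths for the gamma-mixture
targets (4.36 and 6.16 for Γ(20,1) and Γ(10,2) against Poisson(20)) are
therefore soft values that depend mildly on the objective.

## Built-in circuits

**Toggle switch.** Synthesis `r_u/(1 + (v/K_v)^β)` for U and
`r_v/(1 + (u/K_u)^γ)` for V (each protein repressed by the other), linear
degradation.  The antibiotic perturbation replaces V's degradation
constant by `d_v0 + d_v1·A/(A + k_A)`.  The Hill convention — `K_v`
gates repression *of U by V* — matters only for asymmetric parameter
sets.

**T7 circuit.** State `(n, m)`: free T7 RNAP and inactive promoters
(of `M` total).  Five chemical reactions (basal synthesis `k_0·m`,
active synthesis `k_1·(M − m)`, activation `k_f·m·n`, deactivation
`k_b·(M − m)`, degradation `d_x0·n`) plus division as a jump reaction
with propensity `μ/(1 + n/θ)` — fast growth at low T7 burden — whose
kernel draws the surviving free count from Binomial(n, ½) and resets all
promoters to the inactive state.  Two conventions needed resolving:

* active-promoter synthesis scales with the *active* count `M − m`
  (with `k_1·m` the positive feedback vanishes and the distribution is
  monomodal for all printed parameter sets);
* promoter-bound T7 is discarded at division (the binomial acts on the
  free count only).  Returning bound molecules to the pool before
  partitioning raises the ON fractions by tens of percentage points and
  is inconsistent with the reproduced values.

The `μ` in the division propensity is the *effective* growth rate of the
log-phase window being modeled (the population growth rate scaled by
unused capacity); the pseudo-steady state treats it as constant.  With
`μ = 0` the OFF mode loses its persistence mechanism and the solution is
monomodal (tested).

## Partition rules and distances

The toggle ON fraction is the mass where the monitored protein
outnumbers the other, with the tie diagonal split 50/50 (exposed as an
option; a fully symmetric circuit then scores exactly 50%).  The
1-D valley rule finds the two most prominent local maxima (plateaus
merged, represented by their leftmost bin), takes the lowest bin strictly
between them as the ON/OFF border, and counts the mass strictly above
the border as ON — the border bin itself is OFF.  If only one peak
exists, the border is the point of smallest finite-difference magnitude
(shoulder rule).  Distributions are compared by the sum of squared
deviations over states (SSD, at most 2 for disjoint point masses);
samples are histogrammed onto the lattice first.

## Gillespie oracle

The direct-method simulator (exponential waiting times from the total
propensity, proportional reaction choice, jump kernels sampled) is kept
as an independent check: its time-weighted occupancy after a 10% burn-in
matches the direct steady state with SSD ≤ 0.01 at t = 1e5 on every
built-in model (tested; typical values are 1e−4 to 2e−3).  States that
leave the analysis box are binned into the nearest boundary cell and the
excess residence fraction reported.  An all-zero propensity state is
absorbing: the trajectory flags it and holds the state to the horizon.
Per-network rate functions are generated and compiled once with
parameters inlined, keeping the event loop at a few microseconds per
event.

## Problem sizes and determinism

The shipped computations are desk-scale by design: 3721 states for the
toggle, 671 for the T7 circuit, ≤ 201 coarse points for the scaled
examples, 10⁴–10⁵ Gibbs cycles and ~10⁶–4·10⁶ simulation events in the
heaviest checks.  Every stochastic routine takes an explicit seed and is
bit-reproducible under it; the CLI records seeds and settings in a
`.meta.json` sidecar next to each artifact.

## Known limitations

* The detailed-balance conditional restricts MGS accuracy on networks
  that violate detailed balance; the error diagnostic quantifies this
  per species but no correction is applied.
* Rotated-line conditionals are path-ordered (species order within each
  inter-point step); alternative orders give slightly different
  conditionals, a component of the method's approximation error.
* Extrinsic-noise boundary handling differs between the grid route
  (renormalization) and the sample route (clipping); near lattice
  boundaries with large σ the routes diverge.
* Model files support a single global scale factor; mixed per-region
  scaling and time-dependent propensities are not implemented.
* `deterministic_fixed_points` uses damped fixed-point iteration, which
  is robust for the shipped circuits but not guaranteed to find all
  stable states of arbitrary stiff networks.
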