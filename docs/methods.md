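# Methods

## Model

`nfsom` simulates a self-organizing map driven by an Amari-type neural
field on a compact domain Ω = [a, b]^q (q = 1 or 2; the reference
experiments use the unit square).  The state is the membrane potential
u(r, t) and the feed-forward weight field (codebook) w_f(r, t) ∈ [0, 1]^m:

    τ ∂u/∂t  = −u + ∫_Ω w_l(|r − r′|) f_l(u(r′, t)) dr′ + f_s(w_f − s(p)),
    ∂w_f/∂t  = γ (s(p) − w_f) ∫_Ω w_e(|r − r′|) f_e(u(r′, t)) dr′,

with f_l = f_e = rect (rectification) and f_s(x) = 1 − |x|₁/m by default;
arbitrary Lipschitz activations can be injected through `ModelParams`.  The
lateral kernel is a difference of Gaussians
w_l(x) = K_e e^{−x²/2σ_e²} − K_i e^{−x²/2σ_i²}.  Stimuli are 2-D points
p ~ U(0,1)² presented one per epoch (online learning); the mapping s is the
identity.  Within an epoch the coupled system is integrated with forward
Euler for a fixed horizon, then the field is reset to zero exactly; the
codebook carries over between epochs.

The codebook-to-stimulus drive I = 1 − |w_f − s(p)|₁/m plays the role of
the SOM distance computation, the localized activity disc around the
best-matching region plays the role of the neighborhood function (fixed
width, set by the lateral kernel), and the excitatory drive
E(r) = ∫ w_e rect(u) dr′ gates an Oja-like pull of each codebook vector
toward the stimulus.

## Discretization and the two lateral-term conventions

Ω is discretized on n nodes per side at a + i·(b−a)/n, i = 1..n (40×40 in
the reference experiments).  The discrete lateral term admits two
normalizations, and the package implements both
(`ModelParams.conv_norm`):

* **`"sum"` (default, used for training).**  The unweighted node sum
  Σ_{r′} w(|r − r′|) g(r′).  At 40×40 this gives the lateral coupling an
  O(10²) gain: the field solves into a localized winner disc — positive on
  ~1% of nodes, strongly negative elsewhere — so rectification confines
  learning to a compact neighborhood of the best-matching unit.  This is
  the regime in which self-organization actually happens: the codebook
  unfolds from its near-zero initialization onto the input square within a
  few hundred epochs.  It reproduces the reference stable-regime results
  (declining distortion reaching the 10⁻³ scale, δx–δy slope near one).
* **`"integral"`.**  The cell-measure-weighted quadrature
  ((b−a)/n)^q Σ w g, the convention in which the continuous-domain
  stability conditions are stated.  Under it the lateral term for the
  reference kernels has gain ~0.05; the field is a smooth, almost uniform
  profile with no rectification cut, every node learns every stimulus at
  nearly the same rate, and the codebook contracts to the input centroid
  instead of unfolding — under the exact reference dynamics, at 16×16 and
  at 40×40 alike.  This convention is retained for the single-step
  operations, the equilibrium solver, the Lyapunov monitor and everything
  in the stability module, where consistency with the analytical
  conditions is what matters.

The split mirrors the model's own usage: its analysis is
continuous-normalized, while the phenomenology (a winner disc confining
learning, with the rest of the sheet silent) belongs to the discrete-sum
system.  A consequence of the `"sum"` convention is that the lattice
resolution is part of the model, not merely an accuracy knob: shrinking
the grid shrinks the lateral gain and changes the regime, which is why the
package never scales tests down by coarsening the grid.

Convolution is *linear* (zero-padded), never circular — the integral runs
over compact Ω only, and wrap-around would couple opposite edges.  Two
equivalent backends: an FFT path (real transforms of size ≥ 2n per axis,
alias-free for the retained central block) and a dense matrix path that is
faster below ~1000 nodes.  Both agree with the naive O(k²) double sum to
machine precision and are cross-checked in the tests.

## Time stepping

Forward Euler with one shared step dt for both equations; field and
weights advance from the same pre-step state (simultaneous explicit
Euler), so the two lateral integrals per step share one forward FFT of
rect(u).  Sequential ordering would differ at O(dt²), below solver
tolerance at dt = 0.015.  The input drive I is recomputed at every Euler
step from the evolving codebook.  dt and the per-epoch horizon t share one
time unit (steps per epoch = floor(t/dt), e.g. 1666 at t = 25): labelling
dt in milliseconds and t in seconds would be inconsistent with τ = 1.0
driving visible within-epoch dynamics.  If the field becomes non-finite or
exceeds 10⁶, integration aborts with a structured error carrying epoch and
step — the expected outcome in strongly unstable regimes, reported as a
distinct run status.

## Stability conditions

Local exponential stability of (u*, w_f* = s(p)) is guaranteed by (i) the
spatial L2 norm of the lateral kernel, w̄_l = sqrt(∫∫ w_l²), below 1/ℓ_l
(ℓ_l = 1 for rect), and (ii) the excitatory drive at the equilibrium,
inf_r ∫ w_e rect(u*), strictly positive.  On a square domain the double
integral has a closed form in the Gauss error function through
ξ_{a,b}(σ) — the squared 1-D Gaussian-overlap integral — giving

    K_e² ξ(σ_e/√2) + K_i² ξ(σ_i/√2) − 2K_eK_i ξ(σ_eσ_i/√(σ_e²+σ_i²)) < 1.

The module evaluates both the closed form (scipy's erf; the classical
4-term rational approximation with |error| ≤ 5×10⁻⁴ is provided as a
cross-check) and the dense lattice quadrature of the double integral,
which collapses the O(k²) pairwise sum to the (2n−1)^q displacement table
via the displacement-multiplicity identity and converges to the closed
form as the grid refines (0.1% at 40×40).  Condition (ii)'s infimum is
approximated by the minimum over lattice nodes.  For the reference
parameter sets the left-hand side evaluates to 0.49 (stable, K_e = 0.90,
K_i = 0.86) and 5.19 (unstable, K_e = 3.0, K_i = 2.80).  u* solves
u = 1 + ∫ w_l rect(u) by Picard iteration from u ≡ 1 (a contraction
exactly when condition (i) holds) to a sup-residual below 10⁻¹²; a
Krylov root-finder reproduces it in the tests.

## Map-quality metrics and how to read P

* **Distortion** 𝒟: mean squared Euclidean distance from samples to their
  nearest codebook vector.  The per-epoch trace scores the codebook
  against the cumulative set of stimuli presented so far; final values use
  the full training sample set.  A perfect n×n map over U(0,1)² floors at
  ≈ h²/6, h = 1/n (1.0×10⁻⁴ at 40×40); trained maps land in the low 10⁻³
  range because of boundary contraction and learning jitter.
* **δx–δy representation**: Euclidean pairwise codebook distances (δx)
  against matching lattice distances (δy) over all unordered pairs,
  summarized by the origin-through-mean slope mean(δx)/mean(δy) and the
  no-intercept least-squares slope Σδxδy/Σδy².
* **Performance index** 𝒫 = |slope_ref − slope_fit|·sqrt(Σ x_i²), with
  abscissae x_i evenly spaced on [0, max δy], k points by default (the
  node count; exposed as a parameter because 𝒫's absolute value scales
  with the abscissa choice).

Two caveats, both verified numerically on synthetic codebooks.  First, a
fully collapsed codebook gives 𝒫 = 0 (both summary lines are flat), so 𝒫
must be read together with the distortion and the slopes.  Second, under
this abscissa convention realistically trained 40×40 maps carry 𝒫 on the
order of 1: decomposing a trained codebook into a smoothed part plus local
jitter shows the jitter (σ ≈ 0.006) contributes only 𝒫 ≈ 0.005, while the
smooth large-scale warp that any fixed-neighborhood SOM retains dominates
the slope gap.  Near-zero absolute 𝒫 would require the two summary slopes
to agree to ~10⁻⁴ — attainable only by a map that is affine to that
accuracy — so small literature values of this index are not comparable
across abscissa conventions, and 𝒫 is best used here as a relative
quantity at a fixed convention.

## Synthetic data

Stimuli are i.i.d. uniform points on [0,1]² from a seeded NumPy PCG64
generator; one seed fixes the codebook initialization (i.i.d. U(0, 0.01))
and then the whole stimulus stream, so runs are bit-reproducible.  This
matches the reference experiments' input exactly.  Not emulated:
structured or correlated stimulus distributions, receptor-grid mappings s
beyond the identity, input noise — passing tests speak to the idealized
uniform-input setting only.

## Problem sizes used in the tests

The full reference profile (40×40, t = 25, γ = 0.002, 7000 epochs) takes
tens of minutes per run and is exercised through `nfsom run --full`.  The
test suite uses a desk-scale profile derived by two rules fixed in
advance: the grid stays at 40×40 (resolution sets the regime, see above),
and the within-epoch horizon is cut 5× with the learning rate raised 5×
(t = 5.0, γ = 0.01), preserving the per-epoch learning pull t·γ = 0.05;
1500 epochs with one reference seed (7659).  Both regimes train in ~3 min
each.  At this profile the stable run reaches a final full-sample
distortion of 0.004 with δx–δy slopes ≈ 0.88/0.81.

## Known limitations

* The stability conditions are sufficient, not necessary, and local.
* The stable/unstable *behavioral* dichotomy of the reference experiments
  is only partly reproduced: under the `"sum"` convention the over-strong
  kernel (K_e = 3.0, K_i = 2.80) settles into a sharper but perfectly
  steady winner disc and trains a good map rather than failing; under the
  `"integral"` convention it diverges numerically but the balanced kernel
  then forms no map either.  No examined combination of normalization and
  learning-rate semantics reproduces both sides at once; the failure mode
  reported for the over-strong kernel evidently hinges on discretization
  details outside the published description.
* Fixed neighborhood width: unfolding from a degenerate initialization is
  not guaranteed (a known fixed-neighborhood SOM property), and
  long-wavelength map warps relax extremely slowly, dominating 𝒫.
* Forward Euler only; basin of attraction and decay-rate constants of the
  exponential envelope are not estimated.
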