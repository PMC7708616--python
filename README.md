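# nfsom — neural-field self-organizing maps and their stability

`nfsom` implements a self-organizing map (SOM) whose learning dynamics is
driven by an Amari-type neural field, together with explicit,
Lyapunov-derived conditions that predict whether the map will form at all.
It is aimed at computational neuroscientists studying topographic map
formation (e.g. in primary somatosensory cortex) and at anyone who wants a
dynamical-systems SOM whose parameter regime can be checked *before*
spending an hour of simulation.

## The model

A membrane-potential field u(r, t) on the unit square Ω and feed-forward
weights w_f(r, t) ∈ [0, 1]^m (the codebook) evolve as

    τ ∂u/∂t  = −u + ∫_Ω w_l(|r − r′|) rect(u(r′, t)) dr′ + I(r, p),
    ∂w_f/∂t  = γ (s(p) − w_f) ∫_Ω w_e(|r − r′|) rect(u(r′, t)) dr′,

with lateral difference-of-Gaussians coupling
w_l(x) = K_e e^{−x²/2σ_e²} − K_i e^{−x²/2σ_i²}, input drive
I = 1 − |w_f − s(p)|₁/m, and rect(x) = max(x, 0).  Each training epoch
presents one stimulus p ~ U(0,1)², integrates the coupled system with
forward Euler for a fixed horizon, and resets the field.  The activity bump
acts as the (fixed) SOM neighborhood; the excitatory drive gates an
Oja-like pull of each codebook vector toward the stimulus.

The equilibrium (u*, w_f* = s(p)) is locally exponentially stable when

    ∫_Ω ∫_Ω w_l(|r − r′|)² dr′ dr  <  1        (lateral L2 norm below 1)

and the excitatory drive at u* is bounded away from zero.  On [a, b]² the
double integral has a closed form in the Gauss error function via

    ξ_{a,b}(σ) = (2σ²(e^{−(a−b)²/2σ²} − 1) + σ√(2π)(a−b) Erf((a−b)/σ√2))²,

giving the testable condition
K_e² ξ(σ_e/√2) + K_i² ξ(σ_i/√2) − 2K_eK_i ξ(σ_eσ_i/√(σ_e²+σ_i²)) < 1.
The balance of lateral excitation and inhibition (K_e ≈ K_i, σ_e ≈ σ_i)
is what keeps this quantity small.

Map quality is measured by the distortion 𝒟 (mean squared distance of
samples to their nearest codebook vector) and by the δx–δy representation:
all pairwise codebook distances (δx) plotted against the matching lattice
distances (δy), summarized by the performance index 𝒫 — the root-sum-square
gap between the origin-through-mean line and the no-intercept regression
line of that cloud.  𝒫 is convention-dependent (see `docs/methods.md` for
how to read it) and is best used as a relative quantity.

The discrete lateral term supports two normalizations
(`ModelParams.conv_norm`): the unweighted node sum (default — the regime in
which the field forms a localized winner disc and the map actually
self-organizes) and the cell-measure quadrature of the continuous integral
(the convention of the stability conditions, used throughout the stability
module).  `docs/methods.md` discusses the distinction and its consequences.

## Worked example

```sh
$ python examples/stability_conditions.py
stable  (Ke=0.90, Ki=0.86):
  closed-form LHS   = 0.4900   (stable iff < 1)
  40x40 quadrature  = 0.4900
  lateral L2 norm   = 0.7000
  excitatory-drive infimum at equilibrium = 0.010614182325071697
  verdict: stable

unstable (Ke=3.00, Ki=2.80):
  closed-form LHS   = 5.1851   (stable iff < 1)
  40x40 quadrature  = 5.1855
  lateral L2 norm   = 2.2772
  excitatory-drive infimum at equilibrium = n/a (no equilibrium)
  verdict: not_guaranteed
```

The balanced kernel sits safely below the threshold (0.49 < 1): training
converges and a topographic map forms.  Tripling the lateral gains pushes
the value to 5.19 > 1: the fixed-point iteration for u* no longer
contracts, and training fails to produce a coherent map.  See
`examples/map_quality_metrics.py` and `examples/train_small_map.py` for the
metrics and the training loop, and `nfsom --help` for the CLI
(`run`, `sweep`, `stability`, `metrics`; add `--full` for the full-scale
40×40 / 7000-epoch reference profile).

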