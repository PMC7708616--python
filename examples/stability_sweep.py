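"""Stability left-hand side across the reference (Ke, Ki) ladder.

Evaluates the closed-form stability condition for the eight reference
amplitude pairs (increasing lateral gain at roughly constant
excitation/inhibition ratio).  The value crosses 1 between the sixth and
seventh pair: beyond that point exponential stability of the field/codebook
equilibrium is no longer guaranteed and trained maps degrade.  Full
per-pair training is available via `nfsom sweep` (add --full for the
reference scale).
"""

from nfsom import KernelSpec, condition_lhs_closed
from nfsom.io_config import DEFAULT_SWEEP_PAIRS

print(f"{'Ke':>5} {'Ki':>5} {'LHS':>8}  verdict")
for ke, ki in DEFAULT_SWEEP_PAIRS:
    lhs = condition_lhs_closed(KernelSpec(ke, 0.1, ki, 1.0))
    verdict = "stable" if lhs < 1 else "not guaranteed"
    print(f"{ke:5.2f} {ki:5.2f} {lhs:8.4f}  {verdict}")

print("\nThe left-hand side grows quadratically with the lateral gains;")
print("balanced excitation/inhibition keeps it below the threshold of 1.")
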