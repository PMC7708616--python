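"""Lyapunov-derived stability conditions for the neural-field SOM.

Two sufficient conditions guarantee local exponential stability of the
coupled field/codebook equilibrium:

1. the spatial L2 norm of the lateral kernel is small enough,
   ``wbar_l = sqrt(int int w_l(r, r')^2 dr' dr) < 1 / l_l`` with ``l_l`` the
   Lipschitz constant of the lateral activation (1 for rectification), and
2. the excitatory drive at the equilibrium field is bounded away from zero,
   ``inf_r int w_e(r, r') f_e(u*(r')) dr' > 0``.

For a difference-of-Gaussians kernel on a square domain [a, b]^2 the double
integral in (1) has a closed form in the Gauss error function through the
auxiliary quantity

    xi_{a,b}(sigma) = ( 2 sigma^2 (exp(-(a-b)^2 / 2 sigma^2) - 1)
                        + sigma sqrt(2 pi) (a - b) Erf((a-b) / (sigma sqrt 2)) )^2,

which equals the square of the 1-D double integral of
``exp(-(x-y)^2 / 2 sigma^2)`` over [a, b]^2.  The stability threshold then
reads

    Ke^2 xi(sigma_e / sqrt 2) + Ki^2 xi(sigma_i / sqrt 2)
        - 2 Ke Ki xi(sigma_e sigma_i / sqrt(sigma_e^2 + sigma_i^2))  <  1.

Both the closed form and a dense grid-sum quadrature of the double integral
are provided; they converge to each other as the grid refines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np
from scipy.special import erf as _erf

from nfsom.grid_kernels import (
    SpatialGrid,
    KernelSpec,
    kernel_on_grid,
    lateral_convolve,
    lateral_weight,
)
from nfsom import dynamics as _dynamics

__all__ = [
    "StabilityReport", "erf_rational", "xi", "condition_lhs_closed",
    "condition_lhs_quadrature", "lateral_l2_norm", "check_condition10",
    "stability_report",
]

# Rational approximation of Erf (Abramowitz & Stegun 7.1.25); absolute
# error <= 5e-4.  Kept as a cross-check; scipy's erf is the default.
_A1, _A2, _A3, _A4 = 0.278393, 0.230389, 0.000972, 0.078108


def erf_rational(x):
    """Rational approximation of the Gauss error function (|error| <= 5e-4).

    Odd extension is used for negative arguments.
    """
    x = np.asarray(x, dtype=float)
    ax = np.abs(x)
    poly = 1.0 + _A1 * ax + _A2 * ax ** 2 + _A3 * ax ** 3 + _A4 * ax ** 4
    val = np.sign(x) * (1.0 - 1.0 / poly ** 4)
    return val.item() if val.ndim == 0 else val


def xi(a: float, b: float, sigma: float, *, erf: Callable = _erf) -> float:
    """Squared 1-D Gaussian-overlap integral over [a, b].

    Equals ``(int_a^b int_a^b exp(-(x-y)^2 / 2 sigma^2) dx dy)^2``.  ``erf``
    may be swapped for :func:`erf_rational` in cross-check mode.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if b < a:
        raise ValueError(f"interval must satisfy b >= a, got [{a}, {b}]")
    d = a - b
    bracket = 2.0 * sigma ** 2 * (math.exp(-(d ** 2) / (2.0 * sigma ** 2)) - 1.0) \
        + sigma * math.sqrt(2.0 * math.pi) * d * erf(d / (sigma * math.sqrt(2.0)))
    return bracket ** 2


def condition_lhs_closed(spec: KernelSpec, a: float = 0.0, b: float = 1.0,
                         *, erf: Callable = _erf) -> float:
    """Closed-form L2 energy of the lateral kernel on [a, b]^2.

    Stability is guaranteed (for 1-Lipschitz lateral activation) when the
    returned value is < 1.
    """
    se, si = spec.sigma_e, spec.sigma_i
    cross = se * si / math.sqrt(se ** 2 + si ** 2)
    return (spec.Ke ** 2 * xi(a, b, se / math.sqrt(2.0), erf=erf)
            + spec.Ki ** 2 * xi(a, b, si / math.sqrt(2.0), erf=erf)
            - 2.0 * spec.Ke * spec.Ki * xi(a, b, cross, erf=erf))


def condition_lhs_quadrature(spec: KernelSpec, grid: SpatialGrid) -> float:
    """Dense grid-sum of ``int int w_l(|r - r'|)^2 dr' dr`` over the lattice.

    Uses the displacement-multiplicity identity: on a uniform n^q lattice the
    number of ordered node pairs at integer displacement (d_1, .., d_q) is
    ``prod_i (n - |d_i|)``, so the O(k^2) pairwise sum collapses to a sum over
    the (2n-1)^q displacement table.  Always >= 0 (squared integrand).
    """
    offs = np.arange(-(grid.n - 1), grid.n)
    counts1d = (grid.n - np.abs(offs)).astype(float)
    if grid.q == 1:
        dist = np.abs(offs) * grid.spacing
        counts = counts1d
    else:
        dist = np.sqrt(offs[:, None] ** 2 + offs[None, :] ** 2) * grid.spacing
        counts = counts1d[:, None] * counts1d[None, :]
    wl2 = lateral_weight(dist, spec) ** 2
    return float(np.sum(counts * wl2) * grid.cell_measure ** 2)


def lateral_l2_norm(w, grid: SpatialGrid) -> float:
    """Spatial L2 norm ``sqrt(int int w(r, r')^2 dr' dr)`` of a kernel.

    ``w`` may be a :class:`KernelSpec` (distance kernel, fast displacement
    sum) or an arbitrary two-argument callable ``w(r, r')`` on node
    coordinate pairs, evaluated by dense quadrature — the general form
    appearing in the first stability condition.
    """
    if isinstance(w, KernelSpec):
        return math.sqrt(condition_lhs_quadrature(w, grid))
    nodes = grid.nodes
    vals = np.asarray(w(nodes[:, None, :], nodes[None, :, :]), dtype=float)
    if vals.shape != (grid.k, grid.k):
        raise ValueError(f"kernel callable returned shape {vals.shape}, expected {(grid.k, grid.k)}")
    return math.sqrt(float(np.sum(vals ** 2)) * grid.cell_measure ** 2)


def check_condition10(u_star: np.ndarray, excit_kernel_table: np.ndarray,
                      grid: SpatialGrid, f_e: Callable = None) -> tuple[float, bool]:
    """Infimum over nodes of the excitatory drive at the equilibrium field.

    Returns ``(inf_value, ok)`` with ``ok`` true iff the infimum of
    ``int w_e(r, r') f_e(u*(r')) dr'`` is strictly positive — the second
    stability condition (sufficient excitation around the equilibrium).
    """
    if f_e is None:
        f_e = _dynamics.rect
    drive = lateral_convolve(f_e(np.asarray(u_star, dtype=float)), excit_kernel_table, grid)
    inf_value = float(drive.min())
    return inf_value, inf_value > 0.0


@dataclass
class StabilityReport:
    """Aggregated verdict of the stability conditions for one parameter set."""

    lhs_closed: float
    lhs_quadrature: float
    wbar_l: float
    cond9_ok: bool
    cond10_inf: float | None
    cond10_ok: bool | None
    verdict: str                      # "stable", "not_guaranteed", "undetermined"
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def stability_report(spec: KernelSpec, grid: SpatialGrid, *, ell_l: float = 1.0,
                     tol: float = 1e-10, max_iter: int = 10_000) -> StabilityReport:
    """Evaluate all stability conditions for a kernel on a grid.

    Computes the closed-form and quadrature left-hand sides, the lateral L2
    norm against the ``1 / ell_l`` threshold, solves for the equilibrium
    field, and checks the excitatory-drive positivity.  When the equilibrium
    solver does not converge (expected outside the contraction regime) the
    drive condition is unknown and the verdict is ``"undetermined"`` unless
    the norm condition already fails.
    """
    a, b = grid.a, grid.b
    lhs_c = condition_lhs_closed(spec, a, b) if grid.q == 2 else float("nan")
    lhs_q = condition_lhs_quadrature(spec, grid)
    wbar = math.sqrt(lhs_q)
    cond9 = wbar < 1.0 / ell_l

    cond10_inf: float | None = None
    cond10 = None
    lat = kernel_on_grid(spec, grid, "lateral")
    exc = kernel_on_grid(spec, grid, "excitatory")
    try:
        u_star = _dynamics.equilibrium_field(lat, grid, tol=tol, max_iter=max_iter)
    except _dynamics.EquilibriumError:
        u_star = None
    if u_star is not None:
        cond10_inf, cond10 = check_condition10(u_star, exc, grid)

    if cond9 and cond10:
        verdict = "stable"
    elif not cond9 or cond10 is False:
        verdict = "not_guaranteed"
    else:
        verdict = "undetermined"

    params = {"Ke": spec.Ke, "sigma_e": spec.sigma_e, "Ki": spec.Ki,
              "sigma_i": spec.sigma_i, "a": a, "b": b, "n": grid.n, "q": grid.q}
    return StabilityReport(lhs_closed=lhs_c, lhs_quadrature=lhs_q, wbar_l=wbar,
                           cond9_ok=cond9, cond10_inf=cond10_inf, cond10_ok=cond10,
                           verdict=verdict, params=params)
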