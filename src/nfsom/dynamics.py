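"""Field dynamics, Oja-like learning, and the online training loop.

The model couples an Amari-type neural field for the membrane potential
``u(r, t)`` with feed-forward weights ``w_f(r, t)`` (the codebook):

    tau du/dt = -u + int_Omega w_l(|r - r'|) f_l(u(r')) dr' + f_s(w_f - s(p)),
    dw_f/dt  = gamma (s(p) - w_f) int_Omega w_e(|r - r'|) f_e(u(r')) dr',

with ``f_l = f_e = rect`` (rectification) and
``f_s(x) = 1 - |x|_1 / m`` by default.  Training is online: each epoch draws
one stimulus, integrates the coupled system with forward Euler for a fixed
horizon, then resets the field activity to zero; the codebook carries over.
The field bump that forms around the best-matching unit acts as the SOM
neighborhood function, and the excitatory drive gates which codebook vectors
move toward the stimulus.

Both the field and the weights are advanced from the same pre-step state
(simultaneous explicit Euler); the two lateral integrals per step share one
forward FFT of ``rect(u)``.  Within an epoch, the input drive ``I`` is
recomputed at every Euler step from the evolving codebook.

Two conventions exist for the discrete lateral term (``ModelParams.conv_norm``):
``"sum"`` — the unweighted node sum, the convention of the reference
simulations, whose strong lateral coupling produces the localized winner
disc that confines learning to a neighborhood; and ``"integral"`` — the
cell-measure-weighted quadrature of the continuous integral, the convention
the stability conditions are stated in.  :func:`field_step` and
:func:`weights_step`, the single-step building blocks, always use the
``"integral"`` convention via :func:`~nfsom.grid_kernels.lateral_convolve`;
``run_epoch`` with ``conv_norm="integral"`` composes exactly those steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Callable

import numpy as np
import pandas as pd

from nfsom.grid_kernels import (
    SpatialGrid,
    KernelSpec,
    FFTConvolver,
    kernel_on_grid,
    lateral_convolve,
    make_convolver,
)

__all__ = [
    "ModelParams", "FieldState", "Codebook", "NumericalBlowupError",
    "EquilibriumError", "TrainResult", "rect", "input_drive", "field_step",
    "weights_step", "run_epoch", "train", "equilibrium_field", "lyapunov_value",
    "uniform_stimuli",
]

BLOWUP_THRESHOLD = 1e6


class NumericalBlowupError(RuntimeError):
    """Field activity became non-finite or exceeded the blow-up threshold."""

    def __init__(self, message: str, epoch: int | None = None, step: int | None = None):
        super().__init__(message)
        self.epoch = epoch
        self.step = step


class EquilibriumError(RuntimeError):
    """Equilibrium iteration did not converge; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def rect(x):
    """Rectification activation max(x, 0); Lipschitz constant 1."""
    return np.maximum(x, 0.0)


@dataclass
class ModelParams:
    """Integration and learning parameters.

    ``tau`` is the field decay constant, ``gamma`` the learning rate, ``dt``
    the forward-Euler step, ``t_epoch`` the integration horizon per epoch
    (``dt`` and ``t_epoch`` share one time unit), ``epochs`` the number of
    stimuli presented.  ``f_l``/``f_e`` are the lateral and learning
    activations (rectification by default); ``f_s`` maps the codebook
    deviation to the scalar input drive (default ``1 - |.|_1 / m``).
    """

    tau: float = 1.0
    gamma: float = 0.002
    dt: float = 0.015
    t_epoch: float = 25.0
    epochs: int = 7000
    init_low: float = 0.0
    init_high: float = 0.01
    f_l: Callable = dataclass_field(default=rect)
    f_e: Callable = dataclass_field(default=rect)
    f_s: Callable | None = None      # None -> input_drive
    conv_norm: str = "sum"           # "sum" (reference simulations) | "integral"

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.gamma < 0 or self.dt <= 0:
            raise ValueError("tau, dt must be > 0 and gamma >= 0")
        if self.t_epoch < self.dt:
            raise ValueError(f"t_epoch ({self.t_epoch}) must be >= dt ({self.dt})")
        if self.conv_norm not in ("sum", "integral"):
            raise ValueError(f"conv_norm must be 'sum' or 'integral', got {self.conv_norm!r}")

    def conv_weight(self, grid: SpatialGrid) -> float:
        """Output scale of the lateral convolution under this normalization."""
        return 1.0 if self.conv_norm == "sum" else grid.cell_measure

    @property
    def steps_per_epoch(self) -> int:
        return int(np.floor(self.t_epoch / self.dt))


@dataclass
class FieldState:
    """Membrane potential sampled on the lattice, plus within-epoch time."""

    u: np.ndarray
    t: float = 0.0


@dataclass
class Codebook:
    """Feed-forward weights: one m-vector per lattice node (grid-shaped)."""

    w: np.ndarray                    # shape grid.shape + (m,)

    @property
    def m(self) -> int:
        return self.w.shape[-1]

    @property
    def flat(self) -> np.ndarray:
        """View of shape (k, m)."""
        return self.w.reshape(-1, self.w.shape[-1])


def input_drive(w: np.ndarray, stimulus: np.ndarray) -> np.ndarray:
    """Scalar input field ``I = 1 - |w_f - s(p)|_1 / m``, in [0, 1].

    ``w`` has shape grid.shape + (m,); ``stimulus`` is the mapped stimulus
    s(p) in [0, 1]^m.  High drive where the codebook is close to the
    stimulus — this is the SOM distance computation.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if w.shape[-1] != stimulus.shape[-1]:
        raise ValueError(
            f"codebook dimension m={w.shape[-1]} does not match stimulus m={stimulus.shape[-1]}")
    return 1.0 - np.abs(w - stimulus).sum(axis=-1) / w.shape[-1]


def field_step(u: np.ndarray, I: np.ndarray, kernel_table: np.ndarray,
               params: ModelParams, grid: SpatialGrid) -> np.ndarray:
    """One forward-Euler step of the field equation.

    ``u <- u + (dt / tau) (-u + conv_l(f_l(u)) + I)``.
    """
    lat = lateral_convolve(params.f_l(u), kernel_table, grid)
    u_new = u + (params.dt / params.tau) * (-u + lat + I)
    if not np.all(np.isfinite(u_new)) or np.abs(u_new).max() > BLOWUP_THRESHOLD:
        raise NumericalBlowupError("field activity diverged during a field step")
    return u_new


def weights_step(w: np.ndarray, u: np.ndarray, stimulus: np.ndarray,
                 excit_kernel_table: np.ndarray, params: ModelParams,
                 grid: SpatialGrid) -> np.ndarray:
    """One forward-Euler step of the learning rule.

    ``w <- w + dt * gamma * (s(p) - w) * E(r)`` with
    ``E(r) = conv_e(f_e(u))``; entries remain in [0, 1] whenever
    ``dt * gamma * E <= 1``.
    """
    E = lateral_convolve(params.f_e(u), excit_kernel_table, grid)
    stimulus = np.asarray(stimulus, dtype=float)
    return w + params.dt * params.gamma * (stimulus - w) * E[..., None]


def run_epoch(u: np.ndarray, w: np.ndarray, stimulus: np.ndarray,
              kernels: KernelSpec, params: ModelParams, grid: SpatialGrid,
              *, convolver=None,
              epoch_index: int | None = None) -> tuple[np.ndarray, dict]:
    """Present one stimulus: integrate the coupled system, then reset u to 0.

    Runs ``floor(t_epoch / dt)`` paired Euler steps; the input drive is
    recomputed every step from the evolving codebook.  Returns the updated
    codebook and per-epoch diagnostics (final field, its max, and the mean
    absolute weight change).  The returned field state is the zero reset.
    """
    if convolver is None:
        lat = kernel_on_grid(kernels, grid, "lateral")
        exc = kernel_on_grid(kernels, grid, "excitatory")
        convolver = make_convolver(grid, lat, exc, weight=params.conv_weight(grid))
    stimulus = np.asarray(stimulus, dtype=float)
    f_l, f_e, f_s = params.f_l, params.f_e, params.f_s
    shared = f_l is rect and f_e is rect
    dt_tau = params.dt / params.tau
    dt_gamma = params.dt * params.gamma

    u = np.array(u, dtype=float)
    w = np.array(w, dtype=float)
    w_before = w.copy()
    for step in range(params.steps_per_epoch):
        if shared:
            lat_term, E = convolver.apply_all(rect(u))
        else:
            lat_term = convolver.apply(f_l(u), 0)
            E = convolver.apply(f_e(u), 1)
        I = input_drive(w, stimulus) if f_s is None else f_s(w - stimulus)
        u_new = u + dt_tau * (-u + lat_term + I)
        w += dt_gamma * (stimulus - w) * E[..., None]
        u = u_new
        if not np.all(np.isfinite(u)) or np.abs(u).max() > BLOWUP_THRESHOLD:
            raise NumericalBlowupError(
                f"field activity diverged (epoch={epoch_index}, step={step})",
                epoch=epoch_index, step=step)
    diagnostics = {
        "field_final": u,
        "field_max": float(u.max()) if u.size else float("nan"),
        "mean_weight_change": float(np.abs(w - w_before).mean()),
    }
    return w, diagnostics


def uniform_stimuli(rng: np.random.Generator, m: int = 2) -> np.ndarray:
    """Default stimulus sampler: one draw from U(0, 1)^m (identity mapping s)."""
    return rng.random(m)


@dataclass
class TrainResult:
    """Final codebook, per-epoch trace, and the stimuli used for training."""

    codebook: np.ndarray             # grid.shape + (m,)
    trace: pd.DataFrame              # columns: epoch, distortion, mean_weight_change, field_max
    samples: np.ndarray              # (epochs, m) stimuli in presentation order
    grid: SpatialGrid


def train(params: ModelParams, kernels: KernelSpec, grid: SpatialGrid,
          sampler: Callable[[np.random.Generator], np.ndarray] = uniform_stimuli,
          seed: int | np.random.Generator = 0, *, m: int = 2,
          log_stride: int = 1,
          callback: Callable[[int, np.ndarray], None] | None = None) -> TrainResult:
    """Online SOM training: one stimulus per epoch, field reset in between.

    The codebook is initialized i.i.d. U(init_low, init_high) from the seeded
    generator, which then also drives the stimulus stream — one seed fixes
    the whole run.  The per-epoch distortion logged every ``log_stride``
    epochs is computed against the cumulative set of stimuli presented so
    far.  Raises :class:`NumericalBlowupError` (with the epoch index) if the
    field diverges.
    """
    from nfsom.metrics import distortion as _distortion

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = rng.uniform(params.init_low, params.init_high, size=grid.shape + (m,))
    u = np.zeros(grid.shape)

    lat = kernel_on_grid(kernels, grid, "lateral")
    exc = kernel_on_grid(kernels, grid, "excitatory")
    convolver = make_convolver(grid, lat, exc, weight=params.conv_weight(grid))

    samples = np.empty((params.epochs, m))
    rows: list[tuple] = []
    for epoch in range(params.epochs):
        p = np.asarray(sampler(rng), dtype=float)
        samples[epoch] = p
        w, diag = run_epoch(u, w, p, kernels, params, grid,
                            convolver=convolver, epoch_index=epoch)
        if (epoch + 1) % log_stride == 0 or epoch == params.epochs - 1:
            d = _distortion(samples[: epoch + 1], w.reshape(-1, m))
            rows.append((epoch, d, diag["mean_weight_change"], diag["field_max"]))
        if callback is not None:
            callback(epoch, w)

    trace = pd.DataFrame(rows, columns=["epoch", "distortion",
                                        "mean_weight_change", "field_max"])
    return TrainResult(codebook=w, trace=trace, samples=samples, grid=grid)


def equilibrium_field(kernel_table: np.ndarray, grid: SpatialGrid,
                      f_l: Callable = rect, tol: float = 1e-12,
                      max_iter: int = 10_000, drive: float = 1.0) -> np.ndarray:
    """Solve ``u* = drive + conv_l(f_l(u*))`` by Picard iteration from u = drive.

    Converges when the lateral L2-norm contraction condition holds; outside
    that regime it raises :class:`EquilibriumError` carrying the last
    sup-norm residual.
    """
    u = np.full(grid.shape, float(drive))
    residual = np.inf
    for _ in range(max_iter):
        u_next = drive + lateral_convolve(f_l(u), kernel_table, grid)
        residual = float(np.abs(u_next - u).max())
        u = u_next
        if residual < tol:
            return u
        if not np.isfinite(residual):
            break
    raise EquilibriumError(
        f"equilibrium iteration did not reach tol={tol} in {max_iter} iterations "
        f"(last residual {residual:.3e})", residual=residual)


def lyapunov_value(u_dev: np.ndarray, w_dev: np.ndarray, rho: float,
                   tau: float, gamma: float, grid: SpatialGrid) -> float:
    """Lyapunov functional ``(tau/2) ||u~||^2 + (rho / 2 gamma) ||w~||^2``.

    ``u_dev = u - u*`` and ``w_dev = w_f - s(p)`` are deviations from the
    equilibrium pattern; spatial L2 norms are cell-measure-weighted sums.
    Along stable-regime trajectories near the equilibrium this quantity is
    non-increasing (after transients), which is the monitoring use.
    """
    if rho <= 0:
        raise ValueError(f"rho must be > 0, got {rho}")
    cell = grid.cell_measure
    u2 = float(np.sum(np.asarray(u_dev) ** 2)) * cell
    w2 = float(np.sum(np.asarray(w_dev) ** 2)) * cell
    return 0.5 * tau * u2 + 0.5 * rho / gamma * w2
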