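"""Shared fixtures, including the two desk-scale training runs.

The stable/unstable reference parameter sets are exercised end-to-end at the
package's desk-scale profile: the full 40x40 lattice (grid resolution sets
the lateral-gain regime and cannot be reduced), 5.0-unit epochs with the
learning rate raised to 0.01 so the per-epoch learning pull t*gamma matches
the full-scale reference runs, and 1500 epochs.  The two runs are
session-scoped because several test modules share them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from nfsom import (
    KernelSpec,
    SpatialGrid,
    NumericalBlowupError,
)
from nfsom.dynamics import ModelParams, train
from nfsom.experiments import seed_stream

STABLE_SPEC = KernelSpec(Ke=0.90, sigma_e=0.1, Ki=0.86, sigma_i=1.0)
UNSTABLE_SPEC = KernelSpec(Ke=3.0, sigma_e=0.1, Ki=2.80, sigma_i=1.0)

#: Desk-scale training profile (see module docstring and docs/methods.md).
DESK_PARAMS = dict(tau=1.0, gamma=0.01, dt=0.015, t_epoch=5.0, epochs=1500)
DESK_GRID_N = 40
DESK_SEED = 7659                     # one of the reference PRNG seeds
DESK_LOG_STRIDE = 10


@pytest.fixture(scope="session")
def desk_grid() -> SpatialGrid:
    return SpatialGrid(0.0, 1.0, DESK_GRID_N, 2)


@pytest.fixture()
def small_grid() -> SpatialGrid:
    return SpatialGrid(0.0, 1.0, 8, 2)


@pytest.fixture()
def stable_spec() -> KernelSpec:
    return STABLE_SPEC


@pytest.fixture()
def unstable_spec() -> KernelSpec:
    return UNSTABLE_SPEC


@dataclasses.dataclass
class DeskRun:
    """Outcome of one desk-scale training run plus trajectory invariants."""

    status: str                      # "ok" or "blowup"
    result: object | None            # TrainResult when status == "ok"
    codebook_min: float              # min codebook entry seen on any logged epoch
    codebook_max: float
    blowup_epoch: int | None = None


def _desk_run(spec: KernelSpec, grid: SpatialGrid) -> DeskRun:
    params = ModelParams(**DESK_PARAMS)
    bounds = {"lo": np.inf, "hi": -np.inf}

    def track_bounds(epoch: int, w: np.ndarray) -> None:
        if epoch % DESK_LOG_STRIDE == 0:
            bounds["lo"] = min(bounds["lo"], float(w.min()))
            bounds["hi"] = max(bounds["hi"], float(w.max()))

    try:
        result = train(params, spec, grid, seed=seed_stream(DESK_SEED),
                       log_stride=DESK_LOG_STRIDE, callback=track_bounds)
        return DeskRun("ok", result, bounds["lo"], bounds["hi"])
    except NumericalBlowupError as exc:
        return DeskRun("blowup", None, bounds["lo"], bounds["hi"],
                       blowup_epoch=exc.epoch)


@pytest.fixture(scope="session")
def stable_run(desk_grid) -> DeskRun:
    """Desk-scale training with the stable (balanced) lateral kernel."""
    return _desk_run(STABLE_SPEC, desk_grid)


@pytest.fixture(scope="session")
def unstable_run(desk_grid) -> DeskRun:
    """Desk-scale training with the unstable (over-strong) lateral kernel."""
    return _desk_run(UNSTABLE_SPEC, desk_grid)
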