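"""Map-quality metrics: distortion and the dx-dy topology representation.

Distortion is the vector-quantization loss — the mean squared Euclidean
distance from each training sample to its nearest codebook vector.  It
tracks convergence of the learning process but not map topology.

Topology preservation is quantified through the dx-dy representation: for
every unordered node pair (i < j), ``dx`` is the Euclidean distance between
the two codebook vectors and ``dy`` the distance between the corresponding
lattice nodes of the input-space discretization.  A well-formed topographic
map yields a cloud tightly aligned with a straight line.  Two lines
summarize the cloud: the reference line through the origin and the cloud
mean (slope = mean(dx) / mean(dy)) and the no-intercept least-squares
regression (slope = sum(dx dy) / sum(dy^2)).  The scalar performance index
is the root-sum-square gap between the two lines sampled at evenly spaced
abscissae on [0, max(dy)] — near zero for a well-organized map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from nfsom.grid_kernels import SpatialGrid

__all__ = [
    "DxDyCloud", "MetricsTrace", "distortion", "dxdy_cloud",
    "reference_slope", "regression_slope", "performance_index", "map_quality",
]


@dataclass
class DxDyCloud:
    """Pair-aligned pairwise distances: ``dy`` in input space, ``dx`` between codebooks.

    Pairs follow the condensed i < j convention over the k nodes; both arrays
    have length k (k - 1) / 2.
    """

    dy: np.ndarray
    dx: np.ndarray

    def __post_init__(self) -> None:
        self.dy = np.asarray(self.dy, dtype=float)
        self.dx = np.asarray(self.dx, dtype=float)
        if self.dy.shape != self.dx.shape:
            raise ValueError(f"dy and dx must be pair-aligned, got {self.dy.shape} vs {self.dx.shape}")

    @property
    def k(self) -> int:
        """Number of nodes implied by the pair count."""
        return int(round((1 + np.sqrt(1 + 8 * self.dy.size)) / 2))


@dataclass
class MetricsTrace:
    """Per-run summary: distortion trajectory, final slopes, and the index."""

    distortion_by_epoch: np.ndarray
    slope_reference: float
    slope_regression: float
    final_P: float


def distortion(samples: np.ndarray, codebook: np.ndarray,
               chunk: int = 2048) -> float:
    """Mean squared distance from each sample to its nearest codebook vector.

    ``samples`` has shape (n, m); ``codebook`` (k, m) or grid-shaped
    (..., m).  Chunked over samples so large sample sets stay in cache.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.size == 0:
        raise ValueError("distortion requires at least one sample")
    cb = np.asarray(codebook, dtype=float).reshape(-1, samples.shape[1])
    total = 0.0
    for start in range(0, samples.shape[0], chunk):
        block = samples[start:start + chunk]
        d2 = ((block[:, None, :] - cb[None, :, :]) ** 2).sum(axis=-1)
        total += d2.min(axis=1).sum()
    return total / samples.shape[0]


def dxdy_cloud(codebook: np.ndarray, grid: SpatialGrid) -> DxDyCloud:
    """All-pairs codebook distances against all-pairs lattice-node distances."""
    cb = np.asarray(codebook, dtype=float)
    cb = cb.reshape(-1, cb.shape[-1])
    if cb.shape[0] != grid.k:
        raise ValueError(f"codebook has {cb.shape[0]} vectors but grid has {grid.k} nodes")
    if grid.k < 2:
        raise ValueError("dx-dy representation needs at least two nodes")
    return DxDyCloud(dy=pdist(grid.nodes), dx=pdist(cb))


def reference_slope(cloud: DxDyCloud) -> float:
    """Slope of the line through the origin and the cloud mean: mean(dx)/mean(dy)."""
    mean_dy = cloud.dy.mean()
    if mean_dy <= 0:
        raise ValueError("degenerate cloud: mean(dy) must be positive")
    return float(cloud.dx.mean() / mean_dy)


def regression_slope(cloud: DxDyCloud) -> float:
    """No-intercept least-squares slope: sum(dx * dy) / sum(dy^2)."""
    denom = float(np.dot(cloud.dy, cloud.dy))
    if denom <= 0:
        raise ValueError("degenerate cloud: sum(dy^2) must be positive")
    return float(np.dot(cloud.dx, cloud.dy) / denom)


def performance_index(slope_ref: float, slope_fit: float, cloud: DxDyCloud,
                      k_eval: int | None = None) -> float:
    """Root-sum-square gap between the two summary lines.

    Both lines are evaluated at ``k_eval`` abscissae evenly spaced on
    [0, max(dy)] (default: the node count k), giving
    ``|slope_ref - slope_fit| * sqrt(sum_i x_i^2)``.
    """
    if k_eval is None:
        k_eval = cloud.k
    x = np.linspace(0.0, float(cloud.dy.max()), k_eval)
    return float(abs(slope_ref - slope_fit) * np.sqrt(np.sum(x ** 2)))


def map_quality(codebook: np.ndarray, grid: SpatialGrid,
                k_eval: int | None = None) -> dict:
    """Convenience bundle: slopes and performance index for a codebook."""
    cloud = dxdy_cloud(codebook, grid)
    s_ref = reference_slope(cloud)
    s_fit = regression_slope(cloud)
    return {
        "slope_ref": s_ref,
        "slope_fit": s_fit,
        "P": performance_index(s_ref, s_fit, cloud, k_eval=k_eval),
    }
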