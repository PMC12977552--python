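"""Myeloid-cell point-pattern statistics.

Implements the two readouts used for Iba1+ cells on flat-mounts: the cell
density inside square regions of interest (630 x 630 um^2 in the study
design) and the mean distance from randomly sampled reference cells to
their five nearest neighbors, averaged into a single value per region and
biological replicate. Distances are plain Euclidean distances in the
flat-mount plane; no edge correction is applied, matching measurement in an
image-analysis tool, and the window geometry is carried in the summary so
the edge bias is documented rather than hidden.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .geometry import Rect, SquareROI, Window

__all__ = [
    "PointPattern",
    "NNConfig",
    "NNSummary",
    "knn_distances",
    "knn_distances_all",
    "nn_region_summary",
    "density",
    "csr_mean_knn_distance",
]

LAYERS = ("GCL_RNFL", "IPL")
REGIONS = ("CENTRAL", "PERIPHERAL")


@dataclass
class PointPattern:
    """Labeled point set in micron coordinates within an observation window."""

    points: np.ndarray  # (n, 2) array of (x_um, y_um)
    window: Window
    layer: Optional[str] = None
    region: Optional[str] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 2)
        if self.window.area_um2 <= 0:
            raise ValueError("window area must be positive")
        if self.layer is not None and self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}")
        if self.region is not None and self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}")

    @property
    def n(self) -> int:
        return len(self.points)

    def scaled(self, s: float) -> "PointPattern":
        """Rescale all coordinates (and the window) by a factor s."""
        if isinstance(self.window, Rect):
            win: Window = Rect(
                self.window.x0 * s, self.window.y0 * s, self.window.x1 * s, self.window.y1 * s
            )
        else:
            from .geometry import Disc

            win = Disc(self.window.cx * s, self.window.cy * s, self.window.radius * s)
        return PointPattern(self.points * s, win, self.layer, self.region)


@dataclass(frozen=True)
class NNConfig:
    """Sampling scheme for the nearest-neighbor summary.

    The study design samples 10 reference cells per region and measures the
    distance to each one's 5 nearest neighbors.
    """

    n_reference: int = 10
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reference < 1:
            raise ValueError("n_reference must be >= 1")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass
class NNSummary:
    """Per-region nearest-neighbor summary (one value per replicate)."""

    mean_nn_um: float
    per_reference_means: np.ndarray
    n_points: int
    n_reference_used: int
    all_points_used: bool
    window: Window
    layer: Optional[str] = None
    region: Optional[str] = None


def knn_distances(pattern: PointPattern, reference_index: int, k: int) -> np.ndarray:
    """Distances from one reference point to its k nearest neighbors.

    Returns the k smallest Euclidean distances to the *other* points of the
    pattern, in ascending order.
    """
    n = pattern.n
    if n < k + 1:
        raise ValueError(f"pattern has {n} points; k={k} neighbors require at least {k + 1}")
    if not 0 <= reference_index < n:
        raise IndexError(f"reference_index {reference_index} out of range for {n} points")
    tree = cKDTree(pattern.points)
    d, _ = tree.query(pattern.points[reference_index], k=k + 1)
    return np.asarray(d[1:], dtype=float)  # drop the zero self-distance


def knn_distances_all(pattern: PointPattern, k: int) -> np.ndarray:
    """(n, k) matrix of each point's k nearest-neighbor distances, ascending."""
    n = pattern.n
    if n < k + 1:
        raise ValueError(f"pattern has {n} points; k={k} neighbors require at least {k + 1}")
    tree = cKDTree(pattern.points)
    d, _ = tree.query(pattern.points, k=k + 1)
    return np.asarray(d[:, 1:], dtype=float)


def nn_region_summary(pattern: PointPattern, cfg: NNConfig) -> NNSummary:
    """Mean k-NN distance over randomly sampled reference cells.

    Samples ``n_reference`` distinct points uniformly without replacement
    (seeded), averages each reference's ``k_neighbors`` nearest-neighbor
    distances, and returns the mean of those per-reference means. If the
    pattern has fewer points than requested references, every point is used
    and the summary is flagged.

    Sampling is performed over a canonical coordinate-sorted ordering, so
    the result does not depend on the order in which points are listed.
    """
    n = pattern.n
    if n <= cfg.k_neighbors:
        raise ValueError(
            f"pattern has {n} points; need more than k={cfg.k_neighbors} to summarize"
        )
    order = np.lexsort((pattern.points[:, 1], pattern.points[:, 0]))
    rng = np.random.default_rng(cfg.seed)
    all_points_used = cfg.n_reference >= n
    if all_points_used:
        chosen = order
    else:
        chosen = order[rng.choice(n, size=cfg.n_reference, replace=False)]

    dmat = knn_distances_all(pattern, cfg.k_neighbors)
    per_ref = dmat[chosen].mean(axis=1)
    return NNSummary(
        mean_nn_um=float(per_ref.mean()),
        per_reference_means=per_ref,
        n_points=n,
        n_reference_used=len(chosen),
        all_points_used=all_points_used,
        window=pattern.window,
        layer=pattern.layer,
        region=pattern.region,
    )


def density(pattern: PointPattern, roi: SquareROI) -> float:
    """Points per mm^2 inside a square ROI (half-open membership).

    A 630 x 630 um^2 ROI has area 0.3969 mm^2, so 100 points give
    251.95.../mm^2.
    """
    rect = roi.rect
    if isinstance(pattern.window, Rect):
        w = pattern.window
        inside = rect.x0 >= w.x0 and rect.y0 >= w.y0 and rect.x1 <= w.x1 and rect.y1 <= w.y1
    else:
        corners_x = np.array([rect.x0, rect.x1, rect.x0, rect.x1])
        corners_y = np.array([rect.y0, rect.y0, rect.y1, rect.y1])
        inside = bool(np.all(pattern.window.contains(corners_x, corners_y)))
    if not inside:
        raise ValueError(f"ROI {roi} extends outside the observation window")
    if pattern.n == 0:
        return 0.0
    m = rect.contains(pattern.points[:, 0], pattern.points[:, 1])
    return float(np.count_nonzero(m) / roi.area_mm2)


def csr_mean_knn_distance(lambda_per_mm2: float, k: int) -> float:
    """Closed-form mean k-NN distance (um) under complete spatial randomness.

    For a homogeneous Poisson process of intensity lambda,
    E[d_k] = k * C(2k, k) / (4^k * sqrt(lambda)).
    """
    from math import comb, sqrt

    lam_um2 = lambda_per_mm2 * 1e-6
    return k * comb(2 * k, k) / (4.0**k * sqrt(lam_um2))
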