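"""Dot-blot cytokine array densitometry and profile clustering.

Quantifies membrane scans with fixed circular ROIs of identical size: each
spot's integrated density (sum of pixel intensities over the ROI) is
measured, the integrated density of a same-sized background ROI over a
blank membrane area is subtracted (clamped at zero), technical duplicates
are averaged, and values are log10-transformed with a configurable floor.
Analyte profiles are then clustered with Euclidean distance and unweighted
average linkage (UPGMA) for heatmap display.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .image import Image2D

__all__ = [
    "ArrayLayout",
    "SpotQuant",
    "ClusterResult",
    "to_grayscale",
    "measure_spot",
    "quantify_membrane",
    "quant_table",
    "cluster_rows",
    "export_heatmap",
]


@dataclass(frozen=True)
class ArrayLayout:
    """Measurement geometry for a membrane: one shared ROI radius, two
    duplicate spot centers per analyte, and a background ROI center over a
    blank area."""

    spot_centers: dict  # analyte -> ((x1, y1), (x2, y2)) in pixels
    spot_radius_px: float
    background_center: tuple

    def __post_init__(self) -> None:
        if self.spot_radius_px <= 0:
            raise ValueError("spot_radius_px must be positive")
        all_centers = []
        for analyte, centers in self.spot_centers.items():
            if len(centers) != 2 or tuple(centers[0]) == tuple(centers[1]):
                raise ValueError(
                    f"analyte {analyte!r} must have exactly 2 distinct spot centers "
                    "(technical duplicates)"
                )
            all_centers.extend(centers)
        bx, by = self.background_center
        for cx, cy in all_centers:
            if (cx - bx) ** 2 + (cy - by) ** 2 < (2.0 * self.spot_radius_px) ** 2:
                raise ValueError("background ROI overlaps a spot ROI")


@dataclass
class SpotQuant:
    """Background-subtracted densitometry of one analyte's duplicate spots."""

    analyte: str
    raw_integrated_density: tuple
    background_subtracted: tuple
    duplicate_mean: float
    log10_value: float


@dataclass
class ClusterResult:
    """UPGMA merge tree over analyte rows plus the canonical leaf order."""

    linkage: np.ndarray          # scipy linkage matrix (merge tree + heights)
    leaf_order: list             # analyte names, left-to-right
    analytes: list               # input row names, original order
    newick: str


def to_grayscale(image) -> Image2D:
    """Coerce a scanned membrane to 8-bit single-channel.

    Accepts a file path, an array, or an :class:`Image2D`. Multi-channel
    inputs are converted by averaging channels; 16-bit rasters are rescaled
    to the 0-255 range; 8-bit inputs pass through unchanged.
    """
    if isinstance(image, (str, Path)):
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(image))
    elif isinstance(image, Image2D):
        arr = image.pixels
    else:
        arr = np.asarray(image)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    if arr.dtype == np.uint16:
        arr = arr / 257.0
    arr = np.clip(np.asarray(arr, dtype=np.float64), 0.0, 255.0)
    return Image2D(np.rint(arr), 1.0)


def _circle_mask(shape, center, radius_px: float) -> np.ndarray:
    h, w = shape
    cx, cy = center
    if cx - radius_px < -0.5 or cy - radius_px < -0.5 or cx + radius_px > w - 0.5 or cy + radius_px > h - 0.5:
        raise ValueError(f"circular ROI at {center} radius {radius_px} out of image bounds")
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px**2


def measure_spot(image: Image2D, center, radius_px: float) -> tuple[float, float]:
    """Integrated density and mean gray value over a circular ROI.

    Pixels whose centers lie within the circle are summed; the mean gray
    value is that sum divided by the pixel count.
    """
    m = _circle_mask(image.shape, center, radius_px)
    n = int(np.count_nonzero(m))
    total = float(image.pixels[m].sum())
    return total, total / n if n else 0.0


def quantify_membrane(
    image: Image2D, layout: ArrayLayout, floor: float = 1.0
) -> list[SpotQuant]:
    """Measure every spot, subtract the background ROI, average duplicates.

    The background ROI's integrated density is measured once and subtracted
    from each spot's integrated density (clamped at zero, since ROI sizes
    are identical). Duplicates are averaged after subtraction, and the
    duplicate mean is log10-transformed with values below ``floor`` floored
    (default floor of 1 integrated-density unit maps to log10 = 0).
    """
    bg, _ = measure_spot(image, layout.background_center, layout.spot_radius_px)
    out: list[SpotQuant] = []
    for analyte, centers in layout.spot_centers.items():
        raw = tuple(
            measure_spot(image, c, layout.spot_radius_px)[0] for c in centers
        )
        sub = tuple(max(r - bg, 0.0) for r in raw)
        dup_mean = float(np.mean(sub))
        log10_value = float(np.log10(max(dup_mean, floor)))
        out.append(
            SpotQuant(
                analyte=analyte,
                raw_integrated_density=raw,
                background_subtracted=sub,
                duplicate_mean=dup_mean,
                log10_value=log10_value,
            )
        )
    return out


def quant_table(quants: list[SpotQuant]) -> pd.DataFrame:
    """Tidy per-analyte table of the densitometry results."""
    return pd.DataFrame(
        {
            "analyte": [q.analyte for q in quants],
            "raw_1": [q.raw_integrated_density[0] for q in quants],
            "raw_2": [q.raw_integrated_density[1] for q in quants],
            "background_subtracted_1": [q.background_subtracted[0] for q in quants],
            "background_subtracted_2": [q.background_subtracted[1] for q in quants],
            "duplicate_mean": [q.duplicate_mean for q in quants],
            "log10_value": [q.log10_value for q in quants],
        }
    )


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _canonical_order(tree, names: list[str]) -> list[int]:
    """Leaf order from a recursive traversal, left subtree first.

    At every merge the child cluster containing the lexicographically
    smallest analyte name goes left, which makes the order deterministic and
    independent of input row order.
    """

    def walk(node) -> tuple[list[int], str]:
        if node.is_leaf():
            return [node.id], names[node.id]
        left_ids, left_min = walk(node.left)
        right_ids, right_min = walk(node.right)
        if right_min < left_min:
            left_ids, right_ids = right_ids, left_ids
            left_min, right_min = right_min, left_min
        return left_ids + right_ids, left_min

    ids, _ = walk(tree)
    return ids


def _newick(tree, names: list[str]) -> str:
    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    body = walk(tree, tree.dist)
    return body + ";"


def cluster_rows(matrix: pd.DataFrame) -> ClusterResult:
    """Agglomerative clustering of analyte rows (Euclidean, UPGMA).

    Rows are the analyte profiles (e.g. log10 values per condition or
    time-point). Returns the merge tree, its heights, and a canonical
    left-to-right leaf order for heatmap display.
    """
    if len(matrix) < 2:
        raise ValueError("clustering requires at least 2 rows")
    values = matrix.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("matrix contains non-finite values")
    names = [str(i) for i in matrix.index]
    Z = hierarchy.linkage(values, method="average", metric="euclidean")
    tree = hierarchy.to_tree(Z)
    order_ids = _canonical_order(tree, names)
    return ClusterResult(
        linkage=Z,
        leaf_order=[names[i] for i in order_ids],
        analytes=names,
        newick=_newick(tree, names),
    )


def export_heatmap(
    matrix: pd.DataFrame,
    order: list,
    out_csv: str | Path,
    out_png: Optional[str | Path] = None,
) -> pd.DataFrame:
    """Write the row-reordered matrix as CSV and render a heatmap PNG.

    Values are written untouched; only the row order changes.
    """
    ordered = matrix.loc[list(order)]
    ordered.to_csv(out_csv)
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import seaborn as sns

        fig, ax = plt.subplots(
            figsize=(max(4, 0.6 * ordered.shape[1] + 2), max(3, 0.35 * ordered.shape[0] + 1))
        )
        sns.heatmap(ordered, cmap="vlag", center=0.0, ax=ax, cbar_kws={"label": "log10 density"})
        fig.tight_layout()
        fig.savefig(out_png, dpi=150)
        plt.close(fig)
    return ordered
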