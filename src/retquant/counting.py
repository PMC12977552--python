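"""Automated RGC soma counting on flat-mount images.

The pipeline mirrors the stages of the automated counting approach used for
RBPMS-stained flat-mounts:

1. background suppression — absolute background subtraction, grayscale
   morphological opening with a small disc, and kernel-based local
   background subtraction (white-tophat with a large disc), which together
   remove sub-cellular-sized background noise;
2. declumping — repeated Gaussian blurring and grayscale erosion to carve
   valleys between touching somas;
3. binarization — local adaptive thresholding (pixel > local mean + offset),
   robust to uneven illumination;
4. center detection — Euclidean distance transform of the foreground, whose
   local maxima (plateaus collapsed to their centroids) mark object centers;
5. filtering — size bounds on the supporting component and greedy
   suppression of centers closer than a minimum intra-center distance,
   yielding the final coordinate list.

Default parameters are derived from soma geometry (nominal soma diameter
12 um) and scale with the pixel calibration, so a config built with
:meth:`CountingConfig.from_geometry` is resolution-portable.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .geometry import SquareROI
from .image import Image2D

__all__ = [
    "CountingConfig",
    "Candidates",
    "CellDetections",
    "RegionMask",
    "suppress_background",
    "declump",
    "binarize",
    "locate_centers",
    "filter_detections",
    "count_cells",
    "count_in_regions",
]


@dataclass(frozen=True)
class CountingConfig:
    """Free parameters of the counting pipeline, in pixel units."""

    absolute_background: float = 0.0
    opening_radius_px: int = 3
    background_kernel_radius_px: int = 25
    blur_sigma_px: float = 1.0
    erosion_radius_px: int = 2
    declump_iterations: int = 2
    adaptive_block_px: int = 51
    adaptive_offset: float = 400.0
    min_area_px: float = 38.5
    max_area_px: float = 1810.0
    min_center_distance_px: float = 10.0
    min_peak_distance_px: float = 8.0

    def __post_init__(self) -> None:
        if not (0 < self.min_area_px < self.max_area_px):
            raise ValueError("areas must satisfy 0 < min_area_px < max_area_px")
        if self.adaptive_block_px < 3 or self.adaptive_block_px % 2 == 0:
            raise ValueError("adaptive_block_px must be odd and >= 3")
        if min(
            self.opening_radius_px,
            self.background_kernel_radius_px,
            self.erosion_radius_px,
        ) < 0 or self.blur_sigma_px < 0:
            raise ValueError("kernel radii must be non-negative")
        if self.declump_iterations < 0:
            raise ValueError("declump_iterations must be >= 0")

    @classmethod
    def from_geometry(
        cls,
        microns_per_px: float = 0.5,
        soma_diameter_um: float = 12.0,
        absolute_background: float = 0.0,
        adaptive_offset: float = 400.0,
    ) -> "CountingConfig":
        """Derive pixel-space parameters from soma geometry.

        Lengths scale with the soma diameter in pixels, d = diameter/scale
        (24 at the reference 0.5 um/px): opening radius d/8, background
        kernel ~d, declump blur sigma d/24 with erosion d/12 over two
        rounds, adaptive block ~2.1 d (odd). Size bounds account for the
        mask shrinkage the declump rounds cause: a nominal soma footprint
        loses roughly iterations x erosion + blur_sigma of radius, so the
        area floor is 25% of pi (d/2 - d/6 - d/24)^2, while the ceiling
        stays at 4x the un-eroded soma area to reject merged clusters and
        artifacts.
        The distance-map peak separation is d/3 and the final intra-center
        distance 5 d/12, sized so detected centroids of touching somas
        (which jitter a few pixels inward) are not suppressed.

        ``adaptive_offset`` is in intensity units and should be roughly
        10-15% of a typical soma peak amplitude above background.
        """
        d_px = soma_diameter_um / microns_per_px  # 24 at the reference scale
        nominal_area = np.pi * (d_px / 2.0) ** 2
        block = int(round(2.125 * d_px))
        if block % 2 == 0:
            block += 1
        return cls(
            absolute_background=absolute_background,
            opening_radius_px=max(1, int(round(d_px / 8.0))),
            background_kernel_radius_px=max(3, int(round(25.0 / 24.0 * d_px))),
            blur_sigma_px=d_px / 24.0,
            erosion_radius_px=max(1, int(round(d_px / 12.0))),
            declump_iterations=2,
            adaptive_block_px=max(3, block),
            adaptive_offset=adaptive_offset,
            min_area_px=0.25 * np.pi * (d_px / 2.0 - d_px / 6.0 - d_px / 24.0) ** 2,
            max_area_px=4.0 * nominal_area,
            min_center_distance_px=5.0 * d_px / 12.0,
            min_peak_distance_px=d_px / 3.0,
        )


@dataclass
class Candidates:
    """Center candidates from the distance map, prior to filtering."""

    x_px: np.ndarray
    y_px: np.ndarray
    edt_value: np.ndarray
    area_px: np.ndarray

    def __len__(self) -> int:
        return len(self.x_px)


@dataclass
class CellDetections:
    """Final detected cell centers with per-object sizes."""

    centers_px: np.ndarray  # (n, 2) of (x, y) in pixels
    areas_px: np.ndarray
    microns_per_px: float = 1.0

    @property
    def count(self) -> int:
        return len(self.centers_px)

    @property
    def centers_um(self) -> np.ndarray:
        return self.centers_px * self.microns_per_px

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "x_px": self.centers_px[:, 0],
                "y_px": self.centers_px[:, 1],
                "x_um": self.centers_um[:, 0],
                "y_um": self.centers_um[:, 1],
                "area_px": self.areas_px,
            }
        )


@dataclass
class RegionMask:
    """Binary mask congruent with the image it restricts."""

    mask: np.ndarray
    provenance: str = "WHOLE_RETINA_OUTLINE"
    roi: Optional[SquareROI] = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @classmethod
    def from_square_roi(cls, image: Image2D, roi: SquareROI) -> "RegionMask":
        h, w = image.shape
        x0 = roi.x_um / image.microns_per_px
        y0 = roi.y_um / image.microns_per_px
        side = roi.side_um / image.microns_per_px
        if x0 < 0 or y0 < 0 or x0 + side > w or y0 + side > h:
            raise ValueError(f"ROI {roi} extends outside the {h}x{w} image")
        mask = np.zeros((h, w), dtype=bool)
        mask[int(np.ceil(y0)) : int(np.ceil(y0 + side)), int(np.ceil(x0)) : int(np.ceil(x0 + side))] = True
        return cls(mask=mask, provenance=f"SQUARE_ROI({roi.x_um}, {roi.y_um}, {roi.side_um})", roi=roi)


def _check_congruent(image: Image2D, mask: RegionMask) -> None:
    if mask.mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.mask.shape} != image shape {image.shape}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _grey_open(pixels: np.ndarray, radius: int) -> np.ndarray:
    if radius <= 0:
        return pixels
    return ndimage.grey_opening(pixels, footprint=disk(radius))


def suppress_background(image: Image2D, cfg: CountingConfig) -> Image2D:
    """Absolute subtraction, small opening, and kernel background removal.

    The local background is estimated by a grayscale opening with the large
    background kernel and subtracted (a white-tophat), which removes both
    smooth illumination and sub-cellular-sized noise. All subtractions clamp
    at zero.
    """
    h, w = image.shape
    k = 2 * cfg.background_kernel_radius_px + 1
    if k > min(h, w):
        raise ValueError(
            f"background kernel ({k} px) larger than image ({h}x{w})"
        )
    px = np.clip(image.pixels - cfg.absolute_background, 0.0, None)
    px = _grey_open(px, cfg.opening_radius_px)
    background = _grey_open(px, cfg.background_kernel_radius_px)
    px = np.clip(px - background, 0.0, None)
    return Image2D(px, image.microns_per_px)


def declump(image: Image2D, cfg: CountingConfig) -> Image2D:
    """Repeated Gaussian blurring and grayscale erosion.

    Each round smooths the image and then erodes it with a small disc,
    deepening the intensity valleys between touching somas so the adaptive
    threshold separates them. Zero iterations return the input unchanged.
    """
    px = image.pixels
    for _ in range(cfg.declump_iterations):
        if cfg.blur_sigma_px > 0:
            px = ndimage.gaussian_filter(px, cfg.blur_sigma_px)
        if cfg.erosion_radius_px > 0:
            px = ndimage.grey_erosion(px, footprint=disk(cfg.erosion_radius_px))
    return Image2D(px, image.microns_per_px)


def binarize(image: Image2D, cfg: CountingConfig) -> np.ndarray:
    """Local adaptive threshold: foreground where intensity exceeds the
    block-local mean by more than ``adaptive_offset``."""
    h, w = image.shape
    if cfg.adaptive_block_px > min(h, w):
        raise ValueError(
            f"adaptive block ({cfg.adaptive_block_px} px) larger than image ({h}x{w})"
        )
    local_mean = ndimage.uniform_filter(
        image.pixels, size=cfg.adaptive_block_px, mode="reflect"
    )
    return image.pixels > local_mean + cfg.adaptive_offset


def locate_centers(mask: np.ndarray, cfg: CountingConfig) -> Candidates:
    """Distance-map local maxima as center candidates.

    Computes the Euclidean distance transform of the foreground; candidate
    centers are its local maxima within ``min_peak_distance_px`` (plateaus
    collapse to their centroid), each carrying the pixel area of its
    supporting connected component. An empty mask yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return Candidates(np.empty(0), np.empty(0), np.empty(0), np.empty(0))

    edt = ndimage.distance_transform_edt(mask)
    labels, _ = ndimage.label(mask)
    areas = np.bincount(labels.ravel())

    r = max(1, int(round(cfg.min_peak_distance_px)))
    neighborhood_max = ndimage.grey_dilation(edt, footprint=disk(r))
    is_peak = mask & (edt >= neighborhood_max)

    # collapse plateau maxima (e.g. disc centers) to their centroids
    peak_labels, n_peaks = ndimage.label(is_peak)
    if n_peaks == 0:
        return Candidates(np.empty(0), np.empty(0), np.empty(0), np.empty(0))
    centroids = ndimage.center_of_mass(is_peak, peak_labels, np.arange(1, n_peaks + 1))
    cy = np.array([c[0] for c in centroids])
    cx = np.array([c[1] for c in centroids])
    # representative pixel of each plateau for value / component lookup
    ys, xs = np.nonzero(is_peak)
    first = np.full(n_peaks + 1, -1, dtype=int)
    for i, lab in enumerate(peak_labels[ys, xs]):
        if first[lab] < 0:
            first[lab] = i
    rep = first[1:]
    vals = edt[ys[rep], xs[rep]]
    comp = labels[ys[rep], xs[rep]]
    cand_areas = areas[comp].astype(float)

    # enforce the minimum peak separation between plateau centroids with
    # the same greedy rule used in the final filter
    keep = _greedy_suppress(cx, cy, vals, cand_areas, cfg.min_peak_distance_px)
    return Candidates(cx[keep], cy[keep], vals[keep], cand_areas[keep])


def _greedy_suppress(
    x: np.ndarray, y: np.ndarray, value: np.ndarray, area: np.ndarray, min_dist: float
) -> np.ndarray:
    """Greedy suppression of candidates closer than ``min_dist``.

    Candidates are visited in descending value; ties broken by larger area,
    then by row-major position (y, then x). Returns indices of accepted
    candidates, in visiting order.
    """
    n = len(x)
    if n == 0:
        return np.empty(0, dtype=int)
    order = sorted(range(n), key=lambda i: (-value[i], -area[i], y[i], x[i]))
    accepted: list[int] = []
    min_d2 = min_dist * min_dist
    for i in order:
        ok = True
        for j in accepted:
            if (x[i] - x[j]) ** 2 + (y[i] - y[j]) ** 2 < min_d2:
                ok = False
                break
        if ok:
            accepted.append(i)
    return np.asarray(accepted, dtype=int)


def filter_detections(
    candidates: Candidates, cfg: CountingConfig, microns_per_px: float = 1.0
) -> CellDetections:
    """Size filtering plus greedy intra-center-distance suppression.

    Candidates whose supporting component area falls outside
    ``[min_area_px, max_area_px]`` are discarded; the remainder are visited
    in descending distance-map value (ties: larger area, then row-major
    position) and any candidate closer than ``min_center_distance_px`` to an
    already-accepted one is suppressed.
    """
    sel = (candidates.area_px >= cfg.min_area_px) & (candidates.area_px <= cfg.max_area_px)
    x = candidates.x_px[sel]
    y = candidates.y_px[sel]
    v = candidates.edt_value[sel]
    a = candidates.area_px[sel]
    keep = _greedy_suppress(x, y, v, a, cfg.min_center_distance_px)
    centers = np.column_stack([x[keep], y[keep]]) if len(keep) else np.empty((0, 2))
    return CellDetections(centers_px=centers, areas_px=a[keep], microns_per_px=microns_per_px)


def count_cells(
    image: Image2D, cfg: Optional[CountingConfig] = None, mask: Optional[RegionMask] = None
) -> CellDetections:
    """End-to-end soma counting.

    Composes background suppression, declumping, binarization, distance-map
    center detection and filtering. When a mask is given, only detections
    whose center lies inside the mask are returned; the mask restricts the
    detection list rather than the image, so it introduces no artificial
    edges into the filtering stages.
    """
    if cfg is None:
        cfg = CountingConfig.from_geometry(image.microns_per_px)
    if mask is not None:
        _check_congruent(image, mask)
    det = filter_detections(
        locate_centers(binarize(declump(suppress_background(image, cfg), cfg), cfg), cfg),
        cfg,
        microns_per_px=image.microns_per_px,
    )
    if mask is not None and det.count:
        ix = np.clip(np.rint(det.centers_px[:, 0]).astype(int), 0, image.width_px - 1)
        iy = np.clip(np.rint(det.centers_px[:, 1]).astype(int), 0, image.height_px - 1)
        inside = mask.mask[iy, ix]
        det = CellDetections(
            centers_px=det.centers_px[inside],
            areas_px=det.areas_px[inside],
            microns_per_px=det.microns_per_px,
        )
    return det


def count_in_regions(
    image: Image2D, cfg: Optional[CountingConfig] = None, rois: Sequence[SquareROI] = ()
):
    """Count and density (cells/mm^2) per square ROI.

    Runs the pipeline once on the full image and assigns detections to each
    half-open ROI; density = count / (side_um^2 * 1e-6).
    """
    import pandas as pd

    for roi in rois:
        # raises with the offending ROI named
        RegionMask.from_square_roi(image, roi)
    det = count_cells(image, cfg)
    rows = []
    for roi in rois:
        rect = roi.rect
        if det.count:
            m = rect.contains(det.centers_um[:, 0], det.centers_um[:, 1])
            n = int(np.count_nonzero(m))
        else:
            n = 0
        rows.append(
            {
                "x_um": roi.x_um,
                "y_um": roi.y_um,
                "side_um": roi.side_um,
                "count": n,
                "density_per_mm2": n / roi.area_mm2,
            }
        )
    return pd.DataFrame(rows)
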