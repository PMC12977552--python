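"""Ground-truthed synthetic data for every analysis stage.

This module renders flat-mount-like images of RBPMS-stained retinal ganglion
cell somas, simulates uniform and clustered point patterns standing in for
Iba1+ myeloid-cell distributions, applies sector-restricted cell loss (the
mosaic-deletion geometry), and draws dot-blot membranes whose spot
intensities encode a known abundance vector in technical duplicates.

Every generator is deterministic given its spec and seed: the same inputs
produce bit-identical images and ground truth.

Default parameters describe the imaging regime the analysis assumes: a
retina carrying ~50,000 ganglion cells at roughly 3,400 somas/mm^2, somas
about 12 um across, imaged at 0.5 um/px on a 16-bit camera with modest
uneven illumination and read noise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import Disc, Rect, Window
from .image import Image2D
from .spatial import PointPattern

__all__ = [
    "FlatMountSpec",
    "GroundTruth",
    "PointPatternSpec",
    "ArrayMembraneSpec",
    "PackingError",
    "generate_flatmount",
    "apply_sector_loss",
    "generate_point_pattern",
    "generate_membrane",
    "membrane_layout",
]


class PackingError(RuntimeError):
    """Requested cell density is incompatible with the minimum separation."""


# ---------------------------------------------------------------------------
# Flat-mount scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlatMountSpec:
    """Parameters of a synthetic RBPMS flat-mount image.

    Somas are rendered as additive isotropic Gaussian blobs truncated at
    3*sigma with sigma = soma_radius/2. A ``clump_fraction`` of cells is
    placed in touching clumps (center spacing uniform in 0.8-1.2 soma
    diameters), which is the case the declumping stage must solve. The
    background is a constant offset plus a planar illumination ramp of the
    stated peak amplitude, with additive Gaussian noise and optional Poisson
    shot noise.
    """

    width_px: int = 512
    height_px: int = 512
    microns_per_px: float = 0.5
    retina_radius_um: Optional[float] = None  # None -> full rectangular tile
    n_cells: Optional[int] = None             # overrides density when given
    density_per_mm2: float = 3400.0
    soma_radius_um_mean: float = 6.0
    soma_radius_um_sd: float = 0.5
    peak_intensity_mean: float = 3000.0
    peak_intensity_sd: float = 400.0
    clump_fraction: float = 0.2
    clump_size_mean: float = 2.3
    background_offset: float = 500.0
    gradient_amplitude: float = 300.0
    noise_sd: float = 60.0
    poisson_noise: bool = False
    min_separation_um: Optional[float] = None  # None -> 0.9 soma diameters
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.microns_per_px <= 0:
            raise ValueError("microns_per_px must be positive")
        if not 0.0 <= self.clump_fraction <= 1.0:
            raise ValueError("clump_fraction must lie in [0, 1]")
        if self.n_cells is not None and self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.soma_radius_um_mean <= 0:
            raise ValueError("soma radius must be positive")
        if self.clump_size_mean < 2:
            raise ValueError("clump_size_mean must be >= 2")

    @property
    def window(self) -> Window:
        w = self.width_px * self.microns_per_px
        h = self.height_px * self.microns_per_px
        if self.retina_radius_um is not None:
            return Disc(w / 2.0, h / 2.0, self.retina_radius_um)
        return Rect(0.0, 0.0, w, h)

    @property
    def soma_diameter_um(self) -> float:
        return 2.0 * self.soma_radius_um_mean

    @property
    def separation_um(self) -> float:
        if self.min_separation_um is not None:
            return self.min_separation_um
        return 0.9 * self.soma_diameter_um

    def target_n_cells(self) -> int:
        if self.n_cells is not None:
            return self.n_cells
        return int(round(self.density_per_mm2 * self.window.area_mm2))


@dataclass
class GroundTruth:
    """True cell record of a synthetic scene.

    ``cells`` has one row per soma: x_um, y_um, radius_um, peak_intensity,
    sector_label. ``true_count`` always equals the number of rows.
    """

    cells: pd.DataFrame
    window: Window
    microns_per_px: float = 0.5

    COLUMNS = ("x_um", "y_um", "radius_um", "peak_intensity", "sector_label")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.cells.columns]
        if missing:
            raise ValueError(f"ground-truth table missing columns: {missing}")

    @property
    def true_count(self) -> int:
        return len(self.cells)

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def _empty_truth_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "radius_um": pd.Series(dtype=float),
            "peak_intensity": pd.Series(dtype=float),
            "sector_label": pd.Series(dtype=object),
        }
    )


class _DartBoard:
    """Grid-bucketed dart thrower enforcing a minimum center separation."""

    def __init__(self, window: Window, separation: float) -> None:
        self.window = window
        self.sep = separation
        self.cell = max(separation, 1e-9)
        self.grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
        self.points: list[tuple[float, float]] = []

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(math.floor(x / self.cell)), int(math.floor(y / self.cell)))

    def ok(self, x: float, y: float, ignore: Optional[set[int]] = None) -> bool:
        """True if (x, y) is >= separation away from all accepted points.

        ``ignore`` holds indices of points exempt from the check (clump
        mates, whose spacing is sampled explicitly).
        """
        kx, ky = self._key(x, y)
        sep2 = self.sep * self.sep
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for idx in self.grid.get((kx + dx, ky + dy), ()):  # type: ignore[arg-type]
                    if ignore and idx in ignore:
                        continue
                    px, py = self.points[idx]
                    if (px - x) ** 2 + (py - y) ** 2 < sep2:
                        return False
        return True

    def add(self, x: float, y: float) -> int:
        idx = len(self.points)
        self.points.append((x, y))
        self.grid.setdefault(self._key(x, y), []).append(idx)
        return idx


def _sample_in_window(rng: np.random.Generator, window: Window, margin: float) -> tuple[float, float]:
    if isinstance(window, Rect):
        x = rng.uniform(window.x0 + margin, window.x1 - margin)
        y = rng.uniform(window.y0 + margin, window.y1 - margin)
        return x, y
    # rejection-sample within the disc's bounding box
    r = window.radius - margin
    if r <= 0:
        raise PackingError("window too small for the requested soma radius")
    while True:
        x = rng.uniform(window.cx - r, window.cx + r)
        y = rng.uniform(window.cy - r, window.cy + r)
        if (x - window.cx) ** 2 + (y - window.cy) ** 2 <= r * r:
            return x, y


def _place_cells(rng: np.random.Generator, spec: FlatMountSpec, n: int) -> np.ndarray:
    """Place n cell centers; returns (n, 2) array of (x_um, y_um).

    Non-clumped cells (and clump anchors) keep a minimum pairwise separation;
    clump members are chained off an existing member at a center spacing
    uniform in [0.8, 1.2] soma diameters, exempt from the separation rule
    against their own clump only.
    """
    window = spec.window
    margin = spec.soma_radius_um_mean  # edge policy: cells wholly inside
    board = _DartBoard(window, spec.separation_um)

    n_clumped_target = int(round(spec.clump_fraction * n))
    clump_sizes: list[int] = []
    remaining = n_clumped_target
    while remaining >= 2:
        size = 2 + int(rng.poisson(spec.clump_size_mean - 2.0))
        size = min(size, remaining)
        if size < 2:
            size = 2
        clump_sizes.append(size)
        remaining -= size
    n_single = n - sum(clump_sizes)

    max_attempts_per_cell = 2000

    def throw(ignore: Optional[set[int]] = None) -> tuple[float, float]:
        for _ in range(max_attempts_per_cell):
            x, y = _sample_in_window(rng, window, margin)
            if board.ok(x, y, ignore):
                return x, y
        achieved = len(board.points)
        raise PackingError(
            f"could not place cell {achieved + 1}/{n}: density "
            f"{spec.target_n_cells() / window.area_mm2:.0f}/mm^2 with "
            f"min separation {spec.separation_um:.1f} um is infeasible; "
            f"achievable maximum here is ~{achieved / window.area_mm2:.0f}/mm^2"
        )

    # clumps are grown first, while the board is sparse, then singles fill
    # the gaps; the fixed order keeps the draw sequence deterministic
    diam = spec.soma_diameter_um
    for size in clump_sizes:
        x, y = throw()
        members = {board.add(x, y)}
        placed = 1
        attempts = 0
        while placed < size:
            attempts += 1
            if attempts > max_attempts_per_cell:
                achieved = len(board.points)
                raise PackingError(
                    "could not grow a clump without violating the minimum "
                    f"separation against neighboring cells; achievable maximum "
                    f"here is ~{achieved / window.area_mm2:.0f}/mm^2"
                )
            base = board.points[
                list(members)[int(rng.integers(len(members)))]
            ]
            spacing = diam * rng.uniform(0.8, 1.2)
            theta = rng.uniform(0.0, 2.0 * math.pi)
            cx = base[0] + spacing * math.cos(theta)
            cy = base[1] + spacing * math.sin(theta)
            if not bool(window.contains(cx, cy, margin=margin)):
                continue
            if not board.ok(cx, cy, ignore=members):
                continue
            # clump mates are exempt from the global separation rule but
            # still keep at least 0.8 soma diameters between their centers
            min_mate2 = (0.8 * diam) ** 2
            too_close = False
            for idx in members:
                mx, my = board.points[idx]
                if (mx - cx) ** 2 + (my - cy) ** 2 < min_mate2:
                    too_close = True
                    break
            if too_close:
                continue
            members.add(board.add(cx, cy))
            placed += 1

    for _ in range(n_single):
        x, y = throw()
        board.add(x, y)

    return np.asarray(board.points, dtype=float)


def _render_somas(
    pixels: np.ndarray,
    spec: FlatMountSpec,
    xy_um: np.ndarray,
    radii_um: np.ndarray,
    peaks: np.ndarray,
) -> None:
    """Add one truncated Gaussian blob per cell, in place."""
    mpp = spec.microns_per_px
    h, w = pixels.shape
    for (x_um, y_um), r_um, peak in zip(xy_um, radii_um, peaks):
        sigma_px = (r_um / 2.0) / mpp
        trunc = 3.0 * sigma_px
        cx = x_um / mpp
        cy = y_um / mpp
        x_lo = max(int(math.floor(cx - trunc)), 0)
        x_hi = min(int(math.ceil(cx + trunc)) + 1, w)
        y_lo = max(int(math.floor(cy - trunc)), 0)
        y_hi = min(int(math.ceil(cy + trunc)) + 1, h)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        ys = np.arange(y_lo, y_hi, dtype=float)[:, None] - cy
        xs = np.arange(x_lo, x_hi, dtype=float)[None, :] - cx
        r2 = xs * xs + ys * ys
        blob = peak * np.exp(-r2 / (2.0 * sigma_px**2))
        blob[r2 > trunc * trunc] = 0.0
        pixels[y_lo:y_hi, x_lo:x_hi] += blob


def _background(rng: np.random.Generator, spec: FlatMountSpec) -> np.ndarray:
    """Constant offset plus a planar ramp of the stated peak amplitude."""
    h, w = spec.height_px, spec.width_px
    bg = np.full((h, w), float(spec.background_offset))
    theta = rng.uniform(0.0, 2.0 * math.pi)  # drawn regardless of amplitude
    if spec.gradient_amplitude != 0.0:
        yy, xx = np.mgrid[0:h, 0:w]
        proj = xx * math.cos(theta) + yy * math.sin(theta)
        span = proj.max() - proj.min()
        if span > 0:
            bg += spec.gradient_amplitude * (proj - proj.min()) / span
    return bg


def generate_flatmount(spec: FlatMountSpec) -> tuple[Image2D, GroundTruth]:
    """Render a synthetic flat-mount tile and its ground truth.

    Returns the float image (quantize via :meth:`Image2D.to_uint16` when
    writing) and a :class:`GroundTruth` listing every rendered soma.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.target_n_cells()

    if n > 0:
        xy = _place_cells(rng, spec, n)
        radii = np.clip(
            rng.normal(spec.soma_radius_um_mean, spec.soma_radius_um_sd, size=n),
            0.25 * spec.soma_radius_um_mean,
            None,
        )
        peaks = np.clip(
            rng.normal(spec.peak_intensity_mean, spec.peak_intensity_sd, size=n),
            0.1 * spec.peak_intensity_mean,
            None,
        )
    else:
        xy = np.empty((0, 2))
        radii = np.empty(0)
        peaks = np.empty(0)

    pixels = _background(rng, spec)
    _render_somas(pixels, spec, xy, radii, peaks)

    if spec.poisson_noise:
        pixels = rng.poisson(np.clip(pixels, 0.0, None)).astype(np.float64)
    if spec.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, None)

    cells = _empty_truth_frame()
    if n > 0:
        cells = pd.DataFrame(
            {
                "x_um": xy[:, 0],
                "y_um": xy[:, 1],
                "radius_um": radii,
                "peak_intensity": peaks,
                "sector_label": np.full(n, "cre_neg", dtype=object),
            }
        )
    truth = GroundTruth(cells=cells, window=spec.window, microns_per_px=spec.microns_per_px)
    return Image2D(pixels, spec.microns_per_px), truth


def apply_sector_loss(
    truth: GroundTruth,
    angular_range_deg: float,
    loss_fraction: float,
    seed: int,
    start_deg: float = 0.0,
) -> GroundTruth:
    """Remove cells inside an angular sector with a given probability.

    Emulates mosaic gene deletion confined to a retinal sector: cells whose
    polar angle about the window center lies in ``[start, start + range)``
    are labeled ``cre_pos`` and each removed independently with probability
    ``loss_fraction``; cells outside the sector are labeled ``cre_neg`` and
    untouched.
    """
    if not 0.0 <= loss_fraction <= 1.0:
        raise ValueError("loss_fraction must lie in [0, 1]")
    if truth.true_count == 0:
        return truth

    rng = np.random.default_rng(seed)
    cx, cy = truth.window.center
    ang = np.degrees(
        np.arctan2(truth.cells["y_um"].to_numpy() - cy, truth.cells["x_um"].to_numpy() - cx)
    ) % 360.0
    rel = (ang - start_deg) % 360.0
    in_sector = rel < min(angular_range_deg, 360.0)
    if angular_range_deg >= 360.0:
        in_sector = np.ones(truth.true_count, dtype=bool)

    removed = in_sector & (rng.random(truth.true_count) < loss_fraction)
    cells = truth.cells.copy()
    cells["sector_label"] = np.where(in_sector, "cre_pos", "cre_neg")
    cells = cells.loc[~removed].reset_index(drop=True)
    return GroundTruth(cells=cells, window=truth.window, microns_per_px=truth.microns_per_px)


# ---------------------------------------------------------------------------
# Point patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PointPatternSpec:
    """A homogeneous Poisson (CSR) or Thomas cluster process in a window.

    For the Thomas process, parents follow a Poisson process of intensity
    ``thomas_parent_per_mm2``; each parent spawns Poisson(``mean_offspring``)
    points displaced by an isotropic Gaussian of scale ``thomas_sigma_um``.
    The product parent_intensity * mean_offspring is the realized intensity
    and should match ``lambda_per_mm2``.
    """

    process: str = "CSR"  # "CSR" | "THOMAS"
    lambda_per_mm2: float = 200.0
    window_um: Window = field(default_factory=lambda: Rect(0.0, 0.0, 1000.0, 1000.0))
    thomas_parent_per_mm2: float = 40.0
    thomas_mean_offspring: float = 5.0
    thomas_sigma_um: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.process not in ("CSR", "THOMAS"):
            raise ValueError("process must be 'CSR' or 'THOMAS'")
        if self.lambda_per_mm2 <= 0:
            raise ValueError("lambda_per_mm2 must be positive")
        if self.window_um.area_um2 <= 0:
            raise ValueError("window area must be positive")
        if self.process == "THOMAS":
            realized = self.thomas_parent_per_mm2 * self.thomas_mean_offspring
            if not math.isclose(realized, self.lambda_per_mm2, rel_tol=0.05):
                raise ValueError(
                    "Thomas parent intensity x mean offspring "
                    f"({realized:.1f}) must approximate lambda_per_mm2 "
                    f"({self.lambda_per_mm2:.1f})"
                )


def _uniform_in(rng: np.random.Generator, window: Window, n: int) -> np.ndarray:
    if isinstance(window, Rect):
        xs = rng.uniform(window.x0, window.x1, size=n)
        ys = rng.uniform(window.y0, window.y1, size=n)
        return np.column_stack([xs, ys])
    pts = []
    while len(pts) < n:
        x = rng.uniform(window.cx - window.radius, window.cx + window.radius)
        y = rng.uniform(window.cy - window.radius, window.cy + window.radius)
        if (x - window.cx) ** 2 + (y - window.cy) ** 2 <= window.radius**2:
            pts.append((x, y))
    return np.asarray(pts) if pts else np.empty((0, 2))


def generate_point_pattern(
    spec: PointPatternSpec, layer: Optional[str] = None, region: Optional[str] = None
) -> PointPattern:
    """Simulate one realization of the specified point process."""
    rng = np.random.default_rng(spec.seed)
    window = spec.window_um
    lam_um2 = spec.lambda_per_mm2 * 1e-6  # points per um^2

    if spec.process == "CSR":
        n = int(rng.poisson(lam_um2 * window.area_um2))
        pts = _uniform_in(rng, window, n)
    else:
        # simulate parents in the window dilated by 4 sigma so offspring of
        # outside parents can fall into the window (edge-corrected Thomas)
        pad = 4.0 * spec.thomas_sigma_um
        if isinstance(window, Rect):
            ext: Window = Rect(window.x0 - pad, window.y0 - pad, window.x1 + pad, window.y1 + pad)
        else:
            ext = Disc(window.cx, window.cy, window.radius + pad)
        kappa_um2 = spec.thomas_parent_per_mm2 * 1e-6
        n_parents = int(rng.poisson(kappa_um2 * ext.area_um2))
        parents = _uniform_in(rng, ext, n_parents)
        offspring = []
        for px, py in parents:
            m = int(rng.poisson(spec.thomas_mean_offspring))
            if m == 0:
                continue
            pts_i = rng.normal(0.0, spec.thomas_sigma_um, size=(m, 2)) + (px, py)
            offspring.append(pts_i)
        pts = np.concatenate(offspring, axis=0) if offspring else np.empty((0, 2))
        if len(pts):
            keep = np.asarray(window.contains(pts[:, 0], pts[:, 1]), dtype=bool)
            pts = pts[keep]

    return PointPattern(points=pts, window=window, layer=layer, region=region)


# ---------------------------------------------------------------------------
# Dot-blot membranes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArrayMembraneSpec:
    """Synthetic dot-blot membrane with technical-duplicate spots.

    Each analyte maps to exactly two grid positions; the two spots share the
    analyte's abundance equally, so the total rendered intensity is
    proportional to ``true_abundance``. Spots are uniform discs convolved
    with a Gaussian (film blur) over a uniform background with optional
    Gaussian noise.
    """

    n_rows: int = 4
    n_cols: int = 6
    spot_radius_px: float = 8.0
    spot_pitch_px: float = 40.0
    duplicate_pairs: dict = field(
        default_factory=dict
    )  # analyte -> ((row, col), (row, col))
    true_abundance: dict = field(default_factory=dict)  # analyte -> abundance > 0
    background_level: float = 20.0
    blur_sigma_px: float = 2.0
    noise_sd: float = 0.0
    intensity_per_unit: float = 50.0  # peak counts per abundance unit
    seed: int = 0

    def __post_init__(self) -> None:
        if self.spot_pitch_px < 2.0 * self.spot_radius_px:
            raise ValueError("spots overlap: pitch must be >= 2 x radius")
        seen: dict[tuple[int, int], str] = {}
        for analyte, positions in self.duplicate_pairs.items():
            if len(positions) != 2 or positions[0] == positions[1]:
                raise ValueError(
                    f"analyte {analyte!r} must map to exactly 2 distinct grid positions"
                )
            for pos in positions:
                r, c = pos
                if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                    raise ValueError(f"grid position {pos} outside {self.n_rows}x{self.n_cols}")
                if pos in seen:
                    raise ValueError(f"grid position {pos} assigned twice")
                seen[pos] = analyte
            if analyte not in self.true_abundance:
                raise ValueError(f"no abundance for analyte {analyte!r}")
            if self.true_abundance[analyte] <= 0:
                raise ValueError("abundances must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        h = int(round((self.n_rows + 1) * self.spot_pitch_px))
        w = int(round((self.n_cols + 1) * self.spot_pitch_px))
        return h, w

    def center_of(self, row: int, col: int) -> tuple[float, float]:
        """Pixel center (x, y) of a grid position."""
        return ((col + 1) * self.spot_pitch_px, (row + 1) * self.spot_pitch_px)


def generate_membrane(spec: ArrayMembraneSpec) -> tuple[Image2D, dict]:
    """Render a membrane; returns the image and the true abundance mapping."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    ideal = np.zeros((h, w), dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]

    for analyte, positions in spec.duplicate_pairs.items():
        amp = spec.intensity_per_unit * spec.true_abundance[analyte]
        for row, col in positions:
            cx, cy = spec.center_of(row, col)
            disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= spec.spot_radius_px**2
            ideal[disc] += amp

    if spec.blur_sigma_px > 0:
        ideal = ndimage.gaussian_filter(ideal, spec.blur_sigma_px)
    pixels = ideal + spec.background_level
    if spec.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, spec.noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, None)
    return Image2D(pixels, 1.0), dict(spec.true_abundance)


def membrane_layout(spec: ArrayMembraneSpec, roi_radius_px: Optional[float] = None):
    """Build the quantification layout matching a membrane spec.

    The measurement ROI defaults to spot_radius + 3*blur_sigma so the
    blurred spot is captured essentially completely; the background ROI is
    placed in the blank top-left grid margin.
    """
    from .array_quant import ArrayLayout

    if roi_radius_px is None:
        roi_radius_px = spec.spot_radius_px + 3.0 * spec.blur_sigma_px
    half_pitch = spec.spot_pitch_px / 2.0
    background_center = (half_pitch, half_pitch)
    centers = {
        analyte: tuple(spec.center_of(*pos) for pos in positions)
        for analyte, positions in spec.duplicate_pairs.items()
    }
    return ArrayLayout(
        spot_centers=centers,
        spot_radius_px=float(roi_radius_px),
        background_center=background_center,
    )
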