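"""EB1 comet morphometry on fixed two-channel images.

The junction channel (e.g. ZO-1) segments the field into cells by
marker-based watershed; the comet channel is thresholded and connected
components become particles whose moment-fit ellipse gives the aspect
ratio (AR = major/minor axis), the proxy for comet length at constant
comet width.  ARs are averaged per cell, and conditions are summarized
as mean ± SEM over cells (the cell is the statistical unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import local_minima
from skimage.segmentation import watershed

from .stats import summarize


@dataclass
class CellLabelMap:
    """Integer cell label per pixel; 0 is background/junction line."""

    labels: np.ndarray  # (H, W) int, 0 = watershed line / background
    n_cells: int
    border_touching: set[int] = field(default_factory=set)

    def cell_of(self, y: float, x: float) -> int:
        iy = int(round(y))
        ix = int(round(x))
        H, W = self.labels.shape
        if not (0 <= iy < H and 0 <= ix < W):
            return 0
        return int(self.labels[iy, ix])


@dataclass
class Particle:
    """One detected comet."""

    centroid: tuple[float, float]  # (y, x) px
    area: float  # px^2
    major_axis: float  # px, full moment-fit ellipse axis
    minor_axis: float  # px
    aspect_ratio: float  # major / minor, >= 1
    cell_label: int


@dataclass
class CellMorphometry:
    """Per-cell comet summary; cells without comets are not represented."""

    cell_label: int
    n_comets: int
    mean_ar: float


def segment_cells(
    junction_image: np.ndarray,
    min_cell_area: float = 64.0,
    smoothing_sigma: float = 3.0,
    quantize_levels: int = 64,
    exclude_border_cells: bool = False,
) -> CellLabelMap:
    """Segment cells from a junction-stained channel.

    The junction signal is bright on cell-cell boundaries, so cell
    interiors are basins of the smoothed image.  The smoothed image is
    quantized to ``quantize_levels`` grey levels so that flat interiors
    form connected minima plateaus; plateau components with area >=
    ``min_cell_area`` become watershed markers and the watershed of the
    smoothed image assigns every pixel to a cell.  Regions touching the
    frame border are flagged and optionally relabelled to 0.
    """
    img = np.asarray(junction_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("junction image must be 2-D")
    sm = ndi.gaussian_filter(img, smoothing_sigma)
    rng_ = sm.max() - sm.min()
    if rng_ <= 0:
        labels = np.ones(img.shape, dtype=np.int32)
        return CellLabelMap(labels, 1, border_touching={1})
    q = np.floor((sm - sm.min()) / rng_ * (quantize_levels - 1)).astype(np.int32)
    minima = local_minima(q, connectivity=2, allow_borders=True)
    marker_cc = cc_label(minima, connectivity=2)
    markers = np.zeros_like(marker_cc)
    next_id = 0
    for r in regionprops(marker_cc):
        if r.area >= min_cell_area:
            next_id += 1
            markers[marker_cc == r.label] = next_id
    if next_id == 0:
        raise ValueError(
            "no watershed markers found; lower min_cell_area or smooth more"
        )
    labels = watershed(sm, markers).astype(np.int32)
    border = set(np.unique(np.concatenate([
        labels[0], labels[-1], labels[:, 0], labels[:, -1]
    ])).tolist()) - {0}
    if exclude_border_cells:
        for b in border:
            labels[labels == b] = 0
        # relabel contiguously
        remaining = sorted(set(np.unique(labels).tolist()) - {0})
        remap = {old: new for new, old in enumerate(remaining, start=1)}
        out = np.zeros_like(labels)
        for old, new in remap.items():
            out[labels == old] = new
        return CellLabelMap(out, len(remaining), border_touching=set())
    return CellLabelMap(labels, next_id, border_touching=border)


MIN_COMET_AREA_DEFAULT = 4.0  # px^2 at the 3x-upscaled resolution


def detect_comet_particles(
    comet_image: np.ndarray,
    cells: CellLabelMap,
    min_area: float = MIN_COMET_AREA_DEFAULT,
    threshold_method: str = "otsu",
    fixed_threshold: float | None = None,
) -> list[Particle]:
    """Detect comet particles and assign each to a cell.

    The (already upscaled and background-subtracted) comet channel is
    thresholded — Otsu by default, or a caller-fixed level — and
    8-connected components are measured.  Components smaller than
    ``min_area`` or with a degenerate (zero-minor-axis) moment ellipse
    are discarded; each surviving component is assigned to the cell
    containing its centroid, and components whose centroid falls on
    label 0 are discarded.  Ellipse axes follow the moment-fit
    convention: full axes are ``4 * sqrt(eigenvalue)`` of the 2x2
    covariance of member pixel coordinates.
    """
    img = np.asarray(comet_image, dtype=float)
    if img.shape != cells.labels.shape:
        raise ValueError("comet image and cell map shapes differ")
    if threshold_method == "otsu":
        if np.ptp(img) == 0:
            return []
        thr = threshold_otsu(img)
    elif threshold_method == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed_threshold required for threshold_method='fixed'")
        thr = float(fixed_threshold)
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    mask = img > thr
    if not mask.any():
        return []
    comps = cc_label(mask, connectivity=2)
    particles: list[Particle] = []
    for r in regionprops(comps):
        if r.area < min_area:
            continue
        minor = r.axis_minor_length
        major = r.axis_major_length
        if minor <= 0:
            continue  # collinear pixels: ellipse degenerate
        cy, cx = r.centroid
        owner = cells.cell_of(cy, cx)
        if owner == 0:
            continue
        particles.append(Particle(
            centroid=(float(cy), float(cx)),
            area=float(r.area),
            major_axis=float(major),
            minor_axis=float(minor),
            aspect_ratio=float(major / minor),
            cell_label=owner,
        ))
    return particles


def per_cell_mean_ar(particles: list[Particle],
                     cells: CellLabelMap) -> list[CellMorphometry]:
    """Mean comet aspect ratio per cell; cells with no comets are omitted."""
    by_cell: dict[int, list[float]] = {}
    for p in particles:
        if not (1 <= p.cell_label <= cells.n_cells):
            raise ValueError(f"particle assigned to unknown cell {p.cell_label}")
        by_cell.setdefault(p.cell_label, []).append(p.aspect_ratio)
    return [
        CellMorphometry(cell, len(ars), float(np.mean(ars)))
        for cell, ars in sorted(by_cell.items())
    ]


def condition_summary(cell_values: list[float] | np.ndarray,
                      label: str = "") -> tuple[float, float, int]:
    """Condition-level mean ± SEM over per-cell values (N = cells)."""
    vals = np.asarray(cell_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 cells for a condition summary")
    mean, sem, n = summarize(vals)
    return mean, sem, n
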