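"""Kymograph-based lateral motility quantification.

A region inside an epithelial island is "time-sliced": every sampled
row and column of the region becomes a kymograph whose rows are time
and columns are position along the line.  A stationary feature is a
vertical streak; a feature moving along the sampled line at s px/frame
is a streak of slope s columns per row, i.e. at atan(s) from vertical.
Streaks are traced with the ridge detector and each trace is scored by
the absolute deviation of its Feret (maximum-caliper) angle from the
vertical time axis, in [0°, 90°]; deviations pooled over all kymographs
of a region are averaged into the region's motility score.

Movies are expected to be stabilized (optional) and temporally
running-averaged first, which removes fast zero-mean jitter and leaves
only sustained lateral movement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imgio import ImageStack
from .preprocess import RUNNING_AVERAGE_WINDOW_DEFAULT, running_average, stabilize
from .ridges import RidgeParams, detect_ridges


@dataclass
class Kymograph:
    """Rows = time (one per frame), columns = position along the line."""

    pixels: np.ndarray  # (n_frames, extent)
    line_axis: str  # 'x': a row of the region was sampled; 'y': a column
    line_index: int  # which row/column of the region

    def __post_init__(self) -> None:
        if self.line_axis not in ("x", "y"):
            raise ValueError("line_axis must be 'x' or 'y'")


@dataclass
class MotilityResult:
    region_id: int
    mean_deviation: float  # degrees in [0, 90]
    n_traces: int
    per_trace_deviations: list[float] = field(default_factory=list)


@dataclass
class Rect:
    """Region rectangle in pixels: origin (y, x), size (height, width)."""

    y: int
    x: int
    height: int
    width: int


def build_kymographs(movie: ImageStack, region: Rect | tuple[int, int, int, int],
                     stride: int = 1) -> list[Kymograph]:
    """Time-slice a region in both x and y directions.

    Every ``stride``-th row of the region yields a kymograph with
    ``line_axis='x'`` (pixel (t, s) = movie[t, row, x+s]) and every
    ``stride``-th column one with ``line_axis='y'``.
    """
    if int(stride) < 1:
        raise ValueError("stride must be >= 1")
    if not isinstance(region, Rect):
        region = Rect(*region)
    frames_axis = movie.axis_index("t")
    frames = np.moveaxis(movie.pixels, frames_axis, 0)
    H, W = frames.shape[-2:]
    if not (0 <= region.y and 0 <= region.x
            and region.y + region.height <= H and region.x + region.width <= W
            and region.height >= 1 and region.width >= 1):
        raise ValueError(f"region {region} outside frame bounds {H}x{W}")
    sub = frames[:, region.y:region.y + region.height,
                 region.x:region.x + region.width]
    kymos = []
    for r in range(0, region.height, int(stride)):
        kymos.append(Kymograph(np.ascontiguousarray(sub[:, r, :]), "x", r))
    for c in range(0, region.width, int(stride)):
        kymos.append(Kymograph(np.ascontiguousarray(sub[:, :, c]), "y", c))
    return kymos


def feret_diameter_angle(points: np.ndarray) -> tuple[float, float]:
    """Maximum-caliper (Feret) diameter and orientation of a point set.

    Returns ``(diameter, angle_deg)`` with the angle of the diameter
    chord measured from the column (position) axis in [0°, 180°).  The
    search runs over convex hull vertices (every diameter endpoint lies
    on the hull); ties on the exact squared distance resolve to the
    lexicographically first index pair in the original ordering.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points")
    idx = _hull_indices(pts)
    cand = pts[idx]
    diff = cand[:, None, :] - cand[None, :, :]
    d2 = (diff**2).sum(axis=2)
    best = -1.0
    best_pair = (0, 0)
    k = len(idx)
    for a in range(k):
        for b in range(a + 1, k):
            ia, ib = int(idx[a]), int(idx[b])
            i, j = (ia, ib) if ia < ib else (ib, ia)
            if d2[a, b] > best or (d2[a, b] == best and (i, j) < best_pair):
                best = d2[a, b]
                best_pair = (i, j)
    p1, p2 = pts[best_pair[0]], pts[best_pair[1]]
    dt = p2[0] - p1[0]  # rows = time
    dc = p2[1] - p1[1]  # columns = position
    ang = math.degrees(math.atan2(dt, dc)) % 180.0
    return math.sqrt(best), ang


def _hull_indices(pts: np.ndarray) -> np.ndarray:
    from scipy.spatial import ConvexHull, QhullError

    if len(pts) <= 3:
        return np.arange(len(pts))
    try:
        return np.sort(ConvexHull(pts).vertices)
    except QhullError:  # collinear or degenerate input
        return np.arange(len(pts))


def vertical_deviation(angle_deg: float) -> float:
    """Absolute angle away from the vertical time axis, clipped to [0, 90]."""
    return float(np.clip(abs(90.0 - (angle_deg % 180.0)), 0.0, 90.0))


def streak_ridge_params(window: int, speed_px_per_frame: float,
                        feature_width_px: float = 4.0,
                        contrast: float = 30.0) -> RidgeParams:
    """Ridge parameters matched to the expected kymograph streak width.

    Temporal running-averaging over ``window`` frames smears a feature
    moving at ``s`` px/frame along the time axis of the kymograph, so a
    thin streak becomes a ribbon of perpendicular width
    ``window * s / sqrt(1 + s^2)`` (saturating at the window length for
    fast movement).  The tracing scale and minimum trace length are
    derived from that width; ``speed_px_per_frame`` is a pilot estimate
    of the motion being quantified — in practice start from a guess and
    iterate once.
    """
    from .ridges import thresholds_from_contrast

    s = abs(speed_px_per_frame)
    perp = max(window * s / math.hypot(1.0, s), feature_width_px)
    sigma = max(3.0, perp / 2.8)
    upper, lower = thresholds_from_contrast(contrast, perp, sigma)
    return RidgeParams(sigma=sigma, upper_threshold=upper, lower_threshold=lower,
                       min_length=max(40.0, 2.2 * perp))


def trace_and_score(kymo: Kymograph, params: RidgeParams,
                    normalize: bool = True,
                    border_margin: float | None = None) -> list[float]:
    """Detect streaks in a kymograph and score their deviations.

    Each detected ridge polyline contributes ``|90° - feret_angle|``
    degrees; an empty kymograph yields an empty list.  With
    ``normalize`` the kymograph is min-max scaled to [0, 100] first, so
    the ridge thresholds refer to that scale.  ``border_margin``
    (pixels; defaults to the ridge sigma) drops trace points closer
    than that to the kymograph border before the Feret computation —
    smoothing boundary effects bend trace ends and would otherwise bias
    the angle toward vertical.  Traces whose remaining net extent falls
    below half the minimum length are discarded as residual fragments.
    """
    img = np.asarray(kymo.pixels, dtype=float)
    if normalize:
        img = img - img.min()
        peak = img.max()
        if peak > 0:
            img = img * (100.0 / peak)
    ridge_set = detect_ridges(img, params)
    margin = params.sigma if border_margin is None else border_margin
    H, W = img.shape
    out = []
    for poly in ridge_set.polylines:
        pts = poly.points
        keep = ((pts[:, 0] >= margin) & (pts[:, 0] <= H - 1 - margin)
                & (pts[:, 1] >= margin) & (pts[:, 1] <= W - 1 - margin))
        pts = pts[keep]
        if len(pts) < 2:
            continue
        if np.linalg.norm(pts[-1] - pts[0]) < params.min_length / 2.0:
            continue
        _, ang = feret_diameter_angle(pts)
        out.append(vertical_deviation(ang))
    return out


@dataclass
class MotilityConfig:
    """Configuration for the region-motility pipeline.

    Stabilization is off by default: it removes whole-frame rigid
    motion, which is appropriate for camera/stage jitter but would also
    cancel a field-wide cellular drift; enable it when the movie has
    uncorrected acquisition jitter and a static reference background.
    The 50-frame running average suppresses fast zero-mean organelle
    jiggling, leaving sustained lateral movement; frames whose
    averaging window was truncated at the sequence ends are dropped
    before slicing (``trim_boundary``) because their content does not
    move at the steady-state rate.  ``axes`` selects which slicing
    directions are pooled: kymographs measure the motion component
    along their own line, so when the drift direction is known,
    slicing the matching axis avoids diluting the score with the
    perpendicular direction's near-vertical traces.
    """

    stabilize: bool = False
    window: int = RUNNING_AVERAGE_WINDOW_DEFAULT
    stride: int = 4
    axes: str = "both"  # 'x', 'y' or 'both'
    trim_boundary: bool = True
    ridge: RidgeParams = field(
        default_factory=lambda: streak_ridge_params(
            RUNNING_AVERAGE_WINDOW_DEFAULT, 1.0)
    )


def region_motility(movie: ImageStack, regions: list[Rect | tuple],
                    config: MotilityConfig | None = None) -> list[MotilityResult]:
    """Full lateral-motility pipeline over one or more regions.

    stabilize (optional) -> running average -> kymographs -> ridge
    tracing -> Feret deviation from vertical, pooled per region.
    """
    config = config or MotilityConfig()
    if config.axes not in ("x", "y", "both"):
        raise ValueError("axes must be 'x', 'y' or 'both'")
    if config.stabilize:
        movie, _ = stabilize(movie)
    movie = running_average(movie, config.window)
    if config.trim_boundary and movie.n_frames > config.window:
        it = movie.axis_index("t")
        lo = config.window // 2
        hi = movie.n_frames - (config.window - 1) // 2
        core = np.take(movie.pixels, np.arange(lo, hi), axis=it)
        movie = ImageStack(core, axes=movie.axes, pixel_size=movie.pixel_size,
                           frame_interval=movie.frame_interval)
    results = []
    for rid, region in enumerate(regions):
        deviations: list[float] = []
        for kymo in build_kymographs(movie, region, stride=config.stride):
            if config.axes != "both" and kymo.line_axis != config.axes:
                continue
            deviations.extend(trace_and_score(kymo, config.ridge))
        mean_dev = float(np.mean(deviations)) if deviations else float("nan")
        results.append(MotilityResult(rid, mean_dev, len(deviations), deviations))
    return results
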