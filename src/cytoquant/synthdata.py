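"""Synthetic fluorescence microscopy with serialized ground truth.

Four generators emulate the data the quantification pipelines consume:

* :func:`gen_filaments` — tubulin-like maximum projections: bounded-
  curvature random-walk filaments with Gaussian cross-section.
* :func:`gen_comet_field` — fixed two-channel fields: a junction channel
  (blurred boundaries of a Voronoi cell tessellation) and a comet
  channel of anisotropic Gaussian spots placed inside cells.
* :func:`gen_comet_movie` — time-lapse of point spots nucleating,
  moving with constant velocity and disappearing.
* :func:`gen_drift_movie` — epithelial-island-like textured movies with
  slow sustained drift plus fast zero-mean jitter.

The imaging model is an isotropic Gaussian PSF with additive Gaussian
noise parameterized as SNR = peak / noise_sd, a deliberately simple
stand-in for confocal imaging that is sufficient for parameter-recovery
testing.  Every generator takes a mandatory seed and is bit-for-bit
deterministic given identical parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import scipy.ndimage as ndi
from scipy.spatial import cKDTree

from .imgio import ImageStack


@dataclass
class GroundTruth:
    """Full generator configuration plus the quantities recovery tests
    compare against (filament polylines, per-comet shape, per-spot
    kinematics, drift vector)."""

    kind: str  # filaments | comet_field | comet_movie | drift_movie
    parameters: dict[str, Any]
    truth: dict[str, Any]
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, default=_jsonable, indent=1)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _add_noise(img: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd <= 0:
        return np.clip(img, 0.0, None)
    return np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, None)


def _splat_gaussian(canvas: np.ndarray, cy: float, cx: float, amp: float,
                    sy: float, sx: float, theta: float) -> None:
    """Accumulate one rotated anisotropic Gaussian in place.

    ``sy``/``sx`` are the sds along the spot's major/minor axes and
    ``theta`` the major-axis orientation (radians, from +x)."""
    H, W = canvas.shape
    r = 4.0 * max(sy, sx)
    y0, y1 = max(0, int(cy - r)), min(H, int(cy + r) + 1)
    x0, x1 = max(0, int(cx - r)), min(W, int(cx + r) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy = yy - cy
    dx = xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st  # along major axis
    v = -dx * st + dy * ct
    canvas[y0:y1, x0:x1] += amp * np.exp(-0.5 * ((u / sy) ** 2 + (v / sx) ** 2))


# ---------------------------------------------------------------------------
# Filament fields


def gen_filaments(
    n_filaments: int,
    length_range: tuple[float, float] = (40.0, 120.0),
    line_width_px: float = 3.0,
    peak_intensity: float = 100.0,
    noise_sd: float = 12.5,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    curvature_sd: float = 0.06,
) -> tuple[ImageStack, GroundTruth]:
    """Simulate a field of curvilinear filaments.

    Each filament is a unit-step random walk whose heading receives a
    Gaussian increment of sd ``curvature_sd`` rad per step (bounded
    curvature) and is steered back when approaching the border.  The
    field is rendered with a Gaussian cross-section of sd
    ``line_width_px / 2`` and centre-line peak ``peak_intensity``, then
    additive Gaussian noise of sd ``noise_sd`` is applied (SNR =
    peak/noise_sd).  Truth stores the polylines and total arc length.
    """
    if min(shape) < 64:
        raise ValueError("shape must be at least 64x64")
    if n_filaments < 0 or peak_intensity <= 0 or line_width_px <= 0:
        raise ValueError("parameters must be positive (n_filaments >= 0)")
    rng = np.random.default_rng(seed)
    H, W = shape
    margin = 4.0 + line_width_px
    polylines: list[np.ndarray] = []
    for _ in range(n_filaments):
        length = rng.uniform(*length_range)
        y = rng.uniform(margin, H - margin)
        x = rng.uniform(margin, W - margin)
        heading = rng.uniform(0, 2 * math.pi)
        pts = [(y, x)]
        travelled = 0.0
        while travelled < length:
            heading += rng.normal(0.0, curvature_sd)
            ny = y + math.sin(heading)
            nx = x + math.cos(heading)
            if not (margin <= ny <= H - margin and margin <= nx <= W - margin):
                # steer toward the image centre and retry the step
                heading = math.atan2(H / 2 - y, W / 2 - x) + rng.normal(0.0, 0.3)
                continue
            y, x = ny, nx
            pts.append((y, x))
            travelled += 1.0
        polylines.append(np.array(pts))

    sigma_w = line_width_px / 2.0
    canvas = np.zeros(shape, dtype=float)
    spacing = 0.25
    # impulses along each centre line, blurred to a Gaussian cross-section
    for pts in polylines:
        seg = np.diff(pts, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg_len)])
        total = cum[-1]
        if total <= 0:
            continue
        s = np.arange(0.0, total, spacing)
        iy = np.interp(s, cum, pts[:, 0])
        ix = np.interp(s, cum, pts[:, 1])
        _bilinear_splat(canvas, iy, ix,
                        peak_intensity * math.sqrt(2 * math.pi) * sigma_w * spacing)
    canvas = ndi.gaussian_filter(canvas, sigma_w, mode="constant")
    img = _add_noise(canvas, noise_sd, rng)

    total_length = float(sum(
        np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)) for p in polylines
    ))
    truth = GroundTruth(
        kind="filaments",
        parameters=dict(n_filaments=n_filaments, length_range=list(length_range),
                        line_width_px=line_width_px, peak_intensity=peak_intensity,
                        noise_sd=noise_sd, shape=list(shape), seed=seed,
                        curvature_sd=curvature_sd),
        truth=dict(polylines=[p.tolist() for p in polylines],
                   total_length=total_length),
    )
    return ImageStack(img, axes="yx"), truth


def _bilinear_splat(canvas: np.ndarray, ys: np.ndarray, xs: np.ndarray,
                    weight: float) -> None:
    H, W = canvas.shape
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    fy = ys - y0
    fx = xs - x0
    for dy, dx, w in (
        (0, 0, (1 - fy) * (1 - fx)),
        (0, 1, (1 - fy) * fx),
        (1, 0, fy * (1 - fx)),
        (1, 1, fy * fx),
    ):
        yy = y0 + dy
        xx = x0 + dx
        ok = (yy >= 0) & (yy < H) & (xx >= 0) & (xx < W)
        np.add.at(canvas, (yy[ok], xx[ok]), weight * w[ok])


# ---------------------------------------------------------------------------
# Comet fields (fixed two-channel images)


def _poisson_disc(rng: np.random.Generator, n: int, shape: tuple[int, int],
                  margin: float) -> np.ndarray:
    """Dart-throwing Poisson-disc sampling of n seed points."""
    H, W = shape
    min_dist = 0.62 * math.sqrt((H - 2 * margin) * (W - 2 * margin) / n)
    pts: list[tuple[float, float]] = []
    attempts = 0
    while len(pts) < n:
        attempts += 1
        if attempts > 20000:
            raise RuntimeError("could not place cell seeds; lower n_cells")
        y = rng.uniform(margin, H - margin)
        x = rng.uniform(margin, W - margin)
        if all((y - p[0]) ** 2 + (x - p[1]) ** 2 >= min_dist**2 for p in pts):
            pts.append((y, x))
    return np.array(pts)


def gen_comet_field(
    n_cells: int = 10,
    comets_per_cell: int = 8,
    true_ar: float = 2.0,
    sigma_minor_px: float = 2.0,
    snr: float = 10.0,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    ar_sd: float = 0.0,
    junction_width_px: float = 2.0,
    peak_intensity: float = 100.0,
) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Simulate a fixed two-channel field: junctions plus comets.

    Cells are the Voronoi tessellation of Poisson-disc seeds; the
    junction channel renders the tessellation boundaries blurred to
    ``junction_width_px``.  Comets are anisotropic Gaussian spots
    (sd ``true_ar * sigma_minor_px`` along a uniformly random major axis,
    ``sigma_minor_px`` across) placed inside cells away from boundaries,
    with per-comet aspect ratios drawn Normal(true_ar, ar_sd) truncated
    at 1.  Raises if comets cannot be packed without heavy overlap.
    Truth stores per-comet AR, position, orientation and owning cell.
    """
    if true_ar < 1:
        raise ValueError("true_ar must be >= 1")
    rng = np.random.default_rng(seed)
    H, W = shape
    seeds = _poisson_disc(rng, n_cells, shape, margin=8.0)

    yy, xx = np.mgrid[0:H, 0:W]
    grid = np.column_stack([yy.ravel(), xx.ravel()])
    _, lab = cKDTree(seeds).query(grid)
    labels = (lab + 1).reshape(H, W)

    boundary = np.zeros((H, W), dtype=bool)
    boundary[:-1, :] |= labels[:-1, :] != labels[1:, :]
    boundary[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    boundary[0, :] = boundary[-1, :] = True
    boundary[:, 0] = boundary[:, -1] = True
    junction = ndi.gaussian_filter(boundary.astype(float), junction_width_px / 2.0,
                                   mode="nearest")
    junction *= peak_intensity / junction.max()
    junction_img = _add_noise(junction, peak_intensity / (snr * 4.0), rng)

    interior_dist = ndi.distance_transform_edt(~boundary)
    comet_canvas = np.zeros((H, W), dtype=float)
    comets: list[dict] = []
    warnings: list[str] = []
    all_placed: list[tuple[float, float]] = []  # global: merging across
    # cell boundaries would create spurious elongated particles
    # minimum separation keeps the intensity saddle between any two
    # comets well below plausible thresholds even when their major axes
    # align, so thresholded components never merge
    min_sep = 4.5 * true_ar * sigma_minor_px
    for cell in range(1, n_cells + 1):
        sigma_major_typ = true_ar * sigma_minor_px
        room = (labels == cell) & (interior_dist >= 2.0 + 2.0 * sigma_major_typ)
        cand = np.argwhere(room)
        if len(cand) == 0:
            warnings.append(f"cell {cell}: no room for comets, skipped")
            continue
        placed: list[tuple[float, float]] = []
        tries = 0
        while len(placed) < comets_per_cell:
            tries += 1
            if tries > 200 * comets_per_cell:
                warnings.append(
                    f"cell {cell}: placed {len(placed)}/{comets_per_cell} "
                    f"comets at separation {min_sep:.1f}px"
                )
                break
            cy, cx = cand[rng.integers(len(cand))] + rng.uniform(-0.5, 0.5, 2)
            if all((cy - p[0]) ** 2 + (cx - p[1]) ** 2 >= min_sep**2
                   for p in all_placed):
                placed.append((cy, cx))
                all_placed.append((cy, cx))
                ar = max(1.0, float(rng.normal(true_ar, ar_sd))) if ar_sd > 0 else true_ar
                theta = float(rng.uniform(0, math.pi))
                _splat_gaussian(comet_canvas, cy, cx, peak_intensity,
                                ar * sigma_minor_px, sigma_minor_px, theta)
                comets.append(dict(y=float(cy), x=float(cx), ar=ar,
                                   orientation=theta, cell=int(cell)))
    requested = n_cells * comets_per_cell
    if requested > 0 and len(comets) < 0.8 * requested:
        raise RuntimeError(
            f"comets overlap beyond the packing limit: placed {len(comets)} of "
            f"{requested} at separation {4.5 * true_ar * sigma_minor_px:.1f}px; "
            "reduce comet density or field crowding"
        )
    comet_img = _add_noise(comet_canvas, peak_intensity / snr, rng)

    truth = GroundTruth(
        kind="comet_field",
        parameters=dict(n_cells=n_cells, comets_per_cell=comets_per_cell,
                        true_ar=true_ar, sigma_minor_px=sigma_minor_px, snr=snr,
                        shape=list(shape), seed=seed, ar_sd=ar_sd,
                        junction_width_px=junction_width_px,
                        peak_intensity=peak_intensity),
        truth=dict(cell_seeds=seeds.tolist(), comets=comets),
        warnings=warnings,
    )
    return (ImageStack(junction_img, axes="yx"),
            ImageStack(comet_img, axes="yx"), truth)


# ---------------------------------------------------------------------------
# Comet movies (plus-end tracking)


def gen_comet_movie(
    n_spots: int = 50,
    speed_um_s: float = 0.13,
    pixel_size_um: float = 0.1,
    frame_interval_s: float = 2.0,
    n_frames: int = 45,
    lifetime_frames: tuple[int, int] = (10, 25),
    snr: float = 10.0,
    shape: tuple[int, int] = (192, 192),
    seed: int = 0,
    spot_sigma_px: float = 1.5,
    peak_intensity: float = 100.0,
    position_jitter_px: float = 0.0,
) -> tuple[ImageStack, GroundTruth]:
    """Simulate a plus-end comet movie with constant-velocity spots.

    Spots nucleate at uniformly random times and positions, travel in a
    uniformly random direction at ``speed_um_s`` for a random lifetime,
    then disappear.  ``position_jitter_px`` adds i.i.d. Gaussian
    localization jitter to the rendered (not the true) positions,
    emulating localization error.  Truth stores each spot's velocity
    vector, birth frame and lifetime.
    """
    if speed_um_s < 0 or n_frames < 2:
        raise ValueError("need speed >= 0 and n_frames >= 2")
    rng = np.random.default_rng(seed)
    H, W = shape
    speed_px = speed_um_s * frame_interval_s / pixel_size_um  # px per frame
    warnings = []
    if speed_px > 0 and min(H, W) / speed_px < 2:
        warnings.append("speed so high spots exit the frame within 2 frames")
    margin = 6.0 + 4 * spot_sigma_px
    spots = []
    for i in range(n_spots):
        life = int(rng.integers(lifetime_frames[0], lifetime_frames[1] + 1))
        life = min(life, n_frames)
        birth = int(rng.integers(0, max(1, n_frames - life + 1)))
        theta = rng.uniform(0, 2 * math.pi)
        vy, vx = speed_px * math.sin(theta), speed_px * math.cos(theta)
        # keep the whole trajectory inside the frame when possible;
        # otherwise (extreme speeds) place freely and let the spot exit
        lo_y = margin + max(0.0, -vy * (life - 1))
        hi_y = H - margin - max(0.0, vy * (life - 1))
        lo_x = margin + max(0.0, -vx * (life - 1))
        hi_x = W - margin - max(0.0, vx * (life - 1))
        if hi_y <= lo_y:
            lo_y, hi_y = margin, H - margin
        if hi_x <= lo_x:
            lo_x, hi_x = margin, W - margin
        y0 = rng.uniform(lo_y, hi_y)
        x0 = rng.uniform(lo_x, hi_x)
        spots.append(dict(id=i, birth=birth, lifetime=life, y0=float(y0),
                          x0=float(x0),
                          vy_px=float(vy), vx_px=float(vx),
                          speed_um_s=float(speed_um_s)))

    frames = np.zeros((n_frames,) + shape, dtype=float)
    for sp in spots:
        for k in range(sp["lifetime"]):
            t = sp["birth"] + k
            if t >= n_frames:
                break
            cy = sp["y0"] + sp["vy_px"] * k
            cx = sp["x0"] + sp["vx_px"] * k
            if position_jitter_px > 0:
                cy += rng.normal(0, position_jitter_px)
                cx += rng.normal(0, position_jitter_px)
            _splat_gaussian(frames[t], cy, cx, peak_intensity,
                            spot_sigma_px, spot_sigma_px, 0.0)
    noise_sd = peak_intensity / snr if snr > 0 else 0.0
    movie = _add_noise(frames, noise_sd, rng)

    truth = GroundTruth(
        kind="comet_movie",
        parameters=dict(n_spots=n_spots, speed_um_s=speed_um_s,
                        pixel_size_um=pixel_size_um,
                        frame_interval_s=frame_interval_s, n_frames=n_frames,
                        lifetime_frames=list(lifetime_frames), snr=snr,
                        shape=list(shape), seed=seed, spot_sigma_px=spot_sigma_px,
                        peak_intensity=peak_intensity,
                        position_jitter_px=position_jitter_px),
        truth=dict(spots=spots, speed_px_per_frame=float(speed_px)),
        warnings=warnings,
    )
    return (ImageStack(movie, axes="tyx", pixel_size=pixel_size_um,
                       frame_interval=frame_interval_s), truth)


# ---------------------------------------------------------------------------
# Drifting island movies


def gen_drift_movie(
    drift_px_per_frame: tuple[float, float] = (0.0, 1.0),
    jitter_amplitude_px: float = 2.0,
    n_frames: int = 120,
    shape: tuple[int, int] = (160, 160),
    seed: int = 0,
    frame_interval_s: float = 15.0,
    pixel_size_um: float = 0.2,
    n_blobs: int = 40,
    peak_intensity: float = 100.0,
    noise_sd: float = 4.0,
) -> tuple[ImageStack, GroundTruth]:
    """Simulate an island interior drifting laterally with fast jitter.

    A textured base scene (band-passed noise plus Gaussian blob
    features) is translated by the cumulative drift plus per-frame
    zero-mean uniform jitter and resampled bilinearly.  The base canvas
    is padded so drifting content never wraps; pixels with no source
    are 0, and analyses should use an interior region.  Truth stores
    the drift vector and the jitter series.
    """
    rng = np.random.default_rng(seed)
    dy, dx = float(drift_px_per_frame[0]), float(drift_px_per_frame[1])
    H, W = shape
    pad_y = int(abs(dy) * n_frames + jitter_amplitude_px + 8)
    pad_x = int(abs(dx) * n_frames + jitter_amplitude_px + 8)
    BH, BW = H + 2 * pad_y, W + 2 * pad_x
    if max(BH, BW) > 4096:
        raise ValueError("drift so large the region leaves any practical frame")

    base = ndi.gaussian_filter(rng.normal(0, 1, (BH, BW)), 2.0)
    base -= ndi.gaussian_filter(base, 8.0)  # band-pass
    base = np.clip(base, 0, None)
    base *= 0.5 * peak_intensity / max(base.max(), 1e-9)
    for _ in range(n_blobs):
        by = rng.uniform(0, BH)
        bx = rng.uniform(0, BW)
        s = rng.uniform(2.0, 5.0)
        _splat_gaussian(base, by, bx, rng.uniform(0.4, 1.0) * peak_intensity, s, s, 0.0)

    jitter = rng.uniform(-jitter_amplitude_px, jitter_amplitude_px, (n_frames, 2))
    jitter -= jitter.mean(axis=0)
    frames = np.empty((n_frames, H, W), dtype=float)
    for t in range(n_frames):
        off_y = dy * t + jitter[t, 0]
        off_x = dx * t + jitter[t, 1]
        # content moves by +off: sample base at (pad - off)
        shifted = ndi.shift(base, (off_y, off_x), order=1, mode="constant", cval=0.0)
        frames[t] = shifted[pad_y:pad_y + H, pad_x:pad_x + W]
    movie = _add_noise(frames, noise_sd, rng)

    truth = GroundTruth(
        kind="drift_movie",
        parameters=dict(drift_px_per_frame=[dy, dx],
                        jitter_amplitude_px=jitter_amplitude_px,
                        n_frames=n_frames, shape=list(shape), seed=seed,
                        frame_interval_s=frame_interval_s,
                        pixel_size_um=pixel_size_um, n_blobs=n_blobs,
                        peak_intensity=peak_intensity, noise_sd=noise_sd),
        truth=dict(drift_px_per_frame=[dy, dx], jitter=jitter.tolist()),
    )
    return (ImageStack(movie, axes="tyx", pixel_size=pixel_size_um,
                       frame_interval=frame_interval_s), truth)
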