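"""Plus-end comet tracking in time-lapse movies.

Spots are detected per frame as local maxima of a Laplacian-of-Gaussian
response with sub-pixel quadratic refinement, linked between consecutive
frames by mutual-nearest-neighbour matching under a displacement gate,
and summarized per track as mean speed (path length / duration), net
displacement and duration in physical units.  EB1 comets are short-lived
near-linear movers, so the linker deliberately has no gap closing and no
merge/split handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import peak_local_max

from .imgio import ImageStack


@dataclass
class Spot:
    frame: int
    position: tuple[float, float]  # (y, x) px
    intensity: float  # peak LoG response


@dataclass
class Track:
    """Time-ordered spots on strictly consecutive frames."""

    spots: list[Spot]

    def __post_init__(self) -> None:
        frames = [s.frame for s in self.spots]
        if len(frames) < 2:
            raise ValueError("a track needs at least 2 spots")
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be consecutive")

    def __len__(self) -> int:
        return len(self.spots)

    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.spots])


@dataclass
class TrackMetrics:
    mean_speed: float  # μm/s, path_length / duration
    duration: float  # s
    displacement: float  # μm, net start -> end
    path_length: float  # μm, sum of step lengths


def detect_spots(frame_image: np.ndarray, sigma: float,
                 min_prominence: float) -> list[Spot]:
    """Detect bright spots in one frame.

    The response is the scale-normalized negated Laplacian of Gaussian
    (positive over bright blobs of radius ~sigma*sqrt(2)); local maxima
    with response >= ``min_prominence`` are kept and refined to
    sub-pixel positions by a per-axis quadratic fit.  A blank frame
    yields no spots.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    img = np.asarray(frame_image, dtype=float)
    resp = -(sigma**2) * ndi.gaussian_laplace(img, sigma, mode="nearest")
    peaks = peak_local_max(resp, min_distance=1, threshold_abs=min_prominence,
                           exclude_border=False)
    H, W = img.shape
    spots = []
    for py, px in peaks:
        y, x = float(py), float(px)
        # quadratic sub-pixel refinement along each axis
        if 0 < py < H - 1:
            denom = resp[py - 1, px] - 2 * resp[py, px] + resp[py + 1, px]
            if denom < 0:
                y += 0.5 * (resp[py - 1, px] - resp[py + 1, px]) / denom
        if 0 < px < W - 1:
            denom = resp[py, px - 1] - 2 * resp[py, px] + resp[py, px + 1]
            if denom < 0:
                x += 0.5 * (resp[py, px - 1] - resp[py, px + 1]) / denom
        y = min(max(y, 0.0), H - 1.0)
        x = min(max(x, 0.0), W - 1.0)
        spots.append(Spot(frame=0, position=(y, x), intensity=float(resp[py, px])))
    return spots


def detect_spots_movie(movie: ImageStack, sigma: float,
                       min_prominence: float) -> list[list[Spot]]:
    """Per-frame spot detection over a whole movie."""
    n = movie.n_frames
    out = []
    for t in range(n):
        spots = detect_spots(movie.frame(t), sigma, min_prominence)
        for s in spots:
            s.frame = t
        out.append(spots)
    return out


MIN_TRACK_FRAMES_DEFAULT = 3  # speed from < 3 points is noise-dominated


def link_tracks(spots_by_frame: list[list[Spot]], max_displacement: float,
                min_frames: int = MIN_TRACK_FRAMES_DEFAULT) -> list[Track]:
    """Link per-frame spots into tracks.

    Between consecutive frames, spot pairs that are mutual nearest
    neighbours within ``max_displacement`` px are linked; every other
    spot terminates or starts a track.  Tracks spanning fewer than
    ``min_frames`` frames are discarded.  Each spot belongs to at most
    one track.
    """
    if not max_displacement > 0:
        raise ValueError("max_displacement must be > 0")
    # active chains keyed by index of their last spot in the previous frame
    chains: list[list[Spot]] = []
    active: dict[int, int] = {}  # prev-frame spot index -> chain index
    finished: list[list[Spot]] = []
    prev: list[Spot] = []
    for t, current in enumerate(spots_by_frame):
        links: dict[int, int] = {}
        if prev and current:
            pa = np.array([s.position for s in prev])
            pb = np.array([s.position for s in current])
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
            fwd = d.argmin(axis=1)
            bwd = d.argmin(axis=0)
            for i, j in enumerate(fwd):
                if bwd[j] == i and d[i, j] <= max_displacement:
                    links[i] = int(j)
        new_active: dict[int, int] = {}
        for i, chain_idx in active.items():
            if i in links:
                chains[chain_idx].append(current[links[i]])
                new_active[links[i]] = chain_idx
            else:
                finished.append(chains[chain_idx])
        linked_js = set(links.values())
        for j, s in enumerate(current):
            if j not in linked_js:
                chains.append([s])
                new_active[j] = len(chains) - 1
        active = new_active
        prev = current
    finished.extend(chains[idx] for idx in active.values())
    return [Track(c) for c in finished if len(c) >= max(min_frames, 2)]


def track_metrics(track: Track, pixel_size: float,
                  frame_interval: float) -> TrackMetrics:
    """Physical per-track metrics.

    duration = (n_spots - 1) * frame_interval; path_length = sum of
    Euclidean steps in μm; mean_speed = path_length / duration (the
    mean frame-to-frame speed); displacement = net start-to-end
    distance, always <= path_length.
    """
    if pixel_size <= 0 or frame_interval <= 0:
        raise ValueError("calibration must be positive")
    pos = track.positions() * pixel_size
    steps = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    path_length = float(steps.sum())
    displacement = float(np.linalg.norm(pos[-1] - pos[0]))
    duration = (len(track) - 1) * frame_interval
    return TrackMetrics(
        mean_speed=path_length / duration,
        duration=float(duration),
        displacement=displacement,
        path_length=path_length,
    )


def track_movie(movie: ImageStack, sigma: float = 1.5,
                min_prominence: float = 10.0, max_displacement: float = 6.0,
                min_frames: int = MIN_TRACK_FRAMES_DEFAULT,
                ) -> tuple[list[Track], list[TrackMetrics]]:
    """Full pipeline: detect spots per frame, link, and measure."""
    spots = detect_spots_movie(movie, sigma, min_prominence)
    tracks = link_tracks(spots, max_displacement, min_frames=min_frames)
    metrics = [track_metrics(t, movie.pixel_size, movie.frame_interval)
               for t in tracks]
    return tracks, metrics
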