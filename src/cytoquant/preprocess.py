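"""Shared image conditioning applied before every quantification.

Maximum projection, rolling-ball background subtraction, integer-factor
bilinear upscaling, translational stabilization (phase correlation) and
a centred temporal running average.

The rolling-ball background is defined exactly: it is the grayscale
morphological opening of the image by a non-flat ball (spherical cap)
structuring element of the given radius, with edge-clamped boundary
handling.  No legacy 8-bit shrink/enlarge approximation is used, so the
operation is directly testable against a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.registration import phase_cross_correlation
from skimage.transform import resize

from .imgio import ImageStack, ImageStackError


@dataclass
class ShiftSeries:
    """Estimated per-frame translation (dy, dx) relative to the reference
    frame (frame 0), in pixels.  Positive dy means the frame's content
    sits *below* where it is in the reference; the stabilizer applies the
    negated shift to undo it."""

    shifts: np.ndarray  # (n_frames, 2) float

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.ndim != 2 or self.shifts.shape[1] != 2:
            raise ValueError("shifts must be (n_frames, 2)")

    def __len__(self) -> int:
        return len(self.shifts)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.shifts[i]


def max_project(stack: ImageStack) -> ImageStack:
    """Maximum-intensity projection along z.

    Each output pixel is the maximum over z of the corresponding input
    pixels; the z axis is removed and the calibration preserved.
    """
    iz = stack.axis_index("z")  # raises if no z axis
    projected = stack.pixels.max(axis=iz)
    axes = stack.axes.replace("z", "")
    return ImageStack(projected, axes=axes, pixel_size=stack.pixel_size,
                      frame_interval=stack.frame_interval)


def ball_height_profile(radius: int) -> tuple[np.ndarray, np.ndarray]:
    """Height map and footprint of a ball (spherical cap) structuring
    element of the given radius.

    Returns ``(heights, footprint)`` where ``heights[dy+r, dx+r] =
    sqrt(r^2 - dy^2 - dx^2)`` on the disc ``dy^2 + dx^2 <= r^2`` and the
    boolean footprint marks the disc.
    """
    r = int(radius)
    if r < 1:
        raise ValueError("radius must be >= 1")
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    d2 = dy * dy + dx * dx
    footprint = d2 <= r * r
    heights = np.zeros_like(d2, dtype=float)
    heights[footprint] = np.sqrt(r * r - d2[footprint])
    return heights, footprint


def rolling_ball_background(image: np.ndarray, radius: int) -> np.ndarray:
    """Smooth background: grayscale opening by a ball of given radius.

    The image is edge-padded by the radius so the morphology sees
    clamped (nearest-edge) values outside the frame.
    """
    if int(radius) < 1:
        raise ValueError("radius must be >= 1")
    r = int(radius)
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    heights, footprint = ball_height_profile(r)
    padded = np.pad(img, r, mode="edge")
    eroded = ndi.grey_erosion(padded, structure=heights, footprint=footprint,
                              mode="nearest")
    opened = ndi.grey_dilation(eroded, structure=heights, footprint=footprint,
                               mode="nearest")
    return opened[r:-r, r:-r]


def rolling_ball_subtract(image: np.ndarray, radius: int) -> np.ndarray:
    """Rolling-ball background subtraction.

    Returns ``image - background`` clipped at zero, where the background
    is :func:`rolling_ball_background`.  Adding a constant offset to the
    input leaves the output unchanged, and the output is never negative.
    """
    img = np.asarray(image, dtype=float)
    bg = rolling_ball_background(img, radius)
    return np.clip(img - bg, 0.0, None)


def upscale(image: np.ndarray, factor: int) -> np.ndarray:
    """Upscale a 2-D image by an integer factor with bilinear interpolation."""
    if factor != int(factor) or int(factor) < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    img = np.asarray(image, dtype=float)
    if factor == 1:
        return img.copy()
    out_shape = (img.shape[0] * factor, img.shape[1] * factor)
    return resize(img, out_shape, order=1, mode="edge", anti_aliasing=False,
                  preserve_range=True)


def upscale_stack(stack: ImageStack, factor: int) -> ImageStack:
    """Upscale the y/x axes of a stack; pixel_size is divided by factor."""
    if factor != int(factor) or int(factor) < 1:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if stack.pixels.ndim == 2:
        out = upscale(stack.pixels, factor)
    else:
        lead_shape = stack.pixels.shape[:-2]
        flat = stack.pixels.reshape((-1,) + stack.pixels.shape[-2:])
        out = np.stack([upscale(f, factor) for f in flat])
        out = out.reshape(lead_shape + out.shape[-2:])
    return ImageStack(out, axes=stack.axes, pixel_size=stack.pixel_size / factor,
                      frame_interval=stack.frame_interval)


UPSCALE_FACTOR_DEFAULT = 3  # comet images are magnified 3-fold before analysis


def stabilize(movie: ImageStack, upsample_factor: int = 50) -> tuple[ImageStack, ShiftSeries]:
    """Register every frame to the first by pure translation.

    Shifts are estimated by phase correlation with sub-pixel refinement
    (Fourier upsampling) and undone by bilinear resampling; pixels pulled
    in from outside the frame are filled with 0.  Returns the stabilized
    movie and the estimated per-frame displacements relative to frame 0.
    """
    it = movie.axis_index("t")
    n = movie.pixels.shape[it]
    if n < 2:
        raise ValueError("stabilize requires at least 2 frames")
    frames = np.moveaxis(movie.pixels, it, 0).astype(float)
    if frames.ndim != 3:
        raise ValueError("stabilize expects a single-channel t,y,x movie")
    ref = frames[0]
    if not np.any(ref):
        raise ValueError("reference frame is all zero; correlation undefined")
    # Hann window suppresses the spurious wrap-around correlation of
    # non-periodic content.  Registration is sequential: each frame is
    # matched to its predecessor (inter-frame motion is small, avoiding
    # large-shift sidelobe lock-in) and corrections accumulate relative
    # to frame 0; a second pass against frame 0 on the corrected frame
    # removes accumulated drift of the estimate.
    window = np.outer(np.hanning(frames.shape[1]), np.hanning(frames.shape[2]))

    def estimate(reference: np.ndarray, frame: np.ndarray) -> np.ndarray:
        corr, _, _ = phase_cross_correlation(
            (reference - reference.mean()) * window,
            (frame - frame.mean()) * window,
            upsample_factor=upsample_factor, normalization=None,
        )
        return corr

    shifts = np.zeros((n, 2), dtype=float)
    out = np.empty_like(frames)
    out[0] = ref
    cumulative = np.zeros(2)
    for t in range(1, n):
        frame = frames[t]
        if not np.any(frame):
            raise ValueError(f"frame {t} is all zero; correlation undefined")
        cumulative = cumulative + estimate(frames[t - 1], frame)
        moved = ndi.shift(frame, cumulative, order=1, mode="constant", cval=0.0)
        # second pass against the reference corrects the slow drift of
        # accumulated estimates; it is gated to small residuals so a
        # spurious sidelobe match cannot override the sequential result
        residual = estimate(ref, moved)
        correction = cumulative + (residual if np.abs(residual).max() <= 1.5
                                   else 0.0)
        cumulative = correction
        shifts[t] = -correction
        out[t] = ndi.shift(frame, correction, order=1, mode="constant", cval=0.0)
    stabilized = np.moveaxis(out, 0, it)
    return (
        ImageStack(stabilized, axes=movie.axes, pixel_size=movie.pixel_size,
                   frame_interval=movie.frame_interval),
        ShiftSeries(shifts),
    )


RUNNING_AVERAGE_WINDOW_DEFAULT = 50  # frames; motility movies are smoothed this much


def running_average(movie: ImageStack, window: int) -> ImageStack:
    """Centred temporal running mean with truncated boundary windows.

    Output frame ``t`` is the mean of input frames in
    ``[t - window//2, t + (window-1)//2]`` intersected with the valid
    range; the number of frames is unchanged.  ``window=1`` is the
    identity.
    """
    if int(window) < 1:
        raise ValueError("window must be >= 1")
    window = int(window)
    it = movie.axis_index("t")
    frames = np.moveaxis(movie.pixels, it, 0).astype(float)
    n = frames.shape[0]
    # cumulative sum with a leading zero slab allows O(1) window sums
    csum = np.concatenate([np.zeros((1,) + frames.shape[1:]), np.cumsum(frames, axis=0)])
    lo = np.maximum(np.arange(n) - window // 2, 0)
    hi = np.minimum(np.arange(n) + (window - 1) // 2 + 1, n)
    out = (csum[hi] - csum[lo]) / (hi - lo).reshape((-1,) + (1,) * (frames.ndim - 1))
    return ImageStack(np.moveaxis(out, 0, it), axes=movie.axes,
                      pixel_size=movie.pixel_size,
                      frame_interval=movie.frame_interval)
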