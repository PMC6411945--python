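"""Calibrated image I/O and annotation tables.

All pipeline modules consume :class:`ImageStack`, which couples a pixel
array with named axes and the physical calibration (``pixel_size`` in
micrometres per pixel, ``frame_interval`` in seconds per frame).  The
calibration is carried on the object so that downstream conversions to
μm and seconds never re-ask for it.

Coordinate convention: 0-based pixel indices, pixel centres at integer
coordinates, ``y`` increases downward and ``x`` rightward (raster order).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

VALID_AXES = ("t", "z", "channel", "y", "x")
CELL_CLASSES = ("epithelial", "mesenchymal")

_DESCRIPTION_KEY = "cytoquant"


class ImageStackError(ValueError):
    """Raised for invalid stack construction or I/O."""


@dataclass
class ImageStack:
    """Pixel array with named axes and physical calibration.

    Parameters
    ----------
    pixels : ndarray
        Non-negative, finite intensities.  One array dimension per axis.
    axes : str
        Axis names in array order, drawn from ``t``, ``z``, ``c``
        (channel), ``y``, ``x``.  ``y`` and ``x`` are mandatory and last.
    pixel_size : float
        Micrometres per pixel (isotropic in y/x).
    frame_interval : float or None
        Seconds per frame; required when a ``t`` axis is present.
    """

    pixels: np.ndarray
    axes: str = "yx"
    pixel_size: float = 1.0
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        ax = self.axes
        if len(ax) != self.pixels.ndim:
            raise ImageStackError(
                f"axes {ax!r} do not match array ndim {self.pixels.ndim}"
            )
        for a in ax:
            if a not in ("t", "z", "c", "y", "x"):
                raise ImageStackError(f"unknown axis {a!r}")
        if len(set(ax)) != len(ax):
            raise ImageStackError(f"duplicate axis in {ax!r}")
        if not ax.endswith("yx"):
            raise ImageStackError("axes must end with 'yx'")
        if self.pixels.shape[ax.index("y")] < 1 or self.pixels.shape[ax.index("x")] < 1:
            raise ImageStackError("y and x sizes must be >= 1")
        if not np.isfinite(self.pixel_size) or self.pixel_size <= 0:
            raise ImageStackError("pixel_size must be a positive real")
        if "t" in ax:
            if self.frame_interval is None:
                raise ImageStackError("frame_interval required when t axis present")
            if not np.isfinite(self.frame_interval) or self.frame_interval <= 0:
                raise ImageStackError("frame_interval must be a positive real")
        if np.issubdtype(self.pixels.dtype, np.floating):
            if not np.all(np.isfinite(self.pixels)):
                raise ImageStackError("intensities must be finite")
            if np.any(self.pixels < 0):
                raise ImageStackError("intensities must be >= 0")

    # -- axis helpers -------------------------------------------------

    def axis_index(self, axis: str) -> int:
        if axis not in self.axes:
            raise ImageStackError(f"stack has no {axis!r} axis (axes={self.axes!r})")
        return self.axes.index(axis)

    def axis_size(self, axis: str) -> int:
        return self.pixels.shape[self.axis_index(axis)]

    @property
    def n_frames(self) -> int:
        return self.axis_size("t")

    @property
    def duration(self) -> float:
        """Total span of the time series in seconds, (n_t - 1) * interval."""
        return (self.n_frames - 1) * float(self.frame_interval)

    def frame(self, t: int) -> np.ndarray:
        """2-D view of frame *t* (requires axes 'tyx')."""
        return np.take(self.pixels, t, axis=self.axis_index("t"))

    def with_pixels(self, pixels: np.ndarray, axes: str | None = None) -> "ImageStack":
        """Copy of this stack with new pixels (calibration preserved)."""
        new = replace(self, pixels=pixels)
        if axes is not None:
            new = ImageStack(pixels, axes=axes, pixel_size=self.pixel_size,
                             frame_interval=self.frame_interval if "t" in axes else self.frame_interval)
        return new


@dataclass
class IslandAnnotation:
    """Manual per-cell classification of one epithelial island.

    ``cell_classes`` holds one label per scored (peripheral) cell, each
    either ``"epithelial"`` or ``"mesenchymal"``.  ``perimeter_segments``
    optionally lists ``(length_um, class)`` pairs partitioning the island
    perimeter by cell class.
    """

    island_id: str
    cell_classes: list[str]
    perimeter_segments: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.cell_classes) < 1:
            raise ValueError(f"island {self.island_id!r}: needs at least 1 cell")
        for c in self.cell_classes:
            if c not in CELL_CLASSES:
                raise ValueError(
                    f"island {self.island_id!r}: unknown cell class {c!r}"
                )
        for length, c in self.perimeter_segments:
            if not length > 0:
                raise ValueError(
                    f"island {self.island_id!r}: segment length must be positive"
                )
            if c not in CELL_CLASSES:
                raise ValueError(
                    f"island {self.island_id!r}: unknown segment class {c!r}"
                )

    @property
    def n_cells(self) -> int:
        return len(self.cell_classes)

    @property
    def n_mesenchymal(self) -> int:
        return sum(1 for c in self.cell_classes if c == "mesenchymal")


# ---------------------------------------------------------------------------
# TIFF I/O


def read_stack(
    path: str | Path,
    pixel_size: float | None = None,
    frame_interval: float | None = None,
    axes: str | None = None,
) -> ImageStack:
    """Read a TIFF into an :class:`ImageStack`.

    Axis inference for plain page series: a 2-D file is ``yx``; a 3-D
    file is ``tyx`` when a frame interval is resolvable (argument or
    embedded metadata) and ``zyx`` otherwise; 4-D is ``czyx``.  Files
    written by :func:`write_stack` carry their axes and calibration in
    the image description and round-trip exactly; the ``pixel_size`` /
    ``frame_interval`` arguments override embedded values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description or ""
    except Exception as exc:  # pragma: no cover - corrupt files
        raise ImageStackError(f"unparseable TIFF {path}: {exc}") from exc

    meta = _parse_description(desc)
    if pixel_size is None:
        pixel_size = meta.get("pixel_size", 1.0)
    if frame_interval is None:
        frame_interval = meta.get("frame_interval")
    if axes is None:
        axes = meta.get("axes")
    if axes is None:
        if arr.ndim == 2:
            axes = "yx"
        elif arr.ndim == 3:
            axes = "tyx" if frame_interval is not None else "zyx"
        elif arr.ndim == 4:
            axes = "czyx"
        else:
            raise ImageStackError(f"cannot infer axes for {arr.ndim}-D TIFF")
    if "t" in axes and frame_interval is None:
        raise ImageStackError(
            f"{path}: t axis present but no frame_interval given or embedded"
        )
    return ImageStack(arr, axes=axes, pixel_size=float(pixel_size),
                      frame_interval=frame_interval)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as a multi-page TIFF.

    Axes and calibration are serialized into the TIFF description so
    that ``read_stack(write_stack(s))`` reproduces pixels, axes and
    calibration exactly (lossless for integer dtypes).
    """
    path = Path(path)
    meta = {
        _DESCRIPTION_KEY: {
            "axes": stack.axes,
            "pixel_size": stack.pixel_size,
            "frame_interval": stack.frame_interval,
        }
    }
    tifffile.imwrite(path, stack.pixels, description=json.dumps(meta),
                     photometric="minisblack")
    return path


def _parse_description(desc: str) -> dict:
    try:
        d = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        return {}
    if not isinstance(d, dict):
        return {}
    inner = d.get(_DESCRIPTION_KEY, {})
    return inner if isinstance(inner, dict) else {}


# ---------------------------------------------------------------------------
# Annotation tables


def read_annotations(path: str | Path) -> list[IslandAnnotation]:
    """Read per-island cell-class annotations from CSV or JSON.

    CSV needs columns ``island_id, cell_id, class`` (one row per cell);
    JSON is a list of objects with ``island_id``, ``cells`` (list of
    class labels) and optional ``perimeter_segments`` as
    ``[[length_um, class], ...]``.  Malformed rows raise with the
    offending row index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        return _annotations_from_json(path)
    return _annotations_from_csv(path)


def _annotations_from_csv(path: Path) -> list[IslandAnnotation]:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no annotation rows")
    required = {"island_id", "cell_id", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: CSV must have columns {sorted(required)}")
    for idx, cls in df["class"].items():
        if cls not in CELL_CLASSES:
            raise ValueError(
                f"{path} row {idx}: unknown class {cls!r} "
                f"(expected one of {CELL_CLASSES})"
            )
    out = []
    for island_id, grp in df.groupby("island_id", sort=True):
        out.append(IslandAnnotation(str(island_id), list(grp["class"])))
    return out


def _annotations_from_json(path: Path) -> list[IslandAnnotation]:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list) or not data:
        raise ValueError(f"{path}: expected a non-empty JSON list of islands")
    out = []
    for i, rec in enumerate(data):
        try:
            segments = [(float(s[0]), s[1]) for s in rec.get("perimeter_segments", [])]
            out.append(IslandAnnotation(str(rec["island_id"]), list(rec["cells"]),
                                        segments))
        except (KeyError, ValueError, TypeError, IndexError) as exc:
            raise ValueError(f"{path} island entry {i}: {exc}") from exc
    return out


def write_annotations(annotations: list[IslandAnnotation], path: str | Path) -> Path:
    """Serialize annotations to JSON (inverse of :func:`read_annotations`)."""
    path = Path(path)
    data = [
        {
            "island_id": a.island_id,
            "cells": a.cell_classes,
            "perimeter_segments": [[l, c] for l, c in a.perimeter_segments],
        }
        for a in annotations
    ]
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
    return path
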