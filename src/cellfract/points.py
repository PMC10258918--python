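"""Cell location points: label-mask centroids and two-channel time series.

Segmentation (e.g. Cellpose) produces one integer-labelled mask per channel
per frame.  Each labelled cell is reduced to a single location point — the
arithmetic mean of its pixel coordinates — and the per-frame point sets of
the two channels form a :class:`TimeSeries` that feeds the boundary
classification step.

Coordinate convention: 0-based pixel indices, ``x`` = column, ``y`` = row.
Centroids are real-valued; they are never rounded to integer pixels because
the downstream nearest-neighbour classification accepts real coordinates.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DimensionError, FormatError, SchemaError

__all__ = [
    "LabelMask",
    "CellPointSet",
    "TimeSeries",
    "centroids_from_mask",
    "load_point_table",
    "save_point_table",
    "load_mask_series",
    "read_mask",
]


@dataclass(frozen=True)
class LabelMask:
    """Integer-labelled segmentation raster for one channel at one frame.

    ``pixels[y, x]`` is 0 for background and ``k > 0`` for cell ``k``.
    Labels need not be contiguous; segmentation tools emit arbitrary ids.
    """

    pixels: np.ndarray
    channel: int
    timepoint: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise FormatError(f"label mask must be 2-D, got {arr.ndim}-D")
        if not np.issubdtype(arr.dtype, np.integer):
            raise FormatError(f"label mask must be integer-typed, got {arr.dtype}")
        if arr.size and arr.min() < 0:
            raise FormatError("label mask contains negative labels")
        object.__setattr__(self, "pixels", arr)


@dataclass(frozen=True)
class CellPointSet:
    """One (x, y) location point per detected cell, for one channel/frame."""

    points: np.ndarray  # shape (n, 2), columns (x, y), float
    channel: int
    timepoint: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class TimeSeries:
    """Ordered two-channel point-set series over a fixed raster extent.

    ``frames[t]`` is a ``(channel-1 CellPointSet, channel-2 CellPointSet)``
    pair; ``raster_shape`` is ``(width, height)`` in pixels and
    ``frame_interval`` the time per frame (defaults to 1 unit — the analysis
    is unit-agnostic).
    """

    frames: list[tuple[CellPointSet, CellPointSet]]
    raster_shape: tuple[int, int]
    frame_interval: float = 1.0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.frames)


def centroids_from_mask(mask: LabelMask) -> CellPointSet:
    """Reduce each labelled cell to its centroid.

    The centroid of label ``k`` is the arithmetic mean of the (x, y)
    coordinates of all pixels carrying ``k``.  One point is returned per
    distinct nonzero label; an all-zero mask yields an empty point set.
    The result is invariant under relabelling of cell ids.
    """
    labels = np.unique(mask.pixels)
    labels = labels[labels > 0]
    if labels.size == 0:
        return CellPointSet(np.empty((0, 2)), mask.channel, mask.timepoint)
    # center_of_mass returns (row, col) = (y, x); swap to (x, y)
    yx = ndimage.center_of_mass(np.ones_like(mask.pixels), mask.pixels, labels)
    pts = np.array([(x, y) for (y, x) in yx], dtype=float)
    return CellPointSet(pts, mask.channel, mask.timepoint)


_REQUIRED_COLUMNS = ("x", "y", "channel", "timepoint")


def load_point_table(
    path: str | os.PathLike,
    raster_shape: tuple[int, int],
    frame_interval: float = 1.0,
    **read_csv_kwargs,
) -> TimeSeries:
    """Read a delimited centroid table into a :class:`TimeSeries`.

    The table must carry columns ``x, y, channel, timepoint`` with channel
    values in {1, 2}.  Frames are grouped and sorted by ascending timepoint;
    both channels must be present at every timepoint (an absent channel
    becomes an empty point set only if the other channel has points —
    downstream stages then reject the frame as degenerate).
    """
    df = pd.read_csv(path, **read_csv_kwargs)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"point table missing column(s): {missing}")
    for col in ("x", "y"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise SchemaError(f"column {col!r} is non-numeric")
    bad_channels = set(df["channel"].unique()) - {1, 2}
    if bad_channels:
        raise SchemaError(f"channel values must be 1 or 2, found {sorted(bad_channels)}")

    frames = []
    for t, group in df.sort_values("timepoint").groupby("timepoint", sort=True):
        pair = []
        for ch in (1, 2):
            sub = group[group["channel"] == ch]
            pair.append(CellPointSet(sub[["x", "y"]].to_numpy(float), ch, int(t)))
        frames.append(tuple(pair))
    return TimeSeries(frames, tuple(raster_shape), frame_interval)


def save_point_table(series: TimeSeries, path: str | os.PathLike) -> None:
    """Write a TimeSeries back to the canonical ``x,y,channel,timepoint`` CSV."""
    rows = []
    for pair in series.frames:
        for ps in pair:
            for x, y in ps.points:
                rows.append((x, y, ps.channel, ps.timepoint))
    pd.DataFrame(rows, columns=list(_REQUIRED_COLUMNS)).to_csv(path, index=False)


def read_mask(path: str | os.PathLike, channel: int, timepoint: int) -> LabelMask:
    """Read a single-page TIFF or PNG label mask from disk."""
    p = str(path)
    if p.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(p)
    else:
        import imageio.v3 as iio

        arr = iio.imread(p)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # greyscale PNG saved with redundant colour axis
        arr = arr[..., 0]
    if not np.issubdtype(arr.dtype, np.integer):
        if np.allclose(arr, np.round(arr)):
            arr = arr.astype(np.int64)
        else:
            raise FormatError(f"mask {p} has non-integer pixel values")
    return LabelMask(arr.astype(np.int64), channel, timepoint)


def load_mask_series(
    paths_by_channel: Mapping[int, Sequence[str | os.PathLike]],
    frame_interval: float = 1.0,
) -> TimeSeries:
    """Assemble a TimeSeries from per-channel, per-frame mask files.

    ``paths_by_channel`` maps channel (1 and 2) to equally long, frame-ordered
    path lists.  All masks must share one raster shape.
    """
    if set(paths_by_channel) != {1, 2}:
        raise SchemaError(f"expected channels {{1, 2}}, got {sorted(paths_by_channel)}")
    n1, n2 = (len(paths_by_channel[ch]) for ch in (1, 2))
    if n1 != n2:
        raise DimensionError(f"frame count mismatch: channel 1 has {n1}, channel 2 has {n2}")

    frames = []
    shape = None
    for t in range(n1):
        pair = []
        for ch in (1, 2):
            mask = read_mask(paths_by_channel[ch][t], ch, t)
            if shape is None:
                shape = mask.pixels.shape
            elif mask.pixels.shape != shape:
                raise DimensionError(
                    f"mask shape {mask.pixels.shape} differs from series shape {shape}"
                )
            pair.append(centroids_from_mask(mask))
        frames.append(tuple(pair))
    height, width = shape
    return TimeSeries(frames, (width, height), frame_interval)
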