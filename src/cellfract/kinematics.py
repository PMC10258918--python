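"""Boundary displacement and velocity.

Displacement is measured against the boundary at first contact — the frame
where the two advancing populations first touch.  For each image row (fixed
``y``), the deviation is the absolute x-offset of the current boundary from
the initial boundary's position at that row; a row holding several boundary
pixels contributes the largest deviation, which captures the tips of any
fingers.  The mean deviation over rows is the frame's displacement.

Velocity is the first difference of the displacement series after a trailing
mean over the most recent ``window`` frames (default 10) smooths the
frame-to-frame noise.  Velocity acts as a proxy for time: it starts at its
maximum when the populations meet and decays to zero as the cell density
equilibrates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .boundary import BoundaryImage
from .errors import NoContactError, UndefinedDisplacementError
from .points import TimeSeries

__all__ = [
    "BoundaryKinematics",
    "boundary_displacement",
    "boundary_velocity",
    "detect_first_contact",
]

DEFAULT_SMOOTHING_WINDOW = 10


@dataclass(frozen=True)
class BoundaryKinematics:
    """Per-series kinematic summary anchored at the first-contact frame."""

    t0: int
    displacement: np.ndarray  # px, one value per analysed frame; [0] == 0
    velocity: np.ndarray  # px per frame, same length
    v_max: float
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW


def _row_positions(img: BoundaryImage) -> dict[int, np.ndarray]:
    ys, xs = np.nonzero(img.pixels)
    order = np.argsort(ys, kind="stable")
    ys, xs = ys[order], xs[order]
    splits = np.searchsorted(ys, np.unique(ys))
    return {int(y): xs[a:b] for y, a, b in zip(np.unique(ys), splits, list(splits[1:]) + [len(xs)])}


def boundary_displacement(current: BoundaryImage, initial: BoundaryImage) -> float:
    """Mean per-row deviation (px) of ``current`` from ``initial``.

    The initial boundary's representative at a row is the mean x of its
    pixels there; the current boundary contributes, per row, the pixel with
    the greatest absolute deviation from that representative.  Rows present
    in only one of the images are skipped.  Units are node-grid pixels
    scaled by ``node_spacing``, i.e. raster pixels.
    """
    if current.n_pixels == 0 or initial.n_pixels == 0:
        raise UndefinedDisplacementError("displacement undefined for an empty boundary")
    if current.pixels.shape != initial.pixels.shape:
        raise UndefinedDisplacementError(
            f"shape mismatch: {current.pixels.shape} vs {initial.pixels.shape}"
        )
    cur_rows = _row_positions(current)
    init_rows = _row_positions(initial)
    devs = []
    for y, xs in cur_rows.items():
        ref = init_rows.get(y)
        if ref is None:
            continue
        devs.append(np.abs(xs - ref.mean()).max())
    if not devs:
        raise UndefinedDisplacementError("no image row holds boundary pixels in both frames")
    return float(np.mean(devs)) * current.node_spacing


def boundary_velocity(
    displacements: np.ndarray,
    window: int = DEFAULT_SMOOTHING_WINDOW,
    frame_interval: float = 1.0,
) -> np.ndarray:
    """Velocity series from a displacement series.

    The displacement is first smoothed with a trailing mean over
    ``min(window, frames seen so far)`` values, then differenced; the first
    velocity is 0 by convention.  For a linear displacement ramp the trailing
    mean is again linear, so the true slope is recovered once the window has
    filled.
    """
    d = np.asarray(displacements, dtype=float)
    if d.size < 2:
        return np.zeros_like(d)
    smoothed = np.array([d[max(0, i - window + 1) : i + 1].mean() for i in range(d.size)])
    v = np.empty_like(smoothed)
    v[0] = 0.0
    v[1:] = np.diff(smoothed) / frame_interval
    return v


def detect_first_contact(series: TimeSeries, threshold: float) -> int:
    """First frame where the two channels come within ``threshold`` px.

    Contact is declared when the minimum inter-channel point distance drops
    to the threshold — a practical stand-in for the visual confirmation used
    with fluorescence imagery.  A sensible threshold is about twice the
    boundary grid's node spacing.  Raises :class:`NoContactError` if the
    populations never meet.
    """
    for t, (ps1, ps2) in enumerate(series.frames):
        if len(ps1) == 0 or len(ps2) == 0:
            continue
        d, _ = cKDTree(ps2.points).query(ps1.points, k=1)
        if d.min() <= threshold:
            return t
    raise NoContactError(f"channels never within {threshold} px across {len(series)} frames")
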