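"""Synthetic fixtures with known ground truth.

Everything the pipeline consumes can be generated here: boundary rasters of
analytically known box-counting dimension (straight line, filled square,
Koch curve, midpoint-displacement rough profile) and two-population
gap-closure point-cloud series with a stored contact frame and controllable
post-contact interdigitation.  All generators are deterministic given their
seed, so no data files ship with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as _draw_line

from .boundary import BoundaryImage
from .errors import ConfigurationError, InsufficientScaleError
from .fractal import BoxCountConfig
from .points import CellPointSet, TimeSeries

__all__ = [
    "FixtureSpec",
    "KOCH_DIMENSION",
    "KOCH_BOXCOUNT",
    "FBM_BOXCOUNT",
    "make_line_boundary",
    "make_filled_boundary",
    "make_koch_boundary",
    "make_fbm_profile_boundary",
    "make_gap_closure_series",
]

KOCH_DIMENSION = np.log(4) / np.log(3)  # ~1.2619, the curve's exact dimension

# Recommended counting windows for the analytic fixtures.  The Koch raster
# needs the top box size excluded: at s = width/3 the whole curve fits in
# three tiles, a finite-size distortion of the count, so b = 4 caps the fit
# one octave lower.  The rough-profile raster is only self-affine between
# the scale of its rasterised inter-sample segments (below ~16 px the drawn
# curve is made of straight lines) and its amplitude crossover, hence the
# [16, width/16] window.
KOCH_BOXCOUNT = BoxCountConfig(b=4.0)
FBM_BOXCOUNT = BoxCountConfig(b=16.0, min_size=16)


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative request for one fixture, with its ground truth attached."""

    kind: str  # {line, filled, koch, fbm_profile, gap_closure}
    shape: tuple[int, int] = (256, 256)  # (width, height) px
    params: dict = field(default_factory=dict)
    seed: int = 0
    truth: float | int | None = None


def make_line_boundary(shape: tuple[int, int] = (100, 100), orientation: str = "horizontal") -> BoundaryImage:
    """One-pixel-wide axis-aligned line spanning the raster; dimension 1."""
    width, height = shape
    if width < 8 or height < 8:
        raise ConfigurationError("line fixture needs shape >= (8, 8)")
    pixels = np.zeros((height, width), dtype=np.uint8)
    if orientation == "horizontal":
        pixels[height // 2, :] = 1
    elif orientation == "vertical":
        pixels[:, width // 2] = 1
    else:
        raise ConfigurationError(f"unknown orientation {orientation!r}")
    return BoundaryImage(pixels, node_spacing=1.0)


def make_filled_boundary(shape: tuple[int, int] = (100, 100)) -> BoundaryImage:
    """Every pixel marked: the area-scaling limit with dimension 2."""
    width, height = shape
    return BoundaryImage(np.ones((height, width), dtype=np.uint8), node_spacing=1.0)


def _koch_segments(order: int) -> np.ndarray:
    """Vertices of the Koch generator curve on the unit interval."""
    pts = np.array([[0.0, 0.0], [1.0, 0.0]])
    third_rot = np.array(
        [[np.cos(np.pi / 3), -np.sin(np.pi / 3)], [np.sin(np.pi / 3), np.cos(np.pi / 3)]]
    )
    for _ in range(order):
        new = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            v = (b - a) / 3.0
            p1 = a + v
            p2 = p1 + third_rot @ v
            p3 = a + 2 * v
            new.extend([p1, p2, p3, b])
        pts = np.array(new)
    return pts


def make_koch_boundary(order: int, width: int | None = None) -> BoundaryImage:
    """Rasterised Koch curve of the given recursion order.

    The curve has exactly ``4 ** order`` segments and box-counting dimension
    log 4 / log 3.  The raster is ``width`` px across — by default
    ``3 ** (order + 1)``, so the smallest segments span 3 px and Bresenham
    rounding does not merge neighbouring segments.  Estimate its dimension
    with :data:`KOCH_BOXCOUNT`.
    """
    if order < 1:
        raise ConfigurationError("order must be >= 1")
    if width is None:
        width = 3 ** (order + 1)
    if width < 3**order:
        raise InsufficientScaleError(
            f"width {width} cannot resolve order {order} (needs >= {3 ** order})"
        )
    verts = _koch_segments(order)
    xs = verts[:, 0] * (width - 1)
    # peak height is sqrt(3)/6 of the base; add margin rows
    height = int(np.ceil((width - 1) * np.sqrt(3) / 6)) + 2
    ys = verts[:, 1] * (width - 1)
    pixels = np.zeros((height, width), dtype=np.uint8)
    xi = np.round(xs).astype(int)
    yi = np.round(ys).astype(int)
    for k in range(len(verts) - 1):
        rr, cc = _draw_line(yi[k], xi[k], yi[k + 1], xi[k + 1])
        pixels[rr, cc] = 1
    return BoundaryImage(pixels, node_spacing=1.0)


def make_fbm_profile_boundary(
    hurst: float, shape: tuple[int, int] = (8192, 1024), seed: int = 0
) -> BoundaryImage:
    """Single-valued rough profile by midpoint displacement.

    The record runs along the rows (one sample per row); the profile value
    runs along x and is stretched to fill the raster width.  Midpoint
    displacements shrink by ``2 ** (-hurst)`` per recursion level, giving a
    fractional-Brownian-motion-like graph whose box-counting dimension is
    ``2 - hurst`` inside its self-affine scaling window.  The default shape
    is deliberately anisotropic: a wide value axis keeps the local
    roughness (the vertical span per box) above the box size over the
    window that :data:`FBM_BOXCOUNT` fits, which a square raster cannot do
    for a 1024-sample record.  ``hurst`` = 1 is the degenerate smooth
    limit.  Deterministic for a fixed seed.
    """
    if not 0.0 < hurst <= 1.0:
        raise ConfigurationError("hurst must be in (0, 1]")
    width, height = shape
    rng = np.random.default_rng(seed)
    n_levels = int(np.ceil(np.log2(max(height - 1, 2))))
    n = 2**n_levels  # profile sampled at n + 1 row positions
    profile = np.zeros(n + 1)
    profile[0], profile[n] = rng.normal(0, 1, 2)
    sigma = 1.0
    step = n
    while step > 1:
        half = step // 2
        idx = np.arange(half, n, step)
        profile[idx] = 0.5 * (profile[idx - half] + profile[idx + half]) + rng.normal(
            0, sigma, idx.size
        )
        sigma *= 2.0 ** (-hurst)
        step = half
    ys = np.linspace(0, height - 1, n + 1)
    span = profile.max() - profile.min()
    if span == 0:
        span = 1.0
    xs = (profile - profile.min()) / span * (width - 1)
    pixels = np.zeros((height, width), dtype=np.uint8)
    xi = np.clip(np.round(xs).astype(int), 0, width - 1)
    yi = np.clip(np.round(ys).astype(int), 0, height - 1)
    for k in range(n):
        rr, cc = _draw_line(yi[k], xi[k], yi[k + 1], xi[k + 1])
        pixels[rr, cc] = 1
    return BoundaryImage(pixels, node_spacing=1.0)


def make_gap_closure_series(spec: FixtureSpec) -> TimeSeries:
    """Two point blocks that approach, touch, and optionally interdigitate.

    Emulates a gap-closure migration assay: channel-1 cells fill the left of
    the raster and channel-2 cells the right, separated by a gap that closes
    at constant speed.  After contact the interface develops sinusoidal
    fingers of amplitude ``amplitude`` px and wavelength ``wavelength`` px,
    ramped in over ``ramp`` frames, so the sharpness of the final boundary
    is controlled by a single dial.  Cell points sit on a jittered lattice
    with ``spacing`` px between neighbours (default 10, a typical cell
    diameter).  The truth contact frame is stored in ``series.meta``.

    params accepted in ``spec.params``: frames (default 12), spacing (10),
    gap (half-gap at t=0, default 60), speed (px of half-gap closed per
    frame, default 12), amplitude (0), wavelength (64), ramp (3),
    jitter (px SD, default 1).
    """
    p = dict(spec.params)
    frames = int(p.get("frames", 12))
    if frames < 2:
        raise ConfigurationError("gap-closure series needs >= 2 frames")
    spacing = float(p.get("spacing", 10.0))
    gap0 = float(p.get("gap", 60.0))
    speed = float(p.get("speed", 12.0))
    amplitude = float(p.get("amplitude", 0.0))
    wavelength = float(p.get("wavelength", 64.0))
    ramp = max(int(p.get("ramp", 3)), 1)
    jitter = float(p.get("jitter", 1.0))
    width, height = spec.shape
    rng = np.random.default_rng(spec.seed)

    contact_frame = int(np.ceil(gap0 / speed))
    # seam sits slightly off the raster midline: a boundary lying exactly on
    # the midline coincides with a box-grid edge at every scale, the
    # worst-case quantization geometry, which no real assay reproduces
    cx = width / 2.0 + 1.2 * spacing
    lat_x = np.arange(spacing / 2, width, spacing)
    lat_y = np.arange(spacing / 2, height, spacing)
    gx, gy = np.meshgrid(lat_x, lat_y)
    base = np.column_stack([gx.ravel(), gy.ravel()])
    # one fixed jitter per lattice site per channel keeps cells identifiable
    jit1 = rng.normal(0, jitter, base.shape)
    jit2 = rng.normal(0, jitter, base.shape)

    out_frames = []
    for t in range(frames):
        half_gap = max(gap0 - speed * t, 0.0)
        growth = min(max(t - contact_frame, 0) / ramp, 1.0) if amplitude > 0 else 0.0
        finger = amplitude * growth * np.sin(2 * np.pi * base[:, 1] / wavelength)
        left_edge = cx - half_gap + finger
        right_edge = cx + half_gap + finger
        pts1 = (base + jit1)[base[:, 0] <= left_edge]
        pts2 = (base + jit2)[base[:, 0] > right_edge]
        out_frames.append(
            (CellPointSet(pts1, 1, t), CellPointSet(pts2, 2, t))
        )
    series = TimeSeries(out_frames, (width, height))
    series.meta["contact_frame"] = min(contact_frame, frames - 1) if gap0 / speed < frames else None
    series.meta["spec"] = spec
    return series
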