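"""Region classification and boundary extraction.

A regular grid of nodes is laid over the raster (one node per ``compression``
pixels) and every node is assigned to region 1 or region 2 according to the
majority type among its ``n_neighbors`` nearest cell location points.  The
boundary layer is then the set of region-1 nodes that touch region 2.

The default configuration — 1 nearest neighbour, a compression factor of 2,
4-connectivity for "touching" — is the one found to best separate
well-mixed from sharply segregated populations while keeping replicate
variability low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ConfigurationError, DegenerateInputError
from .points import CellPointSet

__all__ = ["BoundaryConfig", "RegionGrid", "BoundaryImage", "classify_regions", "extract_boundary"]


@dataclass(frozen=True)
class BoundaryConfig:
    """Knobs of the boundary-definition step.

    n_neighbors
        k of the k-nearest-neighbour vote assigning grid nodes to a region.
    compression
        Pixels per grid node; values below 1 supersample the raster.
    connectivity
        4 or 8: which node adjacency counts as "bordering" region 2.
    """

    n_neighbors: int = 1
    compression: float = 2.0
    connectivity: int = 4

    def __post_init__(self) -> None:
        if self.n_neighbors < 1:
            raise ConfigurationError("n_neighbors must be >= 1")
        if self.compression <= 0:
            raise ConfigurationError("compression must be > 0")
        if self.connectivity not in (4, 8):
            raise ConfigurationError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class RegionGrid:
    """Node raster labelled {1, 2}; ``labels[iy, ix]`` is the node at pixel
    position ``(ix * node_spacing, iy * node_spacing)``."""

    labels: np.ndarray
    node_spacing: float


@dataclass(frozen=True)
class BoundaryImage:
    """Binary node raster: 1 where a region-1 node borders region 2."""

    pixels: np.ndarray
    node_spacing: float

    @property
    def width(self) -> int:
        """x-extent in nodes; the length scale for box-size selection."""
        return self.pixels.shape[1]

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


def _node_positions(raster_shape: tuple[int, int], compression: float):
    width, height = raster_shape
    nx = int(np.ceil(width / compression))
    ny = int(np.ceil(height / compression))
    xs = np.arange(nx) * compression
    ys = np.arange(ny) * compression
    return xs, ys


def classify_regions(
    frame: tuple[CellPointSet, CellPointSet],
    raster_shape: tuple[int, int],
    config: BoundaryConfig = BoundaryConfig(),
) -> RegionGrid:
    """Assign every grid node to the region of its nearest cells.

    With k = 1 a node takes the type of its single nearest point; the result
    is independent of the ordering of nodes and of input points.  Exact
    distance ties (and tied votes for k > 1) resolve to region 1, a
    deterministic, order-independent rule.

    Raises :class:`DegenerateInputError` when either channel is empty —
    there is no boundary to define and callers typically skip the frame.
    """
    ps1, ps2 = frame
    if len(ps1) == 0 or len(ps2) == 0:
        raise DegenerateInputError(
            f"both channels need >= 1 point (got {len(ps1)} and {len(ps2)})"
        )
    xs, ys = _node_positions(raster_shape, config.compression)
    gx, gy = np.meshgrid(xs, ys)  # shape (ny, nx)
    nodes = np.column_stack([gx.ravel(), gy.ravel()])

    k = config.n_neighbors
    if k == 1:
        # Two-tree formulation makes the tie rule (<= prefers region 1) exact.
        d1, _ = cKDTree(ps1.points).query(nodes, k=1)
        d2, _ = cKDTree(ps2.points).query(nodes, k=1)
        labels = np.where(d1 <= d2, 1, 2)
    else:
        pts = np.vstack([ps1.points, ps2.points])
        types = np.concatenate([np.ones(len(ps1), int), np.full(len(ps2), 2, int)])
        k_eff = min(k, len(pts))
        _, idx = cKDTree(pts).query(nodes, k=k_eff)
        idx = np.atleast_2d(idx.T).T  # ensure (n_nodes, k_eff)
        votes2 = (types[idx] == 2).sum(axis=1)
        labels = np.where(votes2 * 2 > k_eff, 2, 1)  # ties -> region 1
    return RegionGrid(labels.reshape(gy.shape).astype(np.int8), config.compression)


_STRUCT4 = ndimage.generate_binary_structure(2, 1)
_STRUCT8 = ndimage.generate_binary_structure(2, 2)


def extract_boundary(grid: RegionGrid, config: BoundaryConfig = BoundaryConfig()) -> BoundaryImage:
    """Mark region-1 nodes with at least one region-2 neighbour.

    A grid containing a single region yields an empty boundary; it is never
    an error, mirroring a frame where one population has pulled out of view.
    """
    struct = _STRUCT4 if config.connectivity == 4 else _STRUCT8
    r2 = grid.labels == 2
    near_r2 = ndimage.binary_dilation(r2, structure=struct)
    pixels = ((grid.labels == 1) & near_r2).astype(np.uint8)
    return BoundaryImage(pixels, grid.node_spacing)


def boundary_coordinates(img: BoundaryImage) -> np.ndarray:
    """(x, y) node coordinates of all boundary pixels, for CSV export."""
    ys, xs = np.nonzero(img.pixels)
    return np.column_stack([xs, ys])
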