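"""Two-population lattice random walk with affinity-weighted moves.

Two cell types start as solid blocks on opposite edges of a rectangular
lattice and migrate into the gap between them.  Each step visits every cell
once in a fresh random order; a cell may hop to one of its four free
neighbouring sites, with the relative weight of each destination set by the
cells adjacent to it:

    q_j = a_l ** n_l * a_d ** n_d * r

where ``n_l`` and ``n_d`` count same- and opposite-type cells adjacent to
destination ``j``, ``a_l`` is the like-type affinity of the moving cell's
type, ``a_d`` the unlike-type affinity shared by both types, and ``r`` is 0
when the destination is occupied or off the grid.  The cell moves in
direction ``i`` with probability ``p_m * q_i / sum_j q_j`` (it stays put
with the remaining ``1 - p_m``, or with certainty when every ``q_j`` is 0).
Affinity multipliers above 1 attract, below 1 repel: a small ``a_d`` makes
cells avoid sites flanked by the other type, which is the lattice analogue
of a high interfacial tension between two immiscible fluids.

Updates are sequential — each cell commits its move before the next cell's
weights are computed — so two cells can never claim one site.  There is no
division or death; per-type counts are conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ConfigurationError
from .points import CellPointSet

__all__ = [
    "SimulationParams",
    "GridState",
    "MoveProposal",
    "initialize",
    "move_weights",
    "step",
    "run",
    "to_point_sets",
]

# direction order: up, down, left, right (dy/dx on the lattice)
_DIRECTIONS = ((0, 1), (0, -1), (-1, 0), (1, 0))


@dataclass(frozen=True)
class SimulationParams:
    """Simulation condition.

    The defaults reproduce the standard setup: a 30 x 50 lattice seeded with
    400 cells of each type as 8-column blocks along the two vertical edges,
    move probability 0.95 for both types, like-affinity 1.5, run for 80
    steps.  ``a_d`` is the experimental dial: 1.5 emulates two mutually
    attracted (like) populations, values well below 1 emulate strong
    differential affinity.
    """

    p_m1: float = 0.95
    p_m2: float = 0.95
    a_l1: float = 1.5
    a_l2: float = 1.5
    a_d: float = 1.5
    grid_cols: int = 30
    grid_rows: int = 50
    block_cols: int = 8
    n_steps: int = 80
    seed: int = 0
    include_self: bool = False  # count the mover's own site toward n_l?

    def __post_init__(self) -> None:
        for name in ("p_m1", "p_m2"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        for name in ("a_l1", "a_l2", "a_d"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if 2 * self.block_cols > self.grid_cols:
            raise ConfigurationError(
                f"seed blocks overlap: 2*{self.block_cols} > {self.grid_cols} columns"
            )


@dataclass
class GridState:
    """Lattice occupancy plus the cell list it mirrors.

    ``occupancy[x, y]`` is 0 (empty), 1 or 2; ``cells`` is an (n, 3) int
    array of columns (x, y, type).  The two representations stay consistent
    at every step.
    """

    occupancy: np.ndarray
    cells: np.ndarray
    iteration: int = 0

    def copy(self) -> "GridState":
        return GridState(self.occupancy.copy(), self.cells.copy(), self.iteration)

    def counts(self) -> tuple[int, int]:
        return int((self.cells[:, 2] == 1).sum()), int((self.cells[:, 2] == 2).sum())


@dataclass(frozen=True)
class MoveProposal:
    """Unnormalised weights of the four candidate moves of one cell."""

    q: np.ndarray  # 4 weights, order up/down/left/right
    n_l: np.ndarray
    n_d: np.ndarray
    r: np.ndarray  # availability flags

    def probabilities(self, p_m: float) -> np.ndarray:
        """Directional move probabilities; sums to p_m if any move is open."""
        total = self.q.sum()
        if total == 0:
            return np.zeros(4)
        return p_m * self.q / total


def initialize(params: SimulationParams) -> GridState:
    """Seed the two type blocks along the left and right lattice edges."""
    occ = np.zeros((params.grid_cols, params.grid_rows), dtype=np.int8)
    occ[: params.block_cols, :] = 1
    occ[params.grid_cols - params.block_cols :, :] = 2
    xs, ys = np.nonzero(occ)
    cells = np.column_stack([xs, ys, occ[xs, ys]]).astype(np.int64)
    return GridState(occ, cells, iteration=0)


def _neighbor_counts(
    occ: np.ndarray, x: int, y: int, own_type: int, exclude: tuple[int, int] | None
) -> tuple[int, int]:
    cols, rows = occ.shape
    n_l = n_d = 0
    for dx, dy in _DIRECTIONS:
        nx, ny = x + dx, y + dy
        if not (0 <= nx < cols and 0 <= ny < rows):
            continue
        if exclude is not None and (nx, ny) == exclude:
            continue
        t = occ[nx, ny]
        if t == own_type:
            n_l += 1
        elif t != 0:
            n_d += 1
    return n_l, n_d


def move_weights(state: GridState, cell_index: int, params: SimulationParams) -> MoveProposal:
    """Affinity weights of the four moves available to one cell.

    A destination is unavailable (r = 0, hence q = 0) when occupied or off
    the grid.  Neighbour counts at an available destination exclude the
    moving cell's own current site, so a cell's weight to step sideways is
    not biased by itself; set ``params.include_self`` to probe the
    alternative convention.
    """
    x, y, ctype = (int(v) for v in state.cells[cell_index])
    a_l = params.a_l1 if ctype == 1 else params.a_l2
    occ = state.occupancy
    cols, rows = occ.shape
    q = np.zeros(4)
    n_l = np.zeros(4, dtype=int)
    n_d = np.zeros(4, dtype=int)
    r = np.zeros(4, dtype=int)
    exclude = None if params.include_self else (x, y)
    for j, (dx, dy) in enumerate(_DIRECTIONS):
        nx, ny = x + dx, y + dy
        if not (0 <= nx < cols and 0 <= ny < rows) or occ[nx, ny] != 0:
            continue
        r[j] = 1
        n_l[j], n_d[j] = _neighbor_counts(occ, nx, ny, ctype, exclude)
        q[j] = a_l ** n_l[j] * params.a_d ** n_d[j]
    return MoveProposal(q, n_l, n_d, r)


def step(state: GridState, params: SimulationParams, rng: np.random.Generator) -> GridState:
    """Advance the lattice by one step (in place) and return the state.

    Cells are visited in a fresh random permutation; each cell draws one
    move (or stay) from its current weights, computed against the occupancy
    already updated by earlier movers in the same step.
    """
    occ = state.occupancy
    cells = state.cells
    order = rng.permutation(len(cells))
    for ci in order:
        proposal = move_weights(state, ci, params)
        total = proposal.q.sum()
        if total == 0:
            continue
        ctype = cells[ci, 2]
        p_m = params.p_m1 if ctype == 1 else params.p_m2
        probs = p_m * proposal.q / total
        u = rng.random()
        cum = 0.0
        chosen = -1  # stay
        for j in range(4):
            cum += probs[j]
            if u < cum:
                chosen = j
                break
        if chosen < 0:
            continue
        x, y = int(cells[ci, 0]), int(cells[ci, 1])
        dx, dy = _DIRECTIONS[chosen]
        occ[x, y] = 0
        occ[x + dx, y + dy] = ctype
        cells[ci, 0] = x + dx
        cells[ci, 1] = y + dy
    state.iteration += 1
    return state


def run(params: SimulationParams, return_states: bool = True) -> list[GridState]:
    """Run the simulation, returning the initial state plus one per step.

    The trajectory is fully reproducible from ``params.seed``; one generator
    drives both the per-step shuffles and the move draws.
    """
    rng = np.random.default_rng(params.seed)
    state = initialize(params)
    trajectory = [state.copy()]
    for _ in range(params.n_steps):
        state = step(state, params, rng)
        if return_states:
            trajectory.append(state.copy())
    if not return_states:
        trajectory.append(state.copy())
    return trajectory


def to_point_sets(
    state: GridState, scale: float = 10.0, timepoint: int | None = None
) -> tuple[CellPointSet, CellPointSet, tuple[int, int]]:
    """Convert lattice occupancy to two pixel-space point sets.

    A cell on site (x, y) becomes a point at ``((x + 0.5) * scale,
    (y + 0.5) * scale)`` — site centres on a raster of ``scale`` px per
    site, with the default matching a typical 10 px cell diameter in the
    imaging data.  Returns the two point sets and the raster shape
    (width, height) for the boundary step.
    """
    if scale < 1:
        raise ConfigurationError("scale must be >= 1")
    t = state.iteration if timepoint is None else timepoint
    out = []
    for ctype in (1, 2):
        sub = state.cells[state.cells[:, 2] == ctype]
        pts = (sub[:, :2].astype(float) + 0.5) * scale
        out.append(CellPointSet(pts, ctype, t))
    cols, rows = state.occupancy.shape
    return out[0], out[1], (int(np.ceil(cols * scale)), int(np.ceil(rows * scale)))
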