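import numpy as np
import pytest
from scipy import stats

from cellfract import (
    GridState,
    SimulationParams,
    initialize,
    move_weights,
    run,
    step,
    to_point_sets,
)
from cellfract.errors import ConfigurationError


def make_state(occ):
    occ = np.asarray(occ, np.int8)
    xs, ys = np.nonzero(occ)
    cells = np.column_stack([xs, ys, occ[xs, ys]]).astype(np.int64)
    return GridState(occ.copy(), cells, 0)


def cell_index(state, x, y):
    return int(np.where((state.cells[:, 0] == x) & (state.cells[:, 1] == y))[0][0])


class TestInitialize:
    def test_default_seeding_400_cells_per_type(self):
        state = initialize(SimulationParams())
        n1, n2 = state.counts()
        assert (n1, n2) == (400, 400)
        assert (state.occupancy[:8, :] == 1).all()
        assert (state.occupancy[-8:, :] == 2).all()
        assert (state.occupancy[8:-8, :] == 0).all()

    def test_single_column_blocks(self):
        state = initialize(SimulationParams(grid_cols=4, grid_rows=3, block_cols=1))
        assert state.counts() == (3, 3)
        assert (state.occupancy[0, :] == 1).all() and (state.occupancy[3, :] == 2).all()

    def test_occupancy_consistent_with_cell_list(self):
        state = initialize(SimulationParams())
        rebuilt = np.zeros_like(state.occupancy)
        for x, y, t in state.cells:
            rebuilt[x, y] = t
        np.testing.assert_array_equal(rebuilt, state.occupancy)

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationParams(grid_cols=10, block_cols=6)


class TestMoveWeights:
    def test_isolated_cell_has_uniform_weights(self):
        occ = np.zeros((7, 7))
        occ[3, 3] = 1
        state = make_state(occ)
        prop = move_weights(state, 0, SimulationParams())
        np.testing.assert_allclose(prop.q, 1.0)
        np.testing.assert_allclose(prop.probabilities(0.95), 0.95 / 4)

    def test_fully_blocked_cell_cannot_move(self):
        occ = np.zeros((5, 5))
        occ[2, 2] = 1
        occ[1, 2] = occ[3, 2] = occ[2, 1] = occ[2, 3] = 2
        state = make_state(occ)
        prop = move_weights(state, cell_index(state, 2, 2), SimulationParams())
        assert (prop.q == 0).all()
        assert prop.probabilities(0.95).sum() == 0.0

    def test_weight_formula_with_one_like_one_unlike_neighbor(self):
        # mover at (2,2); destination (3,2) free with neighbours: like at
        # (4,2), unlike at (3,3); mover's own site excluded from the counts
        occ = np.zeros((6, 6))
        occ[2, 2] = 1
        occ[4, 2] = 1
        occ[3, 3] = 2
        state = make_state(occ)
        params = SimulationParams(a_l1=1.5, a_d=0.5)
        prop = move_weights(state, cell_index(state, 2, 2), params)
        # directions are (up,down,left,right) = ((0,1),(0,-1),(-1,0),(1,0))
        assert prop.q[3] == pytest.approx(1.5 * 0.5)
        assert prop.n_l[3] == 1 and prop.n_d[3] == 1

    def test_own_site_counts_when_include_self(self):
        occ = np.zeros((6, 6))
        occ[2, 2] = 1
        state = make_state(occ)
        prop = move_weights(state, 0, SimulationParams(include_self=True, a_l1=2.0))
        np.testing.assert_allclose(prop.q, 2.0)  # mover contributes n_l = 1 everywhere

    def test_probabilities_sum_to_pm_over_random_states(self, rng):
        params = SimulationParams(a_l1=1.5, a_l2=0.8, a_d=0.3)
        for _ in range(300):
            occ = (rng.random((6, 6)) < 0.5) * rng.integers(1, 3, (6, 6))
            if not occ.any():
                continue
            state = make_state(occ)
            ci = int(rng.integers(len(state.cells)))
            prop = move_weights(state, ci, params)
            total = prop.probabilities(0.95).sum()
            assert total == pytest.approx(0.95) or total == 0.0
            assert (prop.q[prop.r == 0] == 0).all()
            assert (prop.q[prop.r == 1] > 0).all()


class TestStep:
    def test_frozen_dynamics_leave_state_unchanged(self):
        params = SimulationParams(p_m1=0.0, p_m2=0.0, n_steps=5)
        traj = run(params)
        np.testing.assert_array_equal(traj[0].occupancy, traj[-1].occupancy)

    def test_single_cell_walks_uniformly(self):
        # unbiased 4-neighbour walk: direction frequencies consistent with
        # uniform by chi-square over 10^4 accepted moves
        occ = np.zeros((41, 41))
        occ[20, 20] = 1
        state = make_state(occ)
        params = SimulationParams(p_m1=1.0, a_l1=1.5, a_d=1.5,
                                  grid_cols=41, grid_rows=41, block_cols=1)
        rng_ = np.random.default_rng(7)
        moves = {(-1, 0): 0, (1, 0): 0, (0, -1): 0, (0, 1): 0}
        prev = tuple(state.cells[0, :2])
        for _ in range(10_000):
            # re-centre to keep the walker away from the grid edges
            state.occupancy[:] = 0
            state.cells[0, :2] = (20, 20)
            state.occupancy[20, 20] = 1
            step(state, params, rng_)
            dx, dy = int(state.cells[0, 0]) - 20, int(state.cells[0, 1]) - 20
            if (dx, dy) != (0, 0):
                moves[(dx, dy)] += 1
        counts = np.array(list(moves.values()))
        assert counts.sum() == 10_000  # p_m = 1 and 4 free sites: always moves
        chi2 = stats.chisquare(counts).pvalue
        assert chi2 > 1e-4

    def test_conservation_and_exclusion_over_default_run(self):
        traj = run(SimulationParams(a_d=0.2, n_steps=80, seed=3))
        for state in traj[::20]:
            assert state.counts() == (400, 400)
            rebuilt = np.zeros_like(state.occupancy)
            for x, y, t in state.cells:
                assert rebuilt[x, y] == 0, "two cells on one site"
                rebuilt[x, y] = t
            np.testing.assert_array_equal(rebuilt, state.occupancy)


class TestRun:
    def test_same_seed_reproduces_trajectory(self):
        p = SimulationParams(a_d=0.5, n_steps=15, seed=11)
        t1, t2 = run(p), run(p)
        for s1, s2 in zip(t1, t2):
            np.testing.assert_array_equal(s1.cells, s2.cells)

    def test_zero_steps_returns_initial_only(self):
        traj = run(SimulationParams(n_steps=0))
        assert len(traj) == 1 and traj[0].iteration == 0

    def test_gap_closes_by_iteration_30_under_mixing(self):
        traj = run(SimulationParams(a_d=1.5, seed=0))
        gap_cols = traj[30].occupancy[12:18, :]
        assert (gap_cols != 0).mean() > 0.15  # seeded gap substantially occupied
        assert (traj[0].occupancy[12:18, :] == 0).all()

    def test_like_affinity_mixes_more_than_strong_repulsion(self):
        # coarse contrast of the affinity dial: deep interpenetration with
        # a_d = 1.5, almost none with a_d = 0.05
        def crossers(ad):
            final = run(SimulationParams(a_d=ad, seed=5), return_states=False)[-1]
            c = final.cells
            return ((c[:, 2] == 1) & (c[:, 0] >= 15)).sum() + (
                (c[:, 2] == 2) & (c[:, 0] < 15)
            ).sum()

        assert crossers(1.5) > crossers(0.05) + 20

    def test_neutral_parameters_make_types_exchangeable(self):
        # with a_l1 = a_l2 = a_d the labels are statistically exchangeable:
        # type-1 and mirrored type-2 centroids agree within a site
        offs = []
        for seed in range(5):
            final = run(
                SimulationParams(a_d=1.5, a_l1=1.5, a_l2=1.5, seed=seed),
                return_states=False,
            )[-1]
            c = final.cells
            x1 = c[c[:, 2] == 1, 0].mean()
            x2_mirror = (29 - c[c[:, 2] == 2, 0]).mean()
            offs.append(x1 - x2_mirror)
        assert abs(np.mean(offs)) < 1.0


class TestToPointSets:
    def test_unit_scale_maps_to_site_centres(self):
        state = initialize(SimulationParams(grid_cols=4, grid_rows=3, block_cols=1))
        ps1, ps2, shape = to_point_sets(state, scale=1)
        assert shape == (4, 3)
        np.testing.assert_allclose(ps1.points, [[0.5, 0.5], [0.5, 1.5], [0.5, 2.5]])

    def test_doubling_scale_doubles_coordinates(self):
        state = initialize(SimulationParams())
        a, _, _ = to_point_sets(state, scale=5)
        b, _, _ = to_point_sets(state, scale=10)
        np.testing.assert_allclose(b.points, 2 * a.points)

    def test_fractality_invariant_to_rendering_scale(self):
        from cellfract import BoundaryConfig, classify_regions, extract_boundary, fractal_dimension

        state = run(SimulationParams(a_d=0.2, seed=0), return_states=False)[-1]
        fs = []
        for scale in (4, 8, 16):
            ps1, ps2, shape = to_point_sets(state, scale=scale)
            cfg = BoundaryConfig()
            img = extract_boundary(classify_regions((ps1, ps2), shape, cfg), cfg)
            fs.append(fractal_dimension(img).f)
        assert max(fs) - min(fs) < 0.03
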