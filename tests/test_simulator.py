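"""Unit and property tests for the lattice growth model."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from clonemix.simulator import (
    EMPTY,
    WT,
    MUT,
    Mechanics,
    SimParams,
    LatticeState,
    BoundaryOverflowError,
    SizingError,
    initialize,
    step,
    push_chain,
    introduce_mutant,
    run,
)


def make_state(grid):
    return LatticeState.from_grid(np.asarray(grid, dtype=np.int8))


class TestInitialize:
    def test_single_wt_cell_at_center(self):
        params = SimParams(final_size=10_000)
        st_ = initialize(params)
        assert st_.n_wt == 1 and st_.n_mut == 0 and st_.t == 0.0
        side = params.resolved_side()
        assert st_.grid[side // 2, side // 2] == WT
        assert (st_.grid != EMPTY).sum() == 1

    def test_undersized_grid_rejected(self):
        with pytest.raises(SizingError):
            initialize(SimParams(final_size=10_000, side=100))

    def test_explicit_large_side_accepted(self):
        st_ = initialize(SimParams(arise_size=2, final_size=4, side=300))
        assert st_.n_wt == 1

    def test_same_seed_same_state(self):
        p = SimParams(fitness_ratio=2.0, arise_size=10, final_size=200, seed=42)
        s1, _ = run(p)
        s2, _ = run(p)
        assert np.array_equal(s1.grid, s2.grid)
        assert s1.t == s2.t


class TestPushChain:
    def test_row_shifts_toward_first_empty(self):
        # row [A B C _] pushing right from A -> [A _ B C]
        g = np.zeros((7, 7), dtype=np.int8)
        g[3, 1:4] = [WT, MUT, WT]
        st_ = make_state(g)
        push_chain(st_, (3, 1), (0, 1))
        assert list(st_.grid[3, 1:5]) == [WT, EMPTY, MUT, WT]

    def test_adjacent_empty_is_noop(self):
        g = np.zeros((5, 5), dtype=np.int8)
        g[2, 2] = WT
        st_ = make_state(g)
        before = st_.grid.copy()
        push_chain(st_, (2, 2), (1, 0))
        assert np.array_equal(st_.grid, before)

    def test_full_row_to_edge_overflows(self):
        g = np.zeros((5, 5), dtype=np.int8)
        g[2, 2:] = WT
        st_ = make_state(g)
        with pytest.raises(BoundaryOverflowError):
            push_chain(st_, (2, 2), (0, 1))

    def test_labels_travel_with_cells_diagonal(self):
        g = np.zeros((9, 9), dtype=np.int8)
        g[4, 4] = WT
        g[5, 5] = MUT
        g[6, 6] = WT
        st_ = make_state(g)
        push_chain(st_, (4, 4), (1, 1))
        assert st_.grid[5, 5] == EMPTY
        assert st_.grid[6, 6] == MUT and st_.grid[7, 7] == WT

    @given(st.integers(0, 2**31 - 1))
    def test_conservation_random_grids(self, seed):
        """Push chains conserve the multiset of clone labels."""
        rng = np.random.default_rng(seed)
        g = rng.choice([EMPTY, WT, MUT], size=(20, 20), p=[0.4, 0.35, 0.25]).astype(np.int8)
        st_ = make_state(g)
        before = np.bincount(st_.grid.ravel(), minlength=3)
        occ = np.argwhere(g > 0)
        dirs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
        for _ in range(20):
            r, c = occ[rng.integers(len(occ))]
            if st_.grid[r, c] == EMPTY:
                continue  # occupant moved away in an earlier push
            try:
                push_chain(st_, (int(r), int(c)), dirs[rng.integers(8)])
            except BoundaryOverflowError:
                pass
            after = np.bincount(st_.grid.ravel(), minlength=3)
            assert np.array_equal(before, after)


class TestStep:
    def test_single_cell_division_into_moore_neighbor(self, rng):
        g = np.zeros((7, 7), dtype=np.int8)
        g[3, 3] = WT
        st_ = make_state(g)
        step(st_, SimParams(arise_size=2, final_size=4, side=7, allow_small_grid=True), rng)
        assert st_.population == 2
        occ = np.argwhere(st_.grid == WT)
        d = np.abs(occ - [3, 3]).max(axis=1)
        assert set(d) == {0, 1}  # parent plus a Moore neighbor

    def test_surrounded_cell_pushes_and_conserves(self, rng):
        g = np.zeros((11, 11), dtype=np.int8)
        g[4:7, 4:7] = WT
        g[5, 5] = MUT
        st_ = make_state(g)
        params = SimParams(fitness_ratio=1e9, arise_size=2, final_size=20, side=11,
                           allow_small_grid=True)
        step(st_, params, rng)  # the MUT center divides (rate-dominant) and must push
        assert st_.population == 10
        assert st_.n_mut == 2 and st_.n_wt == 8  # every pre-existing cell preserved

    def test_surrounded_cell_blocked_without_pushing(self, rng):
        g = np.zeros((11, 11), dtype=np.int8)
        g[4:7, 4:7] = WT
        g[5, 5] = MUT
        st_ = make_state(g)
        before = st_.grid.copy()
        params = SimParams(fitness_ratio=1e9, arise_size=2, final_size=20, side=11,
                           mechanics=Mechanics.EMPTY_ONLY, death_rate=0.0,
                           allow_small_grid=True)
        t0 = st_.t
        step(st_, params, rng)
        assert np.array_equal(st_.grid, before)  # blocked attempt is a no-op
        assert st_.t > t0  # but consumes the waiting time

    def test_death_removes_cell_under_empty_only(self, rng):
        g = np.zeros((7, 7), dtype=np.int8)
        g[3, 3] = WT
        st_ = make_state(g)
        params = SimParams(arise_size=2, final_size=4, side=7, death_rate=1e9,
                           mechanics=Mechanics.EMPTY_ONLY, allow_small_grid=True)
        step(st_, params, rng)
        assert st_.population == 0 and st_.extinct


class TestIntroduceMutant:
    def test_single_cell_relabeled(self, rng):
        g = np.zeros((30, 30), dtype=np.int8)
        g[10:20, 10:20] = WT
        st_ = make_state(g)
        introduce_mutant(st_, rng)
        assert st_.n_mut == 1 and st_.n_wt == 99
        assert st_.mutant_frequency() == pytest.approx(0.01)

    def test_two_cell_population_gives_half(self, rng):
        g = np.zeros((7, 7), dtype=np.int8)
        g[3, 3] = g[3, 4] = WT
        st_ = make_state(g)
        introduce_mutant(st_, rng)
        assert st_.mutant_frequency() == pytest.approx(0.5)

    def test_second_introduction_rejected(self, rng):
        g = np.zeros((7, 7), dtype=np.int8)
        g[3, 3] = g[3, 4] = WT
        st_ = make_state(g)
        introduce_mutant(st_, rng)
        with pytest.raises(RuntimeError):
            introduce_mutant(st_, rng)

    def test_same_seed_same_cell(self):
        g = np.zeros((30, 30), dtype=np.int8)
        g[10:20, 10:20] = WT
        a = make_state(g)
        b = make_state(g)
        introduce_mutant(a, np.random.default_rng(5))
        introduce_mutant(b, np.random.default_rng(5))
        assert np.array_equal(a.grid, b.grid)


class TestRun:
    def test_stops_exactly_at_final_size(self):
        p = SimParams(fitness_ratio=2.0, arise_size=20, final_size=500, seed=3)
        state, traj = run(p)
        assert state.population == 500
        assert not state.extinct
        assert traj.records[-1][0] == 500

    def test_monotone_growth_under_pushing(self):
        p = SimParams(arise_size=10, final_size=300, seed=8)
        _, traj = run(p, checkpoints=list(range(10, 301, 10)))
        sizes = [r[0] for r in traj.records]
        assert sizes == sorted(sizes)

    def test_trajectory_frequencies_in_unit_interval(self):
        p = SimParams(fitness_ratio=4.0, arise_size=10, final_size=400, seed=9)
        _, traj = run(p, checkpoints=[50, 100, 200, 400])
        for _, _, f, s in traj.records:
            assert 0.0 <= f <= 1.0 and 0.0 <= s <= 1.0

    def test_empty_only_runs_and_may_die_out(self):
        # generous side: near-critical colonies wander before dying out
        p = SimParams(arise_size=5, final_size=60, death_rate=0.9,
                      mechanics=Mechanics.EMPTY_ONLY, seed=11, side=90)
        state, traj = run(p)
        assert state.extinct or state.population == 60
        assert state.extinct == traj.extinct

    def test_counts_match_grid(self):
        p = SimParams(fitness_ratio=3.0, arise_size=50, final_size=800, seed=13)
        state, _ = run(p)
        assert state.n_wt == int((state.grid == WT).sum())
        assert state.n_mut == int((state.grid == MUT).sum())


def _nonspatial_mean_freq(fitness, arise, final, reps, seed):
    """Non-spatial two-type birth-process oracle for the mean mutant
    frequency at the final population size."""
    rng = np.random.default_rng(seed)
    freqs = np.empty(reps)
    for r in range(reps):
        n_wt, n_mut = arise - 1, 1
        while n_wt + n_mut < final:
            if rng.random() * (n_wt + fitness * n_mut) < n_wt:
                n_wt += 1
            else:
                n_mut += 1
        freqs[r] = n_mut / final
    return freqs


class TestNeutralDrift:
    def test_spatial_matches_nonspatial_birth_process(self):
        """Pushing never blocks a division, so the clone-size dynamics
        are a two-type Yule process; the spatial model's mean mutant
        frequency must agree with a non-spatial oracle."""
        arise, final, reps = 10, 200, 300
        oracle = _nonspatial_mean_freq(1.0, arise, final, reps, seed=100)
        root = np.random.SeedSequence(200)
        spatial = np.empty(reps)
        p = SimParams(fitness_ratio=1.0, arise_size=arise, final_size=final)
        for r, ss in enumerate(root.spawn(reps)):
            state, _ = run(p, rng=np.random.default_rng(ss))
            spatial[r] = state.mutant_frequency()
        se = np.hypot(oracle.std(ddof=1), spatial.std(ddof=1)) / np.sqrt(reps)
        assert abs(spatial.mean() - oracle.mean()) < 3 * se
        # both must also agree with the exact martingale value 1/arise
        assert abs(spatial.mean() - 1 / arise) < 3 * spatial.std(ddof=1) / np.sqrt(reps)
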