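"""Tests for center-cell identification and neighbour-pattern statistics."""

import numpy as np
import pytest

from adhesim import pattern_metrics as pm
from adhesim.vertex_sim import CellType, TissueState


def square_lattice_tissue(n_side, box, labeler, jitter_seed=None):
    """n_side x n_side cellular points on a unit grid filling a periodic box."""
    xs = np.arange(n_side) + 0.5
    pts = np.array([[x, y] for y in xs for x in xs]) * (box / n_side)
    labels = np.array(
        [labeler(i % n_side, i // n_side) for i in range(n_side * n_side)],
        dtype=np.int64,
    )
    if jitter_seed is not None:
        pts = pts + np.random.default_rng(jitter_seed).normal(0, 0.01, pts.shape)
        pts %= box
    return TissueState(pts, labels, box)


def block_in_env_sea(rng):
    """3x3 block of cells surrounded by environment points."""
    cells = np.array([[x, y] for y in (9, 10, 11) for x in (9, 10, 11)], dtype=float)
    env = []
    while len(env) < 120:
        p = rng.random(2) * 20.0
        if not (7.5 < p[0] < 12.5 and 7.5 < p[1] < 12.5):
            env.append(p)
    pts = np.vstack([cells, env])
    labels = np.array([int(CellType.IHOG_RED)] * 9 + [int(CellType.ENV)] * 120)
    return TissueState(pts, labels, 20.0)


class TestCenterCells:
    def test_isolated_cell_is_not_center(self, rng):
        env = rng.random((60, 2)) * 10.0
        pts = np.vstack([[[5.0, 5.0]], env])
        labels = np.array([int(CellType.HH)] + [int(CellType.ENV)] * 60)
        assert pm.center_cells(TissueState(pts, labels, 10.0)) == []

    def test_block_center_is_the_middle_cell(self, rng):
        state = block_in_env_sea(rng)
        assert pm.center_cells(state) == [4]

    def test_periodic_monotypic_tissue_all_center(self):
        state = square_lattice_tissue(4, 4.0, lambda x, y: int(CellType.IHOG_RED),
                                      jitter_seed=0)
        assert pm.center_cells(state) == list(range(16))


class TestNeighborStats:
    def test_perfect_checkerboard_has_no_like_neighbors(self):
        state = square_lattice_tissue(
            4, 4.0,
            lambda x, y: int(CellType.IHOG_RED) if (x + y) % 2 == 0 else int(CellType.HH),
            jitter_seed=1,
        )
        stats = pm.neighbor_stats([state])
        assert stats.n_center == 16
        assert stats.mean_like == 0.0
        assert stats.mean_neighbors == pytest.approx(4.0, abs=0.3)

    def test_monotypic_like_equals_total(self):
        state = square_lattice_tissue(4, 4.0, lambda x, y: int(CellType.HH),
                                      jitter_seed=2)
        stats = pm.neighbor_stats([state])
        assert stats.mean_like == stats.mean_neighbors

    def test_like_bounded_by_total(self, rng):
        state = square_lattice_tissue(
            6, 6.0, lambda x, y: int(rng.integers(2)), jitter_seed=3
        )
        stats = pm.neighbor_stats([state])
        assert 0 <= stats.mean_like <= stats.mean_neighbors

    def test_no_center_cells_flagged_empty(self, rng):
        env = rng.random((40, 2)) * 10.0
        pts = np.vstack([[[5.0, 5.0]], env])
        labels = np.array([int(CellType.HH)] + [int(CellType.ENV)] * 40)
        stats = pm.neighbor_stats([TissueState(pts, labels, 10.0)])
        assert stats.empty

    def test_shuffle_null_restores_random_mixing(self):
        """Permuting the labels of a checkerboard destroys the like deficit."""
        state = square_lattice_tissue(
            6, 6.0,
            lambda x, y: int(CellType.IHOG_RED) if (x + y) % 2 == 0 else int(CellType.HH),
            jitter_seed=4,
        )
        assert pm.neighbor_stats([state]).mean_like == 0.0
        rng = np.random.default_rng(0)
        likes = []
        for _ in range(60):
            shuffled = state.copy()
            shuffled.labels = rng.permutation(shuffled.labels)
            likes.append(pm.neighbor_stats([shuffled]).mean_like)
        # 18/18 labels: a random neighbour is like with probability 17/35
        stats = pm.neighbor_stats([state])
        expected = stats.mean_neighbors * 17 / 35
        assert np.mean(likes) == pytest.approx(expected, rel=0.1)


class TestClassification:
    @pytest.mark.parametrize(
        "like,expected",
        [(2.4, "honeycomb"), (0.3, "checkerboard"), (1.2, "transitional")],
    )
    def test_thresholds(self, like, expected):
        stats = pm.NeighborStats(100, 5.0, 0.5, like, 0.5)
        assert pm.classify_pattern(stats) == expected

    def test_monotone_in_like(self):
        order = {"checkerboard": 0, "transitional": 1, "honeycomb": 2}
        classes = [
            order[pm.classify_pattern(pm.NeighborStats(10, 6.0, 0.1, l, 0.1))]
            for l in np.linspace(0.0, 3.0, 31)
        ]
        assert classes == sorted(classes)

    def test_empty_stats_transitional(self):
        assert pm.classify_pattern(pm.neighbor_stats([])) == "transitional"


def test_gamma_sweep_rejects_unsorted_ratios(rng):
    from adhesim.vertex_sim import VertexParams

    with pytest.raises(ValueError):
        pm.gamma_sweep([5.0, 5.0], VertexParams(), rng)
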