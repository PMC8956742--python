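"""Patch labelling and the five landscape-level pattern metrics."""

from collections import deque

import numpy as np
import pytest

from ecovuln.grids import Grid
from ecovuln.landscape import (compute_metrics, label_patches,
                               max_like_adjacencies, metrics_of_grid,
                               moving_window)


def _flood_fill_partition(vals, mask, connectivity):
    """Independent BFS labelling oracle."""
    if connectivity == 4:
        steps = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    nrows, ncols = vals.shape
    labels = np.zeros(vals.shape, dtype=int)
    nxt = 0
    for r0 in range(nrows):
        for c0 in range(ncols):
            if not mask[r0, c0] or labels[r0, c0]:
                continue
            nxt += 1
            q = deque([(r0, c0)])
            labels[r0, c0] = nxt
            while q:
                r, c = q.popleft()
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < nrows and 0 <= cc < ncols and mask[rr, cc]
                            and not labels[rr, cc]
                            and vals[rr, cc] == vals[r, c]):
                        labels[rr, cc] = nxt
                        q.append((rr, cc))
    return labels


class TestLabelPatches:
    def test_uniform_grid_is_one_patch(self):
        ps = label_patches(Grid(values=np.full((5, 5), 2.0)))
        assert ps.n_patches == 1
        code, area, cells = ps.patch_table[1]
        assert (code, cells) == (2, 25)

    def test_diagonal_pair_depends_on_connectivity(self):
        vals = np.array([[1.0, 0.0], [0.0, 1.0]])
        mask = vals == 1.0
        g = Grid(values=vals, mask=mask)
        assert label_patches(g, connectivity=8).n_patches == 1
        assert label_patches(g, connectivity=4).n_patches == 2

    def test_matches_flood_fill_oracle(self, rng):
        vals = rng.integers(1, 4, (12, 12)).astype(float)
        mask = rng.random((12, 12)) > 0.1
        g = Grid(values=vals, mask=mask)
        for conn in (4, 8):
            got = label_patches(g, conn).labels.values.astype(int)
            ref = _flood_fill_partition(vals, mask, conn)
            # same partition: label pairs must biject
            assert got[mask].min() >= 1
            pairs = set(zip(got[mask].tolist(), ref[mask].tolist()))
            assert len(pairs) == len({a for a, _ in pairs})
            assert len(pairs) == len({b for _, b in pairs})

    def test_connectivity8_never_more_patches_than_4(self, rng):
        for _ in range(5):
            g = Grid(values=rng.integers(1, 4, (9, 9)).astype(float))
            assert (label_patches(g, 8).n_patches
                    <= label_patches(g, 4).n_patches)

    def test_empty_grid_rejected(self):
        g = Grid(values=np.zeros((2, 2)), mask=np.zeros((2, 2), dtype=bool))
        with pytest.raises(ValueError):
            label_patches(g)


class TestMaxLikeAdjacencies:
    @pytest.mark.parametrize("m,expect", [
        (1, 0), (2, 1), (3, 2), (4, 4),       # 2x2 square
        (5, 5), (6, 7), (7, 8), (8, 10), (9, 12),
        (10, 13), (12, 17), (16, 24),  # 12 packs as a 3x4 block: 17 edges
    ])
    def test_small_counts_against_hand_enumeration(self, m, expect):
        assert max_like_adjacencies(m) == expect


class TestComputeMetrics:
    def test_single_class_full_grid_is_maximally_aggregated(self):
        rec = metrics_of_grid(Grid(values=np.full((6, 6), 1.0)))
        assert rec.np == 1
        assert rec.lpi == pytest.approx(100.0)
        assert rec.shdi == pytest.approx(0.0, abs=1e-12)
        assert rec.division == pytest.approx(0.0, abs=1e-12)
        assert rec.ai == pytest.approx(100.0)

    def test_two_equal_classes_shannon(self):
        vals = np.zeros((4, 4))
        vals[:, 2:] = 1.0
        rec = metrics_of_grid(Grid(values=vals))
        assert rec.shdi == pytest.approx(np.log(2), abs=1e-12)

    def test_checkerboard_of_distinct_singletons(self):
        # 2x2 grid, four distinct classes: n single-cell patches
        vals = np.array([[1.0, 2.0], [3.0, 4.0]])
        rec = metrics_of_grid(Grid(values=vals))
        assert rec.np == 4
        assert rec.division == pytest.approx(1 - 1 / 4)
        assert rec.ai == pytest.approx(0.0)
        assert rec.lpi == pytest.approx(25.0)

    def test_metrics_invariant_under_class_relabeling(self, rng):
        vals = rng.integers(1, 4, (10, 10)).astype(float)
        a = metrics_of_grid(Grid(values=vals))
        b = metrics_of_grid(Grid(values=vals * 7 + 3))
        assert a.np == b.np
        assert a.ai == pytest.approx(b.ai)
        assert a.shdi == pytest.approx(b.shdi)
        assert a.division == pytest.approx(b.division)

    def test_division_bounded_by_patch_count(self, rng):
        g = Grid(values=rng.integers(1, 4, (8, 8)).astype(float))
        ps = label_patches(g)
        rec = compute_metrics(ps)
        assert 0.0 <= rec.division <= 1 - 1 / ps.n_patches + 1e-12

    def test_np_at_least_number_of_classes(self, rng):
        g = Grid(values=rng.integers(1, 5, (8, 8)).astype(float))
        rec = metrics_of_grid(g)
        n_classes = len(np.unique(g.values))
        assert rec.np >= n_classes
        assert rec.shdi <= np.log(n_classes) + 1e-12


class TestMovingWindow:
    def test_full_extent_window_equals_global_metrics(self, rng):
        vals = rng.integers(1, 4, (7, 7)).astype(float)
        g = Grid(values=vals)
        surfaces = moving_window(g, window=7)
        rec = metrics_of_grid(g)
        center = (3, 3)
        for name, expect in rec.as_dict().items():
            assert surfaces[name].values[center] == pytest.approx(expect)
            assert surfaces[name].mask[center]

    def test_uniform_grid_gives_constant_surfaces(self):
        g = Grid(values=np.full((9, 9), 2.0))
        surfaces = moving_window(g, window=3)
        inner = surfaces["ai"].mask
        assert inner.sum() == 49  # 7x7 evaluated centres
        np.testing.assert_allclose(surfaces["ai"].values[inner], 100.0)
        np.testing.assert_allclose(surfaces["np"].values[inner], 1.0)

    def test_any_center_matches_cropped_subgrid_oracle(self, rng):
        vals = rng.integers(1, 4, (11, 11)).astype(float)
        g = Grid(values=vals)
        w = 5
        surfaces = moving_window(g, window=w)
        for r, c in [(2, 2), (5, 7), (8, 3)]:
            sub = Grid(values=vals[r - 2:r + 3, c - 2:c + 3])
            rec = metrics_of_grid(sub)
            for name, expect in rec.as_dict().items():
                assert surfaces[name].values[r, c] == pytest.approx(expect)

    def test_edges_are_masked_not_padded(self, rng):
        g = Grid(values=rng.integers(1, 3, (9, 9)).astype(float))
        surfaces = moving_window(g, window=5)
        assert not surfaces["np"].mask[0, :].any()
        assert not surfaces["np"].mask[:, 0].any()

    def test_even_window_rejected(self, rng):
        g = Grid(values=rng.integers(1, 3, (8, 8)).astype(float))
        with pytest.raises(ValueError, match="odd"):
            moving_window(g, window=4)

    def test_stride_skips_cells(self, rng):
        g = Grid(values=rng.integers(1, 3, (11, 11)).astype(float))
        surfaces = moving_window(g, window=3, stride=3)
        rows, cols = np.nonzero(surfaces["np"].mask)
        assert np.all(np.diff(sorted(set(rows.tolist()))) == 3)
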