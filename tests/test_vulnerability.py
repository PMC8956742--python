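"""EVI construction, cross-year standardization, grading, and CEVI."""

import numpy as np
import pytest

from ecovuln.grids import Grid, ZoneMap
from ecovuln.spca import fit_spca
from ecovuln.vulnerability import (GradingScheme, cevi_table, classify,
                                   compute_cevi, compute_evi, mean_cevi,
                                   standardize_svi)


def _pca_result(rng, shape=(8, 8), p=4):
    from ecovuln.grids import IndicatorStack

    s = IndicatorStack(epoch="t")
    for j in range(p):
        s.add(f"v{j}", Grid(values=rng.normal(size=shape)))
    return fit_spca(s)


class TestComputeEvi:
    def test_rank_one_single_component_equals_first_score(self, rng):
        from ecovuln.grids import IndicatorStack

        base = rng.normal(size=(6, 6))
        s = IndicatorStack(epoch="t")
        s.add("a", Grid(values=base))
        s.add("b", Grid(values=2.0 * base))
        res = fit_spca(s)
        evi = compute_evi(res, 1)
        # r1 = 1, so EVI is exactly the first score surface
        np.testing.assert_allclose(evi.values, res.scores[0].values, atol=1e-12)

    def test_matches_cellwise_weighted_sum_oracle(self, rng):
        res = _pca_result(rng)
        evi = compute_evi(res, 3)
        for r in range(8):
            for c in range(8):
                expect = sum(res.contribution_rates[i] * res.scores[i].values[r, c]
                             for i in range(3))
                assert evi.values[r, c] == pytest.approx(expect, abs=1e-12)

    def test_k_out_of_range_rejected(self, rng):
        res = _pca_result(rng)
        with pytest.raises(ValueError):
            compute_evi(res, 0)
        with pytest.raises(ValueError):
            compute_evi(res, 5)


class TestStandardizeSvi:
    def test_pooled_extremes_map_to_scale_ends(self, rng):
        a = Grid(values=rng.normal(0, 1, (5, 5)))
        b = Grid(values=rng.normal(3, 1, (5, 5)))
        svi = standardize_svi({"y1": a, "y2": b})
        pooled = np.concatenate([svi["y1"].values.ravel(), svi["y2"].values.ravel()])
        assert pooled.min() == pytest.approx(0.0, abs=1e-12)
        assert pooled.max() == pytest.approx(10.0, abs=1e-12)

    def test_single_epoch_linear_ramp_rescales_affinely(self):
        ramp = np.linspace(-3, 7, 20).reshape(4, 5)
        svi = standardize_svi({"y": Grid(values=ramp)})["y"]
        np.testing.assert_allclose(svi.values,
                                   np.linspace(0, 10, 20).reshape(4, 5),
                                   atol=1e-12)

    def test_cross_epoch_ordering_preserved(self, rng):
        a = Grid(values=rng.uniform(0, 1, (6, 6)))
        b = Grid(values=rng.uniform(5, 9, (6, 6)))  # disjoint ranges
        svi = standardize_svi({"a": a, "b": b})
        assert svi["a"].values.max() < svi["b"].values.min()

    def test_degenerate_pooled_range_rejected(self):
        g = Grid(values=np.full((3, 3), 1.0))
        with pytest.raises(ValueError, match="[Dd]egenerate"):
            standardize_svi({"y": g})


class TestClassify:
    @pytest.mark.parametrize("value,grade", [
        (1.0, 1),   # micro: below 2
        (8.0, 5),   # extreme: boundary value belongs to the top class
        (4.0, 3),   # moderate: lower-closed interior boundary
        (1.9999, 1),
        (2.0, 2),
        (10.0, 5),
    ])
    def test_grade_boundaries(self, value, grade):
        g = Grid(values=np.full((2, 2), value))
        assert np.all(classify(g).classes.values == grade)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify(Grid(values=np.array([[11.0]])))

    def test_proportions_partition_unity(self, rng):
        g = Grid(values=rng.uniform(0, 10, (12, 12)))
        vg = classify(g)
        assert sum(vg.proportions.values()) == pytest.approx(1.0, abs=1e-12)
        assert sum(vg.area_by_class.values()) == pytest.approx(
            g.n_valid * g.cell_area())

    def test_affine_invariance_of_grades_through_svi(self, rng):
        evi = {"y1": Grid(values=rng.normal(size=(7, 7))),
               "y2": Grid(values=rng.normal(size=(7, 7)))}
        scaled = {k: Grid(values=4.2 * v.values - 13.0) for k, v in evi.items()}
        base = {k: classify(v).classes.values
                for k, v in standardize_svi(evi).items()}
        tran = {k: classify(v).classes.values
                for k, v in standardize_svi(scaled).items()}
        for k in base:
            np.testing.assert_array_equal(base[k], tran[k])


class TestCevi:
    def test_uniform_grade_three(self):
        g = Grid(values=np.full((4, 4), 5.0))  # all moderate
        vg = classify(g)
        assert vg.cevi == pytest.approx(3.0)

    def test_half_micro_half_extreme_averages_to_three(self):
        vals = np.concatenate([np.full(8, 1.0), np.full(8, 9.0)]).reshape(4, 4)
        vg = classify(Grid(values=vals))
        assert vg.cevi == pytest.approx(3.0)

    def test_equals_mean_grade_code_on_uniform_cells(self, rng):
        g = Grid(values=rng.uniform(0, 10, (9, 9)))
        vg = classify(g)
        assert vg.cevi == pytest.approx(vg.classes.valid_values().mean())

    def test_cevi_bounds(self, rng):
        vg = classify(Grid(values=rng.uniform(0, 10, (10, 10))))
        assert 1.0 <= vg.cevi <= 5.0

    def test_monotone_raising_a_cell_grade(self, rng):
        vals = rng.uniform(0, 8, (5, 5))
        lo = classify(Grid(values=vals))
        vals2 = vals.copy()
        vals2[0, 0] = 9.9  # push one cell to extreme
        hi = classify(Grid(values=vals2))
        assert hi.cevi >= lo.cevi

    def test_per_zone_values_and_empty_zone_warning(self, rng):
        svi = Grid(values=rng.uniform(0, 10, (4, 4)))
        vg = classify(svi)
        zones_vals = np.ones((4, 4))
        zones_vals[:, 2:] = 2.0
        zmask = np.ones((4, 4), dtype=bool)
        zm = ZoneMap(zones=Grid(values=zones_vals, mask=zmask),
                     names={1: "west", 2: "east"})
        out = compute_cevi(vg, zm)
        assert set(out) == {"west", "east"}
        west = vg.classes.values[:, :2].mean()
        assert out["west"] == pytest.approx(west)


class TestMeanCevi:
    def test_published_highest_town_mean(self):
        assert round(mean_cevi([4.41, 4.17, 3.83]), 2) == 4.14

    def test_published_regional_mean(self):
        assert round(mean_cevi([2.77, 2.71, 2.51]), 2) == 2.66

    def test_identical_values(self):
        assert mean_cevi([2.5, 2.5, 2.5]) == pytest.approx(2.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_cevi([])


def test_cevi_table_layout_and_rounding():
    per_zone = {"1996": {"A": 3.125, "B": 2.0},
                "2007": {"A": 3.0, "B": 2.5}}
    overall = {"1996": 2.5625, "2007": 2.75}
    df = cevi_table(per_zone, overall)
    assert list(df.columns) == ["A", "B", "Total"]
    assert list(df.index) == ["1996", "2007", "Mean"]
    assert df.loc["1996", "A"] == 3.13  # half-up at 2 decimals
    assert df.loc["Mean", "Total"] == pytest.approx(2.66)
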