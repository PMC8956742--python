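"""Spatial PCA: eigendecomposition bookkeeping, rates, and selection."""

import numpy as np
import pytest

from ecovuln.grids import Grid, IndicatorStack
from ecovuln.spca import (contribution_rates, eigen_table, fit_spca,
                          loadings_frame, select_components)


def _stack_from_matrix(data, shape):
    """Columns of ``data`` become layers on an unmasked grid."""
    s = IndicatorStack(epoch="t")
    for j in range(data.shape[1]):
        s.add(f"v{j}", Grid(values=data[:, j].reshape(shape)))
    return s


def _char_poly_eigen_oracle(cov):
    """3x3 symmetric eigenpairs via the characteristic polynomial roots,
    independent of any eigensolver: det(cov - x I) expanded explicitly,
    roots by companion matrix, vectors by SVD null space."""
    a, b, c = cov[0, 0], cov[0, 1], cov[0, 2]
    d, e, f = cov[1, 1], cov[1, 2], cov[2, 2]
    # det([[a-x, b, c], [b, d-x, e], [c, e, f-x]]) = -x^3 + t x^2 - s x + det
    t = a + d + f
    s = a * d + a * f + d * f - b * b - c * c - e * e
    det = a * (d * f - e * e) - b * (b * f - c * e) + c * (b * e - c * d)
    roots = np.roots([-1.0, t, -s, det])
    roots = np.sort(roots.real)[::-1]
    vecs = []
    for lam in roots:
        m = cov - lam * np.eye(3)
        _, _, vh = np.linalg.svd(m)
        vecs.append(vh[-1])
    return roots, np.column_stack(vecs)


class TestFitSpca:
    def test_two_proportional_layers_are_rank_one(self, rng):
        base = rng.normal(size=(6, 6))
        s = IndicatorStack(epoch="t")
        s.add("a", Grid(values=base))
        s.add("b", Grid(values=3.0 * base))
        res = fit_spca(s)
        assert res.contribution_rates[0] == pytest.approx(1.0, abs=1e-12)
        assert res.contribution_rates[1] == pytest.approx(0.0, abs=1e-12)

    def test_distinct_component_scores_have_zero_covariance(self, rng):
        data = rng.normal(size=(64, 4))
        res = fit_spca(_stack_from_matrix(data, (8, 8)))
        flat = np.column_stack([g.values.ravel() for g in res.scores])
        cov = np.cov(flat, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        np.testing.assert_allclose(off, 0.0, atol=1e-10)

    def test_matches_characteristic_polynomial_oracle(self, rng):
        data = rng.normal(size=(100, 3)) @ rng.normal(size=(3, 3))
        res = fit_spca(_stack_from_matrix(data, (10, 10)))
        cov = np.cov(data, rowvar=False, ddof=1)
        lam, vecs = _char_poly_eigen_oracle(cov)
        np.testing.assert_allclose(res.eigenvalues, lam, atol=1e-8)
        for j in range(3):
            v_ref = vecs[:, j] / np.linalg.norm(vecs[:, j])
            v_got = res.loadings[:, j]
            assert abs(abs(v_ref @ v_got) - 1.0) < 1e-8

    def test_trace_conservation(self, rng):
        data = rng.normal(size=(144, 5)) * rng.uniform(0.5, 4.0, 5)
        res = fit_spca(_stack_from_matrix(data, (12, 12)))
        total_var = data.var(axis=0, ddof=1).sum()
        assert res.eigenvalues.sum() == pytest.approx(total_var, abs=1e-8)

    def test_layer_order_invariance(self, rng):
        data = rng.normal(size=(49, 4))
        res_a = fit_spca(_stack_from_matrix(data, (7, 7)))
        res_b = fit_spca(_stack_from_matrix(data[:, ::-1], (7, 7)))
        np.testing.assert_allclose(res_a.eigenvalues, res_b.eigenvalues,
                                   atol=1e-10)
        # loadings match after undoing the column permutation (up to sign)
        for j in range(4):
            a = res_a.loadings[:, j]
            b = res_b.loadings[::-1, j]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-8

    def test_full_reconstruction_recovers_input(self, rng):
        data = rng.normal(size=(81, 4))
        res = fit_spca(_stack_from_matrix(data, (9, 9)))
        scores = np.column_stack([g.values.ravel() for g in res.scores])
        recon = scores @ res.loadings.T + res.means
        np.testing.assert_allclose(recon, data, atol=1e-6)

    def test_constant_layer_warns(self, rng):
        s = IndicatorStack(epoch="t")
        s.add("a", Grid(values=rng.normal(size=(5, 5))))
        s.add("flat", Grid(values=np.full((5, 5), 2.0)))
        with pytest.warns(UserWarning, match="flat"):
            res = fit_spca(s)
        assert res.eigenvalues[-1] == pytest.approx(0.0, abs=1e-12)

    def test_fewer_cells_than_indicators_rejected(self, rng):
        data = rng.normal(size=(2, 3))
        s = IndicatorStack(epoch="t")
        for j in range(3):
            s.add(f"v{j}", Grid(values=data[:, j].reshape(1, 2)))
        with pytest.raises(ValueError, match="valid common cells"):
            fit_spca(s)

    def test_scores_masked_like_common_mask(self, rng):
        mask = rng.random((8, 8)) > 0.2
        s = IndicatorStack(epoch="t")
        for j in range(3):
            s.add(f"v{j}", Grid(values=rng.normal(size=(8, 8)), mask=mask))
        res = fit_spca(s)
        for g in res.scores:
            np.testing.assert_array_equal(g.mask, mask)


class TestContributionRates:
    def test_simple_shares(self):
        np.testing.assert_allclose(contribution_rates([2.0, 1.0, 1.0]),
                                   [0.5, 0.25, 0.25])

    def test_singleton(self):
        np.testing.assert_allclose(contribution_rates([3.7]), [1.0])

    def test_published_eigenvalue_rate_consistency(self):
        # printed first-epoch eigenvalues 1.681, 0.567 against printed
        # rates 47.17%, 15.90%: the ratios must agree to rounding precision
        lam_ratio = 1.681 / 0.567
        rate_ratio = 47.17 / 15.90
        assert lam_ratio == pytest.approx(rate_ratio, abs=0.01)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            contribution_rates([0.0, 0.0])

    def test_rates_sum_to_one(self, rng):
        lam = rng.uniform(0, 5, 9)
        assert contribution_rates(lam).sum() == pytest.approx(1.0)


class TestSelectComponents:
    def test_published_six_component_selection(self):
        rates = [47.17, 15.90, 12.04, 6.36, 5.80, 3.13]
        cumulative = np.cumsum(rates)
        assert cumulative[4] == pytest.approx(87.27, abs=0.01)
        assert cumulative[5] == pytest.approx(90.40, abs=0.01)
        assert select_components(cumulative) == 6

    def test_first_component_sufficient(self):
        assert select_components(np.cumsum([95.0, 5.0]), 90.0) == 1

    def test_sixteen_equal_rates_need_fifteen(self):
        cumulative = np.cumsum([6.25] * 16)
        assert select_components(cumulative, 90.0) == 15

    def test_threshold_never_reached_keeps_all_with_warning(self):
        with pytest.warns(UserWarning):
            assert select_components([10.0, 20.0, 80.0], 90.0) == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_components([])


def test_tables_have_component_columns_and_indicator_rows(rng):
    data = rng.normal(size=(36, 3))
    res = fit_spca(_stack_from_matrix(data, (6, 6)))
    et = eigen_table(res)
    assert list(et.columns) == ["PC1", "PC2", "PC3"]
    assert et.loc["cumulative_rate_pct"].iloc[-1] == pytest.approx(100.0)
    lf = loadings_frame(res, 2)
    assert list(lf.columns) == ["PC1", "PC2"]
    assert list(lf.index) == ["v0", "v1", "v2"]
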