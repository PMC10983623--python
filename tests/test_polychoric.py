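"""Polychoric estimation: thresholds, pairwise ML, matrix assembly."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import symptomnet as sn
from symptomnet._bvn import bvn_cdf
from symptomnet.polychoric import (
    DegenerateItemError,
    estimate_thresholds,
    polychoric_matrix,
    polychoric_rho,
    smooth_correlation_matrix,
)


class TestBvnCdf:
    @pytest.mark.parametrize("rho", [-0.99, -0.93, -0.5, 0.0, 0.5, 0.9, 0.93, 0.99])
    def test_matches_scipy_integration(self, rho):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-4, 4, size=(40, 2))
        ours = bvn_cdf(pts[:, 0], pts[:, 1], rho)
        ref = multivariate_normal.cdf(
            pts, mean=[0, 0], cov=[[1, rho], [rho, 1]], abseps=1e-10, releps=1e-10
        )
        assert np.max(np.abs(ours - ref)) < 1e-7

    def test_infinite_bounds_reduce_to_marginals(self):
        from scipy.special import ndtr

        assert bvn_cdf(np.inf, 0.7, 0.5)[0] == pytest.approx(ndtr(0.7), abs=1e-12)
        assert bvn_cdf(-np.inf, 0.7, 0.5)[0] == 0.0
        assert bvn_cdf(np.inf, np.inf, -0.3)[0] == 1.0


class TestThresholds:
    def test_median_split(self):
        ts = estimate_thresholds([50, 50])
        assert ts.thresholds == pytest.approx((0.0,), abs=1e-12)

    def test_quartile_cuts(self):
        ts = estimate_thresholds([25, 25, 25, 25])
        assert np.round(ts.thresholds, 4).tolist() == [-0.6745, 0.0, 0.6745]

    def test_recovers_generating_cuts_from_large_sample(self):
        rng = np.random.default_rng(7)
        z = rng.standard_normal(100_000)
        codes = np.searchsorted([-1.0, 1.0], z)
        counts = np.bincount(codes, minlength=3)
        ts = estimate_thresholds(counts)
        assert np.allclose(ts.thresholds, [-1.0, 1.0], atol=0.02)

    def test_empty_categories_collapse(self):
        with_gap = estimate_thresholds([30, 0, 70])
        without = estimate_thresholds([30, 70])
        assert with_gap.thresholds == without.thresholds

    def test_single_category_is_degenerate(self):
        with pytest.raises(DegenerateItemError):
            estimate_thresholds([100])


def _discretize_pair(rho, cuts_x, cuts_y, n, seed):
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    x = np.searchsorted(cuts_x, z[:, 0])
    y = np.searchsorted(cuts_y, z[:, 1])
    table = np.zeros((len(cuts_x) + 1, len(cuts_y) + 1))
    np.add.at(table, (x, y), 1.0)
    return table


class TestPolychoricRho:
    def test_independence_table_gives_zero(self):
        margins_r = np.array([20, 30, 50], dtype=float)
        margins_c = np.array([40, 25, 35], dtype=float)
        table = np.outer(margins_r, margins_c)
        tr = estimate_thresholds(margins_r * 100)
        tc = estimate_thresholds(margins_c * 100)
        est = polychoric_rho(table, tr, tc)
        assert est.converged
        assert abs(est.rho) < 1e-3

    def test_recovers_generating_correlation(self):
        cuts_x, cuts_y = [-0.8, 0.0, 0.9], [-0.5, 0.6]
        table = _discretize_pair(0.5, cuts_x, cuts_y, n=100_000, seed=5)
        tr = estimate_thresholds(table.sum(axis=1))
        tc = estimate_thresholds(table.sum(axis=0))
        est = polychoric_rho(table, tr, tc)
        assert est.converged
        assert est.rho == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("seed,rho", [(1, 0.3), (2, -0.6), (3, 0.0)])
    def test_agrees_with_dense_grid_search(self, seed, rho):
        """ML optimum within 1e-4 of brute-force over rho in {-0.999..0.999} step 1e-4."""
        table = _discretize_pair(rho, [-0.5, 0.5], [-0.3, 0.8], n=400, seed=seed)
        tr = estimate_thresholds(table.sum(axis=1))
        tc = estimate_thresholds(table.sum(axis=0))
        est = polychoric_rho(table, tr, tc)

        from symptomnet.polychoric import _cell_probabilities

        grid = np.arange(-0.999, 0.9991, 1e-4)
        nll = np.empty(grid.size)
        for i, r in enumerate(grid):
            p = _cell_probabilities(np.asarray(tr.thresholds), np.asarray(tc.thresholds), r)
            nll[i] = -np.sum(table * np.log(np.maximum(p, 1e-12)))
        assert est.rho == pytest.approx(grid[np.argmin(nll)], abs=1e-4)

    def test_shape_mismatch_rejected(self):
        tr = estimate_thresholds([50, 50])
        with pytest.raises(ValueError):
            polychoric_rho(np.ones((3, 3)), tr, tr)


class TestPolychoricMatrix:
    def test_independent_items_give_near_zero_matrix(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(
            {f"V{j}": np.searchsorted([-0.7, 0.7], rng.standard_normal(5000)) for j in range(6)}
        )
        pm = polychoric_matrix(df)
        off = pm.rho[np.triu_indices(6, 1)]
        assert np.max(np.abs(off)) < 0.05

    def test_symmetric_and_respondent_order_invariant(self):
        df = pd.DataFrame(
            {
                "A": [0, 1, 2, 0, 1, 2, 2, 1, 0, 2],
                "B": [0, 0, 1, 1, 2, 2, 1, 0, 1, 2],
                "C": [1, 0, 1, 0, 1, 0, 1, 1, 0, 1],
            }
        )
        pm1 = polychoric_matrix(df)
        pm2 = polychoric_matrix(df.iloc[::-1])
        assert np.allclose(pm1.rho, pm1.rho.T)
        assert np.allclose(pm1.rho, pm2.rho, atol=1e-12)

    def test_duplicate_items_clip_and_smooth(self):
        rng = np.random.default_rng(1)
        x = np.searchsorted([-0.5, 0.5], rng.standard_normal(400))
        df = pd.DataFrame({"A": x, "B": x, "C": np.searchsorted([0.0], rng.standard_normal(400))})
        pm = polychoric_matrix(df)
        # the ML domain is bounded at 0.999, so a perfect duplicate clips there
        assert 1 - 1e-2 <= pm.rho[0, 1] <= 1 - 1e-4
        assert np.linalg.eigvalsh(pm.rho).min() >= 1e-8  # still usable by glasso

    def test_degenerate_item_raise_or_drop(self):
        df = pd.DataFrame({"A": [1, 1, 1, 1], "B": [0, 1, 0, 1], "C": [0, 0, 1, 1]})
        with pytest.raises(DegenerateItemError):
            polychoric_matrix(df)
        pm = polychoric_matrix(df, on_degenerate="drop")
        assert pm.item_ids == ("B", "C")

    def test_estimates_sharpen_with_sample_size(self):
        errs = []
        for n in (500, 5000, 50000):
            table = _discretize_pair(0.45, [-0.6, 0.4], [-0.2, 1.0], n=n, seed=13)
            tr = estimate_thresholds(table.sum(axis=1))
            tc = estimate_thresholds(table.sum(axis=0))
            errs.append(abs(polychoric_rho(table, tr, tc).rho - 0.45))
        assert errs[2] < errs[0]
        assert errs[2] < 0.02

    def test_smoothing_preserves_diagonal_and_reports_shift(self):
        R = np.array([[1.0, 0.9, 0.9], [0.9, 1.0, -0.9], [0.9, -0.9, 1.0]])
        S, shift = smooth_correlation_matrix(R)
        assert np.allclose(np.diag(S), 1.0)
        assert np.linalg.eigvalsh(S).min() >= 1e-6 - 1e-12
        assert shift > 0
        assert np.max(np.abs(S - R)) <= shift + 1e-15

    def test_serialization_round_trip(self, tmp_path):
        df = pd.DataFrame({"A": [0, 1, 2, 0, 1], "B": [1, 0, 2, 2, 1]})
        pm = polychoric_matrix(df)
        path = tmp_path / "pm.csv"
        pm.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        assert np.allclose(back.to_numpy(), pm.rho, atol=1e-6)
        payload = pm.to_json()
        assert '"smoothed"' in payload
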