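"""Bootstrap edge CIs, difference tests, case-dropping stability, CS coefficients."""

import numpy as np
import pandas as pd
import pytest

import symptomnet as sn
from symptomnet.stability import (
    CaseDropCurve,
    case_drop_bootstrap,
    cs_coefficient,
    difference_test,
    edge_ci_bootstrap,
)

from conftest import simulate_four_node

FAST = dict(n_lambda=30)  # shorter penalty path; the machinery under test is the bootstrap


@pytest.fixture(scope="module")
def strong_edge_boot():
    df = simulate_four_node(n=1000, seed=42)
    return df, edge_ci_bootstrap(df, B=200, seed=7, **FAST)


class TestEdgeCiBootstrap:
    def test_strong_edge_ci_excludes_zero(self, strong_edge_boot):
        """Generating MBI1-MBI2 weight is 0.4; its 95% CI must not cover 0."""
        _, boot = strong_edge_boot
        tab = boot.to_dataframe().set_index(["node_a", "node_b"])
        lo, hi = tab.loc[("MBI1", "MBI2"), ["ci_lower", "ci_upper"]]
        assert lo > 0

    def test_point_estimates_inside_their_cis(self, strong_edge_boot):
        _, boot = strong_edge_boot
        inside = (boot.ci_lower <= boot.point + 1e-12) & (boot.point - 1e-12 <= boot.ci_upper)
        assert inside.mean() >= 0.95

    def test_identical_seed_is_bit_identical(self):
        df = simulate_four_node(n=400, seed=3)
        a = edge_ci_bootstrap(df, B=100, seed=11, **FAST)
        b = edge_ci_bootstrap(df, B=100, seed=11, **FAST)
        assert np.array_equal(a.replicates, b.replicates)
        assert np.array_equal(a.ci_lower, b.ci_lower)

    def test_null_network_cis_cover_zero(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "MBI1": rng.integers(0, 7, 1000),
                "MBI2": rng.integers(0, 7, 1000),
                "PHQ1": rng.integers(0, 4, 1000),
                "PHQ2": rng.integers(0, 4, 1000),
            }
        )
        boot = edge_ci_bootstrap(df, B=100, seed=5, **FAST)
        covers = (boot.ci_lower <= 0) & (0 <= boot.ci_upper)
        assert covers.all()

    def test_ci_width_shrinks_with_sample_size(self):
        widths = []
        for n in (500, 2000):
            df = simulate_four_node(n=n, seed=8)
            boot = edge_ci_bootstrap(df, B=100, seed=1, **FAST)
            widths.append(np.median(boot.ci_upper - boot.ci_lower))
        assert widths[1] < widths[0]

    def test_small_b_rejected(self):
        with pytest.raises(ValueError):
            edge_ci_bootstrap(pd.DataFrame({"MBI1": [0, 1], "MBI2": [1, 0]}), B=10)


class TestDifferenceTest:
    def test_object_not_different_from_itself(self, strong_edge_boot):
        _, boot = strong_edge_boot
        dt = difference_test(boot.replicates, [f"{a}-{b}" for a, b in boot.edge_labels])
        assert not dt.flags.diagonal().any()
        assert np.array_equal(dt.flags, dt.flags.T)

    def test_strong_vs_absent_edge_flagged(self, strong_edge_boot):
        """True weights 0.4 (MBI1-MBI2) vs 0.0 (MBI1-PHQ2) must test different."""
        _, boot = strong_edge_boot
        labels = [f"{a}-{b}" for a, b in boot.edge_labels]
        dt = difference_test(boot.replicates, labels)
        i, j = labels.index("MBI1-MBI2"), labels.index("MBI1-PHQ2")
        assert dt.flags[i, j]

    def test_column_order_does_not_change_flags(self, strong_edge_boot):
        _, boot = strong_edge_boot
        R = boot.replicates[:, :3]
        labels = ["a", "b", "c"]
        dt1 = difference_test(R, labels)
        dt2 = difference_test(R[:, ::-1], labels[::-1])
        assert np.array_equal(dt1.flags, dt2.flags[::-1, ::-1])


class TestCaseDrop:
    def test_mean_correlation_trends_downward(self):
        df = simulate_four_node(n=1200, seed=6)
        curve = case_drop_bootstrap(df, statistic="EI", grid=(0.1, 0.4, 0.7), replicates=50, seed=2, **FAST)
        means = curve.mean_correlations()
        assert means.iloc[-1] <= means.iloc[0] + 0.05  # noise allowance on a decreasing trend

    def test_seed_reproducibility(self):
        df = simulate_four_node(n=500, seed=10)
        c1 = case_drop_bootstrap(df, grid=(0.2,), replicates=50, seed=3, **FAST)
        c2 = case_drop_bootstrap(df, grid=(0.2,), replicates=50, seed=3, **FAST)
        assert np.array_equal(c1.correlations[0.2], c2.correlations[0.2], equal_nan=True)

    def test_constant_statistic_is_flagged_degenerate(self):
        df = simulate_four_node(n=500, seed=4)
        const = lambda net: np.ones(net.n_nodes)  # noqa: E731
        curve = case_drop_bootstrap(df, statistic=const, grid=(0.2,), replicates=50, seed=1, **FAST)
        assert curve.degenerate
        assert np.isnan(curve.correlations[0.2]).all()

    def test_too_small_subsample_skipped(self):
        df = simulate_four_node(n=60, seed=5)
        with pytest.warns(RuntimeWarning, match="skipped"):
            curve = case_drop_bootstrap(df, grid=(0.1, 0.8), replicates=50, seed=1, **FAST)
        assert 0.8 in curve.skipped
        assert 0.8 not in curve.proportions

    def test_joint_statistics_share_refits(self):
        df = simulate_four_node(n=500, seed=12)
        curves = case_drop_bootstrap(df, statistic=("EI", "BEI"), grid=(0.2,), replicates=50, seed=9, **FAST)
        assert set(curves) == {"EI", "BEI"}
        solo = case_drop_bootstrap(df, statistic="EI", grid=(0.2,), replicates=50, seed=9, **FAST)
        assert np.array_equal(
            curves["EI"].correlations[0.2], solo.correlations[0.2], equal_nan=True
        )


def _curve(props, cors_by_prop, reps=100):
    return CaseDropCurve(
        statistic="EI",
        proportions=tuple(props),
        correlations={p: np.asarray(c, dtype=float) for p, c in cors_by_prop.items()},
        replicates=reps,
        seed=0,
    )


class TestCsCoefficient:
    def test_perfectly_stable_statistic_hits_grid_max(self):
        props = (0.1, 0.3, 0.5, 0.75)
        curve = _curve(props, {p: np.ones(100) for p in props})
        assert cs_coefficient(curve).value == 0.75

    def test_never_stable_statistic_is_zero(self):
        props = (0.1, 0.3)
        curve = _curve(props, {p: np.full(100, 0.5) for p in props})
        assert cs_coefficient(curve).value == 0.0

    def test_monotone_in_threshold_r(self):
        rng = np.random.default_rng(0)
        props = (0.1, 0.3, 0.5)
        curve = _curve(props, {p: rng.uniform(0.5, 1.0, 100) for p in props})
        values = [cs_coefficient(curve, r=r).value for r in (0.5, 0.7, 0.9)]
        assert values == sorted(values, reverse=True)

    def test_nan_replicates_count_as_failures(self):
        props = (0.1,)
        cors = np.ones(100)
        cors[:10] = np.nan  # 90% success < 95% confidence
        curve = _curve(props, {0.1: cors})
        assert cs_coefficient(curve).value == 0.0

    def test_acceptability_bands(self):
        props = (0.1, 0.3, 0.6)
        curve = _curve(props, {p: np.ones(100) for p in props})
        cs = cs_coefficient(curve)
        assert cs.acceptable() and cs.ideal()
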