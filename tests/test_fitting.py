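import numpy as np
import pytest

from ndatrophy import (
    AtrophyVector,
    GraphError,
    RCurve,
    SeedVector,
    classify_curve,
    eigenmode_correlations,
    fit_model1,
    fit_model2,
    log_estimate_correlation,
    model1_atrophy,
    model2_atrophy,
    pearson_r,
    select_tcrit,
    sweep_model2,
)
from ndatrophy.models import AtrophyEstimate


def curve(xs, Rs):
    return RCurve(axis="diffusion_depth", xs=np.asarray(xs, float), Rs=np.asarray(Rs, float))


class TestPearson:
    def test_perfect(self):
        a = np.array([1.0, 2.0, 5.0])
        R, p = pearson_r(a, a)
        assert R == pytest.approx(1.0, abs=1e-12)

    def test_anti(self):
        a = np.array([1.0, 2.0, 5.0])
        R, _ = pearson_r(a, -a)
        assert R == pytest.approx(-1.0, abs=1e-12)

    def test_hand_value(self):
        # cov = 3, var_a = 2, sum of squared b deviations = 14/3
        # => R = 3 / sqrt(2 * 14/3) = sqrt(27/28)
        R, _ = pearson_r(np.array([1.0, 2, 3]), np.array([1.0, 2, 4]))
        assert R == pytest.approx(np.sqrt(27 / 28), abs=1e-12)

    def test_constant_rejected(self):
        with pytest.raises(GraphError):
            pearson_r(np.ones(4), np.arange(4.0))

    def test_affine_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=20), rng.normal(size=20)
        R0, p0 = pearson_r(a, b)
        R1, p1 = pearson_r(3.0 * a + 7.0, b)
        assert R1 == pytest.approx(R0, abs=1e-12)
        assert p1 == pytest.approx(p0, rel=1e-9)


class TestFitModel1:
    def test_self_consistency_interior_k(self, eig10):
        seed = SeedVector(np.random.default_rng(0).uniform(0.1, 1, 10))
        k_true = 5
        target = model1_atrophy(eig10, seed, K=k_true).values
        fit = fit_model1(eig10, seed, AtrophyVector(target, (5, 5)))
        assert fit.param["K"] == k_true
        assert fit.R == pytest.approx(1.0, abs=1e-10)

    def test_tie_goes_to_smaller_k(self):
        # hand-built eigensystem with integer modes: the seed is exactly
        # orthogonal to every mode above u2, so all K tie at R = 1 and the
        # sweep must return the smallest K
        from ndatrophy import LaplacianEigensystem

        lambdas = np.array([0.0, 1.0, 1.0, 2.0])
        U = np.eye(4)
        eig = LaplacianEigensystem(L=U @ np.diag(lambdas) @ U.T, lambdas=lambdas, U=U)
        seed = SeedVector(np.array([0.0, 1.0, 0.0, 0.0]))
        measured = AtrophyVector(np.array([0.0, 1.0, 0.0, 0.0]), (5, 5))
        fit = fit_model1(eig, seed, measured)
        assert fit.param["K"] == 2
        assert fit.R == pytest.approx(1.0, abs=1e-12)

    def test_curve_covers_all_k(self, eig10):
        seed = SeedVector.unit(10, 0)
        measured = AtrophyVector(np.random.default_rng(1).normal(size=10), (5, 5))
        fit = fit_model1(eig10, seed, measured)
        assert np.array_equal(fit.curve.xs, np.arange(2, 11))
        assert fit.curve.axis == "eigenmode_count"

    def test_constant_measured_rejected(self, eig10):
        with pytest.raises(GraphError):
            fit_model1(eig10, SeedVector.unit(10, 0), AtrophyVector(np.ones(10), (5, 5)))

    def test_estimate_scale_invariance_of_r(self, eig10):
        measured = AtrophyVector(np.random.default_rng(2).normal(size=10), (5, 5))
        seed = SeedVector.unit(10, 3)
        fit = fit_model1(eig10, seed, measured)
        est = fit.estimate.values
        R_direct, _ = pearson_r(5.0 * est + 1.0, measured.values)
        assert R_direct == pytest.approx(fit.R, abs=1e-12)


class TestSweepModel2:
    def test_self_consistency(self, eig10):
        t_true = 5.0
        grid = np.linspace(0.0, 20.0, 201)  # contains t_true exactly
        target = model2_atrophy(eig10, SeedVector.unit(10, 4), t_true).values
        c = sweep_model2(eig10, 4, AtrophyVector(target, (5, 5)), grid)
        k = np.nanargmax(c.Rs)
        assert c.xs[k] == pytest.approx(t_true)
        assert c.Rs[k] == pytest.approx(1.0, abs=1e-10)

    def test_t0_recorded_missing(self, eig10):
        grid = np.array([0.0, 1.0, 2.0])
        c = sweep_model2(eig10, 0, AtrophyVector(np.random.default_rng(0).normal(size=10), (5, 5)), grid)
        assert np.isnan(c.Rs[0])
        assert np.all(np.isfinite(c.Rs[1:]))

    def test_model1_target_monotone(self, eig10):
        """Limit law: fitting the full pseudo-inverse pattern from the same
        seed gives an R(t) that climbs to a plateau."""
        target = model1_atrophy(eig10, SeedVector.unit(10, 2), K=10).values
        grid = np.linspace(0.0, 500.0, 400)
        c = sweep_model2(eig10, 2, AtrophyVector(target, (5, 5)), grid)
        Rs = c.Rs[np.isfinite(c.Rs)]
        assert Rs[-1] == pytest.approx(1.0, abs=1e-6)
        assert classify_curve(c) == "monotone_increasing"

    def test_single_point_grid(self, eig10):
        measured = AtrophyVector(np.random.default_rng(3).normal(size=10), (5, 5))
        t = 4.0
        c = sweep_model2(eig10, 1, measured, np.array([t]))
        est = model2_atrophy(eig10, SeedVector.unit(10, 1), t).values
        R, _ = pearson_r(est, measured.values)
        assert c.Rs[0] == pytest.approx(R, abs=1e-12)


class TestSelectTcrit:
    def test_unimodal_peak(self):
        xs = np.linspace(0, 20, 400)
        Rs = np.exp(-((xs - 5.56) ** 2))
        sel = select_tcrit(curve(xs, Rs))
        assert sel.t_crit == pytest.approx(5.56, abs=0.05)
        assert not sel.monotone

    def test_shallow_global_max_discarded(self):
        # global max at t = 1.2 must lose to the local max at t = 40
        xs = np.linspace(0, 60, 601)
        Rs = 0.9 * np.exp(-(((xs - 1.2) / 0.5) ** 2)) + 0.5 * np.exp(
            -(((xs - 40) / 5) ** 2)
        )
        sel = select_tcrit(curve(xs, Rs))
        assert sel.t_crit == pytest.approx(40.0, abs=0.5)
        assert sel.R == pytest.approx(0.5, abs=0.01)

    def test_monotone_returns_last(self):
        xs = np.linspace(0, 10, 50)
        Rs = 1 - np.exp(-xs)
        sel = select_tcrit(curve(xs, Rs))
        assert sel.t_crit == xs[-1]
        assert sel.monotone

    def test_nan_at_zero_ignored(self):
        xs = np.array([0.0, 2.0, 5.0, 8.0])
        Rs = np.array([np.nan, 0.2, 0.9, 0.3])
        sel = select_tcrit(curve(xs, Rs))
        assert sel.t_crit == 5.0

    def test_all_missing_rejected(self):
        with pytest.raises(GraphError):
            select_tcrit(curve([0.0, 1.0], [np.nan, np.nan]))

    def test_wrong_axis_rejected(self):
        c = RCurve(axis="eigenmode_count", xs=np.array([2.0, 3.0]), Rs=np.array([0.1, 0.2]))
        with pytest.raises(GraphError):
            select_tcrit(c)


class TestFitModel2:
    def test_planted_noiseless_recovery(self, eig10):
        t_true = 5.0
        grid = np.linspace(0.0, 20.0, 201)
        target = model2_atrophy(eig10, SeedVector.unit(10, 7), t_true).values
        table, fit = fit_model2(eig10, AtrophyVector(target, (5, 5)), grid)
        assert fit.param["seed_region"] == 7
        assert fit.R == pytest.approx(1.0, abs=1e-8)
        assert abs(fit.param["t_crit"] - t_true) <= grid[1] - grid[0]

    def test_seed_subset_table_shape(self, eig10):
        measured = AtrophyVector(np.random.default_rng(5).normal(size=10), (5, 5))
        subset = [1, 3, 8]
        table, fit = fit_model2(eig10, measured, np.linspace(0, 10, 50), seeds=subset)
        assert len(table) == 3
        assert list(table["seed_region"]) == subset
        assert fit.param["seed_region"] in subset
        assert fit.R == pytest.approx(table["R"].max())

    def test_empty_seed_set_rejected(self, eig10):
        measured = AtrophyVector(np.random.default_rng(5).normal(size=10), (5, 5))
        with pytest.raises(GraphError):
            fit_model2(eig10, measured, seeds=[])

    def test_deterministic(self, eig10):
        measured = AtrophyVector(np.random.default_rng(6).normal(size=10), (5, 5))
        grid = np.linspace(0, 30, 100)
        t1, f1 = fit_model2(eig10, measured, grid)
        t2, f2 = fit_model2(eig10, measured, grid)
        assert t1.equals(t2)
        assert f1.param == f2.param


class TestEigenmodeCorrelations:
    def test_peak_at_planted_mode(self, eig10):
        k = 6  # 1-based mode index
        rng = np.random.default_rng(0)
        measured = AtrophyVector(eig10.U[:, k - 1] + 0.01 * rng.normal(size=10), (5, 5))
        c = eigenmode_correlations(eig10, measured)
        assert c.xs[np.argmax(c.Rs)] == k

    def test_sign_invariance(self, eig10):
        k = 4
        m_pos = AtrophyVector(eig10.U[:, k - 1], (5, 5))
        m_neg = AtrophyVector(-eig10.U[:, k - 1], (5, 5))
        c_pos = eigenmode_correlations(eig10, m_pos)
        c_neg = eigenmode_correlations(eig10, m_neg)
        assert np.allclose(c_pos.Rs, c_neg.Rs, atol=1e-12)

    def test_null_scale_on_large_graph(self):
        """Monte-Carlo null: random targets give |R| on the 1/sqrt(N) scale."""
        from ndatrophy import SyntheticSpec, make_connectome

        conn = make_connectome(SyntheticSpec(), np.random.default_rng(0))
        eig = conn.eigensystem()
        rng = np.random.default_rng(1)
        maxima = []
        for _ in range(5):
            measured = AtrophyVector(rng.normal(size=86), (5, 5))
            c = eigenmode_correlations(eig, measured)
            maxima.append(np.max(c.Rs))
        assert np.median(maxima) < 0.45
        assert np.all(np.asarray(maxima) <= 1.0)


class TestClassifyCurve:
    def test_flat_curve_monotone(self):
        assert classify_curve(curve([0, 1, 2], [0.5, 0.5, 0.5])) == "monotone_increasing"

    def test_peaked_curve(self):
        xs = np.linspace(0, 10, 100)
        Rs = np.exp(-((xs - 4) ** 2))
        assert classify_curve(curve(xs, Rs)) == "peak_at_intermediate_t"

    def test_single_point_rejected(self):
        with pytest.raises(GraphError):
            classify_curve(curve([1.0], [0.3]))


class TestLogEstimateCorrelation:
    def test_all_zero_rejected(self, eig10):
        est = AtrophyEstimate(np.zeros(10), model="model2", params={})
        with pytest.raises(GraphError):
            log_estimate_correlation(est, AtrophyVector(np.arange(10.0), (5, 5)))

    def test_constant_rejected(self):
        est = AtrophyEstimate(np.full(10, 2.0), model="model1", params={})
        with pytest.raises(GraphError):
            log_estimate_correlation(est, AtrophyVector(np.arange(10.0), (5, 5)))

    def test_zeros_handled_finite(self):
        est = AtrophyEstimate(np.array([0.0, 1.0, 2.0, 3.0]), model="model2", params={})
        measured = AtrophyVector(np.array([0.1, 0.9, 2.1, 2.9]), (5, 5))
        R, p = log_estimate_correlation(est, measured)
        assert np.isfinite(R) and np.isfinite(p)

    def test_positive_estimate_plain_log(self):
        vals = np.array([1.0, 2.0, 4.0, 8.0])
        est = AtrophyEstimate(vals, model="model2", params={})
        measured = AtrophyVector(np.array([0.0, 1.0, 2.0, 3.0]), (5, 5))
        R, _ = log_estimate_correlation(est, measured)
        assert R == pytest.approx(1.0, abs=1e-12)  # log2 spacing is exactly linear
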