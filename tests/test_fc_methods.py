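"""Functional-connectivity estimators against closed forms and independent
reference implementations."""

import numpy as np
import pytest

from dcovnet.containers import SparseLatentConfig, TimeSeriesMatrix
from dcovnet.fc_methods import (
    conditional_granger,
    differential_covariance,
    partial_covariance,
    partial_differential_covariance,
    regularized_partial_covariance,
    sample_covariance,
    sparse_latent_split,
)
from dcovnet.synthkit import generate_network, simulate_neural
from dcovnet.validation import pairwise_regression_dcov_p


def _ts(values, dt=1.0):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return TimeSeriesMatrix(values, [f"n{i}" for i in range(values.shape[0])], dt, "neural")


class TestSampleCovariance:
    def test_hand_computed_value(self):
        cm = sample_covariance(_ts([[1, 2, 3], [1, 2, 3]]))
        assert np.allclose(cm.values, 1.0)

    def test_identical_rows_share_variance(self):
        rng = np.random.default_rng(0)
        row = rng.standard_normal(100)
        cm = sample_covariance(_ts(np.vstack([row, row])))
        assert cm.values[0, 1] == pytest.approx(cm.values[0, 0])

    def test_independent_noise_offdiagonals_shrink(self):
        rng = np.random.default_rng(1)
        cm = sample_covariance(_ts(rng.standard_normal((2, 100_000))))
        assert abs(cm.values[0, 1]) < 5 / np.sqrt(100_000)


class TestPartialCovariance:
    def test_diagonal_covariance_inverts_elementwise(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((3, 50_000)) * np.array([[1.0], [2.0], [0.5]])
        cm = partial_covariance(_ts(x))
        v = np.var(x, axis=1, ddof=1)
        assert np.allclose(np.diag(cm.values), 1 / v, rtol=0.05)

    def test_two_node_closed_form(self):
        rho = 0.6
        rng = np.random.default_rng(3)
        z = rng.standard_normal((2, 200_000))
        z[1] = rho * z[0] + np.sqrt(1 - rho ** 2) * z[1]
        cm = partial_covariance(_ts(z))
        assert cm.values[0, 1] == pytest.approx(-rho / (1 - rho ** 2), rel=0.05)

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(4)
        z = _ts(rng.standard_normal((4, 500)))
        cov = sample_covariance(z).values
        p = partial_covariance(z).values
        assert np.allclose(np.linalg.inv(p), cov, atol=1e-8)

    def test_rank_deficiency_warns_and_uses_pinv(self):
        rng = np.random.default_rng(5)
        row = rng.standard_normal(100)
        z = _ts(np.vstack([row, row, rng.standard_normal(100)]))
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            partial_covariance(z)


class TestRegularizedPartialCovariance:
    def test_zero_penalty_equals_precision(self):
        rng = np.random.default_rng(6)
        z = _ts(rng.standard_normal((4, 300)))
        p = partial_covariance(z).values
        for kind in ("L1", "L2"):
            r = regularized_partial_covariance(z, kind, penalty=0.0)
            assert np.allclose(r.values, p, atol=1e-6)

    def test_huge_l1_penalty_kills_offdiagonals(self):
        rng = np.random.default_rng(7)
        z = _ts(rng.standard_normal((4, 300)))
        r = regularized_partial_covariance(z, "L1", penalty=1e5).values
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(r[off], 0.0, atol=1e-8)

    def test_l2_path_is_shrinking(self):
        rng = np.random.default_rng(8)
        z = _ts(rng.standard_normal((5, 400)))
        off = ~np.eye(5, dtype=bool)
        mags = [np.mean(np.abs(regularized_partial_covariance(z, "L2", rho).values[off]))
                for rho in (0.01, 0.1, 1.0, 10.0)]
        assert all(a >= b for a, b in zip(mags, mags[1:]))


class TestDifferentialCovariance:
    def test_constant_rows_give_zero(self):
        cm = differential_covariance(_ts(np.ones((3, 20))))
        assert np.allclose(cm.values, 0.0)

    def test_sinusoid_orthogonal_to_own_derivative(self):
        # over whole periods, cov(cos, sin) vanishes by quadrature
        t = np.linspace(0, 20 * np.pi, 4001)[:-1]
        cm = differential_covariance(_ts(np.sin(t)[None, :], dt=t[1] - t[0]))
        assert abs(cm.values[0, 0]) < 1e-4

    def test_antisymmetry_on_stationary_data(self):
        net = generate_network(10, 0.2, seed=0)
        v = simulate_neural(net, 100_000, dt=0.01, noise_sd=1.0, seed=1)
        cm = differential_covariance(v)
        assert cm.meta["antisymmetry_ratio"] < 0.1
        assert cm.directed


class TestPartialDifferentialCovariance:
    def test_two_nodes_reduce_to_dcov(self):
        rng = np.random.default_rng(9)
        z = _ts(rng.standard_normal((2, 200)))
        dc = differential_covariance(z).values
        dp = partial_differential_covariance(z).values
        off = ~np.eye(2, dtype=bool)
        assert np.allclose(dp[off], dc[off])

    @pytest.mark.parametrize("n", [3, 5])
    def test_matches_residual_regression_reference(self, n):
        rng = np.random.default_rng(10 + n)
        z = _ts(rng.standard_normal((n, 400)))
        dp = partial_differential_covariance(z).values
        assert np.max(np.abs(dp - pairwise_regression_dcov_p(z))) < 1e-8

    def test_chain_effect_is_suppressed(self):
        # 1 -> 2 -> 3 chain: conditioning on node 2 shrinks the spurious 3<-1 entry
        W = np.array([[-1.0, 0.0, 0.0], [0.6, -1.0, 0.0], [0.0, 0.6, -1.0]])
        from dcovnet.containers import GroundTruthNetwork

        net = GroundTruthNetwork(W, ["a", "b", "c"], 2 / 6, 0)
        v = simulate_neural(net, 200_000, dt=0.05, noise_sd=1.0, seed=11)
        dc = np.abs(differential_covariance(v).values)
        dp = np.abs(partial_differential_covariance(v).values)
        assert dp[2, 0] < dc[2, 0]


class TestSparseLatentSplit:
    def test_zero_input_gives_zero_parts(self):
        from dcovnet.containers import ConnectivityMatrix

        dp = ConnectivityMatrix(np.zeros((5, 5)), [f"n{i}" for i in range(5)], "dcov_p", True)
        s, latent = sparse_latent_split(dp)
        assert np.all(s.values == 0) and np.all(latent.values == 0)

    def test_pure_sparse_input_passes_through(self):
        rng = np.random.default_rng(12)
        from dcovnet.containers import ConnectivityMatrix

        n = 20
        m = np.zeros((n, n))
        pos = rng.choice(n * n, size=n * n // 20, replace=False)
        m.flat[pos] = rng.standard_normal(pos.size) * 3
        dp = ConnectivityMatrix(m, [f"n{i}" for i in range(n)], "dcov_p", True)
        s, latent = sparse_latent_split(dp)
        assert np.max(np.abs(s.values - m)) < 1e-6
        assert np.max(np.abs(latent.values)) < 1e-6

    def test_planted_decomposition_recovery(self):
        from dcovnet.validation import sparse_latent_recovery

        out = sparse_latent_recovery(n=30, seed=0)
        assert out["support_accuracy"] >= 0.95
        assert out["constraint_residual"] < 1e-6

    def test_constraint_conservation(self):
        rng = np.random.default_rng(13)
        from dcovnet.containers import ConnectivityMatrix

        m = rng.standard_normal((15, 15))
        dp = ConnectivityMatrix(m, [f"n{i}" for i in range(15)], "dcov_p", True)
        cfg = SparseLatentConfig(tol=1e-7)
        s, latent = sparse_latent_split(dp, cfg)
        assert np.linalg.norm(s.values + latent.values - m) < 1e-6 * np.linalg.norm(m) * 10

    def test_alpha_resolution(self):
        assert SparseLatentConfig().resolve_alpha(25) == pytest.approx(1 / 5)
        assert SparseLatentConfig("1/N").resolve_alpha(25) == pytest.approx(1 / 25)
        with pytest.raises(ValueError):
            SparseLatentConfig(-1.0).resolve_alpha(25)


class TestConditionalGranger:
    def test_statistics_are_nonnegative_with_unit_diagonal_p(self):
        rng = np.random.default_rng(14)
        z = _ts(rng.standard_normal((3, 2000)))
        F, p = conditional_granger(z, max_order=3)
        assert np.all(F.values >= 0)
        assert np.all(np.diag(p) == 1)
        assert np.all(np.diag(F.values) == 0)

    def test_planted_edge_detected(self):
        from dcovnet.validation import granger_planted_detection

        assert granger_planted_detection(n_seeds=20, seed=0) >= 0.9

    def test_null_pvalues_uniform(self):
        from dcovnet.validation import granger_calibration

        assert granger_calibration(n_repeats=10, seed=0) > 0.01


class TestSymmetryClasses:
    def test_symmetric_estimators_are_symmetric(self):
        rng = np.random.default_rng(15)
        z = _ts(rng.standard_normal((5, 600)))
        for fn in (sample_covariance, partial_covariance):
            v = fn(z).values
            assert np.allclose(v, v.T, atol=1e-10)
        for kind in ("L1", "L2"):
            v = regularized_partial_covariance(z, kind).values
            assert np.allclose(v, v.T, atol=1e-10)

    def test_directed_estimators_tagged_directed(self):
        rng = np.random.default_rng(16)
        z = _ts(rng.standard_normal((4, 600)))
        assert differential_covariance(z).directed
        assert partial_differential_covariance(z).directed
        assert differential_covariance(z).convention == "row=sink,col=source"
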