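import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lowrankmr.denoise_core import (
    DecompositionResult,
    ImageMatrix,
    SolverConfig,
    WeightVector,
    solve_rl,
    solve_rlre,
    update_noise_term,
    update_weights,
    weighted_soft_threshold,
    weighted_svt,
)

from oracles import (
    l1_objective,
    scalar_prox_bruteforce,
    singular_value_prox_bruteforce,
    svt_objective,
)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class TestImageMatrix:
    def test_rejects_non_finite(self):
        with pytest.raises(ValueError, match="non-finite"):
            ImageMatrix(np.array([[1.0, np.nan]]))

    def test_rejects_wrong_ndim(self):
        with pytest.raises(ValueError):
            ImageMatrix(np.ones(3))

    def test_default_range(self):
        img = ImageMatrix(np.zeros((2, 2)))
        assert img.intensity_range == (0.0, 255.0)


class TestSolverConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"lambda1": -1.0},
            {"lambda2": 0.0},
            {"epsilon": 0.0},
            {"rho": 1.0},
            {"tol": 0.0},
            {"max_iter": 0},
            {"mu0": -0.5},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            SolverConfig(**kwargs)

    def test_roundtrip(self):
        cfg = SolverConfig(lambda1=0.2, lambda2=3.0, tol=1e-5, max_iter=77)
        assert SolverConfig.from_dict(cfg.to_dict()) == cfg

    def test_roundtrip_infinite_lambda2(self):
        cfg = SolverConfig(lambda2=math.inf)
        restored = SolverConfig.from_dict(cfg.to_dict())
        assert math.isinf(restored.lambda2)

    def test_resolve_defaults(self):
        cfg = SolverConfig().resolve((50, 50), spectral_norm=10.0)
        assert cfg.lambda1 == pytest.approx(1 / math.sqrt(50))
        assert cfg.c_weight == pytest.approx(math.sqrt(50))
        assert cfg.mu0 == pytest.approx(0.125)


# ---------------------------------------------------------------------------
# weighted_svt
# ---------------------------------------------------------------------------


class TestWeightedSVT:
    def test_equal_weights_reduce_to_plain_svt(self):
        Y = np.diag([5.0, 1.0])
        out = weighted_svt(Y, np.ones(2), tau=2.0)
        np.testing.assert_allclose(np.sort(np.diag(out))[::-1], [3.0, 0.0], atol=1e-12)

    def test_zero_weights_identity(self, rng):
        Y = rng.standard_normal((4, 3))
        out = weighted_svt(Y, np.zeros(3), tau=7.0)
        np.testing.assert_allclose(out, Y, atol=1e-10)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        Y = rng.standard_normal((3, 3)) * 3
        sig = np.linalg.svd(Y, compute_uv=False)
        w = 1.0 / (sig + 0.01)
        tau = 0.5
        out = weighted_svt(Y, w, tau)
        # oracle: the problem separates across singular values for fixed weights
        U, s, Vt = np.linalg.svd(Y)
        w_sorted = np.sort(w)
        shrunk = [singular_value_prox_bruteforce(sj, wj, tau) for sj, wj in zip(s, w_sorted)]
        oracle = (U * shrunk) @ Vt
        gap = svt_objective(out, Y, w, tau) - svt_objective(oracle, Y, w, tau)
        assert gap <= 1e-6

    def test_output_spectrum_valid(self, rng):
        Y = rng.standard_normal((5, 4)) * 10
        w = rng.uniform(0, 3, size=4)
        out = weighted_svt(Y, w, tau=1.3)
        sig = np.linalg.svd(out, compute_uv=False)
        assert np.all(sig >= -1e-12)
        assert np.all(np.diff(sig) <= 1e-9)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            weighted_svt(np.array([[np.inf, 0.0]]), np.ones(1), 1.0)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            weighted_svt(np.empty((0, 3)), np.ones(1), 1.0)

    def test_rejects_negative_weights(self):
        with pytest.raises(ValueError):
            weighted_svt(np.eye(2), np.array([-1.0, 1.0]), 1.0)


# ---------------------------------------------------------------------------
# weighted_soft_threshold
# ---------------------------------------------------------------------------


class TestWeightedSoftThreshold:
    def test_scalar_above_threshold(self):
        out = weighted_soft_threshold(np.array([[5.0]]), np.array([[1.0]]), tau=2.0)
        assert out[0, 0] == pytest.approx(3.0)

    def test_scalar_below_threshold(self):
        out = weighted_soft_threshold(np.array([[-1.5]]), np.array([[1.0]]), tau=2.0)
        assert out[0, 0] == 0.0

    def test_matches_scalar_bruteforce(self):
        rng = np.random.default_rng(7)
        Y = rng.standard_normal((4, 4)) * 2
        W = 1.0 / (np.abs(Y) + 0.1)
        tau = 1.0
        out = weighted_soft_threshold(Y, W, tau)
        oracle = np.vectorize(scalar_prox_bruteforce)(Y, W, tau)
        gap = l1_objective(out, Y, W, tau) - l1_objective(oracle, Y, W, tau)
        assert gap <= 1e-8

    def test_rejects_negative_weights(self):
        with pytest.raises(ValueError, match="non-negative"):
            weighted_soft_threshold(np.ones((2, 2)), -np.ones((2, 2)), 1.0)

    @given(
        y=st.floats(-1e3, 1e3),
        w=st.floats(0, 10),
        tau=st.floats(1e-3, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_shrinks_magnitude_and_keeps_sign(self, y, w, tau):
        out = weighted_soft_threshold(np.array([[y]]), np.array([[w]]), tau)[0, 0]
        assert abs(out) <= abs(y) + 1e-12
        assert out * y >= 0


# ---------------------------------------------------------------------------
# update_noise_term / update_weights
# ---------------------------------------------------------------------------


class TestNoiseUpdate:
    def test_zero_penalty_returns_input(self, seeded_image):
        np.testing.assert_array_equal(update_noise_term(seeded_image, 0.0, 2.0), seeded_image)

    def test_infinite_penalty_kills_term(self, seeded_image):
        np.testing.assert_array_equal(
            update_noise_term(seeded_image, math.inf, 2.0), np.zeros_like(seeded_image)
        )

    def test_closed_form_example(self):
        out = update_noise_term(np.ones((2, 2)), lambda2=1.0, mu=2.0)
        np.testing.assert_allclose(out, 0.5 * np.ones((2, 2)))

    def test_large_lambda2_limit(self, seeded_image):
        out = update_noise_term(seeded_image, 1e12, 2.0)
        assert np.max(np.abs(out)) < 1e-9


class TestUpdateWeights:
    def test_formula(self):
        H = np.diag([10.0, 0.0])
        res = DecompositionResult(H=H, S=np.zeros((2, 2)), E=np.zeros((2, 2)),
                                  iterations=1, residual=0.0, converged=True)
        cfg = SolverConfig(c_weight=1.0, epsilon=0.1)
        w_h, w_s = update_weights(res, cfg)
        np.testing.assert_allclose(w_h.w, [1 / 10.1, 10.0])
        np.testing.assert_allclose(w_s, 1 / 0.1 * np.ones((2, 2)))

    def test_zero_sparse_gives_uniform_max_weight(self):
        res = DecompositionResult(H=np.eye(3), S=np.zeros((3, 3)), E=np.zeros((3, 3)),
                                  iterations=1, residual=0.0, converged=True)
        cfg = SolverConfig(c_weight=2.0, epsilon=0.5)
        _, w_s = update_weights(res, cfg)
        np.testing.assert_allclose(w_s, 4.0 * np.ones((3, 3)))

    def test_monotone_in_sigma(self, rng):
        H = rng.standard_normal((6, 6)) * 20
        res = DecompositionResult(H=H, S=np.zeros((6, 6)), E=np.zeros((6, 6)),
                                  iterations=1, residual=0.0, converged=True)
        w_h, _ = update_weights(res, SolverConfig(c_weight=3.0, epsilon=0.2))
        # singular values are non-ascending, so weights must be non-descending
        assert np.all(np.diff(w_h.w) >= -1e-12)
        assert np.all(w_h.w > 0)

    def test_epsilon_zero_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(epsilon=0.0)

    def test_weight_vector_rejects_negative(self):
        with pytest.raises(ValueError):
            WeightVector(np.array([-1.0]))


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------


def _rank1_target(n=50, scale=100.0, seed=7):
    rng = np.random.default_rng(seed)
    u = rng.standard_normal(n)
    u /= np.linalg.norm(u)
    v = rng.standard_normal(n)
    v /= np.linalg.norm(v)
    return scale * np.outer(u, v)


class TestSolveRLRE:
    def test_zero_matrix_fixed_point(self):
        res = solve_rlre(np.zeros((6, 6)))
        assert res.converged
        assert res.iterations <= 2
        assert np.allclose(res.H, 0) and np.allclose(res.S, 0) and np.allclose(res.E, 0)

    def test_rank1_signal_lands_in_H(self):
        D = _rank1_target()
        cfg = SolverConfig(lambda1=1 / math.sqrt(50), lambda2=10.0)
        res = solve_rlre(D, cfg)
        assert res.converged
        nd = np.linalg.norm(D)
        assert np.linalg.norm(res.H - D) / nd <= 0.05
        assert np.linalg.norm(res.S) / nd <= 0.05

    def test_feasibility_on_convergence(self, rng):
        D = rng.uniform(0, 255, (32, 32))
        res = solve_rlre(D)
        assert res.converged
        assert res.residual <= SolverConfig().tol
        gap = np.linalg.norm(D - res.reconstruction()) / np.linalg.norm(D)
        assert gap <= SolverConfig().tol

    def test_determinism_bit_identical(self, rng):
        D = rng.uniform(0, 255, (24, 24))
        a = solve_rlre(D)
        b = solve_rlre(D)
        assert np.array_equal(a.H, b.H)
        assert np.array_equal(a.S, b.S)
        assert np.array_equal(a.E, b.E)
        assert a.iterations == b.iterations and a.residual == b.residual

    def test_objective_non_increasing_over_last_sweep(self, rng):
        D = rng.uniform(0, 255, (40, 40)) + rng.normal(0, 10, (40, 40))
        res = solve_rlre(D)
        tail = np.asarray(res.objective_trace[-5:])
        rel = np.diff(tail) / max(abs(tail[-1]), 1.0)
        assert np.all(rel <= 1e-6)

    def test_nonconvergence_flagged_not_silent(self, rng, caplog):
        D = rng.uniform(0, 255, (16, 16))
        with caplog.at_level("WARNING", logger="lowrankmr.denoise_core"):
            res = solve_rlre(D, SolverConfig(max_iter=2))
        assert not res.converged
        assert res.iterations == 2
        assert any("did not converge" in r.message for r in caplog.records)


class TestSolveRL:
    def test_zero_matrix(self):
        res = solve_rl(np.zeros((5, 5)))
        assert res.converged and np.allclose(res.reconstruction(), 0)

    def test_E_pinned_at_zero(self, rng):
        D = rng.uniform(0, 255, (20, 20))
        res = solve_rl(D)
        assert np.array_equal(res.E, np.zeros_like(D))

    def test_reduction_consistency_one_iteration(self, rng):
        # unit weights + infinite lambda2 makes one RLRE sweep identical to RL
        D = rng.uniform(0, 255, (20, 20))
        cfg = SolverConfig(lambda2=math.inf, max_iter=1)
        a = solve_rlre(D, cfg, weighted=False)
        b = solve_rl(D, SolverConfig(max_iter=1))
        np.testing.assert_allclose(a.H, b.H, atol=1e-10)
        np.testing.assert_allclose(a.S, b.S, atol=1e-10)
        np.testing.assert_allclose(a.E, b.E, atol=1e-10)

    def test_reduction_consistency_full_run(self, rng):
        D = rng.uniform(0, 255, (20, 20))
        a = solve_rlre(D, SolverConfig(lambda2=math.inf), weighted=False)
        b = solve_rl(D)
        assert a.iterations == b.iterations
        np.testing.assert_allclose(a.H, b.H, atol=1e-10)
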