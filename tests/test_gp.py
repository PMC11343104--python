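"""Gaussian-process core: kernels, posterior, marginal likelihood, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hilopt.gp import (
    GaussianProcess,
    HyperparamBounds,
    KernelHyperparams,
    ObservationSet,
    composite_kernel,
    fit,
    optimize_hyperparams,
    static_kernel,
    temporal_kernel,
)


def brute_force_posterior(obs, hp, u, t, center=True):
    """Textbook GP posterior via dense solves, written independently of gp.py."""
    n = len(obs)
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = composite_kernel(
                obs.inputs[i], obs.times[i], obs.inputs[j], obs.times[j], hp
            )
    K += hp.noise_variance * np.eye(n)
    ks = np.array(
        [composite_kernel(u, t, obs.inputs[j], obs.times[j], hp) for j in range(n)]
    )
    ymean = obs.outputs.mean() if center else 0.0
    yc = obs.outputs - ymean
    sol = np.linalg.solve(K, yc)
    mean = ymean + ks @ sol
    var = composite_kernel(u, t, u, t, hp) - ks @ np.linalg.solve(K, ks)
    return mean, max(var, 0.0), K, yc


class TestKernels:
    @pytest.mark.parametrize(
        "u1,u2,hp_args,expected",
        [
            ([1.0], [1.0], ((2.0,), 1.0), 1.0),
            ([1.0], [3.0], ((2.0,), 1.0), np.exp(-0.5)),
            ([0.0, 0.0], [1.0, 1.0], ((1.0, 1.0), 2.0), 2.0 * np.exp(-1.0)),
        ],
    )
    def test_static_kernel_hand_values(self, u1, u2, hp_args, expected):
        hp = KernelHyperparams(*hp_args)
        assert static_kernel(u1, u2, hp) == pytest.approx(expected, rel=1e-12)

    def test_static_kernel_symmetric(self, rng):
        hp = KernelHyperparams((0.7, 1.3), 2.1)
        u1, u2 = rng.normal(size=2), rng.normal(size=2)
        assert static_kernel(u1, u2, hp) == static_kernel(u2, u1, hp)

    def test_static_kernel_dimension_mismatch(self):
        hp = KernelHyperparams((1.0,), 1.0)
        with pytest.raises(ValueError, match="dimension"):
            static_kernel([1.0, 2.0], [0.0, 0.0], hp)

    @pytest.mark.parametrize(
        "t1,t2,alpha,expected",
        [(7, 7, 0.5, 1.0), (0, 100, 0.0, 1.0), (0, 3, 0.1, 0.9**3)],
    )
    def test_temporal_kernel_values(self, t1, t2, alpha, expected):
        assert temporal_kernel(t1, t2, alpha) == pytest.approx(expected, rel=1e-12)

    def test_temporal_kernel_rejects_bad_alpha(self):
        for alpha in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                temporal_kernel(0, 1, alpha)

    def test_composite_equals_static_times_temporal(self):
        hp = KernelHyperparams((2.0,), 1.0, alpha=0.1)
        got = composite_kernel([1.0], 0, [3.0], 3, hp)
        assert got == pytest.approx(np.exp(-0.5) * 0.9**3, rel=1e-12)

    def test_composite_alpha_zero_is_static_bitwise(self, rng):
        hp = KernelHyperparams((1.7,), 2.3, alpha=0.0)
        for _ in range(20):
            u1, u2 = rng.normal(size=1), rng.normal(size=1)
            t1, t2 = rng.integers(0, 50, 2)
            assert composite_kernel(u1, t1, u2, t2, hp) == static_kernel(u1, u2, hp)

    def test_diagonal_value_is_signal_variance(self):
        hp = KernelHyperparams((1.0,), 3.3, alpha=0.4)
        assert composite_kernel([2.0], 5, [2.0], 5, hp) == pytest.approx(3.3)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        alpha=st.floats(0.0, 0.9),
        ls=st.floats(0.1, 10.0),
        sv=st.floats(0.01, 100.0),
    )
    def test_kernel_matrix_positive_semidefinite(self, seed, alpha, ls, sv):
        r = np.random.default_rng(seed)
        hp = KernelHyperparams((ls,), sv, alpha=alpha)
        X = r.uniform(-5, 5, (10, 1))
        t = np.sort(r.integers(0, 30, 10))
        K = np.array(
            [
                [composite_kernel(X[i], t[i], X[j], t[j], hp) for j in range(10)]
                for i in range(10)
            ]
        )
        assert np.linalg.eigvalsh(K).min() >= -1e-8 * sv


class TestHyperparams:
    def test_invalid_hyperparams_rejected(self):
        with pytest.raises(ValueError):
            KernelHyperparams((0.0,), 1.0)
        with pytest.raises(ValueError):
            KernelHyperparams((1.0,), -1.0)
        with pytest.raises(ValueError):
            KernelHyperparams((1.0,), 1.0, alpha=1.0)
        with pytest.raises(ValueError):
            KernelHyperparams((1.0,), 1.0, noise_variance=-0.1)

    def test_observation_set_invariants(self):
        with pytest.raises(ValueError, match="equal length"):
            ObservationSet([[0.0]], [0, 1], [1.0])
        with pytest.raises(ValueError, match="non-decreasing"):
            ObservationSet([[0.0], [1.0]], [3, 1], [1.0, 2.0])


class TestPosterior:
    def test_noiseless_interpolation_single_point(self):
        obs = ObservationSet([[0.5]], [0], [2.7])
        hp = KernelHyperparams((1.0,), 1.5, noise_variance=0.0)
        m = fit(obs, hp)
        p = m.predict([0.5], 0)
        assert p.mean == pytest.approx(2.7, abs=1e-9)
        assert p.function_variance == pytest.approx(0.0, abs=1e-9)
        assert p.model_variance == pytest.approx(0.0, abs=1e-9)

    def test_prior_recovery_far_from_data(self, small_obs):
        hp = KernelHyperparams((1e-3,), 2.0, alpha=0.0, noise_variance=1e-8)
        m = fit(small_obs, hp)
        p = m.predict([100.0], 3)
        assert p.mean == pytest.approx(small_obs.outputs.mean(), abs=1e-6)
        assert p.function_variance == pytest.approx(2.0, rel=1e-6)

    @pytest.mark.parametrize("alpha,nv", [(0.0, 0.01), (0.2, 0.05), (0.35, 0.0)])
    def test_matches_brute_force_oracle(self, rng, alpha, nv):
        x = rng.uniform(-2, 2, 5)
        obs = ObservationSet(x[:, None], np.arange(5), rng.normal(0, 1, 5))
        hp = KernelHyperparams((0.8,), 1.3, alpha=alpha, noise_variance=nv)
        m = fit(obs, hp)
        for uq, tq in [([0.3], 6), ([-1.5], 2), ([2.5], 10)]:
            mean_o, var_o, _, _ = brute_force_posterior(obs, hp, np.array(uq), tq)
            p = m.predict(uq, tq)
            assert p.mean == pytest.approx(mean_o, abs=1e-8)
            assert p.function_variance == pytest.approx(var_o, abs=1e-8)

    def test_model_variance_identity(self, small_obs, rng):
        hp = KernelHyperparams((0.9,), 1.1, alpha=0.15, noise_variance=0.07)
        m = fit(small_obs, hp)
        for _ in range(10):
            p = m.predict([float(rng.uniform(-4, 4))], int(rng.integers(0, 20)))
            assert p.model_variance == p.function_variance + hp.noise_variance

    def test_training_point_zero_variance_when_noiseless(self, rng):
        x = rng.uniform(-2, 2, 4)
        obs = ObservationSet(x[:, None], np.arange(4), rng.normal(size=4))
        hp = KernelHyperparams((1.2,), 1.0, noise_variance=0.0)
        m = fit(obs, hp)
        p = m.predict([float(x[1])], 1)
        assert p.function_variance == pytest.approx(0.0, abs=1e-7)

    def test_empty_observation_set_rejected(self):
        obs = ObservationSet(np.empty((0, 1)), [], [])
        with pytest.raises(ValueError, match="empty"):
            fit(obs, KernelHyperparams((1.0,), 1.0))


class TestMarginalLikelihood:
    def test_single_observation_closed_form(self):
        obs = ObservationSet([[1.0]], [0], [0.0])
        hp = KernelHyperparams((1.0,), 0.7, noise_variance=0.3)
        m = fit(obs, hp, center=False)
        v = 0.7 + 0.3
        assert m.log_marginal_likelihood() == pytest.approx(
            -0.5 * np.log(2 * np.pi * v), rel=1e-12
        )

    def test_reordering_invariance(self, rng):
        x = rng.uniform(-2, 2, 5)
        y = rng.normal(size=5)
        t = np.full(5, 3)  # equal times so any order keeps times sorted
        hp = KernelHyperparams((0.9,), 1.0, alpha=0.2, noise_variance=0.05)
        perm = rng.permutation(5)
        l1 = fit(ObservationSet(x[:, None], t, y), hp).log_marginal_likelihood()
        l2 = fit(ObservationSet(x[perm][:, None], t, y[perm]), hp).log_marginal_likelihood()
        assert l1 == pytest.approx(l2, rel=1e-10)

    def test_matches_dense_formula(self, rng):
        x = rng.uniform(-2, 2, 4)
        obs = ObservationSet(x[:, None], np.arange(4), rng.normal(size=4))
        hp = KernelHyperparams((0.8,), 1.4, alpha=0.1, noise_variance=0.05)
        _, _, K, yc = brute_force_posterior(obs, hp, np.zeros(1), 0)
        expected = (
            -0.5 * yc @ np.linalg.solve(K, yc)
            - 0.5 * np.linalg.slogdet(K)[1]
            - 2.0 * np.log(2 * np.pi)
        )
        assert fit(obs, hp).log_marginal_likelihood() == pytest.approx(expected, abs=1e-8)


class TestHyperparamFitting:
    def test_recovers_length_scale_within_factor_two(self):
        r = np.random.default_rng(42)
        n, true_ls = 40, 1.0
        x = r.uniform(-5, 5, n)
        K = np.exp(-0.5 * (x[:, None] - x[None, :]) ** 2 / true_ls**2) + 0.01 * np.eye(n)
        y = np.linalg.cholesky(K) @ r.normal(size=n)
        obs = ObservationSet(x[:, None], np.arange(n), y)
        bounds = HyperparamBounds(length_scale=(0.05, 20.0), alpha=(0.0, 0.0))
        hp = optimize_hyperparams(obs, bounds, rng=np.random.default_rng(0), maxiter=60)
        assert 0.5 <= hp.length_scales[0] <= 2.0

    def test_all_fixed_returns_unchanged(self, small_obs):
        fixed = {
            "length_scales": (1.7,),
            "signal_variance": 2.2,
            "noise_variance": 0.03,
            "alpha": 0.12,
        }
        hp = optimize_hyperparams(small_obs, HyperparamBounds(), fixed=fixed)
        assert hp.length_scales == (1.7,)
        assert hp.signal_variance == 2.2
        assert hp.noise_variance == 0.03
        assert hp.alpha == 0.12

    def test_collapsed_bounds_return_that_point(self, small_obs):
        bounds = HyperparamBounds(
            length_scale=(1.5, 1.5),
            signal_variance=(2.0, 2.0),
            noise_variance=(0.01, 0.01),
            alpha=(0.3, 0.3),
        )
        hp = optimize_hyperparams(small_obs, bounds)
        assert hp.length_scales[0] == pytest.approx(1.5)
        assert hp.signal_variance == pytest.approx(2.0)
        assert hp.noise_variance == pytest.approx(0.01)
        assert hp.alpha == pytest.approx(0.3)

    def test_gradient_matches_finite_differences(self, rng):
        from hilopt.gp import _MarginalLikelihoodProblem

        x = rng.uniform(-3, 3, 12)
        obs = ObservationSet(x[:, None], np.arange(12), rng.normal(size=12))
        prob = _MarginalLikelihoodProblem(obs)
        th = np.array([np.log(0.9), np.log(1.2), np.log(0.04), 0.15])
        f0, g = prob.value_and_grad(th[:1], th[1], th[2], th[3], True)
        for k in range(4):
            tp = th.copy()
            tp[k] += 1e-6
            fp, _ = prob.value_and_grad(tp[:1], tp[1], tp[2], tp[3], True)
            assert g[k] == pytest.approx((fp - f0) / 1e-6, rel=5e-3, abs=1e-5)
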