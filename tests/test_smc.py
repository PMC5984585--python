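"""Particle filter internals: initialization, stepping, resampling,
summarization, and end-to-end recovery behavior."""

import numpy as np
import pytest

import haplosmc.smc as smc
from haplosmc.model import CountData, PriorHyperparams
from haplosmc.simulate import SimulationConfig, simulate, simulate_null
from haplosmc.smc import (
    FilterConfig,
    init_particles,
    resample,
    resample_indices,
    run_filter,
    step,
    summarize_posterior,
)


def harmonic(T):
    return float((1.0 / np.arange(1, T + 1)).sum())


class TestInitParticles:
    def test_background_only_at_start(self, rng):
        cloud = init_particles(FilterConfig(n_particles=5, n_passes=1), 3, rng)
        assert (cloud.n_columns() == 0).all()
        state = cloud.particle(0)
        assert state.params.theta.shape == (1, 3)
        assert cloud.weights == pytest.approx(np.full(5, 0.2))

    def test_noise_prior_moments(self, rng):
        hyper = PriorHyperparams()
        config = FilterConfig(n_particles=20_000, n_passes=1, hyper=hyper)
        cloud = init_particles(config, 2, rng)
        beta_mean = hyper.a00 / (hyper.a00 + hyper.b00)
        assert cloud.p.mean() == pytest.approx(beta_mean, abs=0.002)


class TestResample:
    def test_degenerate_weights_clone_the_winner(self, rng):
        config = FilterConfig(n_particles=6, n_passes=1)
        cloud = init_particles(config, 2, rng)
        w = np.zeros(6)
        w[2] = 1.0
        winner_theta = cloud.theta[2].copy()
        resample(cloud, w, rng)
        assert (cloud.theta == winner_theta[None]).all()

    def test_offspring_counts_unbiased(self, rng):
        w = np.array([0.05, 0.1, 0.15, 0.3, 0.4])
        n, reps = 5, 10_000
        counts = np.zeros(5)
        for _ in range(reps):
            idx = resample_indices(w, n, rng)
            counts += np.bincount(idx, minlength=5)
        mean = counts / reps
        se = np.sqrt(n * w * (1 - w) / reps)
        assert (np.abs(mean - n * w) < 3 * se + 1e-9).all()

    def test_systematic_scheme_unbiased(self, rng):
        w = np.array([0.2, 0.5, 0.3])
        counts = np.zeros(3)
        reps = 10_000
        for _ in range(reps):
            counts += np.bincount(
                resample_indices(w, 3, rng, "systematic"), minlength=3
            )
        assert counts / reps == pytest.approx(3 * w, abs=0.05)

    def test_offspring_are_independent_copies(self, rng):
        config = FilterConfig(n_particles=4, n_passes=1)
        cloud = init_particles(config, 2, rng)
        resample(cloud, np.array([1.0, 0, 0, 0]), rng)
        cloud.theta[0, 0, 0] = 123.0
        assert cloud.theta[1, 0, 0] != 123.0

    def test_zero_weights_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            resample_indices(np.zeros(3), 3, rng)


class TestStep:
    def test_single_particle_grows_one_row(self, rng):
        config = FilterConfig(n_particles=1, n_passes=1)
        cloud = init_particles(config, 2, rng)
        step(cloud, 1, np.array([3, 1]), np.array([10, 10]), config, rng)
        assert cloud.t == 1
        assert cloud.reconstruct_Z().shape[1] == 1
        assert cloud.weights == pytest.approx([1.0])

    def test_weight_normalization_example(self):
        # two particles whose per-row likelihoods are in ratio 3:1 get
        # normalized weights (0.75, 0.25) before resampling
        log_w = np.log(np.array([3.0, 1.0]))
        from scipy.special import logsumexp

        w = np.exp(log_w - logsumexp(log_w))
        assert w == pytest.approx([0.75, 0.25])

    def test_impossible_row_aborts_with_index(self, rng):
        config = FilterConfig(n_particles=3, n_passes=1)
        cloud = init_particles(config, 1, rng)
        with pytest.raises(RuntimeError, match="SNV index 1"):
            smc._weigh_and_resample(
                cloud, np.full(3, -np.inf), 1, config, rng
            )

    def test_time_index_contract(self, rng):
        config = FilterConfig(n_particles=2, n_passes=1)
        cloud = init_particles(config, 1, rng)
        with pytest.raises(ValueError, match="time index"):
            step(cloud, 5, np.array([1]), np.array([2]), config, rng)

    def test_constant_likelihood_recovers_ibp_prior(self, rng):
        # rows with v = 0 make every particle's likelihood equal, so the
        # forward filter must reproduce the IBP column-count law
        T, N = 3, 5000
        config = FilterConfig(n_particles=N, n_passes=1)
        cloud = init_particles(config, 2, rng)
        zero = np.zeros(2, dtype=int)
        for t in range(1, T + 1):
            step(cloud, t, zero, zero, config, rng)
        lam = 1.0 * harmonic(T)
        # resampling at uniform weights inflates the Monte-Carlo error;
        # allow a generous band around the Poisson mean
        assert cloud.n_columns().mean() == pytest.approx(lam, abs=0.2)

    def test_evidence_finite_on_positive_depth(self, rng):
        data, _ = simulate(SimulationConfig(T=10, S=3, C=2, r=30, seed=0))
        fit = run_filter(data, FilterConfig(n_particles=50, n_passes=1, seed=1))
        assert np.isfinite(fit.log_evidence)


class TestSummarize:
    def _make_cloud(self, Z_list, theta_list, p_list):
        n = len(Z_list)
        T = Z_list[0].shape[0]
        cap = max(Z.shape[1] for Z in Z_list)
        S = theta_list[0].shape[1]
        cloud = smc.ParticleCloud(n, S, capacity=cap)
        cloud.t = T
        dense = np.zeros((n, T, cap), dtype=np.int8)
        for i, (Z, th) in enumerate(zip(Z_list, theta_list)):
            k = Z.shape[1]
            dense[i, :, :k] = Z
            cloud.m[i, :k] = Z.sum(axis=0)
            cloud.active[i] = k
            cloud.theta[i, : k + 1] = th
            cloud.p[i] = p_list[i]
        cloud._base_Z = dense
        cloud._base_t = T
        return cloud

    def test_identical_particles_returned_exactly(self):
        Z = np.array([[1, 0], [1, 1], [0, 1]], dtype=np.int8)
        theta = np.array([[0.1, 0.1], [1.0, 2.0], [2.0, 1.0]])
        cloud = self._make_cloud([Z] * 3, [theta] * 3, [0.05] * 3)
        Z_hat, W_hat, p_hat, C_hat = summarize_posterior(cloud)
        assert C_hat == 2
        assert (Z_hat == Z).all()
        assert W_hat == pytest.approx(theta / theta.sum(axis=0), abs=1e-12)
        assert p_hat == pytest.approx(0.05)

    def test_column_permutation_is_absorbed(self):
        Z = np.array([[1, 0], [1, 0], [0, 1]], dtype=np.int8)
        theta = np.array([[0.2, 0.2], [1.0, 3.0], [2.0, 0.5]])
        perm_theta = np.array([[0.2, 0.2], [2.0, 0.5], [1.0, 3.0]])
        cloud = self._make_cloud(
            [Z, Z[:, ::-1]], [theta, perm_theta], [0.05, 0.05]
        )
        Z_hat, W_hat, _, C_hat = summarize_posterior(cloud)
        assert C_hat == 2
        assert sorted(map(tuple, Z_hat.T)) == sorted(map(tuple, Z.T))

    def test_empty_cloud_rejected(self):
        cloud = smc.ParticleCloud(0, 1)
        with pytest.raises(ValueError, match="empty"):
            summarize_posterior(cloud)


class TestRunFilter:
    def test_smoke_contract(self):
        data = CountData(
            np.array([[2]]), np.array([[10]]), ["L1"], ["s1"]
        )
        fit = run_filter(data, FilterConfig(n_particles=1, n_passes=1, seed=0))
        assert fit.Z_hat.shape[0] == 1
        assert fit.W_hat.sum(axis=0) == pytest.approx([1.0])

    def test_reproducible_given_seed(self):
        data, _ = simulate(SimulationConfig(T=15, S=3, C=2, r=100, seed=2))
        config = FilterConfig(n_particles=50, n_passes=2, seed=11)
        f1 = run_filter(data, config)
        f2 = run_filter(data, config)
        assert (f1.Z_hat == f2.Z_hat).all()
        assert f1.W_hat == pytest.approx(f2.W_hat)
        assert f1.p_hat == f2.p_hat

    def test_restart_mode_reports_best_evidence(self):
        data, _ = simulate(SimulationConfig(T=10, S=3, C=2, r=100, seed=3))
        fit = run_filter(
            data,
            FilterConfig(n_particles=30, n_passes=3, seed=5, pass_mode="restart"),
        )
        assert len(fit.pass_log_evidences) == 3
        assert fit.log_evidence == max(fit.pass_log_evidences)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_null_data_recovers_background_model(self, seed):
        data, _ = simulate_null(T=40, S=5, r=1000, p_true=0.02, seed=seed)
        fit = run_filter(
            data, FilterConfig(n_particles=200, n_passes=3, seed=seed + 10)
        )
        assert fit.C_hat <= 1
        assert abs(fit.p_hat - 0.02) <= 0.02

    def test_posterior_vaf_consistency_improves_with_particles(self):
        from haplosmc.evaluate import compute_errors

        data, truth = simulate(SimulationConfig(T=30, S=5, C=3, r=1000, seed=6))
        small = run_filter(data, FilterConfig(n_particles=30, n_passes=2, seed=7))
        large = run_filter(data, FilterConfig(n_particles=300, n_passes=2, seed=7))
        e_small = compute_errors(small, truth).e_pts
        e_large = compute_errors(large, truth).e_pts
        assert e_large < 0.05
        assert e_large <= e_small + 0.01

    def test_online_extension_continues_the_fit(self):
        data, truth = simulate(SimulationConfig(T=30, S=4, C=2, r=500, seed=8))
        Y, V = data.variant_counts, data.total_counts
        first = CountData(Y[:20], V[:20], data.locus_ids[:20], data.sample_ids)
        rest = CountData(Y[20:], V[20:], data.locus_ids[20:], data.sample_ids)
        config = FilterConfig(n_particles=100, n_passes=2, seed=9)
        base = run_filter(first, config)
        extended = run_filter(rest, config, initial_cloud=base.particle_cloud)
        assert extended.Z_hat.shape[0] == 30
        assert np.isfinite(extended.log_evidence)
        # the original cloud is untouched (copies only)
        assert base.particle_cloud.t == 20
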