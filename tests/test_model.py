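"""Expected-VAF construction, binomial likelihood and parameter dynamics."""

import numpy as np
import pytest
from scipy import stats

from haplosmc.model import (
    CountData,
    NoiseParam,
    PriorHyperparams,
    ProportionParams,
    draw_initial_params,
    expected_vaf,
    log_likelihood_row,
    propagate_params,
)


class TestCountData:
    def test_variant_exceeding_total_names_cell(self):
        with pytest.raises(ValueError, match="locus 'L2', sample 'B'"):
            CountData(
                np.array([[0, 0], [0, 5]]),
                np.array([[2, 2], [2, 4]]),
                ["L1", "L2"],
                ["A", "B"],
            )


class TestExpectedVaf:
    def test_background_only(self):
        props = ProportionParams(np.ones((1, 3)))
        out = expected_vaf(np.zeros(0), props, NoiseParam(0.02))
        assert out == pytest.approx([0.02] * 3)

    def test_single_haplotype_saturation(self):
        # theta_1 / theta_0 -> inf drives the VAF to 1
        props = ProportionParams(np.array([[1e-9], [1.0]]))
        out = expected_vaf(np.array([1]), props, NoiseParam(0.02))
        assert out[0] == pytest.approx(1.0, abs=1e-6)

    def test_matches_elementwise_oracle(self, rng):
        for _ in range(20):
            theta = rng.gamma(1.0, 1.0, size=(4, 1)) + 1e-3
            props = ProportionParams(theta)
            z = (rng.random(3) < 0.5).astype(int)
            p = float(rng.uniform(0.01, 0.1))
            w = theta / theta.sum(axis=0)
            oracle = w[0, 0] * p + sum(z[c] * w[c + 1, 0] for c in range(3))
            out = expected_vaf(z, props, NoiseParam(p))
            assert out[0] == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch_rejected(self):
        props = ProportionParams(np.ones((3, 2)))
        with pytest.raises(ValueError, match="haplotypes"):
            expected_vaf(np.array([1]), props, NoiseParam(0.02))

    def test_monotone_in_carried_theta(self):
        base = np.array([[0.5, 0.5], [1.0, 1.0], [2.0, 2.0]])
        z = np.array([1, 0])
        lo = expected_vaf(z, ProportionParams(base), NoiseParam(0.02))
        bumped = base.copy()
        bumped[1] += 1.0
        hi = expected_vaf(z, ProportionParams(bumped), NoiseParam(0.02))
        assert (hi >= lo).all()


class TestLogLikelihoodRow:
    def test_certain_success(self):
        ll = log_likelihood_row(np.array([2]), np.array([2]), np.array([1.0]))
        assert ll == pytest.approx(0.0, abs=1e-9)

    def test_closed_form(self):
        ll = log_likelihood_row(np.array([1]), np.array([2]), np.array([0.5]))
        assert ll == pytest.approx(np.log(0.5))

    def test_matches_scipy_product_oracle(self, rng):
        for _ in range(20):
            v = rng.integers(1, 50, size=4)
            p = rng.uniform(0.05, 0.95, size=4)
            y = rng.binomial(v, p)
            oracle = float(np.log(stats.binom.pmf(y, v, p)).sum())
            assert log_likelihood_row(y, v, p) == pytest.approx(oracle, abs=1e-10)

    def test_contract_violation(self):
        with pytest.raises(ValueError, match="exceed"):
            log_likelihood_row(np.array([3]), np.array([2]), np.array([0.5]))

    def test_invariant_under_column_permutation(self, rng):
        theta = rng.gamma(1.0, 1.0, size=(4, 5)) + 1e-3
        z = np.array([1, 0, 1])
        p = NoiseParam(0.02)
        y = rng.integers(0, 10, size=5)
        v = y + rng.integers(0, 10, size=5)
        perm = [2, 0, 1]
        base = log_likelihood_row(
            y, v, expected_vaf(z, ProportionParams(theta), p)
        )
        theta_p = np.vstack([theta[:1], theta[1:][perm]])
        permuted = log_likelihood_row(
            y, v, expected_vaf(z[perm], ProportionParams(theta_p), p)
        )
        assert base == pytest.approx(permuted, abs=1e-12)


class TestDynamics:
    def test_sigma_zero_is_identity(self, rng):
        hyper = PriorHyperparams(sigma=0.0)
        props = ProportionParams(np.array([[0.4], [1.2]]))
        noise = NoiseParam(0.02)
        out_p, out_n = propagate_params((props, noise), hyper, rng)
        assert (out_p.theta == props.theta).all()
        assert out_n.p == noise.p

    def test_interior_moves_have_sigma_std(self, rng):
        hyper = PriorHyperparams(sigma=0.1)
        n = 100_000
        start = ProportionParams(np.full((1, 1), 5.0))  # far from boundary
        moves = np.empty(n)
        for i in range(n):
            out, _ = propagate_params((start, NoiseParam(0.5)), hyper, rng)
            moves[i] = out.theta[0, 0] - 5.0
        assert moves.std() == pytest.approx(0.1, rel=0.02)
        assert abs(moves.mean()) < 3 * 0.1 / np.sqrt(n)

    def test_noise_rate_stays_in_unit_interval(self, rng):
        hyper = PriorHyperparams(sigma=2.0)
        state = (ProportionParams(np.ones((2, 2))), NoiseParam(0.99))
        for _ in range(200):
            state = propagate_params(state, hyper, rng)
            assert 0.0 < state[1].p < 1.0
            assert (state[0].theta > 0).all()


class TestInitialDraws:
    def test_gamma_and_beta_moments(self, rng):
        hyper = PriorHyperparams()
        n = 20_000
        theta0 = np.empty(n)
        ps = np.empty(n)
        for i in range(n):
            props, noise = draw_initial_params(1, 0, hyper, rng)
            theta0[i] = props.theta[0, 0]
            ps[i] = noise.p
        assert theta0.mean() == pytest.approx(
            hyper.a0, abs=3 * np.sqrt(hyper.a0 / n)
        )
        beta_mean = hyper.a00 / (hyper.a00 + hyper.b00)
        assert ps.mean() == pytest.approx(beta_mean, abs=0.002)

    def test_no_haplotypes_gives_unit_background(self, rng):
        props, _ = draw_initial_params(4, 0, PriorHyperparams(), rng)
        assert props.weights.shape == (1, 4)
        assert props.weights == pytest.approx(np.ones((1, 4)))

    def test_weights_columns_sum_to_one(self, rng):
        props, _ = draw_initial_params(3, 5, PriorHyperparams(), rng)
        assert props.weights.sum(axis=0) == pytest.approx(np.ones(3), abs=1e-12)
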