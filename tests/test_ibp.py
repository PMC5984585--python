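"""Indian buffet process construction and left-ordered pmf."""

import itertools

import numpy as np
import pytest
from scipy import stats

from haplosmc.ibp import (
    HaplotypeMatrix,
    IBPConfig,
    append_row,
    ibp_log_pmf,
    left_order,
    sample_matrix,
    sample_next_row,
)


def harmonic(T):
    return float((1.0 / np.arange(1, T + 1)).sum())


class TestSampleNextRow:
    def test_first_row_alpha_zero_is_empty(self, rng):
        row, n_new = sample_next_row(
            HaplotypeMatrix.empty(), 1, IBPConfig(alpha=0.0), rng
        )
        assert row.shape == (0,)
        assert n_new == 0

    def test_row_index_contract(self, rng):
        with pytest.raises(ValueError, match="inconsistent"):
            sample_next_row(HaplotypeMatrix.empty(), 2, IBPConfig(), rng)

    def test_existing_column_inclusion_is_m_over_t(self, rng):
        # one previous row carrying the column: P(z_21 = 1) = 1/2
        prev = HaplotypeMatrix(np.array([[1]]))
        config = IBPConfig(alpha=0.0)
        n = 40_000
        hits = sum(
            int(sample_next_row(prev, 2, config, rng)[0][0]) for _ in range(n)
        )
        se = np.sqrt(0.25 / n)
        assert abs(hits / n - 0.5) < 3 * se

    def test_new_columns_follow_poisson(self, rng):
        # first customer: n_new ~ Pois(alpha)
        alpha, n = 2.0, 100_000
        draws = np.array(
            [
                sample_next_row(HaplotypeMatrix.empty(), 1, IBPConfig(alpha), rng)[1]
                for _ in range(n)
            ]
        )
        kmax = 10
        observed = np.bincount(np.minimum(draws, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax), alpha)
        expected = np.append(pmf, 1.0 - pmf.sum()) * n
        chi2 = stats.chisquare(observed, expected)
        assert chi2.pvalue > 1e-3

    def test_append_preserves_earlier_rows(self, rng):
        config = IBPConfig(alpha=1.0)
        Z = HaplotypeMatrix.empty()
        prev_entries = Z.entries.copy()
        for t in range(1, 9):
            row, _ = sample_next_row(Z, t, config, rng)
            Z = append_row(Z, row)
            assert (Z.entries[: t - 1, : prev_entries.shape[1]] == prev_entries).all()
            prev_entries = Z.entries.copy()
            # column counts never decrease and never exceed t
            assert (Z.column_counts >= 1).all()
            assert (Z.column_counts <= t).all()


class TestLeftOrder:
    def test_first_row_one_moves_left(self):
        out = left_order(np.array([[0, 1], [1, 0]], dtype=np.int8))
        assert (out == np.array([[1, 0], [0, 1]])).all()

    def test_idempotent_on_random_matrices(self, rng):
        for _ in range(50):
            Z = (rng.random((5, 4)) < 0.5).astype(np.int8)
            once = left_order(Z)
            assert (left_order(once) == once).all()

    def test_stable_for_equal_histories(self):
        Z = np.array([[1, 0, 1], [0, 1, 0]], dtype=np.int8)
        out = left_order(Z)
        # two identical '10' histories keep their relative order
        assert (out == np.array([[1, 1, 0], [0, 0, 1]])).all()


class TestLogPmf:
    def test_zero_column_matrix(self):
        ev = ibp_log_pmf(np.zeros((3, 0), dtype=np.int8), IBPConfig(alpha=1.0))
        assert ev.log_pmf == pytest.approx(-harmonic(3))
        assert ev.c_plus == 0

    def test_all_zero_column_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            ibp_log_pmf(np.array([[1, 0], [1, 0]], dtype=np.int8), IBPConfig())

    def test_total_mass_sums_to_one(self):
        # T = 2: non-zero column histories are (0,1), (1,0), (1,1); a
        # left-ordered matrix is a multiset of them.  Summing the pmf
        # over all multisets up to size K approaches 1.
        config = IBPConfig(alpha=1.0)
        histories = [(0, 1), (1, 0), (1, 1)]
        total = np.exp(ibp_log_pmf(np.zeros((2, 0), np.int8), config).log_pmf)
        K = 8
        for k1, k2, k3 in itertools.product(range(K + 1), repeat=3):
            if k1 + k2 + k3 == 0:
                continue
            cols = [histories[0]] * k1 + [histories[1]] * k2 + [histories[2]] * k3
            Z = np.array(cols, dtype=np.int8).T
            total += np.exp(ibp_log_pmf(Z, config).log_pmf)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_sampler_frequencies_match_pmf(self, rng):
        config = IBPConfig(alpha=0.5)
        n = 100_000
        counts = {}
        for _ in range(n):
            Z = left_order(sample_matrix(2, config, rng))
            counts[Z.entries.tobytes() + bytes([Z.column_count])] = (
                counts.get(Z.entries.tobytes() + bytes([Z.column_count]), 0) + 1
            )
        # check the most frequent left-ordered forms against the pmf
        checked = 0
        for key, c in sorted(counts.items(), key=lambda kv: -kv[1])[:6]:
            k = key[-1]
            Z = np.frombuffer(key[:-1], dtype=np.int8).reshape(2, k)
            p = np.exp(ibp_log_pmf(Z, config).log_pmf)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(c / n - p) < 3 * se + 1e-12
            checked += 1
        assert checked >= 4

    @pytest.mark.parametrize("T", [5, 10])
    @pytest.mark.parametrize("alpha", [0.5, 1.0, 2.0])
    def test_expected_column_count_is_alpha_harmonic(self, T, alpha, rng):
        # C+ after T rows is Poisson(alpha * H_T)
        lam = alpha * harmonic(T)
        n = 10_000
        config = IBPConfig(alpha=alpha)
        counts = np.array(
            [sample_matrix(T, config, rng).column_count for _ in range(n)]
        )
        se = np.sqrt(lam / n)
        assert abs(counts.mean() - lam) < 3 * se
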