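"""Tests of the permutation-matched reconstruction metrics."""

import itertools

import numpy as np
import pytest

from smclone.metrics import (
    evaluate_estimate,
    genotype_error,
    match_columns,
    proportion_error,
    pts_error,
)


def brute_force_min_error(Z_hat, Z_true):
    """Exhaustive-permutation oracle for the minimum genotype error."""
    C = Z_true.shape[1]
    best = np.inf
    for perm in itertools.permutations(range(C)):
        err = np.mean(np.abs(Z_hat[:, list(perm)] - Z_true))
        best = min(best, err)
    return best


class TestMatchColumns:
    def test_identity_when_equal(self, rng):
        Z = rng.choice([0.0, 0.5, 1.0], size=(8, 4))
        perm = match_columns(Z, Z)
        assert genotype_error(Z, Z, perm) == 0.0

    def test_recovers_column_swap(self, rng):
        Z = rng.choice([0.0, 0.5, 1.0], size=(10, 3))
        while np.unique(Z, axis=1).shape[1] < 3:  # ensure distinct columns
            Z = rng.choice([0.0, 0.5, 1.0], size=(10, 3))
        shuffled = Z[:, [2, 0, 1]]
        perm = match_columns(shuffled, Z)
        np.testing.assert_array_equal(shuffled[:, perm], Z)

    @pytest.mark.parametrize("n_cols", [2, 3, 4, 5, 6])
    def test_assignment_equals_exhaustive_search(self, rng, n_cols):
        for _ in range(20):
            Z_true = rng.choice([0.0, 0.5, 1.0], size=(12, n_cols))
            Z_hat = rng.choice([0.0, 0.5, 1.0], size=(12, n_cols))
            perm = match_columns(Z_hat, Z_true)
            got = genotype_error(Z_hat, Z_true, perm)
            assert got == pytest.approx(brute_force_min_error(Z_hat, Z_true))

    def test_unequal_widths_are_padded(self, rng):
        Z_true = rng.choice([0.5, 1.0], size=(6, 3))
        Z_hat = Z_true[:, :2]
        perm = match_columns(Z_hat, Z_true)
        assert len(perm) == 3
        report = evaluate_estimate(
            Z_hat, np.vstack([np.full((1, 2), 0.1), np.full((2, 2), 0.45)]),
            0.02, Z_true, np.full((4, 2), 0.25),
            np.zeros((6, 2)),
        )
        assert report.columns_padded

    def test_empty_matrices_rejected(self):
        with pytest.raises(ValueError):
            match_columns(np.zeros((3, 0)), np.zeros((3, 0)))


class TestGenotypeError:
    def test_single_column_example(self):
        Z_hat = np.array([[0.0], [0.5]])
        Z_true = np.array([[1.0], [0.5]])
        assert genotype_error(Z_hat, Z_true, np.array([0])) == pytest.approx(0.5)

    def test_maximum_deviation_is_one(self):
        Z_hat = np.zeros((4, 2))
        Z_true = np.ones((4, 2))
        assert genotype_error(Z_hat, Z_true, np.arange(2)) == pytest.approx(1.0)

    def test_invariant_to_shared_permutation(self, rng):
        Z = rng.choice([0.0, 0.5, 1.0], size=(9, 4))
        Z_hat = rng.choice([0.0, 0.5, 1.0], size=(9, 4))
        perm = match_columns(Z_hat, Z)
        e = genotype_error(Z_hat, Z, perm)
        order = rng.permutation(4)
        perm2 = match_columns(Z_hat[:, order], Z[:, order])
        e2 = genotype_error(Z_hat[:, order], Z[:, order], perm2)
        assert e == pytest.approx(e2)


class TestProportionError:
    def test_printed_formula_divides_by_c_times_s(self):
        # C=1, S=1: rows (noise, one subclone); sum of |diff| over BOTH rows
        W_hat = np.array([[0.4], [0.6]])
        W_true = np.array([[0.2], [0.8]])
        got = proportion_error(W_hat, W_true, np.array([0]))
        assert got == pytest.approx(0.4)  # (0.2 + 0.2) / (1 * 1)

    def test_identical_matrices_give_zero(self, rng):
        W = rng.dirichlet(np.ones(4), size=5).T
        assert proportion_error(W, W, np.arange(3)) == 0.0

    def test_swapping_identical_rows_changes_nothing(self):
        W_hat = np.array([[0.2, 0.2], [0.4, 0.4], [0.4, 0.4]])
        W_true = np.array([[0.1, 0.1], [0.5, 0.3], [0.4, 0.6]])
        e01 = proportion_error(W_hat, W_true, np.array([0, 1]))
        e10 = proportion_error(W_hat, W_true, np.array([1, 0]))
        assert e01 == pytest.approx(e10)


class TestPtsError:
    def test_perfect_estimate_gives_zero(self, rng):
        Z = rng.choice([0.0, 0.5, 1.0], size=(6, 3))
        W = rng.dirichlet(np.ones(4), size=4).T
        p = 0.02
        from smclone.observation import success_probability_matrix
        P = success_probability_matrix(Z, W, p)
        assert pts_error(Z, W, p, P) == 0.0

    def test_constant_offset_recovered(self, rng):
        Z = rng.choice([0.0, 0.5], size=(5, 2))
        W = rng.dirichlet(np.ones(3), size=3).T
        from smclone.observation import success_probability_matrix
        P = success_probability_matrix(Z, W, 0.02)
        assert pts_error(Z, W, 0.02, P + 0.07) == pytest.approx(0.07)

    def test_invariant_to_consistent_permutation(self, rng):
        Z = rng.choice([0.0, 0.5, 1.0], size=(7, 3))
        W = rng.dirichlet(np.ones(4), size=5).T
        from smclone.observation import success_probability_matrix
        P = success_probability_matrix(Z, W, 0.05) + 0.01
        order = np.array([2, 0, 1])
        e1 = pts_error(Z, W, 0.05, P)
        e2 = pts_error(Z[:, order], np.vstack([W[0:1], W[1:][order]]), 0.05, P)
        assert e1 == pytest.approx(e2)


class TestBinaryModeConvention:
    def test_estimated_homozygous_mapped_to_half(self):
        Z_true = np.array([[0.5], [0.0], [0.5]])
        Z_hat = np.array([[1.0], [0.0], [0.5]])  # the 1 should count as 0.5
        W = np.array([[0.5], [0.5]])
        P = np.zeros((3, 1))
        report = evaluate_estimate(Z_hat, W, 0.0, Z_true, W, P,
                                   binary_mode=True)
        assert report.e_Z == 0.0
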