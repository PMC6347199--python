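"""Tests of the particle-filter engine."""

import numpy as np
import pytest

from smclone.cibp import CIBPParams, sample_genotype_matrix
from smclone.observation import ReadCountData
from smclone.smc import (
    DegenerateWeightsError,
    Particle,
    SMCConfig,
    init_particles,
    normalize_log_weights,
    propagate,
    resample,
    run,
    summarize,
    weight_update,
)


def make_particle(Z, theta, p=0.02, log_weight=0.0):
    return Particle(Z=np.asarray(Z, dtype=float),
                    theta=np.asarray(theta, dtype=float),
                    p=p, log_weight=log_weight)


class TestInit:
    def test_uniform_weights_and_shapes(self, rng):
        config = SMCConfig(n_particles=3)
        parts = init_particles(config, n_samples=4, rng=rng)
        assert len(parts) == 3
        for q in parts:
            assert q.Z.shape == (0, 0)
            assert q.theta.shape == (1, 4)
            assert q.log_weight == pytest.approx(-np.log(3))
            np.testing.assert_allclose(q.W.sum(axis=0), 1.0)

    def test_noise_rate_prior_mean(self, rng):
        config = SMCConfig(n_particles=2, a00=1.0, b00=30.0)
        ps = []
        for _ in range(5000):
            ps.extend(q.p for q in init_particles(config, 2, rng))
        mean = 1.0 / 31.0
        se = np.std(ps, ddof=1) / np.sqrt(len(ps))
        assert abs(np.mean(ps) - mean) < 3 * se

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SMCConfig(n_particles=1)
        with pytest.raises(ValueError):
            SMCConfig(a0=0)
        with pytest.raises(ValueError):
            SMCConfig(resampling="stratified")
        with pytest.raises(ValueError):
            SMCConfig(proposal="optimal")


class TestPropagate:
    def test_no_new_columns_keeps_theta_rows(self, rng):
        config = SMCConfig(cibp=CIBPParams(alpha=1e-9))
        q = make_particle([[0.5, 1.0]], np.ones((3, 4)))
        moved = propagate(q, 2, config, rng)
        assert moved.Z.shape == (2, 2)
        assert moved.theta.shape == (3, 4)

    def test_new_columns_extend_theta_and_pad_history(self, rng):
        config = SMCConfig(cibp=CIBPParams(alpha=200.0))
        q = make_particle([[0.5]], np.ones((2, 3)))
        moved = propagate(q, 2, config, rng)
        d = moved.Z.shape[1] - 1
        assert d >= 1  # alpha/t = 100 new columns on average
        assert moved.theta.shape == (2 + d, 3)
        np.testing.assert_array_equal(moved.Z[0, 1:], np.zeros(d))

    def test_zero_sigma_freezes_parameters(self, rng):
        config = SMCConfig(sigma_theta=0.0, sigma_p=0.0,
                           cibp=CIBPParams(alpha=1e-9))
        theta = np.array([[0.4, 1.2], [0.7, 0.9]])
        q = make_particle([[1.0]], theta, p=0.33)
        moved = propagate(q, 2, config, rng)
        np.testing.assert_array_equal(moved.theta, theta)
        assert moved.p == 0.33

    def test_input_particle_untouched(self, rng):
        config = SMCConfig()
        q = make_particle([[0.5]], np.ones((2, 3)))
        snapshot = (q.Z.copy(), q.theta.copy(), q.p)
        propagate(q, 2, config, rng)
        np.testing.assert_array_equal(q.Z, snapshot[0])
        np.testing.assert_array_equal(q.theta, snapshot[1])

    def test_wrong_time_index_rejected(self, rng):
        q = make_particle([[0.5]], np.ones((2, 2)))
        with pytest.raises(ValueError):
            propagate(q, 4, SMCConfig(), rng)


class TestWeightUpdate:
    def test_zero_depth_leaves_weight_unchanged(self):
        q = make_particle([[0.5, 1.0]], np.ones((3, 2)))
        got = weight_update(-1.7, np.zeros(2), np.zeros(2), q)
        assert got == pytest.approx(-1.7)

    def test_higher_likelihood_gives_larger_weight(self):
        # particle whose success probabilities match the data better wins
        theta_good = np.array([[0.01], [1.0]])
        theta_bad = np.array([[1.0], [0.01]])
        good = make_particle([[1.0]], theta_good)  # pts ~ 1 -> fits y=v
        bad = make_particle([[1.0]], theta_bad)
        y, v = np.array([98]), np.array([100])
        assert weight_update(0.0, y, v, good) > weight_update(0.0, y, v, bad)

    def test_normalized_weights_sum_to_one(self, rng):
        lw = rng.normal(size=50) * 30
        w, ess = normalize_log_weights(lw)
        assert w.sum() == pytest.approx(1.0, abs=1e-10)
        assert 1.0 <= ess <= 50.0


class TestResample:
    def test_point_mass_duplicates_winner(self, rng):
        parts = [make_particle([[0.5]], np.ones((2, 2)), p=0.1 * (i + 1))
                 for i in range(4)]
        weights = np.array([0.0, 1.0, 0.0, 0.0])
        out = resample(parts, weights, rng)
        assert all(q.p == pytest.approx(0.2) for q in out)
        assert all(q.log_weight == pytest.approx(-np.log(4)) for q in out)

    def test_offspring_are_independent_copies(self, rng):
        parts = [make_particle([[0.5]], np.ones((2, 2)))] * 2
        out = resample(parts, np.array([0.5, 0.5]), rng)
        out[0].Z[0, 0] = 1.0
        assert out[1].Z[0, 0] == 0.5

    def test_uniform_weights_preserve_mean_offspring(self, rng):
        n = 8
        parts = [make_particle([[0.5]], np.ones((2, 2)), p=i / 10)
                 for i in range(n)]
        counts = np.zeros(n)
        reps = 4000
        for _ in range(reps):
            out = resample(parts, np.full(n, 1 / n), rng)
            for q in out:
                counts[int(round(q.p * 10))] += 1
        mean = counts / reps
        se = np.sqrt(1.0 * (1 - 1 / n) / reps)  # binomial-ish count scale
        assert np.all(np.abs(mean - 1.0) < 4 * se)

    def test_resampling_preserves_weighted_means(self, rng):
        # unbiasedness: E[mean of statistic after resampling] = weighted mean
        n = 10
        values = np.arange(n, dtype=float)
        parts = [make_particle([[0.5]], np.ones((2, 1)), p=0.01 + 0.05 * i)
                 for i in range(n)]
        raw = rng.random(n)
        weights = raw / raw.sum()
        target = float(np.sum(weights * values))
        reps = 4000
        means = []
        for _ in range(reps):
            out = resample(parts, weights, rng)
            means.append(np.mean([round((q.p - 0.01) / 0.05) for q in out]))
        se = np.std(means, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(means) - target) < 3 * se

    def test_all_zero_weights_raise(self, rng):
        parts = [make_particle([[0.5]], np.ones((2, 2)))] * 3
        with pytest.raises(DegenerateWeightsError):
            resample(parts, np.zeros(3), rng)


class TestSummarize:
    def test_single_particle_summary_is_exact(self):
        Z = np.array([[0.5, 1.0], [0.0, 0.5]])
        theta = np.array([[0.1, 0.2], [0.6, 0.5], [0.3, 0.3]])
        q = make_particle(Z, theta, p=0.03)
        s = summarize([q], np.array([1.0]))
        assert s.c_map == 2
        np.testing.assert_array_equal(s.Z_hat, Z)
        np.testing.assert_allclose(s.W_hat, q.W, atol=1e-12)
        assert s.p_hat == pytest.approx(0.03)

    def test_identical_particles_give_point_mass(self):
        Z = np.array([[1.0]])
        parts = [make_particle(Z, np.ones((2, 2))) for _ in range(5)]
        s = summarize(parts, np.full(5, 0.2))
        assert s.c_pmf == {1: pytest.approx(1.0)}

    def test_genotype_tie_breaks_to_smaller_value(self):
        a = make_particle(np.array([[0.0]]), np.ones((2, 1)))
        b = make_particle(np.array([[1.0]]), np.ones((2, 1)))
        s = summarize([a, b], np.array([0.5, 0.5]))
        assert s.Z_hat[0, 0] == 0.0

    def test_map_tie_breaks_to_smaller_count(self):
        a = make_particle(np.array([[1.0]]), np.ones((2, 1)))
        b = make_particle(np.array([[1.0, 0.5]]), np.ones((3, 1)))
        s = summarize([a, b], np.array([0.5, 0.5]))
        assert s.c_map == 1


class TestRun:
    def test_empty_input_rejected(self):
        data = ReadCountData(Y=np.zeros((0, 3), dtype=int),
                             V=np.zeros((0, 3), dtype=int))
        with pytest.raises(ValueError):
            run(data, SMCConfig(n_particles=10))

    def test_identical_seeds_give_identical_summaries(self):
        from smclone.simulate import SimConfig, simulate_dataset
        data, _ = simulate_dataset(SimConfig(C=2, S=3, T=6, r=50, seed=5))
        config = SMCConfig(n_particles=40, seed=7)
        _, s1 = run(data, config)
        _, s2 = run(data, config)
        assert s1.c_pmf == s2.c_pmf
        np.testing.assert_array_equal(s1.Z_hat, s2.Z_hat)
        np.testing.assert_array_equal(s1.W_hat, s2.W_hat)
        assert s1.p_hat == s2.p_hat

    def test_prior_mode_matches_cibp_column_distribution(self, rng):
        # with all-zero depths the likelihood is flat, so the filter must
        # reproduce the prior distribution of column counts
        T = 5
        alpha = 1.0
        data = ReadCountData(Y=np.zeros((T, 2), dtype=int),
                             V=np.zeros((T, 2), dtype=int))
        config = SMCConfig(n_particles=3000, seed=3, proposal="prior",
                           cibp=CIBPParams(alpha=alpha))
        particles, _ = run(data, config)
        counts = np.array([q.n_columns for q in particles])
        prior_counts = np.array([
            sample_genotype_matrix(T, CIBPParams(alpha=alpha), rng).shape[1]
            for _ in range(3000)
        ])
        expected = alpha * np.sum(1.0 / np.arange(1, T + 1))
        se = np.sqrt(np.var(prior_counts, ddof=1) / 3000 +
                     np.var(counts, ddof=1) / 3000)
        assert abs(counts.mean() - prior_counts.mean()) < 3 * se
        assert abs(counts.mean() - expected) < 4 * se

    def test_ess_trace_is_recorded_and_bounded(self):
        from smclone.simulate import SimConfig, simulate_dataset
        data, _ = simulate_dataset(SimConfig(C=2, S=3, T=5, r=50, seed=2))
        config = SMCConfig(n_particles=30, seed=1)
        _, summary = run(data, config)
        assert len(summary.ess_trace) == 5
        assert all(1.0 <= e <= 30.0 + 1e-9 for e in summary.ess_trace)

    def test_guided_recovers_structure_on_easy_instance(self):
        # smoke-level parameter recovery on a small, well-separated dataset
        from smclone.simulate import SimConfig, simulate_dataset
        from smclone.metrics import evaluate_estimate
        data, truth = simulate_dataset(SimConfig(C=2, S=8, T=15, r=200, seed=21))
        config = SMCConfig(n_particles=200, seed=4, resampling="systematic")
        _, s = run(data, config)
        rep = evaluate_estimate(s.Z_hat, s.W_hat, s.p_hat,
                                truth.Z_true, truth.W_true, truth.P_true)
        assert abs(s.c_map - 2) <= 1
        assert rep.e_pts < 0.2
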