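import itertools

import numpy as np
import pytest
from scipy import stats

from asymadstrat.cohort import CohortError
from asymadstrat.ebm import (
    BiomarkerMixture,
    EbmConfig,
    EbmState,
    fast_config,
    fit_ebm,
    fit_mixtures,
    greedy_init,
    mcmc_sample,
    planted_order_distance,
    recalibrate,
    stage_distribution_test,
    stage_subjects,
    state_log_likelihood,
    _random_state,
)
from asymadstrat.synthetic import generate_event_cascade


def make_mixture(n, sep=4.0, names=None):
    return BiomarkerMixture(
        names or [f"b{i}" for i in range(n)],
        normal_mean=np.zeros(n), normal_sd=np.ones(n),
        abnormal_mean=np.full(n, sep), abnormal_sd=np.ones(n),
        weight_normal=np.full(n, 0.5), direction=np.ones(n))


def enumeration_loglik(order, assignment, X, mixtures):
    """Independent plain-loop oracle for the marginal state likelihood."""
    n_clusters = len(order)
    total = 0.0
    for x in X:
        subject = 0.0
        for stage in range(n_clusters + 1):
            abnormal_clusters = set(order[:stage])
            lik = 1.0 / (n_clusters + 1)
            for b, val in enumerate(x):
                if assignment[b] in abnormal_clusters:
                    lik *= stats.norm.pdf(val, mixtures.abnormal_mean[b],
                                          mixtures.abnormal_sd[b])
                else:
                    lik *= stats.norm.pdf(val, mixtures.normal_mean[b],
                                          mixtures.normal_sd[b])
            subject += lik
        total += np.log(subject)
    return total


class TestConfig:
    def test_burn_in_validation(self):
        with pytest.raises(CohortError):
            EbmConfig(mcmc_iterations=100, burn_in=100)

    def test_implicit_feature_exclusion_rejected(self):
        with pytest.raises(CohortError, match="implicit_feature_exclusion"):
            EbmConfig(implicit_feature_exclusion=1)


class TestMixtureFit:
    def test_known_generator_recovery(self):
        rng = np.random.default_rng(0)
        X = np.concatenate([rng.normal(0, 1, 200),
                            rng.normal(3, 1, 200)])[:, None]
        labels = ["Control"] * 200 + ["AD"] * 200
        m = fit_mixtures(X, labels)
        assert abs(m.normal_mean[0] - 0.0) < 0.2
        assert abs(m.abnormal_mean[0] - 3.0) < 0.2

    def test_identical_groups_degenerate_flag(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 100)
        X = np.concatenate([x, x])[:, None]
        labels = ["Control"] * 100 + ["AD"] * 100
        m = fit_mixtures(X, labels)
        assert m.degenerate is not None and m.degenerate[0]

    def test_direction_matches_effect_sign(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([
            np.concatenate([rng.normal(0, 1, 150), rng.normal(2, 1, 150)]),
            np.concatenate([rng.normal(0, 1, 150), rng.normal(-2, 1, 150)]),
        ])
        labels = ["Control"] * 150 + ["AD"] * 150
        m = fit_mixtures(X, labels)
        assert m.direction[0] == 1 and m.direction[1] == -1


class TestLikelihood:
    def test_zero_information_all_states_equal(self, rng):
        m = make_mixture(8, sep=0.0)
        X = rng.normal(size=(20, 8))
        lls = []
        for order in itertools.permutations(range(4)):
            state = EbmState(order, (0, 0, 1, 1, 2, 2, 3, 3))
            lls.append(state_log_likelihood(state, X, m))
        assert np.ptp(lls) < 1e-9

    def test_single_subject_single_cluster_analytic(self):
        m = make_mixture(1, sep=2.0)
        x = np.array([[0.7]])
        state = EbmState((0,), (0,))
        expected = np.log(0.5 * stats.norm.pdf(0.7, 0, 1)
                          + 0.5 * stats.norm.pdf(0.7, 2, 1))
        assert state_log_likelihood(state, x, m) == pytest.approx(
            expected, abs=1e-12)

    def test_all_orderings_match_enumeration_oracle(self, rng):
        m = make_mixture(3, sep=2.5)
        X = rng.normal(size=(10, 3)) + rng.integers(0, 2, (10, 3)) * 2.5
        assignment = (0, 1, 2)
        for order in itertools.permutations(range(3)):
            state = EbmState(order, assignment)
            got = state_log_likelihood(state, X, m)
            want = enumeration_loglik(order, assignment, X, m)
            assert got == pytest.approx(want, abs=1e-10)

    def test_invalid_state_rejected(self, rng):
        m = make_mixture(4)
        X = rng.normal(size=(5, 4))
        with pytest.raises(CohortError):
            state_log_likelihood(EbmState((0, 0), (0, 0, 1, 1)), X, m)


class TestGreedy:
    def test_zero_iterations_returns_initial_state(self, rng):
        m = make_mixture(8)
        X = rng.normal(size=(30, 8))
        cfg = EbmConfig(greedy_starts=1, greedy_iterations=0,
                        mcmc_iterations=10, burn_in=5, seed=42)
        state = greedy_init(X, m, cfg)
        order0, assign0 = _random_state(np.random.default_rng(42), cfg)
        assert state.cluster_order == tuple(order0)
        assert state.cluster_assignment == tuple(assign0)

    def test_monotone_improvement(self, rng):
        m = make_mixture(8)
        X = rng.normal(size=(40, 8)) + rng.integers(0, 2, (40, 8)) * 4.0
        cfg = EbmConfig(greedy_starts=1, greedy_iterations=50,
                        mcmc_iterations=10, burn_in=5, seed=7)
        state = greedy_init(X, m, cfg)
        order0, assign0 = _random_state(np.random.default_rng(7), cfg)
        ll0 = state_log_likelihood(
            EbmState(tuple(order0), tuple(assign0)), X, m)
        assert state.log_likelihood >= ll0 - 1e-12

    def test_recovers_planted_order(self):
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            ordering = list(np.random.default_rng(seed).permutation(4))
            table, truth = generate_event_cascade(
                500, ordering, [(0, 1, 4, 1)] * 8, [0.2] * 5, seed=seed)
            X = table.peptide_matrix()
            mix = make_mixture(8)
            cfg = EbmConfig(greedy_starts=10, greedy_iterations=200, seed=seed,
                            mcmc_iterations=10, burn_in=5)
            state = greedy_init(X, mix, cfg)
            clusters = [[2 * c, 2 * c + 1] for c in range(4)]
            hits += planted_order_distance(state, ordering, clusters) == 0
        assert hits >= 0.8 * n_seeds - 1


class TestMcmc:
    def test_fixed_seed_identical_stream(self, rng):
        m = make_mixture(4)
        X = rng.normal(size=(20, 4))
        cfg = EbmConfig(n_clusters=2, cluster_size=2, mcmc_iterations=500,
                        burn_in=100, greedy_starts=1, greedy_iterations=10,
                        seed=3)
        init = greedy_init(X, m, cfg)
        f1 = mcmc_sample(init, X, m, cfg)
        f2 = mcmc_sample(init, X, m, cfg)
        assert f1.samples == f2.samples

    def test_zero_information_orders_uniform(self, rng):
        m = make_mixture(8, sep=0.0)
        X = rng.normal(size=(30, 8))
        cfg = EbmConfig(mcmc_iterations=25_000, burn_in=5_000,
                        greedy_starts=1, greedy_iterations=0, seed=0)
        fit = mcmc_sample(greedy_init(X, m, cfg), X, m, cfg)
        # thin to reduce autocorrelation before the goodness-of-fit test
        orders = [s[0] for s in fit.samples[::10]]
        counts = {p: 0 for p in itertools.permutations(range(4))}
        for o in orders:
            counts[o] += 1
        observed = np.array(list(counts.values()))
        p = stats.chisquare(observed).pvalue
        assert p > 0.01

    def test_modal_order_equals_exhaustive_argmax(self, rng):
        mix = make_mixture(3, sep=3.0)
        X = np.vstack([rng.normal(0, 1, (10, 3)),
                       rng.normal([3, 0, 0], 1, (10, 3)),
                       rng.normal([3, 3, 0], 1, (10, 3))])
        cfg = EbmConfig(n_clusters=3, cluster_size=1, mcmc_iterations=4000,
                        burn_in=1000, greedy_starts=3, greedy_iterations=50,
                        seed=1)
        fit = fit_ebm(X, ["Control"] * 10 + ["AD"] * 20, cfg)
        # exhaustive oracle over the 6 orderings with the modal assignment
        assignment = fit.modal_state.cluster_assignment
        best = max(itertools.permutations(range(3)),
                   key=lambda o: enumeration_loglik(o, assignment, X,
                                                    fit.mixtures))
        assert fit.modal_state.cluster_order == best

    def test_sample_count_and_positional_variance(self, rng):
        m = make_mixture(4)
        X = rng.normal(size=(20, 4))
        cfg = EbmConfig(n_clusters=2, cluster_size=2, mcmc_iterations=1000,
                        burn_in=400, greedy_starts=1, greedy_iterations=10,
                        seed=0)
        fit = mcmc_sample(greedy_init(X, m, cfg), X, m, cfg)
        assert len(fit.samples) == 600
        assert np.allclose(fit.positional_variance.sum(axis=1), 1.0)
        assert np.allclose(fit.biomarker_positional_variance.sum(axis=1), 1.0)


class TestStaging:
    def _fit(self, rng, sep=4.0):
        mix = make_mixture(8, sep=sep)
        table, truth = generate_event_cascade(
            300, [0, 1, 2, 3], [(0, 1, sep, 1)] * 8, [0.2] * 5, seed=5)
        X = table.peptide_matrix()
        cfg = fast_config(mcmc_iterations=5000, burn_in=2000,
                          greedy_starts=5, greedy_iterations=100, seed=5)
        init = greedy_init(X, mix, cfg)
        return mcmc_sample(init, X, mix, cfg)

    def test_extreme_subjects(self, rng):
        fit = self._fit(rng)
        X = np.vstack([np.zeros(8), np.full(8, 4.0)])
        post = stage_subjects(fit, X)
        assert post.ml_stage[0] == 0
        assert post.ml_stage[1] == 4

    def test_posterior_matches_hand_computation(self, rng):
        mix = make_mixture(2, sep=2.0)
        state = EbmState((0, 1), (0, 1), 0.0)
        cfg = EbmConfig(n_clusters=2, cluster_size=1, mcmc_iterations=10,
                        burn_in=5)
        fit = object.__new__(type(self._fit(rng)))
        fit.config, fit.mixtures, fit.modal_state = cfg, mix, state
        x = np.array([[1.2, 0.3]])
        pdf = stats.norm.pdf
        terms = [pdf(1.2, 0, 1) * pdf(0.3, 0, 1),
                 pdf(1.2, 2, 1) * pdf(0.3, 0, 1),
                 pdf(1.2, 2, 1) * pdf(0.3, 2, 1)]
        expected = np.array(terms) / sum(terms)
        post = stage_subjects(fit, x)
        assert np.allclose(post.probabilities[0], expected, atol=1e-10)

    def test_missing_value_flagged(self, rng):
        fit = self._fit(rng)
        X = np.vstack([np.zeros(8), np.full(8, np.nan)])
        X[1, 0] = 0.0
        post = stage_subjects(fit, X)
        assert not post.incomplete[0] and post.incomplete[1]
        assert post.ml_stage[1] == 0

    def test_normalization_exact(self, rng):
        fit = self._fit(rng)
        X = rng.normal(size=(50, 8))
        post = stage_subjects(fit, X)
        assert np.abs(post.probabilities.sum(axis=1) - 1).max() < 1e-9


class TestRecalibrate:
    def _fit(self):
        table, truth = generate_event_cascade(
            400, [0, 1, 2, 3], [(0, 1, 4, 1)] * 8, [0.3, 0.1, 0.1, 0.1, 0.4],
            seed=2)
        X = table.peptide_matrix()
        cfg = fast_config(mcmc_iterations=5000, burn_in=2000,
                          greedy_starts=5, greedy_iterations=100, seed=2)
        fit = fit_ebm(X, table.group_labels, cfg)
        return fit, X, table.group_labels

    def test_fixed_point_on_training_data(self):
        fit, X, labels = self._fit()
        m2 = recalibrate(fit, X, labels)
        assert np.allclose(m2.normal_mean, fit.mixtures.normal_mean, atol=1e-6)
        assert np.allclose(m2.abnormal_mean, fit.mixtures.abnormal_mean,
                           atol=1e-6)

    def test_shift_equivariance_unlabelled(self):
        fit, X, _ = self._fit()
        shift = 2.5
        m2 = recalibrate(fit, X + shift)
        assert np.allclose(m2.normal_mean - fit.mixtures.normal_mean,
                           shift, atol=0.35)
        assert np.allclose(m2.abnormal_mean - fit.mixtures.abnormal_mean,
                           shift, atol=0.35)

    def test_shift_equivariance_labelled(self):
        fit, X, labels = self._fit()
        shift = 2.5
        m2 = recalibrate(fit, X + shift, labels)
        assert np.allclose(m2.normal_mean - fit.mixtures.normal_mean,
                           shift, atol=1e-6)
        assert np.allclose(m2.abnormal_mean - fit.mixtures.abnormal_mean,
                           shift, atol=1e-6)

    def test_staging_preserved_after_shift_recalibration(self):
        fit, X, _ = self._fit()
        original = stage_subjects(fit, X).ml_stage
        m2 = recalibrate(fit, X + 2.5)
        shifted = stage_subjects(fit, X + 2.5, m2).ml_stage
        assert (original == shifted).mean() >= 0.95

    def test_missing_biomarker_named(self):
        fit, X, _ = self._fit()
        with pytest.raises(CohortError, match="b7"):
            recalibrate(fit, X[:, :7], names=fit.mixtures.names[:7])


class TestStageChi2:
    def test_identical_distributions(self):
        stages = [0, 1, 2, 0, 1, 2]
        groups = ["a", "a", "a", "b", "b", "b"]
        chi2, p = stage_distribution_test(stages, groups)
        assert chi2 == 0.0 and p == 1.0

    def test_hand_formula_2x2(self):
        # [[30,10],[10,30]]: E=20 everywhere, chi2 = 4 * 100/20 = 20
        stages = [0] * 30 + [1] * 10 + [0] * 10 + [1] * 30
        groups = ["a"] * 40 + ["b"] * 40
        chi2, p = stage_distribution_test(stages, groups)
        assert chi2 == pytest.approx(20.0, abs=1e-10)

    def test_single_group_error(self):
        with pytest.raises(CohortError):
            stage_distribution_test([0, 1], ["a", "a"])


def test_planted_order_distance_identity():
    state = EbmState((2, 0, 3, 1), (0, 0, 1, 1, 2, 2, 3, 3))
    clusters = [[0, 1], [2, 3], [4, 5], [6, 7]]
    assert planted_order_distance(state, [2, 0, 3, 1], clusters) == 0
    assert planted_order_distance(state, [0, 2, 3, 1], clusters) == 1
    assert planted_order_distance(state, [1, 3, 0, 2], clusters) > 1
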