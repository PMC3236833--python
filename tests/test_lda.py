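"""Collapsed Gibbs sampler: degenerate cases, count-table consistency,
determinism, estimator invariants and the mixture/top-term/likelihood
operations."""

import numpy as np
import pytest
from scipy.special import gammaln
from sklearn.base import clone

from adrtopics import (
    Corpus,
    GibbsLDA,
    LdaConfig,
    LdaFit,
    TopicState,
    fit_lda,
    log_likelihood,
    mixture_word_prob,
    top_terms,
)
from adrtopics.evaluate import exact_topic_posterior


def small_fit(theta, phi, vocab=None):
    theta = np.asarray(theta, float)
    phi = np.asarray(phi, float)
    return LdaFit(
        theta=theta,
        phi=phi,
        vocabulary=vocab or [f"t{i}" for i in range(phi.shape[1])],
        doc_ids=[f"d{i}" for i in range(theta.shape[0])],
        config=LdaConfig(n_topics=phi.shape[0]),
        log_likelihood_trace=np.empty((0, 2)),
    )


class TestFit:
    def test_single_word_type(self):
        corpus = Corpus(vocabulary=["w"], docs=[np.array([0, 0, 0])])
        est = GibbsLDA(n_topics=2, n_iterations=60, burn_in=20, thinning=2).fit(corpus)
        assert np.allclose(est.phi_, 1.0)
        assert abs(est.theta_.sum() - 1.0) < 1e-9

    def test_rows_stochastic_and_positive(self, tiny_corpus):
        est = GibbsLDA(n_topics=2, n_iterations=100, burn_in=40, thinning=2).fit(tiny_corpus)
        assert np.abs(est.theta_.sum(1) - 1).max() < 1e-9
        assert np.abs(est.phi_.sum(1) - 1).max() < 1e-9
        assert (est.theta_ > 0).all() and (est.phi_ > 0).all()

    def test_fixed_seed_bit_identical(self, tiny_corpus):
        a = GibbsLDA(n_topics=2, n_iterations=80, burn_in=20, random_state=42).fit(tiny_corpus)
        b = GibbsLDA(n_topics=2, n_iterations=80, burn_in=20, random_state=42).fit(tiny_corpus)
        assert (a.state_.z == b.state_.z).all()
        assert (a.theta_ == b.theta_).all() and (a.phi_ == b.phi_).all()
        assert (a.log_likelihood_trace_ == b.log_likelihood_trace_).all()

    def test_count_tables_consistent_with_assignments(self, tiny_corpus):
        est = GibbsLDA(n_topics=2, n_iterations=50, burn_in=10).fit(tiny_corpus)
        est.state_.validate()
        broken = TopicState(
            est.state_.doc_of_token,
            est.state_.word_of_token,
            est.state_.z,
            est.state_.n_dj + 1,
            est.state_.n_jw,
            est.state_.n_j,
        )
        with pytest.raises(ValueError):
            broken.validate()

    def test_empty_document_kept_with_uniform_theta(self):
        corpus = Corpus(vocabulary=["w0", "w1"], docs=[np.array([0, 1]), np.array([], dtype=int)])
        with pytest.warns(UserWarning, match="empty"):
            est = GibbsLDA(n_topics=2, n_iterations=40, burn_in=10).fit(corpus)
        assert np.allclose(est.theta_[1], 0.5)

    def test_empty_corpus_fatal(self):
        with pytest.raises(ValueError):
            GibbsLDA(n_topics=2, n_iterations=10, burn_in=1).fit(
                Corpus(vocabulary=["w"], docs=[])
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_topics": 1},
            {"alpha": 0.0},
            {"beta": -1.0},
            {"burn_in": 50, "n_iterations": 50},
            {"thinning": 0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs, tiny_corpus):
        with pytest.raises(ValueError):
            GibbsLDA(**{"n_topics": 2, "n_iterations": 10, "burn_in": 1, **kwargs}).fit(tiny_corpus)

    def test_sklearn_estimator_protocol(self, tiny_corpus):
        est = GibbsLDA(n_topics=3, n_iterations=30, burn_in=10)
        cloned = clone(est)
        assert cloned.get_params()["n_topics"] == 3
        est.set_params(n_topics=2).fit(tiny_corpus)
        assert est.theta_.shape == (2, 2)

    def test_count_matrix_input_accepted(self):
        X = np.array([[2, 0], [0, 2]])
        est = GibbsLDA(n_topics=2, n_iterations=40, burn_in=10).fit(X)
        assert est.theta_.shape == (2, 2)


class TestTransform:
    def test_training_corpus_returns_theta(self, tiny_corpus):
        est = GibbsLDA(n_topics=2, n_iterations=40, burn_in=10).fit(tiny_corpus)
        assert est.transform(tiny_corpus) is est.theta_

    def test_fold_in_new_docs_row_stochastic(self, tiny_corpus):
        est = GibbsLDA(n_topics=2, n_iterations=40, burn_in=10).fit(tiny_corpus)
        new = Corpus(vocabulary=["w0", "w1"], docs=[np.array([0, 1, 1])], doc_ids=["new"])
        theta = est.transform(new)
        assert theta.shape == (1, 2)
        assert abs(theta.sum() - 1.0) < 1e-9

    def test_vocabulary_mismatch_rejected(self, tiny_corpus):
        est = GibbsLDA(n_topics=2, n_iterations=40, burn_in=10).fit(tiny_corpus)
        with pytest.raises(ValueError):
            est.transform(Corpus(vocabulary=["a", "b", "c"], docs=[np.array([2])], doc_ids=["x"]))


class TestMixtureWordProb:
    def test_one_hot_theta_degenerates_to_phi(self):
        fit = small_fit([[0.0, 1.0]], [[0.3, 0.7], [0.9, 0.1]])
        assert mixture_word_prob(fit, 0, 0) == pytest.approx(0.9)

    def test_sums_to_one_over_vocabulary(self):
        rng = np.random.default_rng(0)
        theta = rng.dirichlet(np.ones(3), size=4)
        phi = rng.dirichlet(np.ones(6), size=3)
        fit = small_fit(theta, phi)
        for d in range(4):
            total = sum(mixture_word_prob(fit, d, w) for w in range(6))
            assert abs(total - 1.0) < 1e-9

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        theta = rng.dirichlet(np.ones(5), size=3)
        phi = rng.dirichlet(np.ones(8), size=5)
        fit = small_fit(theta, phi)
        for d in range(3):
            for w in range(8):
                oracle = sum(phi[j, w] * theta[d, j] for j in range(5))
                assert mixture_word_prob(fit, d, w) == pytest.approx(oracle, abs=1e-12)

    def test_index_errors(self):
        fit = small_fit([[1.0]], [[1.0]])
        with pytest.raises(IndexError):
            mixture_word_prob(fit, 1, 0)
        with pytest.raises(IndexError):
            mixture_word_prob(fit, 0, 5)


class TestTopTerms:
    def test_simple_ordering(self):
        fit = small_fit([[1.0]], [[0.7, 0.2, 0.1]])
        assert [t for t, _ in top_terms(fit, 0, 2)] == ["t0", "t1"]

    def test_full_k_is_permutation(self):
        rng = np.random.default_rng(2)
        fit = small_fit([[1.0]], rng.dirichlet(np.ones(7), size=1))
        assert sorted(t for t, _ in top_terms(fit, 0, 7)) == sorted(fit.vocabulary)

    def test_matches_sort_oracle_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            # coarse grid forces ties; tie-break must follow vocabulary order
            row = rng.integers(1, 4, size=9).astype(float)
            row /= row.sum()
            fit = small_fit([[1.0]], row[None, :])
            oracle = [f"t{i}" for i in sorted(range(9), key=lambda i: (-row[i], i))]
            assert [t for t, _ in top_terms(fit, 0, 9)] == oracle

    def test_invalid_arguments(self):
        fit = small_fit([[1.0]], [[0.5, 0.5]])
        with pytest.raises(IndexError):
            top_terms(fit, 3, 1)
        with pytest.raises(ValueError):
            top_terms(fit, 0, 5)


class TestLogLikelihood:
    def test_no_tokens_equals_prior_constant(self):
        T, V = 3, 4
        state = TopicState(
            doc_of_token=np.empty(0, dtype=np.int32),
            word_of_token=np.empty(0, dtype=np.int32),
            z=np.empty(0, dtype=np.int32),
            n_dj=np.zeros((2, T), dtype=np.int64),
            n_jw=np.zeros((T, V), dtype=np.int64),
            n_j=np.zeros(T, dtype=np.int64),
        )
        cfg = LdaConfig(n_topics=T, alpha=0.4, beta=0.2)
        # prior normalizers cancel exactly against the empty-count terms
        expected = (
            2 * (gammaln(T * 0.4) - T * gammaln(0.4))
            + 2 * (T * gammaln(0.4) - gammaln(T * 0.4))
            + T * (gammaln(V * 0.2) - V * gammaln(0.2))
            + T * (V * gammaln(0.2) - gammaln(V * 0.2))
        )
        assert log_likelihood(state, cfg) == pytest.approx(expected, abs=1e-12)

    def test_single_token_closed_form(self):
        # one token: P(w, z) = (1/T) * (1/V) for any symmetric priors
        T, V = 2, 2
        state = TopicState(
            doc_of_token=np.array([0], dtype=np.int32),
            word_of_token=np.array([0], dtype=np.int32),
            z=np.array([1], dtype=np.int32),
            n_dj=np.array([[0, 1]], dtype=np.int64),
            n_jw=np.array([[0, 0], [1, 0]], dtype=np.int64),
            n_j=np.array([0, 1], dtype=np.int64),
        )
        cfg = LdaConfig(n_topics=T, alpha=0.3, beta=0.7)
        assert log_likelihood(state, cfg) == pytest.approx(-np.log(T * V), abs=1e-12)

    def test_trace_rises_from_initialization(self):
        from adrtopics import generate_corpus, generate_ground_truth

        rises = 0
        for seed in (1, 2, 3):
            gt = generate_ground_truth(3, 50, 40, phi_concentration=0.05, seed=seed)
            corpus, _ = generate_corpus(gt, 25, seed=seed + 10)
            fit = fit_lda(
                corpus,
                LdaConfig(n_topics=3, alpha=0.5, n_iterations=200, burn_in=100, thinning=10, seed=seed),
            )
            trace = fit.log_likelihood_trace
            burn_end = trace[trace[:, 0] <= 100][-1, 1]
            rises += burn_end > trace[0, 1]
        assert rises == 3


class TestExactPosterior:
    def test_marginals_are_distributions(self, tiny_corpus):
        m = exact_topic_posterior(tiny_corpus, 2, 1.0, 1.0)
        assert m.shape == (4, 2)
        assert np.abs(m.sum(1) - 1).max() < 1e-12

    def test_symmetric_corpus_gives_uniform_marginals(self, tiny_corpus):
        # word/topic symmetry: every token's topic marginal must be 1/2
        m = exact_topic_posterior(tiny_corpus, 2, 1.0, 1.0)
        assert np.allclose(m, 0.5, atol=1e-12)
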