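"""Latent Dirichlet allocation by collapsed Gibbs sampling.

The model: each document d mixes topics through θ^(d) (a distribution over T
topics, symmetric Dirichlet(α) prior) and each topic j is a distribution
φ_j over the V vocabulary terms (symmetric Dirichlet(β) prior).  A token is
generated by drawing a topic j ~ θ^(d) and then a word w ~ φ_j, so the
marginal word distribution in a document is P(w) = Σ_j φ_j(w)·θ^(d)(j).

Inference integrates θ and φ out and resamples each token's topic indicator
z_i from

    P(z_i = j | z_-i, w)  ∝  (n_dj + α) · (n_jw + β) / (n_j + V·β)

with all counts excluding token i.  θ and φ are reported as averages of the
smoothed posterior-mean estimators over post-burn-in, thinned sweeps.

The sampler is exposed as the scikit-learn style estimator :class:`GibbsLDA`
(``fit`` / ``transform`` / ``get_params``); :func:`fit_lda` is a thin
functional wrapper returning an :class:`LdaFit`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin

from .corpus import Corpus

__all__ = [
    "GibbsLDA",
    "LdaConfig",
    "LdaFit",
    "TopicState",
    "fit_lda",
    "top_terms",
    "mixture_word_prob",
    "log_likelihood",
]


# ---------------------------------------------------------------------------
# state


@dataclass
class TopicState:
    """Token-level topic assignments and their sufficient-statistic tables."""

    doc_of_token: np.ndarray  # int32 (n_tokens,)
    word_of_token: np.ndarray  # int32 (n_tokens,)
    z: np.ndarray  # int32 (n_tokens,)
    n_dj: np.ndarray  # int64 (D, T)
    n_jw: np.ndarray  # int64 (T, V)
    n_j: np.ndarray  # int64 (T,)

    def validate(self) -> None:
        """Check the count tables against a from-scratch recount of ``z``."""
        D, T = self.n_dj.shape
        V = self.n_jw.shape[1]
        n_dj = np.zeros((D, T), dtype=np.int64)
        n_jw = np.zeros((T, V), dtype=np.int64)
        for d, w, j in zip(self.doc_of_token, self.word_of_token, self.z):
            n_dj[d, j] += 1
            n_jw[j, w] += 1
        if not (
            np.array_equal(n_dj, self.n_dj)
            and np.array_equal(n_jw, self.n_jw)
            and np.array_equal(n_jw.sum(axis=1), self.n_j)
        ):
            raise ValueError("count tables inconsistent with topic assignments")


@dataclass
class LdaConfig:
    """Sampler configuration (``alpha=None`` means the 50/T convention)."""

    n_topics: int = 100
    alpha: float | None = None
    beta: float = 0.01
    n_iterations: int = 2000
    burn_in: int = 1000
    thinning: int = 10
    seed: int = 0

    def resolved_alpha(self) -> float:
        return 50.0 / self.n_topics if self.alpha is None else self.alpha


@dataclass
class LdaFit:
    """A fitted topic model: θ (doc×topic), φ (topic×vocab) and diagnostics."""

    theta: np.ndarray
    phi: np.ndarray
    vocabulary: list[str]
    doc_ids: list[str]
    config: LdaConfig
    log_likelihood_trace: np.ndarray  # (n_recorded, 2): sweep index, value
    final_state: TopicState = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=False)
def _run_gibbs(
    doc_of_token,
    word_of_token,
    doc_len,
    D,
    T,
    V,
    alpha,
    beta,
    n_iterations,
    burn_in,
    thinning,
    seed,
    store_z_history,
):  # pragma: no cover - executed via dispatcher
    np.random.seed(seed)
    n_tokens = doc_of_token.shape[0]
    z = np.empty(n_tokens, dtype=np.int32)
    n_dj = np.zeros((D, T), dtype=np.int64)
    n_jw = np.zeros((T, V), dtype=np.int64)
    n_j = np.zeros(T, dtype=np.int64)
    for i in range(n_tokens):
        j = np.random.randint(0, T)
        z[i] = j
        n_dj[doc_of_token[i], j] += 1
        n_jw[j, word_of_token[i]] += 1
        n_j[j] += 1

    n_recorded = 0
    for it in range(n_iterations):
        if it % thinning == 0:
            n_recorded += 1
    n_samples = 0
    for it in range(burn_in, n_iterations):
        if (it - burn_in) % thinning == 0:
            n_samples += 1

    theta_sum = np.zeros((D, T), dtype=np.float64)
    phi_sum = np.zeros((T, V), dtype=np.float64)
    ll_iters = np.empty(n_recorded, dtype=np.int64)
    ll_vals = np.empty(n_recorded, dtype=np.float64)
    if store_z_history:
        z_hist = np.empty((n_samples, n_tokens), dtype=np.int16)
    else:
        z_hist = np.empty((0, n_tokens), dtype=np.int16)

    probs = np.empty(T, dtype=np.float64)
    vbeta = V * beta
    rec = 0
    samp = 0
    for it in range(n_iterations):
        for i in range(n_tokens):
            d = doc_of_token[i]
            w = word_of_token[i]
            j = z[i]
            n_dj[d, j] -= 1
            n_jw[j, w] -= 1
            n_j[j] -= 1
            total = 0.0
            for k in range(T):
                p = (n_dj[d, k] + alpha) * (n_jw[k, w] + beta) / (n_j[k] + vbeta)
                total += p
                probs[k] = total
            u = np.random.random() * total
            jnew = 0
            while probs[jnew] < u and jnew < T - 1:
                jnew += 1
            z[i] = jnew
            n_dj[d, jnew] += 1
            n_jw[jnew, w] += 1
            n_j[jnew] += 1
        if it % thinning == 0:
            ll = D * (math.lgamma(T * alpha) - T * math.lgamma(alpha))
            for d in range(D):
                for k in range(T):
                    ll += math.lgamma(n_dj[d, k] + alpha)
                ll -= math.lgamma(doc_len[d] + T * alpha)
            ll += T * (math.lgamma(vbeta) - V * math.lgamma(beta))
            for k in range(T):
                for w in range(V):
                    ll += math.lgamma(n_jw[k, w] + beta)
                ll -= math.lgamma(n_j[k] + vbeta)
            ll_iters[rec] = it
            ll_vals[rec] = ll
            rec += 1
        if it >= burn_in and (it - burn_in) % thinning == 0:
            for d in range(D):
                denom = doc_len[d] + T * alpha
                for k in range(T):
                    theta_sum[d, k] += (n_dj[d, k] + alpha) / denom
            for k in range(T):
                denom = n_j[k] + vbeta
                for w in range(V):
                    phi_sum[k, w] += (n_jw[k, w] + beta) / denom
            if store_z_history:
                for i in range(n_tokens):
                    z_hist[samp, i] = z[i]
            samp += 1
    return z, n_dj, n_jw, n_j, theta_sum, phi_sum, n_samples, ll_iters, ll_vals, z_hist


@njit(cache=False)
def _fold_in_doc(words, phi, T, alpha, n_iterations, burn_in, seed):  # pragma: no cover
    np.random.seed(seed)
    n = words.shape[0]
    z = np.empty(n, dtype=np.int32)
    n_j = np.zeros(T, dtype=np.int64)
    for i in range(n):
        j = np.random.randint(0, T)
        z[i] = j
        n_j[j] += 1
    theta_sum = np.zeros(T, dtype=np.float64)
    probs = np.empty(T, dtype=np.float64)
    n_samples = 0
    for it in range(n_iterations):
        for i in range(n):
            j = z[i]
            n_j[j] -= 1
            total = 0.0
            for k in range(T):
                total += (n_j[k] + alpha) * phi[k, words[i]]
                probs[k] = total
            u = np.random.random() * total
            jnew = 0
            while probs[jnew] < u and jnew < T - 1:
                jnew += 1
            z[i] = jnew
            n_j[jnew] += 1
        if it >= burn_in:
            denom = n + T * alpha
            for k in range(T):
                theta_sum[k] += (n_j[k] + alpha) / denom
            n_samples += 1
    return theta_sum / n_samples


# ---------------------------------------------------------------------------
# estimator


class GibbsLDA(BaseEstimator, TransformerMixin):
    """Collapsed-Gibbs LDA with posterior-mean θ/φ estimates.

    Parameters
    ----------
    n_topics : int, default=100
        Number of topics T.
    alpha : float or None, default=None
        Symmetric document-topic Dirichlet concentration; ``None`` uses the
        classical 50/T convention.
    beta : float, default=0.01
        Symmetric topic-word Dirichlet concentration.
    n_iterations, burn_in, thinning : int
        Gibbs schedule; θ/φ average the smoothed count estimators over
        post-burn-in sweeps spaced ``thinning`` apart.  The collapsed log
        joint is recorded every ``thinning`` sweeps from the start.
    random_state : int, default=0
        Seed for topic initialization and all resampling.
    store_z_history : bool, default=False
        Keep the sampled token-topic assignments of every retained sweep
        (``z_history_``); intended for small corpora / diagnostics.

    Attributes
    ----------
    theta_ : ndarray (n_docs, n_topics)
        Posterior-mean document-topic distributions (rows sum to 1).
    phi_ : ndarray (n_topics, n_words)
        Posterior-mean topic-word distributions (rows sum to 1).
    log_likelihood_trace_ : ndarray (n_recorded, 2)
        Columns: sweep index, collapsed log joint.
    state_ : TopicState
        Final token assignments and count tables.
    """

    def __init__(
        self,
        n_topics: int = 100,
        alpha: float | None = None,
        beta: float = 0.01,
        n_iterations: int = 2000,
        burn_in: int = 1000,
        thinning: int = 10,
        random_state: int = 0,
        store_z_history: bool = False,
    ):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.thinning = thinning
        self.random_state = random_state
        self.store_z_history = store_z_history

    # -- helpers ----------------------------------------------------------

    def _validate_params_(self) -> tuple[float, float]:
        if self.n_topics < 2:
            raise ValueError("n_topics must be >= 2")
        alpha = 50.0 / self.n_topics if self.alpha is None else float(self.alpha)
        beta = float(self.beta)
        if alpha <= 0 or beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        return alpha, beta

    @staticmethod
    def _as_corpus(X) -> Corpus:
        if isinstance(X, Corpus):
            return X
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("expected a Corpus or a 2-D document-term count matrix")
        docs = []
        for row in X:
            toks: list[int] = []
            for w, c in enumerate(row):
                toks.extend([w] * int(c))
            docs.append(np.asarray(toks, dtype=np.int32))
        return Corpus(vocabulary=[f"w{j}" for j in range(X.shape[1])], docs=docs)

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y=None) -> "GibbsLDA":
        """Run the collapsed Gibbs sampler on a corpus (or count matrix)."""
        corpus = self._as_corpus(X)
        alpha, beta = self._validate_params_()
        if corpus.n_docs == 0 or corpus.n_words == 0:
            raise ValueError("empty corpus")
        if corpus.n_tokens == 0:
            raise ValueError("corpus has no tokens")
        n_empty = sum(1 for d in corpus.docs if d.size == 0)
        if n_empty:
            warnings.warn(
                f"{n_empty} empty document(s) retained with uniform theta rows"
            )
        doc_of_token = np.concatenate(
            [np.full(d.size, i, dtype=np.int32) for i, d in enumerate(corpus.docs)]
        )
        word_of_token = np.concatenate(corpus.docs).astype(np.int32)
        doc_len = corpus.doc_lengths()

        (z, n_dj, n_jw, n_j, theta_sum, phi_sum, n_samples, ll_iters, ll_vals, z_hist) = _run_gibbs(
            doc_of_token,
            word_of_token,
            doc_len,
            corpus.n_docs,
            self.n_topics,
            corpus.n_words,
            alpha,
            beta,
            self.n_iterations,
            self.burn_in,
            self.thinning,
            int(self.random_state) & 0x7FFFFFFF,
            self.store_z_history,
        )
        self.alpha_ = alpha
        self.beta_ = beta
        self.theta_ = theta_sum / n_samples
        self.phi_ = phi_sum / n_samples
        self.n_samples_ = int(n_samples)
        self.log_likelihood_trace_ = np.column_stack([ll_iters.astype(float), ll_vals])
        self.state_ = TopicState(doc_of_token, word_of_token, z, n_dj, n_jw, n_j)
        self.vocabulary_ = list(corpus.vocabulary)
        self.doc_ids_ = list(corpus.doc_ids)
        self.corpus_n_tokens_ = corpus.n_tokens
        if self.store_z_history:
            self.z_history_ = z_hist
        return self

    def transform(self, X) -> np.ndarray:
        """Document-topic distributions.

        For the corpus the model was fitted on (same documents), returns
        ``theta_``; otherwise folds new documents in by Gibbs sampling with
        the fitted φ held fixed.
        """
        if not hasattr(self, "theta_"):
            raise RuntimeError("GibbsLDA is not fitted")
        corpus = self._as_corpus(X)
        if (
            corpus.n_docs == len(self.doc_ids_)
            and corpus.n_words == len(self.vocabulary_)
            and corpus.n_tokens == self.corpus_n_tokens_
            and corpus.doc_ids == self.doc_ids_
        ):
            return self.theta_
        if corpus.n_words != len(self.vocabulary_):
            raise ValueError("vocabulary size mismatch with the fitted model")
        theta = np.empty((corpus.n_docs, self.n_topics))
        for i, d in enumerate(corpus.docs):
            if d.size == 0:
                theta[i] = 1.0 / self.n_topics
            else:
                theta[i] = _fold_in_doc(
                    d,
                    self.phi_,
                    self.n_topics,
                    self.alpha_,
                    200,
                    100,
                    (int(self.random_state) + 7919 * (i + 1)) & 0x7FFFFFFF,
                )
        return theta

    # -- reporting ---------------------------------------------------------

    def top_terms(self, topic: int, k: int) -> list[tuple[str, float]]:
        """The k highest-probability terms of a topic (ties by vocab order)."""
        return top_terms(self.to_fit(), topic, k)

    def to_fit(self) -> LdaFit:
        """View the fitted estimator as an :class:`LdaFit` record."""
        if not hasattr(self, "theta_"):
            raise RuntimeError("GibbsLDA is not fitted")
        cfg = LdaConfig(
            n_topics=self.n_topics,
            alpha=self.alpha,
            beta=self.beta,
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            thinning=self.thinning,
            seed=self.random_state,
        )
        return LdaFit(
            theta=self.theta_,
            phi=self.phi_,
            vocabulary=self.vocabulary_,
            doc_ids=self.doc_ids_,
            config=cfg,
            log_likelihood_trace=self.log_likelihood_trace_,
            final_state=self.state_,
        )


# ---------------------------------------------------------------------------
# functional surface


def fit_lda(corpus: Corpus, config: LdaConfig | None = None) -> LdaFit:
    """Fit LDA to a corpus under a config; returns the LdaFit record."""
    config = config or LdaConfig()
    est = GibbsLDA(
        n_topics=config.n_topics,
        alpha=config.alpha,
        beta=config.beta,
        n_iterations=config.n_iterations,
        burn_in=config.burn_in,
        thinning=config.thinning,
        random_state=config.seed,
    )
    est.fit(corpus)
    return est.to_fit()


def mixture_word_prob(fit: LdaFit, doc_index: int, word_index: int) -> float:
    """Marginal word probability P(w) = Σ_j φ_j(w)·θ^(d)(j) for a document."""
    theta = fit.theta
    phi = fit.phi
    if not (0 <= doc_index < theta.shape[0]):
        raise IndexError("doc_index out of range")
    if not (0 <= word_index < phi.shape[1]):
        raise IndexError("word_index out of range")
    return float(theta[doc_index] @ phi[:, word_index])


def top_terms(fit: LdaFit, topic: int, k: int) -> list[tuple[str, float]]:
    """k highest-φ terms of a topic, descending, ties by vocabulary order."""
    phi = fit.phi
    if not (0 <= topic < phi.shape[0]):
        raise IndexError("topic index out of range")
    V = phi.shape[1]
    if k > V:
        raise ValueError("k exceeds vocabulary size")
    row = phi[topic]
    order = np.lexsort((np.arange(V), -row))[:k]
    return [(fit.vocabulary[w], float(row[w])) for w in order]


def write_theta(fit: LdaFit, path) -> None:
    """Theta TSV: rows = drug_id, columns topic_0..topic_{T-1}."""
    T = fit.theta.shape[1]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("drug_id\t" + "\t".join(f"topic_{j}" for j in range(T)) + "\n")
        for did, row in zip(fit.doc_ids, fit.theta):
            fh.write(did + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def write_phi(fit: LdaFit, path) -> None:
    """Phi TSV: rows = topic, columns = vocabulary term_ids."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("topic\t" + "\t".join(fit.vocabulary) + "\n")
        for j, row in enumerate(fit.phi):
            fh.write(f"{j}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def write_top_terms(fit: LdaFit, k: int, path) -> None:
    """Top-terms TSV: ``topic rank term_id prob``."""
    k = min(k, len(fit.vocabulary))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("topic\trank\tterm_id\tprob\n")
        for j in range(fit.phi.shape[0]):
            for rank, (tid, p) in enumerate(top_terms(fit, j, k), 1):
                fh.write(f"{j}\t{rank}\t{tid}\t{p:.10g}\n")


def write_ll_trace(fit: LdaFit, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sweep\tlog_likelihood\n")
        for it, v in fit.log_likelihood_trace:
            fh.write(f"{int(it)}\t{v:.10g}\n")


def log_likelihood(state: TopicState, config: LdaConfig, n_words: int | None = None) -> float:
    """Collapsed log joint log P(w, z) under symmetric Dirichlet priors.

    Used as a convergence diagnostic; raises if the count tables are
    inconsistent with the assignments.
    """
    state.validate()
    T = config.n_topics
    alpha = config.resolved_alpha()
    beta = config.beta
    D = state.n_dj.shape[0]
    V = state.n_jw.shape[1] if n_words is None else n_words
    doc_len = state.n_dj.sum(axis=1)
    ll = D * (gammaln(T * alpha) - T * gammaln(alpha))
    ll += gammaln(state.n_dj + alpha).sum() - gammaln(doc_len + T * alpha).sum()
    ll += T * (gammaln(V * beta) - V * gammaln(beta))
    ll += gammaln(state.n_jw + beta).sum() - gammaln(state.n_j + V * beta).sum()
    return float(ll)
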