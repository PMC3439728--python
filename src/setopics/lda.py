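"""Latent Dirichlet Allocation fitted by collapsed Gibbs sampling.

Each drug label is a bag of side-effect term occurrences; LDA explains it as
a mixture of ``K`` latent side-effect themes.  With symmetric priors
``Dirichlet(alpha)`` on per-drug topic mixtures and ``Dirichlet(beta)`` on
per-topic word distributions, the sampler integrates both out and resamples
each token's topic label from

    p(z = j | rest)  ∝  (n_kw + beta) / (n_k + V beta) * (n_dk + alpha)

where the counts exclude the token itself.  Point estimates are posterior
means, averaged over lagged post-burn-in samples:

    theta[d, k] = (n_dk + alpha) / (N_d + K alpha)
    phi[k, w]   = (n_kw + beta) / (n_k + V beta)

so every entry is strictly positive — which the Kullback-Leibler distance
layer requires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from . import _gibbs
from .corpus import DrugTermMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LdaConfig:
    """Sampler settings; ``alpha=None`` means the 50/K heuristic."""

    n_topics: int
    alpha: float | None = None
    beta: float = 0.1
    n_iterations: int = 1000
    burn_in: int = 500
    sample_lag: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be positive")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be in [0, n_iterations)")
        if self.sample_lag < 1:
            raise ValueError("sample_lag must be positive")

    @property
    def effective_alpha(self) -> float:
        return 50.0 / self.n_topics if self.alpha is None else self.alpha


@dataclass(frozen=True)
class TopicAssignments:
    """Token-level sampler state: labels plus the four count tables."""

    z: np.ndarray  # per-token topic label
    doc: np.ndarray  # per-token document index
    word: np.ndarray  # per-token word index
    n_dk: np.ndarray  # docs x topics
    n_kw: np.ndarray  # topics x words
    n_k: np.ndarray  # topic totals
    n_d: np.ndarray  # document totals

    def check_consistency(self) -> None:
        """Raise if the count tables disagree with each other or with z."""
        if (self.n_dk < 0).any() or (self.n_kw < 0).any() or (self.n_k < 0).any():
            raise ValueError("negative count")
        if not np.array_equal(self.n_dk.sum(axis=1), self.n_d):
            raise ValueError("n_dk rows do not sum to document totals")
        if not np.array_equal(self.n_kw.sum(axis=1), self.n_k):
            raise ValueError("n_kw rows do not sum to topic totals")
        K = self.n_dk.shape[1]
        if not np.array_equal(np.bincount(self.z, minlength=K), self.n_k):
            raise ValueError("z labels do not match topic totals")


@dataclass(frozen=True)
class TopicModelFit:
    """Posterior-mean estimates of P(z|d) and P(w|z)."""

    theta: np.ndarray  # drugs x topics
    phi: np.ndarray  # topics x terms
    log_likelihood_trace: np.ndarray
    config: LdaConfig
    drug_ids: list[str]
    term_ids: list[str]

    def __post_init__(self) -> None:
        for name, arr in (("theta", self.theta), ("phi", self.phi)):
            if np.abs(arr.sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError(f"{name} rows must sum to 1")
            if (arr <= 0).any():
                raise ValueError(f"{name} must be strictly positive")


def _expand_tokens(matrix: DrugTermMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Counts -> token stream, document-major, term order within a document."""
    D, V = matrix.counts.shape
    reps = matrix.counts.ravel()
    ids = np.tile(np.arange(V), D)
    word = np.repeat(ids, reps)
    doc = np.repeat(np.arange(D), matrix.counts.sum(axis=1))
    return doc.astype(np.int64), word.astype(np.int64)


def log_likelihood(assignments: TopicAssignments, config: LdaConfig) -> float:
    """Collapsed joint log p(w, z | alpha, beta) from the count tables."""
    assignments.check_consistency()
    if assignments.z.size == 0:
        raise ValueError("empty corpus")
    a = config.effective_alpha
    b = config.beta
    D, K = assignments.n_dk.shape
    V = assignments.n_kw.shape[1]
    ll = D * (gammaln(K * a) - K * gammaln(a))
    ll += gammaln(assignments.n_dk + a).sum()
    ll -= gammaln(assignments.n_d + K * a).sum()
    ll += K * (gammaln(V * b) - V * gammaln(b))
    ll += gammaln(assignments.n_kw + b).sum()
    ll -= gammaln(assignments.n_k + V * b).sum()
    return float(ll)


def _loglik_tables(n_dk, n_kw, n_k, n_d, a, b) -> float:
    D, K = n_dk.shape
    V = n_kw.shape[1]
    ll = D * (gammaln(K * a) - K * gammaln(a))
    ll += gammaln(n_dk + a).sum() - gammaln(n_d + K * a).sum()
    ll += K * (gammaln(V * b) - V * gammaln(b))
    ll += gammaln(n_kw + b).sum() - gammaln(n_k + V * b).sum()
    return float(ll)


def fit(
    matrix: DrugTermMatrix, config: LdaConfig, debug: bool = False
) -> tuple[TopicModelFit, TopicAssignments]:
    """Run the collapsed Gibbs sampler on a drug-term count matrix.

    Tokens are the count multiplicities expanded in a fixed order; identical
    (matrix, config) pairs give bit-identical fits.  ``debug=True`` verifies
    the count-conservation invariants after every sweep.  Returns the
    posterior-mean fit and the final sampler state.
    """
    K = config.n_topics
    doc, word = _expand_tokens(matrix)
    n_tok = doc.size
    if K > n_tok:
        logger.warning("n_topics=%d exceeds the %d tokens in the corpus", K, n_tok)
    a = config.effective_alpha
    b = config.beta
    D, V = matrix.counts.shape
    n_d = matrix.counts.sum(axis=1)

    state = _gibbs.seed_state(config.seed)
    z, n_dk, n_kw, n_k = _gibbs.init_assignments(doc, word, K, D, V, state)

    theta_acc = np.zeros((D, K))
    phi_acc = np.zeros((K, V))
    n_samples = 0
    trace = np.empty(config.n_iterations)

    for it in range(1, config.n_iterations + 1):
        _gibbs.sweep(doc, word, z, n_dk, n_kw, n_k, a, b, state)
        trace[it - 1] = _loglik_tables(n_dk, n_kw, n_k, n_d, a, b)
        if debug:
            TopicAssignments(z, doc, word, n_dk, n_kw, n_k, n_d).check_consistency()
        if it > config.burn_in and (it - config.burn_in) % config.sample_lag == 0:
            theta_acc += (n_dk + a) / (n_d[:, None] + K * a)
            phi_acc += (n_kw + b) / (n_k[:, None] + V * b)
            n_samples += 1

    if n_samples == 0:  # lag longer than the post-burn-in window
        theta_acc = (n_dk + a) / (n_d[:, None] + K * a)
        phi_acc = (n_kw + b) / (n_k[:, None] + V * b)
        n_samples = 1

    theta = theta_acc / n_samples
    phi = phi_acc / n_samples
    # guard against accumulated rounding before the row-sum invariant check
    theta /= theta.sum(axis=1, keepdims=True)
    phi /= phi.sum(axis=1, keepdims=True)

    fit_ = TopicModelFit(
        theta=theta,
        phi=phi,
        log_likelihood_trace=trace,
        config=config,
        drug_ids=list(matrix.drug_ids),
        term_ids=list(matrix.term_ids),
    )
    assignments = TopicAssignments(z, doc, word, n_dk, n_kw, n_k, n_d)
    return fit_, assignments


def top_terms(fit_: TopicModelFit, topic: int, n: int) -> list[tuple[str, float]]:
    """The n most probable terms of a topic, ties broken by term id."""
    K = fit_.phi.shape[0]
    if not 0 <= topic < K:
        raise ValueError(f"topic must be in [0, {K - 1}]")
    row = fit_.phi[topic]
    order = sorted(range(len(row)), key=lambda j: (-row[j], fit_.term_ids[j]))
    return [(fit_.term_ids[j], float(row[j])) for j in order[:n]]


def match_topics(phi_est: np.ndarray, phi_true: np.ndarray) -> np.ndarray:
    """Greedy one-to-one matching of estimated to true topics.

    Pairs are assigned in order of increasing total-variation distance
    between rows (ties toward lower indices).  Returns ``perm`` with
    ``perm[j]`` the estimated topic matched to true topic ``j``.
    """
    phi_est = np.asarray(phi_est, dtype=float)
    phi_true = np.asarray(phi_true, dtype=float)
    if phi_est.shape != phi_true.shape:
        raise ValueError("phi_est and phi_true must have the same shape")
    K = phi_est.shape[0]
    tv = 0.5 * np.abs(phi_est[:, None, :] - phi_true[None, :, :]).sum(axis=2)
    perm = np.full(K, -1, dtype=np.int64)
    used_est: set[int] = set()
    used_true: set[int] = set()
    order = sorted(
        ((tv[i, j], i, j) for i in range(K) for j in range(K)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    for _, i, j in order:
        if i in used_est or j in used_true:
            continue
        perm[j] = i
        used_est.add(i)
        used_true.add(j)
    return perm
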