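"""Synthetic label corpora drawn from the LDA generative process.

Real inputs for this analysis (DailyMed labels, a licensed MedDRA term list,
SIDER indications) cannot be redistributed, so every downstream stage is
exercised on corpora generated here, where the ground truth — per-drug topic
mixtures, per-topic word distributions and the topic -> indication map — is
known exactly.

Generative process per drug ``d``:

* ``theta_d ~ Dirichlet(alpha)`` over ``K`` topics,
* document length ``N_d ~ max(1, Poisson(L))``,
* each token: topic ``z ~ theta_d`` then word ``w ~ phi_z``,

with ``phi_k ~ Dirichlet(beta)`` over ``V`` synthetic term strings (optionally
restricted to disjoint per-topic vocabulary blocks).  Indications are linked
to the drug's dominant topic: the drug carries all indications of that topic,
plus each other topic's indications independently with probability
``indication_noise``.  Boxed-warning flags are Bernoulli and the ATC level-1
letter is a fixed function of the dominant topic, so category enrichment has
a true signal.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np

from .corpus import DrugRecord, DrugTermMatrix, SideEffectLexicon

# The 14 anatomical main groups of the ATC classification.
ATC_LETTERS = "ABCDGHJLMNPRSV"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for a synthetic corpus.

    Defaults describe a mid-sized label corpus: 200 drugs over a vocabulary
    of 100 side-effect terms, five latent side-effect themes, concentrated
    per-drug mixtures (alpha=0.1), ~60 extracted term occurrences per label,
    one primary indication per theme with 5% cross-theme indication noise,
    and a boxed-warning prevalence of 40%.
    """

    n_drugs: int = 200
    vocab_size: int = 100
    n_topics: int = 5
    alpha: float = 0.1
    beta: float = 0.1
    mean_doc_length: float = 60.0
    indications_per_topic: int = 1
    indication_noise: float = 0.05
    bw_prob: float = 0.4
    n_atc: int = 5
    disjoint_topics: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.vocab_size, self.n_topics) < 1:
            raise ValueError("n_drugs, vocab_size and n_topics must be positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.mean_doc_length <= 0:
            raise ValueError("mean_doc_length must be positive")
        if self.indications_per_topic < 1:
            raise ValueError("indications_per_topic must be positive")
        if not 0.0 <= self.indication_noise <= 1.0:
            raise ValueError("indication_noise must be in [0, 1]")
        if not 0.0 <= self.bw_prob <= 1.0:
            raise ValueError("bw_prob must be in [0, 1]")
        if not 1 <= self.n_atc <= min(self.n_topics, len(ATC_LETTERS)):
            raise ValueError("n_atc must be in [1, min(n_topics, 14)]")
        if self.disjoint_topics and self.vocab_size < self.n_topics:
            raise ValueError("disjoint topics need vocab_size >= n_topics")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a generated corpus."""

    theta_true: np.ndarray  # D x K, rows sum to 1
    phi_true: np.ndarray  # K x V, rows sum to 1
    topic_indications: dict[int, frozenset[str]]
    dominant_topic: np.ndarray  # D, argmax of theta_true

    def __post_init__(self) -> None:
        for name, arr in (("theta_true", self.theta_true), ("phi_true", self.phi_true)):
            if np.abs(np.asarray(arr).sum(axis=1) - 1.0).max() > 1e-9:
                raise ValueError(f"{name} rows must sum to 1")
        sets = list(self.topic_indications.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if sets[i] & sets[j]:
                    raise ValueError("topic indication sets must be disjoint")

    def to_json_obj(self) -> dict:
        return {
            "theta_true": self.theta_true.tolist(),
            "phi_true": self.phi_true.tolist(),
            "topic_indications": {
                str(k): sorted(v) for k, v in self.topic_indications.items()
            },
            "dominant_topic": self.dominant_topic.tolist(),
        }


def _term_strings(vocab_size: int) -> list[str]:
    return [f"seterm{i:04d}" for i in range(vocab_size)]


def corpus_lexicon(config: GeneratorConfig) -> SideEffectLexicon:
    """Lexicon of the V synthetic term strings, ids ``t0001`` ...

    Deterministic given the config; pushing the generated records plus this
    lexicon through ``corpus.build_matrix`` reproduces the generated matrix.
    """
    terms = _term_strings(config.vocab_size)
    return SideEffectLexicon(
        {f"t{i + 1:04d}": terms[i] for i in range(config.vocab_size)}
    )


def _draw_phi(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    K, V = config.n_topics, config.vocab_size
    if not config.disjoint_topics:
        return rng.dirichlet(np.full(V, config.beta), size=K)
    # Disjoint vocabulary blocks: topic k owns an equal contiguous slice.
    phi = np.zeros((K, V))
    bounds = np.linspace(0, V, K + 1).astype(int)
    for k in range(K):
        lo, hi = bounds[k], bounds[k + 1]
        phi[k, lo:hi] = rng.dirichlet(np.full(hi - lo, config.beta))
    return phi


def generate_corpus(
    config: GeneratorConfig,
) -> tuple[list[DrugRecord], DrugTermMatrix, SyntheticTruth]:
    """Generate drug records, their term-count matrix and the ground truth.

    Fully reproducible from ``config.seed``.  The returned matrix contains
    the columns (in lexicon order) of terms appearing at least once in the
    corpus, exactly as ``corpus.build_matrix`` would reconstruct it from the
    emitted records.
    """
    rng = np.random.default_rng(config.seed)
    D, V, K = config.n_drugs, config.vocab_size, config.n_topics

    phi = _draw_phi(config, rng)
    theta = rng.dirichlet(np.full(K, config.alpha), size=D)
    dominant = theta.argmax(axis=1)

    topic_indications = {
        k: frozenset(
            f"ind-{k:02d}-{i:02d}" for i in range(config.indications_per_topic)
        )
        for k in range(K)
    }

    terms = _term_strings(V)
    counts = np.zeros((D, V), dtype=np.int64)
    records: list[DrugRecord] = []
    base_date = datetime.date(2020, 1, 1)

    for d in range(D):
        n_d = max(1, int(rng.poisson(config.mean_doc_length)))
        z = rng.choice(K, size=n_d, p=theta[d])
        words: list[int] = []
        for k in range(K):
            m = int((z == k).sum())
            if m:
                words.extend(rng.choice(V, size=m, p=phi[k]).tolist())
        np.add.at(counts[d], words, 1)

        inds = set(topic_indications[dominant[d]])
        for k in range(K):
            if k == dominant[d]:
                continue
            for ind in sorted(topic_indications[k]):
                if rng.random() < config.indication_noise:
                    inds.add(ind)

        records.append(
            DrugRecord(
                drug_id=f"drug{d:04d}",
                sections={"AR": " ".join(terms[w] for w in words)},
                has_boxed_warning=bool(rng.random() < config.bw_prob),
                indications=frozenset(inds),
                effective_date=base_date + datetime.timedelta(days=d),
                atc_level1=ATC_LETTERS[dominant[d] % config.n_atc],
            )
        )

    used = np.flatnonzero(counts.sum(axis=0) > 0)
    matrix = DrugTermMatrix(
        [r.drug_id for r in records],
        [f"t{j + 1:04d}" for j in used],
        counts[:, used],
    )
    truth = SyntheticTruth(
        theta_true=theta,
        phi_true=phi,
        topic_indications=topic_indications,
        dominant_topic=dominant,
    )
    return records, matrix, truth
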