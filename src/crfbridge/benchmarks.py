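"""Reusable study drivers: transfer benefit and embedding-adaptation checks.

These functions run the full pipelines at the toolkit's reference problem
sizes (documented in the methods note) and return the measured quantities;
both the test suite and the reproduction script call them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np

from .corpus_io import TextCorpus
from .crf import TrainConfig, train_crf, tag_corpus
from .embeddings import SkipGramConfig, train_skipgram
from .evaluation import score
from .synthetic_data import (
    SyntheticSpec,
    generate_tagged_corpora,
    generate_text_corpus,
)
from .transfer import transfer_train

__all__ = [
    "TransferTrialResult",
    "transfer_benefit_trial",
    "transfer_benefit_median",
    "topic_similarity_trial",
    "topic_separation_successes",
]


@dataclass
class TransferTrialResult:
    seed: int
    transfer_macro_f1: float
    cold_macro_f1: float

    @property
    def delta(self) -> float:
        return self.transfer_macro_f1 - self.cold_macro_f1


def transfer_benefit_trial(
    seed: int,
    spec: SyntheticSpec | None = None,
    source_config: TrainConfig | None = None,
    target_config: TrainConfig | None = None,
) -> TransferTrialResult:
    """One paired comparison: bridge transfer vs cold start on one corpus draw.

    The source CRF is trained on the ample coarse-label corpus; the
    transfer model and a cold-start model then train on the same
    low-resource fine-label corpus and are scored (macro-F1 excluding NA)
    on the same held-out test split.
    """
    spec = replace(spec, seed=seed) if spec is not None else SyntheticSpec(seed=seed)
    corpora = generate_tagged_corpora(spec)
    source_config = source_config or TrainConfig(
        max_epochs=15, patience=3, seed=seed
    )
    target_config = target_config or TrainConfig(
        max_epochs=20, patience=5, seed=seed
    )

    source_model = train_crf(
        corpora.source_train,
        corpora.source_dev,
        corpora.source_schema,
        source_config,
    )
    transfer_model = transfer_train(
        source_model,
        corpora.target_train,
        corpora.target_dev,
        corpora.target_schema,
        target_config,
    )
    cold_model = train_crf(
        corpora.target_train,
        corpora.target_dev,
        corpora.target_schema,
        target_config,
    )

    transfer_pred = tag_corpus(transfer_model, corpora.target_test)
    cold_pred = tag_corpus(cold_model, corpora.target_test)
    transfer_f1 = score(
        corpora.target_test, transfer_pred, corpora.target_schema
    ).macro_f1
    cold_f1 = score(
        corpora.target_test, cold_pred, corpora.target_schema
    ).macro_f1
    return TransferTrialResult(seed, transfer_f1, cold_f1)


def transfer_benefit_median(
    n_seeds: int = 10, base_seed: int = 0, **kwargs
) -> tuple[float, list[TransferTrialResult]]:
    """Median transfer-minus-cold macro-F1 gap over ``n_seeds`` corpus draws."""
    results = [
        transfer_benefit_trial(base_seed + i, **kwargs)
        for i in range(n_seeds)
    ]
    return float(np.median([r.delta for r in results])), results


def _mean_pairwise_cosine(vectors: np.ndarray) -> float:
    normed = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
    sims = [
        float(normed[i] @ normed[j])
        for i, j in combinations(range(len(normed)), 2)
    ]
    return float(np.mean(sims))


def topic_similarity_trial(
    seed: int,
    n_sentences: int = 150,
    words_per_topic: int = 10,
    config: SkipGramConfig | None = None,
) -> tuple[float, float]:
    """(within-topic, between-topic) mean cosine similarity of input vectors.

    Trains small skip-gram vectors on a two-topic corpus; words inside one
    topic occur in interchangeable contexts, so their vectors should end up
    closer together than cross-topic pairs.
    """
    config = config or SkipGramConfig(
        dim=16, window=3, negatives=5, initial_lr=0.1, epochs=10, seed=seed
    )
    corpus = generate_text_corpus(
        n_sentences, n_topics=2, words_per_topic=words_per_topic, seed=seed
    )
    model = train_skipgram(corpus, config)

    groups = []
    for k in range(2):
        words = [
            f"topic{k}_w{i:02d}"
            for i in range(words_per_topic)
            if f"topic{k}_w{i:02d}" in model.vocab
        ]
        groups.append(
            np.stack([model.input_vectors[model.vocab[w]] for w in words])
        )
    within = float(
        np.mean([_mean_pairwise_cosine(g) for g in groups])
    )
    normed = [
        g / np.linalg.norm(g, axis=1, keepdims=True) for g in groups
    ]
    between = float(np.mean(normed[0] @ normed[1].T))
    return within, between


def topic_separation_successes(
    n_seeds: int = 10, base_seed: int = 0, **kwargs
) -> tuple[int, list[tuple[float, float]]]:
    """How many of ``n_seeds`` runs put within-topic above between-topic."""
    pairs = [
        topic_similarity_trial(base_seed + i, **kwargs)
        for i in range(n_seeds)
    ]
    wins = sum(1 for w, b in pairs if w > b)
    return wins, pairs
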