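"""Skip-gram word embeddings with negative sampling and incremental
domain adaptation.

The skip-gram objective maximizes, averaged over all T token occurrences,
the log probability of each context word within a window of size c around
the center word.  The full softmax over the vocabulary is replaced by
negative sampling: for each observed (center, context) pair the model scores
the true context against k noise words drawn from a unigram-based
distribution U(w),

    log sigma(v'_ctx . v_ctr) + sum_i log sigma(-v'_neg_i . v_ctr).

Adapting pretrained vectors to a small specialist corpus (vocabulary V_1)
without destroying what a large general corpus (vocabulary V_0) taught uses
two devices:

* **averaged initialization** — a word new to the vocabulary starts at the
  per-dimension mean of the vectors of the words in the sentence where it
  first appears (unknown neighbors contribute the unknown vector v_0);
* **split learning rates** — new words (V_1 \\ V_0) train under a large
  initial rate (0.2 by default) while words the base model already knows
  (V_0 ∩ V_1) move under a rate scaled down by the new-word fraction
  |V_1\\V_0| / |V_0 ∪ V_1|; both decay linearly to zero over the adaptation
  pass.

Updates are applied sequentially in corpus order with a seeded shuffle per
epoch, so training is bit-reproducible for a given seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import TextCorpus

__all__ = [
    "UNK_TOKEN",
    "EmbeddingModel",
    "SkipGramConfig",
    "AdaptSchedule",
    "normalize_digits",
    "negative_sampling_objective",
    "train_skipgram",
    "averaged_init",
    "adapt_learning_rate",
    "incremental_train",
]

UNK_TOKEN = "<unk>"

_DIGIT_RUN = re.compile(r"[0-9]+")


def normalize_digits(token: str) -> str:
    """Replace each maximal run of m digits with the literal ``NUM<m>``.

    Collapses surface variation in dates, phone numbers, bed numbers etc.
    into length patterns, e.g. ``08-08-1988`` -> ``NUM2-NUM2-NUM4``.
    """
    return _DIGIT_RUN.sub(lambda m: f"NUM{len(m.group())}", token)


@dataclass
class EmbeddingModel:
    """Input/output vector tables over a vocabulary.

    ``input_vectors[i]`` is v_w for the word with index i and
    ``output_vectors[i]`` is v'_w.  The unknown-word vector v_0 is the row
    of the ordinary vocabulary entry ``<unk>`` when present, else zeros.
    """

    vocab: dict[str, int]
    input_vectors: np.ndarray
    output_vectors: np.ndarray
    dim: int

    def __post_init__(self) -> None:
        self.input_vectors = np.asarray(self.input_vectors, dtype=np.float64)
        self.output_vectors = np.asarray(self.output_vectors, dtype=np.float64)
        n = len(self.vocab)
        if self.input_vectors.shape != (n, self.dim):
            raise ValueError(
                f"input table shape {self.input_vectors.shape} != ({n}, {self.dim})"
            )
        if self.output_vectors.shape != (n, self.dim):
            raise ValueError(
                f"output table shape {self.output_vectors.shape} != ({n}, {self.dim})"
            )
        if not (
            np.isfinite(self.input_vectors).all()
            and np.isfinite(self.output_vectors).all()
        ):
            raise ValueError("embedding tables contain non-finite entries")

    @property
    def words(self) -> list[str]:
        return sorted(self.vocab, key=self.vocab.__getitem__)

    @property
    def unknown_vector(self) -> np.ndarray:
        idx = self.vocab.get(UNK_TOKEN)
        if idx is None:
            return np.zeros(self.dim)
        return self.input_vectors[idx]

    def vector(self, word: str) -> np.ndarray:
        """Input vector of ``word``, falling back to the unknown vector."""
        idx = self.vocab.get(word)
        if idx is None:
            return self.unknown_vector
        return self.input_vectors[idx]

    def copy(self) -> "EmbeddingModel":
        return EmbeddingModel(
            vocab=dict(self.vocab),
            input_vectors=self.input_vectors.copy(),
            output_vectors=self.output_vectors.copy(),
            dim=self.dim,
        )


@dataclass
class SkipGramConfig:
    """Training hyperparameters.

    Defaults follow the settings commonly reported best for named-entity
    work: 200 dimensions, window 5, 10 negative samples, initial rate 0.05,
    20 epochs.  ``noise_exponent`` is the power applied to the unigram
    distribution U(w) when drawing noise words (1.0 = raw unigram; 0.75 is
    the conventional smoothing and available here).  ``subsample`` enables
    frequent-word subsampling at the given threshold when > 0 (off by
    default).  Words rarer than ``min_count`` are merged into ``<unk>``.
    """

    dim: int = 200
    window: int = 5
    negatives: int = 10
    initial_lr: float = 0.05
    epochs: int = 20
    noise_exponent: float = 1.0
    min_count: int = 1
    subsample: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1 or self.negatives < 1 or self.dim < 1:
            raise ValueError("window, negatives and dim must be >= 1")
        if self.initial_lr <= 0 or self.epochs < 1:
            raise ValueError("initial_lr must be > 0 and epochs >= 1")


@dataclass
class AdaptSchedule:
    """Split linear learning-rate schedule for incremental adaptation.

    ``alpha0_new`` applies to words absent from the base vocabulary;
    ``alpha0_old`` (default: alpha0_new scaled by the new-word fraction of
    the merged vocabulary) applies to words the base model already has.
    Both decay linearly to exactly zero at ``t = n`` consumed samples.
    """

    n: int
    alpha0_new: float = 0.2
    alpha0_old: float | None = None

    def resolve_old_rate(self, n_new_words: int, n_union: int) -> float:
        if self.alpha0_old is not None:
            return self.alpha0_old
        if n_union == 0:
            return 0.0
        return self.alpha0_new * n_new_words / n_union


def adapt_learning_rate(
    t: int, word_class: str, schedule: AdaptSchedule
) -> float:
    """Learning rate after ``t`` of ``schedule.n`` samples for a word class.

    ``word_class`` is ``"new"`` (word in V_1 \\ V_0) or ``"old"``
    (word in V_0 ∩ V_1).  Linear decay: alpha_t = alpha_0 (1 - t/n).
    """
    if t < 0 or t > schedule.n:
        raise ValueError(f"t={t} outside [0, n={schedule.n}]")
    if word_class == "new":
        alpha0 = schedule.alpha0_new
    elif word_class == "old":
        if schedule.alpha0_old is None:
            raise ValueError("schedule.alpha0_old has not been resolved")
        alpha0 = schedule.alpha0_old
    else:
        raise ValueError(f"word_class must be 'new' or 'old', got {word_class!r}")
    if schedule.n == 0:
        return 0.0
    return alpha0 * (1.0 - t / schedule.n)


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def negative_sampling_objective(
    center: int,
    context: int,
    negatives: Sequence[int],
    model: EmbeddingModel,
) -> tuple[float, dict[str, np.ndarray]]:
    """Objective value and exact ascent gradients for one training sample.

    Returns ``(value, grads)`` where grads holds ``d_center`` (w.r.t. the
    center's input vector), ``d_context`` (w.r.t. the context's output
    vector) and ``d_negatives`` (k rows, w.r.t. each noise word's output
    vector).  The value is
    ``log sigma(v'_ctx . v_ctr) + sum_i log sigma(-v'_neg_i . v_ctr)``.
    """
    v_in = model.input_vectors[center]
    v_out = model.output_vectors[context]
    negs = np.asarray(negatives, dtype=np.int64)
    v_negs = model.output_vectors[negs]

    s_pos = float(v_out @ v_in)
    s_negs = v_negs @ v_in

    sig_pos = _sigmoid(s_pos)
    sig_negs = _sigmoid(s_negs)

    value = float(np.log(sig_pos) + np.sum(np.log(1.0 - sig_negs)))
    d_center = (1.0 - sig_pos) * v_out - sig_negs @ v_negs
    d_context = (1.0 - sig_pos) * v_in
    d_negatives = -sig_negs[:, None] * v_in[None, :]
    return value, {
        "d_center": d_center,
        "d_context": d_context,
        "d_negatives": d_negatives,
    }


def _build_vocab(
    corpus: TextCorpus, min_count: int
) -> tuple[dict[str, int], np.ndarray]:
    """Vocabulary (with ``<unk>`` absorbing rare words) and per-id counts."""
    counts: dict[str, int] = {}
    for sent in corpus.sentences:
        for w in sent:
            counts[w] = counts.get(w, 0) + 1
    vocab: dict[str, int] = {UNK_TOKEN: 0}
    unk_count = 0
    for w in sorted(counts):  # sorted for determinism
        if counts[w] >= min_count:
            vocab[w] = len(vocab)
        else:
            unk_count += counts[w]
    freq = np.zeros(len(vocab), dtype=np.float64)
    freq[0] = unk_count
    for w, c in counts.items():
        if w in vocab:
            freq[vocab[w]] = c
    return vocab, freq


def _noise_distribution(freq: np.ndarray, exponent: float) -> np.ndarray:
    p = np.where(freq > 0, freq, 0.0) ** exponent
    total = p.sum()
    if total <= 0:
        raise ValueError("empty corpus: no tokens to build noise distribution")
    return p / total


def _corpus_ids(corpus: TextCorpus, vocab: dict[str, int]) -> list[np.ndarray]:
    unk = vocab[UNK_TOKEN]
    return [
        np.array([vocab.get(w, unk) for w in sent], dtype=np.int64)
        for sent in corpus.sentences
    ]


def _count_pairs(sentences: list[np.ndarray], window: int) -> int:
    total = 0
    for ids in sentences:
        L = len(ids)
        for i in range(L):
            total += min(i + window, L - 1) - max(i - window, 0)
    return total


def _sgns_pass(
    model: EmbeddingModel,
    sentences: list[np.ndarray],
    noise_p: np.ndarray,
    config: SkipGramConfig,
    rng: np.random.Generator,
    rate_fn,
    keep_prob: np.ndarray | None = None,
) -> None:
    """One full set of epochs of sequential SGD updates, in place.

    ``rate_fn(t, word_id)`` returns the step size for the parameter block of
    ``word_id`` after ``t`` consumed samples; a sample is one
    (center, context) pair together with its k negatives.
    """
    k = config.negatives
    vocab_ids = np.arange(len(noise_p))
    t = 0
    for _ in range(config.epochs):
        order = rng.permutation(len(sentences))
        for si in order:
            ids = sentences[si]
            if keep_prob is not None and len(ids) > 1:
                mask = rng.random(len(ids)) < keep_prob[ids]
                ids = ids[mask]
            L = len(ids)
            for i in range(L):
                lo = max(i - config.window, 0)
                hi = min(i + config.window, L - 1)
                for j in range(lo, hi + 1):
                    if j == i:
                        continue
                    center, context = int(ids[i]), int(ids[j])
                    negs = rng.choice(vocab_ids, size=k, p=noise_p)
                    _, grads = negative_sampling_objective(
                        center, context, negs, model
                    )
                    lr_c = rate_fn(t, center)
                    if lr_c > 0:
                        model.input_vectors[center] += lr_c * grads["d_center"]
                    lr_o = rate_fn(t, context)
                    if lr_o > 0:
                        model.output_vectors[context] += lr_o * grads["d_context"]
                    for m, neg in enumerate(negs):
                        lr_n = rate_fn(t, int(neg))
                        if lr_n > 0:
                            model.output_vectors[int(neg)] += (
                                lr_n * grads["d_negatives"][m]
                            )
                    t += 1


def train_skipgram(corpus: TextCorpus, config: SkipGramConfig) -> EmbeddingModel:
    """Train skip-gram vectors with negative sampling from scratch.

    Input vectors start uniform in (-0.5/d, 0.5/d); output vectors start at
    zero.  The learning rate decays linearly from ``initial_lr`` over all
    planned samples (floored at 1e-4 of the initial rate so late samples
    still move).  Deterministic for a given seed.
    """
    if not corpus.sentences:
        raise ValueError("cannot train on an empty corpus")
    vocab, freq = _build_vocab(corpus, config.min_count)
    rng = np.random.default_rng(config.seed)
    n_words = len(vocab)
    model = EmbeddingModel(
        vocab=vocab,
        input_vectors=(rng.random((n_words, config.dim)) - 0.5) / config.dim,
        output_vectors=np.zeros((n_words, config.dim)),
        dim=config.dim,
    )
    noise_p = _noise_distribution(freq, config.noise_exponent)
    sentences = _corpus_ids(corpus, vocab)
    n_total = max(config.epochs * _count_pairs(sentences, config.window), 1)

    keep_prob = None
    if config.subsample > 0:
        rel = freq / max(freq.sum(), 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            keep = np.sqrt(config.subsample / np.where(rel > 0, rel, 1.0)) + (
                config.subsample / np.where(rel > 0, rel, 1.0)
            )
        keep_prob = np.clip(keep, 0.0, 1.0)

    def rate(t: int, _word: int) -> float:
        return config.initial_lr * max(1.0 - t / n_total, 1e-4)

    _sgns_pass(model, sentences, noise_p, config, rng, rate, keep_prob)
    return model


def averaged_init(tokens: Sequence[str], base: EmbeddingModel) -> np.ndarray:
    """Initial vector for a new word: the mean over its sentence's positions.

    Every position contributes its stored input vector when the word is in
    the base vocabulary and the unknown vector v_0 otherwise; the result is
    the per-dimension average over all S positions.
    """
    if not tokens:
        raise ValueError("averaged_init needs a non-empty sentence")
    acc = np.zeros(base.dim)
    for w in tokens:
        acc += base.vector(w)
    return acc / len(tokens)


def incremental_train(
    base: EmbeddingModel,
    new_corpus: TextCorpus,
    schedule: AdaptSchedule | None = None,
    config: SkipGramConfig | None = None,
) -> EmbeddingModel:
    """Adapt a pretrained model to a new domain corpus.

    Words new to the vocabulary (V_1 \\ V_0) are appended with
    averaged-initialization vectors (computed from the first sentence in
    which each appears) and train under the new-word rate; shared words
    (V_0 ∩ V_1) train under the damped old-word rate; words absent from the
    new corpus are untouched.  Returns a new model over V_0 ∪ V_1.
    """
    config = config or SkipGramConfig()
    if config.dim != base.dim:
        raise ValueError(
            f"config dim {config.dim} does not match base model dim {base.dim}"
        )
    if not new_corpus.sentences:
        raise ValueError("cannot adapt on an empty corpus")

    counts: dict[str, int] = {}
    for sent in new_corpus.sentences:
        for w in sent:
            counts[w] = counts.get(w, 0) + 1
    v1 = {w for w, c in counts.items() if c >= config.min_count}
    new_words = sorted(v1 - set(base.vocab))
    n_union = len(set(base.vocab) | v1)

    model = base.copy()
    # Append new words; averaged init from the first sentence containing each.
    pending = set(new_words)
    init_vec: dict[str, np.ndarray] = {}
    for sent in new_corpus.sentences:
        hit = pending.intersection(sent)
        if hit:
            for w in hit:
                init_vec[w] = averaged_init(sent, base)
            pending -= hit
        if not pending:
            break
    if new_words:
        extra_in = np.stack([init_vec[w] for w in new_words])
        extra_out = np.zeros((len(new_words), base.dim))
        model.input_vectors = np.vstack([model.input_vectors, extra_in])
        model.output_vectors = np.vstack([model.output_vectors, extra_out])
        for w in new_words:
            model.vocab[w] = len(model.vocab)

    # Restrict training to the new corpus: ids, counts and noise over V_1.
    unk = model.vocab.get(UNK_TOKEN)
    sentences = []
    for sent in new_corpus.sentences:
        ids = []
        for w in sent:
            if w in v1:
                ids.append(model.vocab[w])
            elif unk is not None:  # below min_count: train through <unk>
                ids.append(unk)
        if ids:
            sentences.append(np.array(ids, dtype=np.int64))
    freq = np.zeros(len(model.vocab))
    for ids in sentences:
        np.add.at(freq, ids, 1.0)
    noise_p = _noise_distribution(freq, config.noise_exponent)

    n_total = max(config.epochs * _count_pairs(sentences, config.window), 1)
    if schedule is None:
        schedule = AdaptSchedule(n=n_total)
    elif schedule.n <= 0:
        schedule = AdaptSchedule(
            n=n_total,
            alpha0_new=schedule.alpha0_new,
            alpha0_old=schedule.alpha0_old,
        )
    schedule.alpha0_old = schedule.resolve_old_rate(len(new_words), n_union)

    is_new = np.zeros(len(model.vocab), dtype=bool)
    for w in new_words:
        is_new[model.vocab[w]] = True

    def rate(t: int, word: int) -> float:
        t_eff = min(t, schedule.n)
        cls = "new" if is_new[word] else "old"
        return adapt_learning_rate(t_eff, cls, schedule)

    rng = np.random.default_rng(config.seed)
    _sgns_pass(model, sentences, noise_p, config, rng, rate)
    return model
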