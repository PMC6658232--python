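"""Linear-chain conditional random field: inference, likelihood, training.

The model assigns a sequence of labels y = (y_1..y_L) to a sentence x the
globally normalized log-linear probability

    p(y | x) = exp( sum_l [ W_f . f(y_l, x) + W_g . g(y_{l-1}, y_l) ] ) / Z(x)

with per-position emission weights W_f (|Y| x F over the sparse feature
space) and label-pair transition weights W_g (|Y| x |Y|).  The partition
function Z and the marginals come from the forward-backward recursions in
log space; decoding is Viterbi with ties broken toward the lower label
index.  Training minimizes the L2-regularized negative log-likelihood with
per-sentence AdaGrad updates and early stopping on development macro-F1
(NA excluded), the stopping metric chosen to match how tagging quality is
ultimately judged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .corpus_io import LabeledSentence, LabelSchema
from .features import (
    FeatureIndex,
    FeatureTemplateSet,
    FeatureVector,
    extract_features,
)

__all__ = [
    "CRFModel",
    "TrainConfig",
    "sentence_potentials",
    "forward_backward",
    "viterbi_decode",
    "neg_log_likelihood_and_grad",
    "emission_posterior",
    "train_crf",
    "tag_corpus",
]


@dataclass
class CRFModel:
    """Emission and transition weights plus the schema and feature index."""

    schema: LabelSchema
    feature_index: FeatureIndex
    templates: FeatureTemplateSet
    W_f: np.ndarray  # (|Y|, F)
    W_g: np.ndarray  # (|Y|, |Y|)

    def __post_init__(self) -> None:
        n_labels = len(self.schema)
        if self.W_f.shape[0] != n_labels:
            raise ValueError(
                f"W_f has {self.W_f.shape[0]} rows for {n_labels} labels"
            )
        if self.W_g.shape != (n_labels, n_labels):
            raise ValueError(f"W_g shape {self.W_g.shape} != ({n_labels},)*2")
        if not (np.isfinite(self.W_f).all() and np.isfinite(self.W_g).all()):
            raise ValueError("model weights contain non-finite entries")

    def save(self, path: str | Path) -> None:
        """Serialize as JSON: schema, feature names, dense weight arrays."""
        payload = {
            "schema": {
                "labels": list(self.schema.labels),
                "na_label": self.schema.na_label,
            },
            "feature_names": self.feature_index.names,
            "W_f": self.W_f.tolist(),
            "W_g": self.W_g.tolist(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CRFModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        schema = LabelSchema(
            labels=tuple(payload["schema"]["labels"]),
            na_label=payload["schema"]["na_label"],
        )
        return cls(
            schema=schema,
            feature_index=FeatureIndex.from_names(payload["feature_names"]),
            templates=FeatureTemplateSet(),
            W_f=np.asarray(payload["W_f"], dtype=np.float64),
            W_g=np.asarray(payload["W_g"], dtype=np.float64),
        )


@dataclass
class TrainConfig:
    """AdaGrad training hyperparameters.

    ``l2_lambda`` weights the (lambda/2)||W||^2 penalty on the full
    objective; ``patience`` is the number of consecutive epochs without
    development macro-F1 improvement tolerated before stopping.
    """

    l2_lambda: float = 1e-3
    adagrad_step: float = 0.1
    adagrad_epsilon: float = 1e-8
    max_epochs: int = 30
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def sentence_potentials(
    model: CRFModel, features: Sequence[FeatureVector]
) -> tuple[np.ndarray, np.ndarray]:
    """Emission score table (L x |Y|) and transition score table (|Y| x |Y|).

    ``emission[i, y] = W_f[y] . f(x_i)``; transitions are position-independent.
    """
    L = len(features)
    emission = np.zeros((L, model.W_f.shape[0]))
    for i, fv in enumerate(features):
        if len(fv.indices) and fv.indices.max() >= model.W_f.shape[1]:
            raise ValueError(
                f"feature id {int(fv.indices.max())} out of range "
                f"for feature space of size {model.W_f.shape[1]}"
            )
        if len(fv.indices):
            emission[i] = model.W_f[:, fv.indices] @ fv.values
    return emission, model.W_g.copy()


def forward_backward(
    emission: np.ndarray, transition: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-partition, per-position marginals, and pairwise marginals.

    Returns ``(log_Z, unary, pairwise)`` where ``unary[i, y] = p(y_i = y | x)``
    and ``pairwise[i, y, y'] = p(y_i = y, y_{i+1} = y' | x)`` (shape
    (L-1, |Y|, |Y|); empty for L = 1).  All recursions run in log space.
    """
    L, Y = emission.shape
    alpha = np.zeros((L, Y))
    alpha[0] = emission[0]
    for i in range(1, L):
        alpha[i] = emission[i] + logsumexp(
            alpha[i - 1][:, None] + transition, axis=0
        )
    log_z = float(logsumexp(alpha[-1]))

    beta = np.zeros((L, Y))
    for i in range(L - 2, -1, -1):
        beta[i] = logsumexp(
            transition + (emission[i + 1] + beta[i + 1])[None, :], axis=1
        )

    unary = np.exp(alpha + beta - log_z)
    unary /= unary.sum(axis=1, keepdims=True)  # clean residual round-off

    pairwise = np.zeros((max(L - 1, 0), Y, Y))
    for i in range(L - 1):
        logp = (
            alpha[i][:, None]
            + transition
            + (emission[i + 1] + beta[i + 1])[None, :]
            - log_z
        )
        pairwise[i] = np.exp(logp)
    return log_z, unary, pairwise


def viterbi_decode(
    emission: np.ndarray, transition: np.ndarray
) -> list[int]:
    """Highest-scoring label path; ties resolve to the lower label index."""
    L, Y = emission.shape
    delta = emission[0].copy()
    back = np.zeros((L, Y), dtype=np.int64)
    for i in range(1, L):
        scores = delta[:, None] + transition  # (prev, cur)
        back[i] = np.argmax(scores, axis=0)  # argmax -> first (lowest) index
        delta = emission[i] + scores[back[i], np.arange(Y)]
    path = [int(np.argmax(delta))]
    for i in range(L - 1, 0, -1):
        path.append(int(back[i, path[-1]]))
    return path[::-1]


def path_score(
    emission: np.ndarray, transition: np.ndarray, path: Sequence[int]
) -> float:
    """Unnormalized log score of one label path."""
    s = emission[0, path[0]]
    for i in range(1, len(path)):
        s += transition[path[i - 1], path[i]] + emission[i, path[i]]
    return float(s)


def neg_log_likelihood_and_grad(
    model: CRFModel,
    batch: Sequence[tuple[Sequence[FeatureVector], Sequence[int]]],
    l2_lambda: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Regularized NLL and its gradients over a batch of sentences.

    ``batch`` holds ``(features, label_ids)`` pairs.  The gradient is the
    classic expected-minus-observed feature counts plus ``lambda * W``.
    """
    if not batch:
        raise ValueError("batch must be non-empty")
    loss = 0.0
    g_wf = np.zeros_like(model.W_f)
    g_wg = np.zeros_like(model.W_g)
    for features, labels in batch:
        emission, transition = sentence_potentials(model, features)
        log_z, unary, pairwise = forward_backward(emission, transition)
        loss += log_z - path_score(emission, transition, labels)
        for i, fv in enumerate(features):
            if not len(fv.indices):
                continue
            diff = unary[i].copy()
            diff[labels[i]] -= 1.0
            g_wf[:, fv.indices] += diff[:, None] * fv.values[None, :]
        for i in range(len(labels) - 1):
            g_wg += pairwise[i]
            g_wg[labels[i], labels[i + 1]] -= 1.0
    if l2_lambda > 0:
        loss += 0.5 * l2_lambda * (
            float(np.sum(model.W_f**2)) + float(np.sum(model.W_g**2))
        )
        g_wf += l2_lambda * model.W_f
        g_wg += l2_lambda * model.W_g
    return float(loss), g_wf, g_wg


def emission_posterior(W_f: np.ndarray, fv: FeatureVector) -> np.ndarray:
    """Softmax over labels of the emission scores — the per-token
    logistic-regression view of the CRF's lower layer.  Numerically stable
    via max subtraction; strictly positive and sums to one.
    """
    if len(fv.indices):
        scores = W_f[:, fv.indices] @ fv.values
    else:
        scores = np.zeros(W_f.shape[0])
    scores = scores - scores.max()
    p = np.exp(scores)
    return p / p.sum()


def _macro_f1(gold: list[list[int]], pred: list[list[int]], schema: LabelSchema) -> float:
    # local import: evaluation pulls in sklearn, keep inference lightweight
    from .evaluation import score as eval_score

    labels = schema.labels
    g = [
        LabeledSentence(["w"] * len(s), [labels[y] for y in s]) for s in gold
    ]
    p = [
        LabeledSentence(["w"] * len(s), [labels[y] for y in s]) for s in pred
    ]
    return eval_score(g, p, schema).macro_f1


def train_crf(
    train: Sequence[LabeledSentence],
    dev: Sequence[LabeledSentence],
    schema: LabelSchema,
    config: TrainConfig,
    templates: FeatureTemplateSet | None = None,
    feature_index: FeatureIndex | None = None,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> CRFModel:
    """Train a CRF with per-sentence AdaGrad and early stopping.

    When ``feature_index`` is omitted a fresh index is grown on the training
    corpus; a supplied index is treated as frozen (the shared-space setting
    used by transfer learning).  ``init`` seeds the optimization; with
    ``max_epochs = 0`` the returned model carries the init weights verbatim.
    The weights returned are those of the best development epoch (macro-F1
    excluding NA); with an empty dev set the final epoch wins.
    """
    if not train:
        raise ValueError("training corpus must be non-empty")
    templates = templates or FeatureTemplateSet()
    grow = feature_index is None
    feature_index = feature_index if feature_index is not None else FeatureIndex()

    train_feats = [
        extract_features(s.tokens, templates, feature_index, grow=grow)
        for s in train
    ]
    dev_feats = [
        extract_features(s.tokens, templates, feature_index, grow=False)
        for s in dev
    ]
    n_labels = len(schema)
    n_features = len(feature_index)
    if init is not None:
        W_f = np.array(init[0], dtype=np.float64)
        W_g = np.array(init[1], dtype=np.float64)
        if W_f.shape != (n_labels, n_features):
            raise ValueError(
                f"init W_f shape {W_f.shape} != ({n_labels}, {n_features})"
            )
    else:
        W_f = np.zeros((n_labels, n_features))
        W_g = np.zeros((n_labels, n_labels))

    model = CRFModel(schema, feature_index, templates, W_f, W_g)
    train_labels = [
        [schema.index(l) for l in s.labels] for s in train
    ]
    dev_gold = [[schema.index(l) for l in s.labels] for s in dev]

    accum_f = np.zeros_like(W_f)
    accum_g = np.zeros_like(W_g)
    rng = np.random.default_rng(config.seed)
    n_train = len(train)
    per_sentence_l2 = config.l2_lambda / n_train

    best_metric = -np.inf
    best = (W_f.copy(), W_g.copy())
    epochs_since_best = 0

    for _epoch in range(config.max_epochs):
        for si in rng.permutation(n_train):
            _, g_wf, g_wg = neg_log_likelihood_and_grad(
                model,
                [(train_feats[si], train_labels[si])],
                per_sentence_l2,
            )
            accum_f += g_wf**2
            accum_g += g_wg**2
            model.W_f -= (
                config.adagrad_step
                * g_wf
                / np.sqrt(accum_f + config.adagrad_epsilon)
            )
            model.W_g -= (
                config.adagrad_step
                * g_wg
                / np.sqrt(accum_g + config.adagrad_epsilon)
            )
        if dev:
            preds = []
            for feats in dev_feats:
                emission, transition = sentence_potentials(model, feats)
                preds.append(viterbi_decode(emission, transition))
            metric = _macro_f1(dev_gold, preds, schema)
        else:
            loss, _, _ = neg_log_likelihood_and_grad(
                model,
                list(zip(train_feats, train_labels)),
                config.l2_lambda,
            )
            metric = -loss
        if metric > best_metric:
            best_metric = metric
            best = (model.W_f.copy(), model.W_g.copy())
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                break

    model.W_f, model.W_g = best
    return model


def tag_corpus(
    model: CRFModel, sentences: Sequence[LabeledSentence]
) -> list[LabeledSentence]:
    """Viterbi-tag sentences (input labels are ignored)."""
    out = []
    for sent in sentences:
        feats = extract_features(
            sent.tokens, model.templates, model.feature_index, grow=False
        )
        emission, transition = sentence_potentials(model, feats)
        path = viterbi_decode(emission, transition)
        out.append(
            LabeledSentence(
                list(sent.tokens), [model.schema.labels[y] for y in path]
            )
        )
    return out
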