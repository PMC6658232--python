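"""Transfer learning between label sets via a label-correlation bridge.

Sequence taggers for two domains rarely share a label inventory: a general
source corpus tags PERSON or DATE while a specialist target form wants
given names, last names, admission dates.  Rather than hand-mapping labels,
the bridge learns the correlation.  The procedure has three steps:

1. train a CRF on the source domain (done elsewhere; its emission matrix
   W_s is frozen here);
2. feed each target-domain token's source-label scores a = W_s f(x) into a
   multinomial logistic classifier with weights W_t over target labels —
   because both layers are linear, the stack is exactly the single
   logistic model softmax((W_t W_s) f(x));
3. initialize the target CRF's emission weights with the product W_t W_s,
   zero the NA row (the dominant irrelevant-content class would otherwise
   bias the start), zero the transitions (label co-occurrence is domain
   specific and not transferred), and fine-tune with AdaGrad under early
   stopping so the inherited source knowledge is not trained away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus_io import LabeledSentence, LabelSchema
from .crf import CRFModel, TrainConfig, train_crf
from .features import FeatureIndex, FeatureVector, extract_features

__all__ = [
    "TransferBridge",
    "source_scores",
    "train_bridge",
    "compose_init",
    "transfer_train",
]


@dataclass
class TransferBridge:
    """Frozen source emission weights plus learned target-over-source weights."""

    source_emission: np.ndarray  # W_s, (|Y_src|, F), never modified
    bridge_weights: np.ndarray  # W_t, (|Y_tgt|, |Y_src|)
    source_schema: LabelSchema
    target_schema: LabelSchema
    # Union feature space: the source model's index grown over the target
    # corpus.  A grown copy, so the source model itself stays untouched.
    feature_index: FeatureIndex | None = None

    def __post_init__(self) -> None:
        if self.bridge_weights.shape != (
            len(self.target_schema),
            len(self.source_schema),
        ):
            raise ValueError(
                f"W_t shape {self.bridge_weights.shape} inconsistent with "
                f"{len(self.target_schema)} target / "
                f"{len(self.source_schema)} source labels"
            )
        if self.source_emission.shape[0] != len(self.source_schema):
            raise ValueError("W_s row count != number of source labels")


def source_scores(bridge: TransferBridge, fv: FeatureVector) -> np.ndarray:
    """Raw linear source-label scores a = W_s f for one token.

    Scores are deliberately not passed through softmax: keeping the layer
    linear makes the product initialization W_t W_s exactly equivalent to
    the stacked classifier.
    """
    if len(fv.indices) == 0:
        return np.zeros(bridge.source_emission.shape[0])
    if fv.indices.max() >= bridge.source_emission.shape[1]:
        raise ValueError(
            f"feature id {int(fv.indices.max())} outside the bridge's "
            f"feature space ({bridge.source_emission.shape[1]})"
        )
    return bridge.source_emission[:, fv.indices] @ fv.values


def _pad_columns(W: np.ndarray, n_cols: int) -> np.ndarray:
    """Zero-pad a weight matrix on the right to ``n_cols`` columns."""
    if W.shape[1] == n_cols:
        return W.copy()
    if W.shape[1] > n_cols:
        raise ValueError("cannot shrink a weight matrix")
    out = np.zeros((W.shape[0], n_cols))
    out[:, : W.shape[1]] = W
    return out


def train_bridge(
    source_model: CRFModel,
    target_train: Sequence[LabeledSentence],
    target_schema: LabelSchema,
    config: TrainConfig,
) -> TransferBridge:
    """Learn W_t: a multinomial logistic map from source scores to target labels.

    Target sentences are featurized against the source model's feature
    index with growth enabled (the shared feature space is the union of
    both domains); the frozen copy of W_s is zero-padded to the grown
    width, so unseen-in-source features contribute nothing to the scores.
    Optimization is AdaGrad from zero initialization over per-token
    examples of the cross-entropy loss; deterministic for a given seed.
    """
    if not target_train:
        raise ValueError("target training corpus must be non-empty")
    shared_index = FeatureIndex.from_names(source_model.feature_index.names)
    feats = [
        extract_features(
            s.tokens, source_model.templates, shared_index, grow=True
        )
        for s in target_train
    ]
    n_features = len(shared_index)
    W_s = _pad_columns(source_model.W_f, n_features)

    # Per-token training examples (a_i, y_i) in the source-score space.
    xs: list[np.ndarray] = []
    ys: list[int] = []
    for sent, sent_feats in zip(target_train, feats):
        for lbl, fv in zip(sent.labels, sent_feats):
            if len(fv.indices):
                xs.append(W_s[:, fv.indices] @ fv.values)
            else:
                xs.append(np.zeros(W_s.shape[0]))
            ys.append(target_schema.index(lbl))
    X = np.stack(xs)
    y = np.array(ys, dtype=np.int64)
    n = len(y)

    n_tgt = len(target_schema)
    W_t = np.zeros((n_tgt, len(source_model.schema)))
    accum = np.zeros_like(W_t)
    rng = np.random.default_rng(config.seed)
    lam = config.l2_lambda / n
    for _ in range(max(config.max_epochs, 1)):
        for i in rng.permutation(n):
            scores = W_t @ X[i]
            scores -= scores.max()
            p = np.exp(scores)
            p /= p.sum()
            p[y[i]] -= 1.0
            g = p[:, None] * X[i][None, :] + lam * W_t
            accum += g**2
            W_t -= config.adagrad_step * g / np.sqrt(
                accum + config.adagrad_epsilon
            )
    return TransferBridge(
        source_emission=W_s,
        bridge_weights=W_t,
        source_schema=source_model.schema,
        target_schema=target_schema,
        feature_index=shared_index,
    )


def bridge_nll_and_grad(
    W_t: np.ndarray, X: np.ndarray, y: np.ndarray, l2_lambda: float = 0.0
) -> tuple[float, np.ndarray]:
    """Cross-entropy loss and gradient of the bridge classifier.

    Exposed separately so the training loss can be checked against
    finite differences and reference solvers.
    """
    scores = X @ W_t.T
    scores -= scores.max(axis=1, keepdims=True)
    logp = scores - np.log(np.exp(scores).sum(axis=1, keepdims=True))
    n = len(y)
    loss = -float(logp[np.arange(n), y].sum())
    p = np.exp(logp)
    p[np.arange(n), y] -= 1.0
    grad = p.T @ X
    if l2_lambda > 0:
        loss += 0.5 * l2_lambda * float(np.sum(W_t**2))
        grad += l2_lambda * W_t
    return loss, grad


def compose_init(bridge: TransferBridge) -> tuple[np.ndarray, np.ndarray]:
    """Target initialization: W_f = W_t W_s with the NA row zeroed.

    Transition weights start at zero — label co-occurrence patterns are
    domain specific and are not transferred.  The NA row reset counters the
    dominance of the irrelevant-content class in the target corpus.
    """
    W_f = bridge.bridge_weights @ bridge.source_emission
    na = bridge.target_schema.na_index  # schema guarantees membership
    W_f[na, :] = 0.0
    W_g = np.zeros((len(bridge.target_schema), len(bridge.target_schema)))
    return W_f, W_g


def transfer_train(
    source_model: CRFModel,
    target_train: Sequence[LabeledSentence],
    target_dev: Sequence[LabeledSentence],
    target_schema: LabelSchema,
    config: TrainConfig,
) -> CRFModel:
    """Full three-step transfer: bridge, product init, fine-tune.

    Fine-tuning runs over the shared (grown) feature index with the
    composed initialization; early stopping on dev macro-F1 keeps the
    model from drifting far from the inherited source weights.
    """
    bridge = train_bridge(source_model, target_train, target_schema, config)
    W_f0, W_g0 = compose_init(bridge)
    return train_crf(
        target_train,
        target_dev,
        target_schema,
        config,
        templates=source_model.templates,
        feature_index=bridge.feature_index,
        init=(W_f0, W_g0),
    )
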