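"""Token-level tagging evaluation and baselines.

Per-class precision, recall and F1 are pooled two ways: macro averaging
(unweighted mean over classes, the headline measure because it rewards
systems that work on rare slots, not just the dominant ones) and micro
averaging (pooled token counts).  The dominant not-applicable class is
excluded from the macro average by default and its F1 reported separately
— filtering irrelevant content is a different job from filling rare slots.

A paired Wilcoxon signed-rank test compares two systems on per-document
scores, with the exact permutation null for small samples.  The Random and
Majority taggers provide the floor baselines.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import precision_recall_fscore_support

from .corpus_io import LabeledSentence, LabelSchema

__all__ = [
    "ClassScore",
    "EvalReport",
    "score",
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "baseline_random",
    "baseline_majority",
]


@dataclass
class ClassScore:
    precision: float
    recall: float
    f1: float
    support: int


@dataclass
class EvalReport:
    """Per-class and averaged precision/recall/F1 with supports."""

    per_class: dict[str, ClassScore]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    na_f1: float
    n_tokens: int

    def to_dict(self) -> dict:
        return {
            "per_class": {
                k: vars(v).copy() for k, v in self.per_class.items()
            },
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "micro_f1": self.micro_f1,
            "na_f1": self.na_f1,
            "n_tokens": self.n_tokens,
        }


def _flatten(
    gold: Sequence[LabeledSentence], pred: Sequence[LabeledSentence]
) -> tuple[list[str], list[str]]:
    if len(gold) != len(pred):
        raise ValueError(
            f"{len(gold)} gold sentences vs {len(pred)} predicted"
        )
    g_out, p_out = [], []
    for gs, ps in zip(gold, pred):
        if len(gs) != len(ps):
            raise ValueError(
                "sentence length mismatch between gold and prediction"
            )
        g_out.extend(gs.labels)
        p_out.extend(ps.labels)
    return g_out, p_out


def score(
    gold: Sequence[LabeledSentence],
    pred: Sequence[LabeledSentence],
    schema: LabelSchema,
    include_na: bool = False,
    drop_absent: bool = False,
) -> EvalReport:
    """Token-level evaluation report.

    ``include_na`` folds the NA class into the macro averages; with
    ``drop_absent`` classes appearing in neither gold nor prediction are
    dropped from the macro average instead of contributing zero.
    """
    g, p = _flatten(gold, pred)
    labels = list(schema.labels)
    prec, rec, f1, support = precision_recall_fscore_support(
        g, p, labels=labels, zero_division=0
    )
    per_class = {
        lbl: ClassScore(float(pr), float(rc), float(fv), int(sp))
        for lbl, pr, rc, fv, sp in zip(labels, prec, rec, f1, support)
    }

    macro_pool = labels if include_na else [l for l in labels if l != schema.na_label]
    if drop_absent:
        seen = set(g) | set(p)
        macro_pool = [l for l in macro_pool if l in seen]
    if macro_pool:
        macro_p = float(np.mean([per_class[l].precision for l in macro_pool]))
        macro_r = float(np.mean([per_class[l].recall for l in macro_pool]))
        macro_f = float(np.mean([per_class[l].f1 for l in macro_pool]))
    else:
        macro_p = macro_r = macro_f = 0.0

    micro_p, micro_r, micro_f, _ = precision_recall_fscore_support(
        g, p, labels=labels, average="micro", zero_division=0
    )
    return EvalReport(
        per_class=per_class,
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=macro_f,
        micro_precision=float(micro_p),
        micro_recall=float(micro_r),
        micro_f1=float(micro_f),
        na_f1=per_class[schema.na_label].f1,
        n_tokens=len(g),
    )


@dataclass
class WilcoxonResult:
    statistic: float  # min(W+, W-)
    w_plus: float
    p_value: float
    n_used: int
    degenerate: bool = False
    method: str = "exact"


def wilcoxon_signed_rank(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    exact_threshold: int = 12,
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped.  Up to ``exact_threshold`` pairs the null
    distribution of W+ is enumerated over all 2^n sign assignments (valid
    under ties in |d| because average ranks are held fixed); beyond that a
    normal approximation with tie and continuity corrections is used.
    All-zero differences give the degenerate result p = 1.
    """
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired score lists must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(0.0, 0.0, 1.0, 0, degenerate=True)
    if n < 5:
        raise ValueError(
            f"need >= 5 non-zero paired differences, got {n}"
        )
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    stat = min(w_plus, w_minus)

    if n <= exact_threshold:
        # Distribution of W+ under random signs, honoring tied ranks.
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        lo = float(np.mean(totals <= w_plus + 1e-9))
        hi = float(np.mean(totals >= w_plus - 1e-9))
        p = min(1.0, 2.0 * min(lo, hi))
        return WilcoxonResult(stat, w_plus, p, n, method="exact")

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    sd = np.sqrt(var)
    z = (stat - mean + 0.5) / sd  # continuity correction toward the mean
    p = min(1.0, 2.0 * float(norm.cdf(z)))
    return WilcoxonResult(stat, w_plus, p, n, method="normal")


def baseline_random(
    test: Sequence[LabeledSentence], schema: LabelSchema, seed: int = 0
) -> list[LabeledSentence]:
    """Assign every token a uniformly random schema label."""
    rng = np.random.default_rng(seed)
    out = []
    for sent in test:
        labels = [
            schema.labels[i]
            for i in rng.integers(0, len(schema.labels), size=len(sent))
        ]
        out.append(LabeledSentence(list(sent.tokens), labels))
    return out


def baseline_majority(
    train: Sequence[LabeledSentence], test: Sequence[LabeledSentence]
) -> list[LabeledSentence]:
    """Assign every token the most frequent training label.

    Frequency ties break to the lexicographically first label.
    """
    if not train:
        raise ValueError("majority baseline needs a non-empty training corpus")
    counts = Counter(l for s in train for l in s.labels)
    top = max(counts.values())
    majority = min(l for l, c in counts.items() if c == top)
    return [
        LabeledSentence(list(s.tokens), [majority] * len(s)) for s in test
    ]
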