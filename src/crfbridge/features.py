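"""Sparse feature extraction for sequence tagging.

Each token position yields unigram features over a three-word window
(w_{i-1}, w_i, w_{i+1}) and bigram features over the two adjacent pairs
(w_{i-1}w_i, w_i w_{i+1}), with explicit BOS/EOS sentinels at the sentence
boundaries.  Template features are binary.  Licensed ontology lookups
(medical metathesaurus candidates, medication codes, parse trees) are
deliberately out of scope; "hook" functions let callers plug in arbitrary
token-level annotators (gazetteer membership, coarse tags, shapes) that feed
the same sparse space.

Dense word-embedding features occupy ids in the same index (names are
disjoint from template names by construction), so a model's weight matrix
addresses both kinds uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

BOS = "<BOS>"
EOS = "<EOS>"

# A hook maps (tokens, position) -> annotation string or None (no feature).
Hook = Callable[[Sequence[str], int], "str | None"]


class FeatureIndex:
    """Mutable feature-name vocabulary mapping names to dense column ids.

    In training mode (``grow=True`` at extraction) unseen names are assigned
    fresh ids; with growth disabled unseen names are silently dropped, so
    test-time feature spaces never exceed the training space.
    """

    def __init__(self) -> None:
        self._ids: dict[str, int] = {}
        self._names: list[str] = []

    def __len__(self) -> int:
        return len(self._ids)

    def __contains__(self, name: str) -> bool:
        return name in self._ids

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def id_of(self, name: str, grow: bool) -> int | None:
        idx = self._ids.get(name)
        if idx is None and grow:
            idx = len(self._names)
            self._ids[name] = idx
            self._names.append(name)
        return idx

    @classmethod
    def from_names(cls, names: Sequence[str]) -> "FeatureIndex":
        fi = cls()
        for n in names:
            fi.id_of(n, grow=True)
        return fi


@dataclass
class FeatureTemplateSet:
    """Window templates plus named hook annotators.

    ``unigram_offsets`` defaults to the three-word window and
    ``bigram_offsets`` to the two adjacent pairs; both can be overridden via
    configuration.
    """

    unigram_offsets: tuple[int, ...] = (-1, 0, 1)
    bigram_offsets: tuple[tuple[int, int], ...] = ((-1, 0), (0, 1))
    hooks: dict[str, Hook] = field(default_factory=dict)


@dataclass
class FeatureVector:
    """Sparse features at one position: strictly increasing ids, finite values."""

    indices: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)

    @classmethod
    def from_pairs(cls, pairs: dict[int, float]) -> "FeatureVector":
        ids = np.array(sorted(pairs), dtype=np.int64)
        vals = np.array([pairs[i] for i in ids], dtype=np.float64)
        return cls(ids, vals)


def _window_token(tokens: Sequence[str], i: int) -> str:
    if i < 0:
        return BOS
    if i >= len(tokens):
        return EOS
    return tokens[i]


def extract_features(
    tokens: Sequence[str],
    templates: FeatureTemplateSet,
    feature_index: FeatureIndex,
    grow: bool = True,
) -> list[FeatureVector]:
    """Extract per-position sparse feature vectors for one sentence.

    Raises ``ValueError`` on an empty sentence.  Extraction is deterministic
    and position-local given the window.
    """
    if not tokens:
        raise ValueError("cannot extract features from an empty sentence")
    out: list[FeatureVector] = []
    for i in range(len(tokens)):
        pairs: dict[int, float] = {}

        def add(name: str, value: float = 1.0) -> None:
            idx = feature_index.id_of(name, grow)
            if idx is not None:
                pairs[idx] = pairs.get(idx, 0.0) + value

        for off in templates.unigram_offsets:
            add(f"U[{off:+d}]={_window_token(tokens, i + off)}")
        for a, b in templates.bigram_offsets:
            add(
                f"B[{a:+d},{b:+d}]="
                f"{_window_token(tokens, i + a)}|{_window_token(tokens, i + b)}"
            )
        for name, hook in templates.hooks.items():
            ann = hook(tokens, i)
            if ann is not None:
                add(f"H[{name}]={ann}")
        out.append(FeatureVector.from_pairs(pairs))
    return out


def attach_embedding_features(
    model,
    tokens: Sequence[str],
    feature_index: FeatureIndex,
    grow: bool = True,
) -> list[FeatureVector]:
    """Dense embedding features: position i carries the input vector of w_i.

    Unknown words fall back to the model's unknown vector.  The d dense
    feature names ``EMB[j]`` live in the shared index but never collide with
    template names.
    """
    blocks: list[FeatureVector] = []
    ids = [feature_index.id_of(f"EMB[{j}]", grow) for j in range(model.dim)]
    for tok in tokens:
        vec = model.vector(tok)
        pairs = {
            idx: float(vec[j]) for j, idx in enumerate(ids) if idx is not None
        }
        blocks.append(FeatureVector.from_pairs(pairs))
    return blocks


def merge_features(a: FeatureVector, b: FeatureVector) -> FeatureVector:
    """Union two sparse vectors (summing values on any shared id)."""
    pairs: dict[int, float] = dict(zip(a.indices.tolist(), a.values.tolist()))
    for i, v in zip(b.indices.tolist(), b.values.tolist()):
        pairs[i] = pairs.get(i, 0.0) + v
    return FeatureVector.from_pairs(pairs)


# ---------------------------------------------------------------------------
# ready-made hook factories


def gazetteer_hook(entries: Sequence[str], lowercase: bool = True) -> Hook:
    """Membership hook: fires "Y" when the current token is in the gazetteer."""
    table = {e.lower() if lowercase else e for e in entries}

    def hook(tokens: Sequence[str], i: int) -> str | None:
        tok = tokens[i].lower() if lowercase else tokens[i]
        return "Y" if tok in table else None

    return hook


def shape_hook() -> Hook:
    """Character-shape hook: maps e.g. ``Ab1-`` to ``Aa0-`` (collapsed runs)."""

    def hook(tokens: Sequence[str], i: int) -> str:
        shape = []
        for ch in tokens[i]:
            if ch.isupper():
                s = "A"
            elif ch.islower():
                s = "a"
            elif ch.isdigit():
                s = "0"
            else:
                s = ch
            if not shape or shape[-1] != s:
                shape.append(s)
        return "".join(shape)

    return hook


def tag_hook(tags: dict[str, str], default: str = "X") -> Hook:
    """Coarse-tag hook from a token-to-tag dictionary (e.g. POS-like tags)."""

    def hook(tokens: Sequence[str], i: int) -> str:
        return tags.get(tokens[i], default)

    return hook
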