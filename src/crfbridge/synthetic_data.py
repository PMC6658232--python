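"""Synthetic corpora for exercising every stage of the toolkit.

Real clinical handover, de-identification and newswire entity corpora are
restricted or licensed, so the pipeline is demonstrated and tested on
generated data that reproduces their *structure*:

* a **source domain** tagged with coarse entity classes (PERSON, DATE, ID,
  HOSPITAL) plus a filler class O;
* a **target domain** whose fine-grained labels each refine exactly one
  source label (PERSON -> given name / last name, DATE -> admission date /
  birth date, ...), with a dominant NA class — the mapping pattern that
  makes label-correlation transfer learnable;
* **topic-structured text corpora** (groups of interchangeable content
  words plus shared function words) for embedding-similarity tests.

Tokens come from disjoint per-label lexicons of synthetic word stems:
tests need controlled separability, not clinical realism.  Every generator
is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import LabeledSentence, LabelSchema, TextCorpus

__all__ = [
    "SyntheticSpec",
    "SyntheticCorpora",
    "generate_tagged_corpora",
    "generate_text_corpus",
]

DEFAULT_REFINEMENTS: dict[str, tuple[str, ...]] = {
    "PERSON": ("GIVEN_NAME", "LAST_NAME"),
    "DATE": ("ADMIT_DATE", "BIRTH_DATE"),
    "ID": ("PATIENT_ID",),
    "HOSPITAL": ("WARD", "TEAM"),
    "O": ("NA",),
}


@dataclass
class SyntheticSpec:
    """Generator parameters for the paired source/target corpora.

    ``refinements`` maps each coarse source label to the fine target labels
    that split it; the source NA-analogue maps to the target NA.  Corpus
    sizes default to the low-resource transfer setting this toolkit is
    built around: an ample source domain (500 train / 50 dev sentences)
    against a 10-sentence target training set with 50 dev and 200 test
    sentences.  ``na_fraction`` makes the filler class dominant (0.6);
    ``noise_rate`` mislabels a token's lexicon with the given probability;
    ``vocab_overlap`` controls how much of the filler vocabulary the two
    domains share.
    """

    refinements: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_REFINEMENTS)
    )
    source_na: str = "O"
    target_na: str = "NA"
    lexicon_size: int = 12
    na_lexicon_size: int = 20
    n_source_train: int = 500
    n_source_dev: int = 50
    n_target_train: int = 10
    n_target_dev: int = 50
    n_target_test: int = 200
    na_fraction: float = 0.6
    noise_rate: float = 0.05
    vocab_overlap: float = 0.5
    sentence_len: tuple[int, int] = (6, 12)
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.na_fraction, self.noise_rate, self.vocab_overlap):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.source_na not in self.refinements:
            raise ValueError(
                f"source NA label {self.source_na!r} missing from refinements"
            )
        if self.refinements[self.source_na] != (self.target_na,):
            raise ValueError(
                "the source NA label must refine to exactly the target NA"
            )
        targets = [t for ts in self.refinements.values() for t in ts]
        if len(targets) != len(set(targets)):
            raise ValueError("each target label may be refined once only")
        if self.lexicon_size < 1 or self.sentence_len[0] < 1:
            raise ValueError("lexicon_size and sentence lengths must be >= 1")

    @property
    def source_schema(self) -> LabelSchema:
        return LabelSchema(tuple(self.refinements), self.source_na)

    @property
    def target_schema(self) -> LabelSchema:
        labels = tuple(
            t for ts in self.refinements.values() for t in ts
        )
        return LabelSchema(labels, self.target_na)

    def target_lexicon(self, target_label: str) -> list[str]:
        """Disjoint synthetic word stems for one fine-grained label."""
        return [
            f"{target_label.lower()}_{i:02d}" for i in range(self.lexicon_size)
        ]

    def na_lexicons(self) -> tuple[list[str], list[str]]:
        """(source filler lexicon, target filler lexicon) with the requested overlap."""
        n_shared = round(self.vocab_overlap * self.na_lexicon_size)
        shared = [f"common_{i:02d}" for i in range(n_shared)]
        n_own = self.na_lexicon_size - n_shared
        src = shared + [f"srcfill_{i:02d}" for i in range(n_own)]
        tgt = shared + [f"tgtfill_{i:02d}" for i in range(n_own)]
        return src, tgt


@dataclass
class SyntheticCorpora:
    source_train: list[LabeledSentence]
    source_dev: list[LabeledSentence]
    target_train: list[LabeledSentence]
    target_dev: list[LabeledSentence]
    target_test: list[LabeledSentence]
    source_schema: LabelSchema
    target_schema: LabelSchema


def _gen_split(
    spec: SyntheticSpec,
    domain: str,
    n_sentences: int,
    rng: np.random.Generator,
) -> list[LabeledSentence]:
    src_na_lex, tgt_na_lex = spec.na_lexicons()
    na_lex = src_na_lex if domain == "source" else tgt_na_lex
    source_entities = [
        s for s in spec.refinements if s != spec.source_na
    ]
    target_entities = [
        t
        for s, ts in spec.refinements.items()
        if s != spec.source_na
        for t in ts
    ]
    all_words = list(na_lex) + [
        w for t in target_entities for w in spec.target_lexicon(t)
    ]
    na_label = spec.source_na if domain == "source" else spec.target_na

    sentences = []
    lo, hi = spec.sentence_len
    for _ in range(n_sentences):
        L = int(rng.integers(lo, hi + 1))
        tokens, labels = [], []
        for _ in range(L):
            if rng.random() < spec.na_fraction:
                label = na_label
                token = na_lex[rng.integers(len(na_lex))]
            elif domain == "source":
                label = source_entities[rng.integers(len(source_entities))]
                # a coarse entity token is drawn from the union of its
                # refinements' sub-lexicons, so source usage carries the
                # information transfer later exploits
                refs = spec.refinements[label]
                sub = spec.target_lexicon(refs[rng.integers(len(refs))])
                token = sub[rng.integers(len(sub))]
            else:
                label = target_entities[rng.integers(len(target_entities))]
                sub = spec.target_lexicon(label)
                token = sub[rng.integers(len(sub))]
            if spec.noise_rate > 0 and rng.random() < spec.noise_rate:
                token = all_words[rng.integers(len(all_words))]
            tokens.append(token)
            labels.append(label)
        sentences.append(LabeledSentence(tokens, labels))
    return sentences


def generate_tagged_corpora(spec: SyntheticSpec) -> SyntheticCorpora:
    """All five splits, deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    return SyntheticCorpora(
        source_train=_gen_split(spec, "source", spec.n_source_train, rng),
        source_dev=_gen_split(spec, "source", spec.n_source_dev, rng),
        target_train=_gen_split(spec, "target", spec.n_target_train, rng),
        target_dev=_gen_split(spec, "target", spec.n_target_dev, rng),
        target_test=_gen_split(spec, "target", spec.n_target_test, rng),
        source_schema=spec.source_schema,
        target_schema=spec.target_schema,
    )


def generate_text_corpus(
    n_sentences: int,
    topics: Mapping[str, Sequence[str]] | None = None,
    n_topics: int = 2,
    words_per_topic: int = 15,
    n_function_words: int = 8,
    function_word_prob: float = 0.3,
    sentence_len: tuple[int, int] = (5, 10),
    seed: int = 0,
) -> TextCorpus:
    """Topic-structured unlabeled text for embedding tests.

    Each sentence draws all content words from a single topic's vocabulary,
    mixed with function words shared across topics, so words within a topic
    occur in interchangeable contexts.  At least two topics are required.
    """
    if topics is None:
        topics = {
            f"topic{k}": [
                f"topic{k}_w{i:02d}" for i in range(words_per_topic)
            ]
            for k in range(n_topics)
        }
    if len(topics) < 2:
        raise ValueError("need at least two topics")
    function_words = [f"func_{i:02d}" for i in range(n_function_words)]
    names = list(topics)
    rng = np.random.default_rng(seed)
    lo, hi = sentence_len
    sentences = []
    for _ in range(n_sentences):
        topic = list(topics[names[rng.integers(len(names))]])
        L = int(rng.integers(lo, hi + 1))
        sent = []
        for _ in range(L):
            if function_words and rng.random() < function_word_prob:
                sent.append(function_words[rng.integers(len(function_words))])
            else:
                sent.append(topic[rng.integers(len(topic))])
        sentences.append(sent)
    return TextCorpus(sentences)
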