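import numpy as np
import pytest

from crfbridge.corpus_io import LabeledSentence, LabelSchema
from crfbridge.features import FeatureIndex, FeatureTemplateSet, extract_features


@pytest.fixture
def tiny_schema() -> LabelSchema:
    return LabelSchema(("A", "B", "NA"), "NA")


@pytest.fixture
def templates() -> FeatureTemplateSet:
    return FeatureTemplateSet()


def random_instance(rng: np.random.Generator, max_len: int = 6, max_labels: int = 5):
    """A random CRF scoring instance (emission, transition)."""
    L = int(rng.integers(1, max_len + 1))
    Y = int(rng.integers(2, max_labels + 1))
    emission = rng.normal(0, 2.0, size=(L, Y))
    transition = rng.normal(0, 1.5, size=(Y, Y))
    return emission, transition


def toy_word_label_corpus(schema: LabelSchema, n: int, seed: int):
    """Deterministic tagging task: each word occurs under exactly one label."""
    rng = np.random.default_rng(seed)
    lexicon = {
        lbl: [f"{lbl.lower()}tok{i}" for i in range(4)] for lbl in schema.labels
    }
    sents = []
    for _ in range(n):
        L = int(rng.integers(2, 6))
        toks, labs = [], []
        for _ in range(L):
            lbl = schema.labels[rng.integers(len(schema.labels))]
            toks.append(lexicon[lbl][rng.integers(4)])
            labs.append(lbl)
        sents.append(LabeledSentence(toks, labs))
    return sents
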