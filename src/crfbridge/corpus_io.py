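"""Corpus and vector-file I/O plus the label schema.

Labeled corpora are CoNLL-style two-column TSV files: one ``token<TAB>label``
line per token, a blank line between sentences, UTF-8 throughout.  Labels are
plain per-token classes (one heading per word plus a designated "not
applicable" class); an optional BIO conversion utility is provided for
interoperability but is not used by the rest of the toolkit.

Word vectors use the word2vec text interchange format: a ``count dim`` header
line followed by one ``word v1 ... vd`` line per vocabulary entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LabelSchema",
    "LabeledSentence",
    "TextCorpus",
    "CorpusFormatError",
    "SchemaError",
    "read_tagged_tsv",
    "write_tagged_tsv",
    "read_text_corpus",
    "read_vectors",
    "write_vectors",
    "to_bio",
    "from_bio",
    "example_handover_schema",
]


class CorpusFormatError(ValueError):
    """A corpus or vector file violates its format contract."""


class SchemaError(ValueError):
    """A label is missing from, or inconsistent with, a :class:`LabelSchema`."""


@dataclass(frozen=True)
class LabelSchema:
    """An ordered label set Y with a designated not-applicable class.

    Parameters
    ----------
    labels
        Ordered, unique, non-empty label names.
    na_label
        The label marking tokens that carry no extractable information.
        Must be a member of ``labels``.
    """

    labels: tuple[str, ...]
    na_label: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        if not self.labels:
            raise SchemaError("schema needs at least one label")
        if len(set(self.labels)) != len(self.labels):
            raise SchemaError("label names must be unique")
        if any(not lbl for lbl in self.labels):
            raise SchemaError("label names must be non-empty")
        if self.na_label not in self.labels:
            raise SchemaError(f"na_label {self.na_label!r} not in labels")

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise SchemaError(f"unknown label {label!r}") from None

    @property
    def na_index(self) -> int:
        return self.labels.index(self.na_label)

    @property
    def entity_labels(self) -> tuple[str, ...]:
        """All labels except the NA class."""
        return tuple(l for l in self.labels if l != self.na_label)


@dataclass
class LabeledSentence:
    """A token sequence with one label per token."""

    tokens: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.labels):
            raise ValueError(
                f"{len(self.tokens)} tokens but {len(self.labels)} labels"
            )
        if not self.tokens:
            raise ValueError("sentence must contain at least one token")

    def __len__(self) -> int:
        return len(self.tokens)

    def validate(self, schema: LabelSchema) -> None:
        for lbl in self.labels:
            if lbl not in schema.labels:
                raise SchemaError(f"label {lbl!r} not in schema")


@dataclass
class TextCorpus:
    """An unlabeled corpus: tokenized sentences for embedding training."""

    sentences: list[list[str]]

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)

    @property
    def vocabulary(self) -> set[str]:
        return {w for s in self.sentences for w in s}


def read_tagged_tsv(
    path: str | Path, schema: LabelSchema | None = None
) -> list[LabeledSentence]:
    """Read a two-column TSV corpus, splitting sentences on blank lines.

    When ``schema`` is given every label is validated against it; pass
    ``None`` to read label-agnostic files (e.g. input to the tagger where
    existing labels are placeholders).
    """
    path = Path(path)
    sentences: list[LabeledSentence] = []
    tokens: list[str] = []
    labels: list[str] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                if tokens:
                    sentences.append(LabeledSentence(tokens, labels))
                    tokens, labels = [], []
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 2 TAB-separated fields, "
                    f"got {len(fields)}"
                )
            tokens.append(fields[0])
            labels.append(fields[1])
    if tokens:
        sentences.append(LabeledSentence(tokens, labels))
    if schema is not None:
        for sent in sentences:
            sent.validate(schema)
    return sentences


def write_tagged_tsv(
    sentences: Iterable[LabeledSentence], path: str | Path
) -> None:
    """Write sentences as two-column TSV, one blank line between sentences."""
    blocks: list[str] = []
    for sent in sentences:
        for tok in sent.tokens:
            if "\t" in tok or "\n" in tok:
                raise ValueError(f"token {tok!r} contains TAB or newline")
        blocks.append(
            "".join(f"{t}\t{l}\n" for t, l in zip(sent.tokens, sent.labels))
        )
    Path(path).write_text("\n".join(blocks), encoding="utf-8")


def read_text_corpus(path: str | Path) -> TextCorpus:
    """Read a one-sentence-per-line whitespace-tokenized plain-text corpus."""
    sentences = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            toks = line.split()
            if toks:
                sentences.append(toks)
    return TextCorpus(sentences)


def write_text_corpus(corpus: TextCorpus, path: str | Path) -> None:
    Path(path).write_text(
        "".join(" ".join(s) + "\n" for s in corpus.sentences), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# word2vec-style text vector files


def write_vectors(model, path: str | Path) -> None:
    """Serialize an embedding model's input vectors as word2vec text.

    Numbers are written with 6 significant digits, the common precision of
    text-format vector interchange.
    """
    words = model.words
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(words)} {model.dim}\n")
        for w in words:
            vec = model.input_vectors[model.vocab[w]]
            fh.write(w + " " + " ".join(f"{x:.6g}" for x in vec) + "\n")


def read_vectors(path: str | Path):
    """Read a word2vec text vector file into an :class:`EmbeddingModel`.

    Only input vectors are stored in the format; the returned model's output
    vectors are zero-initialized (they are retrained on any further pass).
    """
    from .embeddings import EmbeddingModel

    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise CorpusFormatError(f"{path}:1: expected 'count dim' header")
        try:
            count, dim = int(header[0]), int(header[1])
        except ValueError:
            raise CorpusFormatError(
                f"{path}:1: non-integer header fields"
            ) from None
        vocab: dict[str, int] = {}
        vectors = np.zeros((count, dim), dtype=np.float64)
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split(" ")
            if len(fields) < 2:
                continue
            word, values = fields[0], fields[1:]
            if len(values) != dim:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected {dim} values, "
                    f"got {len(values)}"
                )
            if len(vocab) >= count:
                raise CorpusFormatError(
                    f"{path}:{lineno}: more rows than header count {count}"
                )
            vocab[word] = len(vocab)
            vectors[vocab[word]] = [float(v) for v in values]
    if len(vocab) != count:
        raise CorpusFormatError(
            f"{path}: header promised {count} rows, found {len(vocab)}"
        )
    return EmbeddingModel(
        vocab=vocab,
        input_vectors=vectors,
        output_vectors=np.zeros_like(vectors),
        dim=dim,
    )


# ---------------------------------------------------------------------------
# optional BIO conversion (off by default everywhere in the toolkit)


def to_bio(sentences: Iterable[LabeledSentence], na_label: str) -> list[LabeledSentence]:
    """Convert plain per-token classes to BIO encoding (NA maps to ``O``)."""
    out = []
    for sent in sentences:
        labels = []
        prev = None
        for lbl in sent.labels:
            if lbl == na_label:
                labels.append("O")
            elif lbl == prev:
                labels.append(f"I-{lbl}")
            else:
                labels.append(f"B-{lbl}")
            prev = lbl
        out.append(LabeledSentence(list(sent.tokens), labels))
    return out


def from_bio(sentences: Iterable[LabeledSentence], na_label: str) -> list[LabeledSentence]:
    """Inverse of :func:`to_bio` (drops the B/I distinction)."""
    out = []
    for sent in sentences:
        labels = [
            na_label if l == "O" else l.split("-", 1)[1] for l in sent.labels
        ]
        out.append(LabeledSentence(list(sent.tokens), labels))
    return out


def example_handover_schema() -> LabelSchema:
    """The bundled example schema: 37 handover-form headings plus NA.

    The heading inventory follows the structure of nursing shift-change
    handover forms (patient introduction, own-shift observations, appointments,
    medication, future care), which group fine-grained slots such as given
    name, ward, or admission reason under a dominant NA class for all other
    words.
    """
    headings = [
        "PI_GIVEN_NAMES", "PI_LAST_NAME", "PI_GENDER", "PI_AGE_IN_YEARS",
        "PI_CURRENT_ROOM", "PI_CURRENT_BED", "PI_ADMISSION_REASON",
        "PI_CHRONIC_CONDITION", "PI_DISEASE_HISTORY", "PI_UNDERDR_GIVEN_NAMES",
        "PI_UNDERDR_LAST_NAME", "PI_ADMIT_DATE",
        "MS_STATUS", "MS_CONTRAPTION", "MS_INPUT_DIET", "MS_INPUT_FLUID",
        "MS_OUTPUT_URINE", "MS_OUTPUT_OTHER", "MS_WOUND", "MS_MOBILITY",
        "MS_ACTIVITY", "MS_RISK_FALLS", "MS_RISK_PRESSURE", "MS_RISK_OTHER",
        "AP_CLINICIAN_TITLE", "AP_CLINICIAN_GIVEN_NAMES",
        "AP_CLINICIAN_LAST_NAME", "AP_HOSPITAL", "AP_CITY", "AP_WARD",
        "AP_DAY", "AP_TIME", "AP_PROCEDURE",
        "MED_MEDICINE", "MED_DOSAGE",
        "FC_ALERT", "FC_GOAL",
    ]
    return LabelSchema(labels=tuple(headings) + ("NA",), na_label="NA")
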