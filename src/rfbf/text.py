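"""Text cleaning, tokenization and vocabulary construction."""

from __future__ import annotations

import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

PAD_TOKEN = "<pad>"
OOV_TOKEN = "<oov>"

_NON_ALNUM = re.compile(r"[^a-z0-9 ]+")
_WS = re.compile(r"\s+")


def clean_text(raw: str) -> str:
    """Normalise raw note text to lowercase ASCII words.

    Accented characters are transliterated where the Unicode
    decomposition allows, everything outside ``[a-z0-9 ]`` is removed,
    and whitespace is collapsed. Idempotent; may return an empty string.
    """
    text = unicodedata.normalize("NFKD", raw)
    text = text.encode("ascii", "ignore").decode("ascii").lower()
    text = _NON_ALNUM.sub(" ", text)
    return _WS.sub(" ", text).strip()


def tokenize(cleaned: str) -> list[str]:
    """Whitespace tokenization of cleaned text."""
    return cleaned.split()


@dataclass
class Document:
    """One note: raw text, cleaned tokens, binary outcome and patient id."""

    doc_id: str
    raw_text: str
    tokens: list[str]
    label: int
    patient_id: str

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if not self.tokens:
            raise ValueError(f"document {self.doc_id!r} has no tokens after cleaning")


def make_document(doc_id: str, raw_text: str, label: int, patient_id: str) -> Document:
    return Document(
        doc_id=str(doc_id),
        raw_text=raw_text,
        tokens=tokenize(clean_text(raw_text)),
        label=int(label),
        patient_id=str(patient_id),
    )


@dataclass
class Vocabulary:
    """Token-to-id map with reserved pad (0) and out-of-vocabulary (1) ids."""

    token_to_id: dict[str, int] = field(default_factory=dict)

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def oov_id(self) -> int:
        return 1

    def __len__(self) -> int:
        return len(self.token_to_id) + 2

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self.token_to_id.get(t, self.oov_id) for t in tokens], dtype=np.int64)

    def decode(self, ids: Iterable[int]) -> list[str]:
        rev = {i: t for t, i in self.token_to_id.items()}
        rev[self.pad_id] = PAD_TOKEN
        rev[self.oov_id] = OOV_TOKEN
        return [rev[int(i)] for i in ids]


def build_vocabulary(train_documents: Sequence[Document], min_count: int = 1) -> Vocabulary:
    """Build the vocabulary from the train split only.

    Tokens seen fewer than ``min_count`` times map to the reserved
    out-of-vocabulary id. Ordering is deterministic: descending
    frequency, then lexicographic.
    """
    if not train_documents:
        raise ValueError("cannot build a vocabulary from an empty train set")
    counts: Counter[str] = Counter()
    for doc in train_documents:
        counts.update(doc.tokens)
    kept = sorted(
        (t for t, c in counts.items() if c >= min_count),
        key=lambda t: (-counts[t], t),
    )
    return Vocabulary({t: i + 2 for i, t in enumerate(kept)})


def encode_documents(documents: Sequence[Document], vocab: Vocabulary) -> list[np.ndarray]:
    return [vocab.encode(doc.tokens) for doc in documents]


def save_vocabulary(vocab: Vocabulary, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(vocab.token_to_id, fh, sort_keys=True)


def load_vocabulary(path) -> Vocabulary:
    import json

    with open(path) as fh:
        return Vocabulary({str(t): int(i) for t, i in json.load(fh).items()})
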