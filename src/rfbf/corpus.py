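"""Synthetic clinical-note corpus generation and corpus file I/O.

The generator plants three kinds of structure that the diagnostics in
this package are designed to surface, so every pipeline stage can be
exercised without access to protected health information:

* **class-discriminative ngrams** (e.g. ``hardware removal``) inserted
  into notes with different rates in the patient and control classes;
* **template boilerplate** — multi-token sequences inserted at equal
  rates in both classes, emulating EHR template artifacts that a model
  can overfit to;
* **patient-name spans** — every note opens with the fixed pattern
  ``patient name <first> <last>``, one unique synthetic name per
  patient, which is what the information-leakage diagnostics extract.

All notes of a patient share one label and one name. Everything is
deterministic under the spec's seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .text import Document, make_document

__all__ = ["SyntheticCorpusSpec", "generate_corpus", "corpus_manifest", "write_corpus", "read_corpus"]

# Fixed synthetic name pools (not real patient data); 40 x 40 = 1600
# unique (first, last) combinations.
FIRST_NAMES = (
    "alba bram cora dain elia fenn gale hollis iver jory kest lira milo "
    "nerys orin pola quill rena soren tova ulric vesper wren xan yara zeph "
    "arlo brynn cael dova ewan fara gideon hester ines jarek kaia lorne "
    "maren niles"
).split()
LAST_NAMES = (
    "ashford barrow calder dunmore elwick fairburn glenhart hollowell "
    "ironwood jessop kirkwall lindhurst marwood northgate oakden pemberly "
    "quarry ravenhill stonebrook thornfield underhill vexley wadsworth "
    "yarrow zellman ashby birchall crowhurst dellmore eastgate foxwell "
    "greystone harlow ingleby jarvis kentwell ledbury moorcroft nethercot "
    "ostler"
).split()


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Configuration of the planted-feature note generator.

    Rates are per-note insertion probabilities. ``notes_per_patient``
    and ``note_length`` are inclusive integer ranges. The defaults
    describe a moderately sized cohort (500 patients, 2-4 short notes
    each, balanced classes) whose planted ngrams carry *weak* class
    signal — the regime of real clinical outcome prediction, where
    models overfit to patient names and template artifacts, which is
    exactly what the diagnostics in this package are meant to surface.
    Raise the rates (e.g. 0.9 vs 0.05) for a strongly separable corpus.
    """

    n_patients: int = 500
    notes_per_patient: tuple[int, int] = (2, 4)
    patient_fraction: float = 0.5
    discriminative_ngrams: tuple[tuple[tuple[str, ...], float, float], ...] = (
        (("hardware", "removal"), 0.35, 0.10),
        (("wound", "infection"), 0.25, 0.08),
    )
    template_tokens: tuple[tuple[str, ...], ...] = (
        ("progress", "note", "reviewed"),
        ("plan", "continue", "current", "management"),
    )
    template_rate: float = 0.5
    name_template: tuple[str, str] = ("patient", "name")
    vocabulary_size: int = 200
    note_length: tuple[int, int] = (15, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not 0.0 < self.patient_fraction < 1.0:
            raise ValueError("patient_fraction must be in (0, 1)")
        for _, p_rate, c_rate in self.discriminative_ngrams:
            if not (0.0 <= p_rate <= 1.0 and 0.0 <= c_rate <= 1.0):
                raise ValueError("ngram insertion rates must be in [0, 1]")
        if not 0.0 <= self.template_rate <= 1.0:
            raise ValueError("template_rate must be in [0, 1]")
        lo, hi = self.notes_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("notes_per_patient must be a nonempty positive range")
        lo, hi = self.note_length
        if lo < 1 or hi < lo:
            raise ValueError("note_length must be a nonempty positive range")
        if self.n_patients > len(FIRST_NAMES) * len(LAST_NAMES):
            raise ValueError("not enough unique synthetic names for n_patients")
        if self.vocabulary_size < 1:
            raise ValueError("vocabulary_size must be positive")


def generate_corpus(spec: SyntheticCorpusSpec) -> list[Document]:
    """Generate a seeded corpus of synthetic notes.

    Every note opens with ``patient name <first> <last>`` followed by
    filler tokens; discriminative ngrams and template boilerplate are
    spliced into the filler at the class-conditional rates. Exactly
    ``round(patient_fraction * n_patients)`` patients carry label 1.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    n_pos = int(round(spec.patient_fraction * n))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    name_idx = rng.choice(len(FIRST_NAMES) * len(LAST_NAMES), size=n, replace=False)
    docs: list[Document] = []
    for p in range(n):
        pid = f"p{p:05d}"
        label = int(labels[p])
        first = FIRST_NAMES[name_idx[p] // len(LAST_NAMES)]
        last = LAST_NAMES[name_idx[p] % len(LAST_NAMES)]
        n_notes = int(rng.integers(spec.notes_per_patient[0], spec.notes_per_patient[1] + 1))
        for note in range(n_notes):
            body_len = int(rng.integers(spec.note_length[0], spec.note_length[1] + 1))
            body = [f"w{int(i):03d}" for i in rng.integers(0, spec.vocabulary_size, size=body_len)]
            inserts: list[tuple[str, ...]] = []
            for ngram, p_rate, c_rate in spec.discriminative_ngrams:
                if rng.random() < (p_rate if label == 1 else c_rate):
                    inserts.append(tuple(ngram))
            for seq in spec.template_tokens:
                if rng.random() < spec.template_rate:
                    inserts.append(tuple(seq))
            for seq in inserts:
                pos = int(rng.integers(0, len(body) + 1))
                body[pos:pos] = list(seq)
            tokens = [*spec.name_template, first, last, *body]
            docs.append(
                make_document(
                    doc_id=f"{pid}-{note:02d}",
                    raw_text=" ".join(tokens),
                    label=label,
                    patient_id=pid,
                )
            )
    return docs


def corpus_manifest(spec: SyntheticCorpusSpec, documents: Sequence[Document]) -> dict:
    """Planted ground truth of a generated corpus (for tests and audits)."""
    patients: dict[str, dict] = {}
    for doc in documents:
        prefix_len = len(spec.name_template)
        name = " ".join(doc.tokens[prefix_len : prefix_len + 2])
        patients.setdefault(doc.patient_id, {"label": doc.label, "name": name, "n_notes": 0})
        patients[doc.patient_id]["n_notes"] += 1
    d = asdict(spec)
    d["discriminative_ngrams"] = [
        {"ngram": " ".join(g), "patient_rate": p, "control_rate": c}
        for g, p, c in spec.discriminative_ngrams
    ]
    d["template_tokens"] = [" ".join(t) for t in spec.template_tokens]
    return {"spec": d, "patients": patients}


_REQUIRED_COLUMNS = ("text", "label", "patient_id")


def write_corpus(documents: Sequence[Document], path) -> None:
    """Write documents as a tab-separated file with a header row."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["doc_id", *_REQUIRED_COLUMNS])
        for doc in documents:
            writer.writerow([doc.doc_id, doc.raw_text, doc.label, doc.patient_id])


def read_corpus(path) -> list[Document]:
    """Read a corpus file written by :func:`write_corpus` (or hand-made).

    The header must contain ``text``, ``label`` and ``patient_id``;
    a ``doc_id`` column is optional (row numbers are used otherwise).
    Malformed records raise with their line number.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"corpus file {path} is missing required column(s): {', '.join(missing)}")
        docs = []
        for i, row in enumerate(reader, start=2):
            try:
                label = int(row["label"])
            except (TypeError, ValueError):
                raise ValueError(f"line {i}: label {row.get('label')!r} is not an integer") from None
            try:
                docs.append(
                    make_document(
                        doc_id=row.get("doc_id") or f"row{i}",
                        raw_text=row["text"] or "",
                        label=label,
                        patient_id=row["patient_id"],
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {i}: {exc}") from None
    return docs
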