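"""Per-filter activation records (ZF dictionaries) and discrimination metrics.

A ZF dictionary — in the style of Zeiler–Fergus feature visualisation —
records, for every filter of a model and one dataset: each document's
max-pool ngram, filter logit and window location, plus the top distinct
ngrams by logit with their class-wise occurrence counts. Interclass
discrimination is summarised per filter by the Mann-Whitney AUC of its
logits against the outcome labels and by the logit deltas

    delta_med = med{l_k | y=1} - med{l_k | y=0}
    delta_mean = mean{l_k | y=1} - mean{l_k | y=0}

which measure discriminative capability rather than raw activation
magnitude — large logits fired indiscriminately by both classes (an
overfit hallmark) produce a small delta.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .model import TextCNNModel, forward_batch, filter_importance
from .text import Document, Vocabulary, PAD_TOKEN, encode_documents
from .training import _pad_batch

__all__ = [
    "NgramActivation",
    "ZFDict",
    "FilterMetrics",
    "calc_zf_dict",
    "logit_delta",
    "filter_auc",
    "compute_filter_metrics",
    "rank_filters",
    "count_ngram_instances",
]

RANK_KEYS = ("delta_mean", "delta_median", "auc", "importance")


@dataclass(frozen=True)
class NgramActivation:
    """One distinct max-pool ngram of a filter on a dataset."""

    ngram_tokens: tuple[str, ...]
    logit: float  # largest per-instance filter logit of this ngram
    cosine: float
    embedding_magnitude: float
    patient_count: int
    control_count: int


@dataclass
class _FilterRecord:
    top_activations: list[NgramActivation]
    sample_logits: np.ndarray
    sample_labels: np.ndarray
    sample_locations: np.ndarray


@dataclass
class ZFDict:
    """Per-filter activation record of one model on one dataset.

    Indexable by filter index 0..K-1; serialises to a line-per-filter
    JSON text format for exploratory analysis outside this package.
    """

    dataset_name: str
    filters: list[_FilterRecord]

    @property
    def n_filters(self) -> int:
        return len(self.filters)

    def keys(self) -> range:
        return range(self.n_filters)

    def __getitem__(self, k: int) -> _FilterRecord:
        return self.filters[k]

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"dataset_name": self.dataset_name, "n_filters": self.n_filters}) + "\n")
            for k, rec in enumerate(self.filters):
                row = {
                    "filter": k,
                    "top_activations": [
                        {**asdict(a), "ngram_tokens": list(a.ngram_tokens)} for a in rec.top_activations
                    ],
                    "sample_logits": rec.sample_logits.tolist(),
                    "sample_labels": rec.sample_labels.tolist(),
                    "sample_locations": rec.sample_locations.tolist(),
                }
                fh.write(json.dumps(row) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "ZFDict":
        with open(path) as fh:
            header = json.loads(fh.readline())
            filters = []
            for line in fh:
                row = json.loads(line)
                filters.append(
                    _FilterRecord(
                        top_activations=[
                            NgramActivation(
                                ngram_tokens=tuple(a["ngram_tokens"]),
                                logit=a["logit"],
                                cosine=a["cosine"],
                                embedding_magnitude=a["embedding_magnitude"],
                                patient_count=a["patient_count"],
                                control_count=a["control_count"],
                            )
                            for a in row["top_activations"]
                        ],
                        sample_logits=np.array(row["sample_logits"]),
                        sample_labels=np.array(row["sample_labels"]),
                        sample_locations=np.array(row["sample_locations"]),
                    )
                )
        if len(filters) != header["n_filters"]:
            raise ValueError("truncated ZF dictionary file")
        return cls(dataset_name=header["dataset_name"], filters=filters)


@dataclass(frozen=True)
class FilterMetrics:
    """Interclass discrimination summary of one filter on one dataset."""

    filter_index: int
    auc: float
    delta_median: float
    delta_mean: float
    patient_central: float
    control_central: float
    importance: float
    class_sign: int


def count_ngram_instances(ngram_tokens: Sequence[str], documents: Sequence[Document]) -> tuple[int, int]:
    """Overlapping sliding-window occurrence counts, split by label."""
    ngram = tuple(ngram_tokens)
    if not ngram:
        raise ValueError("ngram must be non-empty")
    n = len(ngram)
    patient = control = 0
    for doc in documents:
        toks = doc.tokens
        hits = sum(1 for j in range(len(toks) - n + 1) if tuple(toks[j : j + n]) == ngram)
        if doc.label == 1:
            patient += hits
        else:
            control += hits
    return patient, control


def _ngram_counters(documents: Sequence[Document], sizes: Sequence[int]):
    counters = {n: (Counter(), Counter()) for n in sizes}
    for doc in documents:
        toks = tuple(doc.tokens)
        for n in sizes:
            c = counters[n][doc.label]
            for j in range(len(toks) - n + 1):
                c[toks[j : j + n]] += 1
    return counters


def calc_zf_dict(
    model: TextCNNModel,
    documents: Sequence[Document],
    vocab: Vocabulary,
    dataset_name: str = "dataset",
    top_n: int = 4,
    chunk_size: int = 256,
) -> ZFDict:
    """Compute the ZF dictionary of ``model`` on a labeled dataset.

    For every filter the record holds each document's filter logit,
    label and max-pool location, plus the ``top_n`` *distinct* max-pool
    ngrams ranked by their largest per-instance logit. Each listed ngram
    carries dataset-wide patient/control occurrence counts and the
    cosine and embedding magnitude of its maximum-logit instance.
    """
    if not documents:
        raise ValueError("cannot compute a ZF dictionary on an empty dataset")
    cfg = model.config
    if len(vocab) != cfg.vocab_size:
        raise ValueError(
            f"vocabulary size {len(vocab)} does not match model vocab_size {cfg.vocab_size}"
        )
    n_max = max(cfg.ngram_sizes)
    enc = encode_documents(documents, vocab)
    N, K = len(documents), cfg.n_filters
    logits = np.empty((N, K))
    locations = np.empty((N, K), dtype=np.int64)
    for start in range(0, N, chunk_size):
        idx = np.arange(start, min(start + chunk_size, N))
        ids, lengths = _pad_batch(enc, idx, n_max, vocab.pad_id)
        _, pf, locs = forward_batch(model, ids, lengths)
        logits[idx] = pf
        locations[idx] = locs
    labels = np.array([doc.label for doc in documents], dtype=np.int64)

    counters = _ngram_counters(documents, cfg.ngram_sizes)
    filters: list[_FilterRecord] = []
    for k in range(K):
        s, f = model.filter_coords(k)
        n = cfg.ngram_sizes[s]
        best: dict[tuple[str, ...], tuple[float, int]] = {}
        for i in range(N):
            j = int(locations[i, k])
            toks = documents[i].tokens
            window = tuple((toks + [PAD_TOKEN] * n_max)[j : j + n])
            lg = float(logits[i, k])
            if window not in best or lg > best[window][0]:
                best[window] = (lg, i)
        ranked = sorted(best.items(), key=lambda kv: (-kv[1][0], kv[0]))[:top_n]
        top = []
        for window, (lg, i) in ranked:
            ids_i = enc[i]
            padded = np.concatenate([ids_i, np.full(n_max, vocab.pad_id, dtype=np.int64)])
            j = int(locations[i, k])
            x_flat = model.embedding[padded[j : j + n]].ravel()
            w_flat = model.conv_weights[s][f].ravel()
            mag = float(np.linalg.norm(x_flat))
            wn = float(np.linalg.norm(w_flat))
            cos = 0.0 if mag == 0.0 or wn == 0.0 else float(np.dot(x_flat, w_flat) / (mag * wn))
            p_cnt, c_cnt = counters[n][1][window], counters[n][0][window]
            top.append(
                NgramActivation(
                    ngram_tokens=window,
                    logit=lg,
                    cosine=cos,
                    embedding_magnitude=mag,
                    patient_count=int(p_cnt),
                    control_count=int(c_cnt),
                )
            )
        filters.append(
            _FilterRecord(
                top_activations=top,
                sample_logits=logits[:, k].copy(),
                sample_labels=labels.copy(),
                sample_locations=locations[:, k].copy(),
            )
        )
    return ZFDict(dataset_name=dataset_name, filters=filters)


def logit_delta(patient_logits, control_logits, mode: str = "median") -> float:
    """Central patient logit minus central control logit."""
    p = np.asarray(patient_logits, dtype=np.float64)
    c = np.asarray(control_logits, dtype=np.float64)
    if p.size == 0:
        raise ValueError("patient logit list is empty")
    if c.size == 0:
        raise ValueError("control logit list is empty")
    if mode == "median":
        return float(np.median(p) - np.median(c))
    if mode == "mean":
        return float(np.mean(p) - np.mean(c))
    raise ValueError(f"unknown mode {mode!r}; expected 'median' or 'mean'")


def filter_auc(logits, labels) -> float:
    """Mann-Whitney concordance of logits against binary labels.

    Fraction of (patient, control) pairs where the patient logit is
    greater, crediting ties 0.5.
    """
    x = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(x)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def compute_filter_metrics(
    zf: ZFDict, model: TextCNNModel, central_statistic: str = "median"
) -> list[FilterMetrics]:
    """Per-filter discrimination metrics from a ZF dictionary.

    ``patient_central``/``control_central`` use ``central_statistic``;
    both deltas are always reported.
    """
    if central_statistic not in ("median", "mean"):
        raise ValueError("central_statistic must be 'median' or 'mean'")
    stat = np.median if central_statistic == "median" else np.mean
    out = []
    for k in range(zf.n_filters):
        rec = zf[k]
        y = rec.sample_labels
        p = rec.sample_logits[y == 1]
        c = rec.sample_logits[y == 0]
        imp, sign = filter_importance(model, k)
        out.append(
            FilterMetrics(
                filter_index=k,
                auc=filter_auc(rec.sample_logits, y),
                delta_median=logit_delta(p, c, "median"),
                delta_mean=logit_delta(p, c, "mean"),
                patient_central=float(stat(p)),
                control_central=float(stat(c)),
                importance=imp,
                class_sign=sign,
            )
        )
    return out


def rank_filters(
    metrics_a: Sequence[FilterMetrics],
    metrics_b: Sequence[FilterMetrics],
    key: str = "delta_mean",
    sort_on: str = "first",
) -> list[int]:
    """Filter indices in descending order of the chosen metric.

    ``sort_on`` selects which dataset's metrics drive the order
    (importance is dataset-independent). Ties break by ascending filter
    index.
    """
    if key not in RANK_KEYS:
        raise ValueError(f"unknown rank key {key!r}; expected one of {RANK_KEYS}")
    if sort_on not in ("first", "second"):
        raise ValueError("sort_on must be 'first' or 'second'")
    if len(metrics_a) != len(metrics_b):
        raise ValueError("metric lists must have equal length")
    chosen = metrics_a if sort_on == "first" else metrics_b
    return sorted(range(len(chosen)), key=lambda k: (-getattr(chosen[k], key), k))
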