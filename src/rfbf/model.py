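"""Single-logit TextCNN and its per-filter logit decomposition.

The model is the standard shallow text CNN — token embeddings, parallel
banks of ngram convolution filters, a max pool that *scans* the document
for the window most resembling each filter, and a fully connected (FC)
classification layer — with one modification: the FC layer emits a single
logit instead of two. The two parameterisations have identical capacity
(the single logit is the halfway distance between the two original
logits), and the single-logit form makes the network an additive ensemble
of K one-filter classifiers:

    logit = sum_k l_k + bias,       l_k = (max-pooled activation_k) * FC_k

Each filter logit further factors into four interpretable components plus
an explicit kernel-bias term:

    l_k = cos(theta) * ||x_{j:j+n}|| * Imp_k * sign(FC_k) + b_k * FC_k

where ``cos(theta)`` is the cosine between the max-pool window's flattened
embedding and the filter weights, ``Imp_k = ||w_k|| * |FC_k|`` is the
sample-independent filter importance, and ``sign(FC_k)`` assigns the
filter to the patient (+1) or control (-1) class. Keeping the convolution
kernel bias ``b_k`` as an explicit additive term makes the reconstruction
exact rather than approximate.

All numerics are float64 numpy; no deep-learning framework is involved.
"""

from __future__ import annotations

import copy
import io
import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .config import ModelConfig

__all__ = [
    "TextCNNModel",
    "TwoLogitHead",
    "LogitDecomposition",
    "forward",
    "forward_batch",
    "predict_probability",
    "convert_two_logit_head",
    "decompose_filter_logit",
    "filter_importance",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TextCNNModel:
    """Weights of a single-logit TextCNN.

    ``conv_weights[s]`` has shape ``(filters_per_size, n_s, embed_dim)``
    and ``kernel_biases[s]`` shape ``(filters_per_size,)`` for the s-th
    ngram size. Filters are indexed globally in sub-layer order:
    ``k = s * filters_per_size + f``.
    """

    config: ModelConfig
    embedding: np.ndarray
    conv_weights: list[np.ndarray]
    kernel_biases: list[np.ndarray]
    fc_weights: np.ndarray
    fc_bias: float

    def __post_init__(self) -> None:
        cfg = self.config
        if self.embedding.shape != (cfg.vocab_size, cfg.embed_dim):
            raise ValueError("embedding shape does not match config")
        if len(self.conv_weights) != len(cfg.ngram_sizes):
            raise ValueError("one conv bank per ngram size required")
        for n, w, b in zip(cfg.ngram_sizes, self.conv_weights, self.kernel_biases):
            if w.shape != (cfg.filters_per_size, n, cfg.embed_dim):
                raise ValueError(f"conv bank for size {n} has shape {w.shape}")
            if b.shape != (cfg.filters_per_size,):
                raise ValueError(f"kernel bias bank for size {n} has shape {b.shape}")
        if self.fc_weights.shape != (cfg.n_filters,):
            raise ValueError("fc_weights length must equal total filter count")

    @classmethod
    def initialize(cls, config: ModelConfig) -> "TextCNNModel":
        """Randomly initialise weights (seeded from ``config.seed``).

        Embeddings are uniform in ±0.1 with the pad row frozen at zero;
        convolution and FC weights use a fan-in-scaled normal.
        """
        rng = np.random.default_rng(config.seed)
        emb = rng.uniform(-0.1, 0.1, size=(config.vocab_size, config.embed_dim))
        emb[config.pad_token_index] = 0.0
        conv_w, conv_b = [], []
        for n in config.ngram_sizes:
            fan_in = n * config.embed_dim
            conv_w.append(
                rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(config.filters_per_size, n, config.embed_dim))
            )
            conv_b.append(np.zeros(config.filters_per_size))
        fc = rng.normal(0.0, 1.0 / np.sqrt(config.n_filters), size=config.n_filters)
        return cls(config, emb, conv_w, conv_b, fc, 0.0)

    @property
    def n_filters(self) -> int:
        return self.config.n_filters

    def filter_coords(self, filter_index: int) -> tuple[int, int]:
        """Map a global filter index to (ngram-size index, within-bank index)."""
        k = int(filter_index)
        if not 0 <= k < self.n_filters:
            raise ValueError(f"filter index {filter_index} out of range [0, {self.n_filters})")
        return divmod(k, self.config.filters_per_size)

    def filter_ngram_size(self, filter_index: int) -> int:
        s, _ = self.filter_coords(filter_index)
        return self.config.ngram_sizes[s]

    def copy(self) -> "TextCNNModel":
        return copy.deepcopy(self)


@dataclass(frozen=True)
class TwoLogitHead:
    """Classification layer of an unmodified two-logit TextCNN."""

    fc_weights_class0: np.ndarray
    fc_weights_class1: np.ndarray
    fc_bias_class0: float
    fc_bias_class1: float

    def __post_init__(self) -> None:
        if self.fc_weights_class0.shape != self.fc_weights_class1.shape:
            raise ValueError("class0/class1 weight vectors must have the same length")


@dataclass(frozen=True)
class LogitDecomposition:
    """One filter's logit on one document, split into its components."""

    filter_index: int
    location: int
    ngram_tokens: tuple[int, ...]
    cosine: float
    embedding_magnitude: float
    importance: float
    class_sign: int
    kernel_bias_term: float
    filter_logit: float


def _pad_ids(model: TextCNNModel, token_ids) -> np.ndarray:
    cfg = model.config
    ids = np.asarray(token_ids, dtype=np.int64).ravel()
    if ids.size == 0:
        raise ValueError("empty token sequence")
    if ids.min() < 0 or ids.max() >= cfg.vocab_size:
        bad = ids[(ids < 0) | (ids >= cfg.vocab_size)][0]
        raise ValueError(f"token id {bad} out of range for vocabulary of size {cfg.vocab_size}")
    n_max = max(cfg.ngram_sizes)
    if ids.size < n_max:
        ids = np.concatenate([ids, np.full(n_max - ids.size, cfg.pad_token_index, dtype=np.int64)])
    return ids


def forward_batch(
    model: TextCNNModel, token_ids: np.ndarray, lengths: np.ndarray, return_cache: bool = False
):
    """Forward pass over a padded batch.

    Parameters
    ----------
    token_ids
        Integer array ``(B, T)``, right-padded with the pad token.
    lengths
        True (pre-padding) document lengths ``(B,)``; each document is
        conceptually padded to at least the largest ngram size, and the
        max pool ranges only over fully in-bounds windows of that padded
        sequence — positions introduced purely by batch padding are
        masked out.

    Returns
    -------
    (sample_logits (B,), per_filter_logits (B, K), locations (B, K))
    and, with ``return_cache``, a dict of intermediates for backprop.
    """
    cfg = model.config
    ids = np.asarray(token_ids, dtype=np.int64)
    if ids.ndim != 2:
        raise ValueError("token_ids must be 2-d (batch, position)")
    if ids.min() < 0 or ids.max() >= cfg.vocab_size:
        raise ValueError("token id out of range")
    B, T = ids.shape
    n_max = max(cfg.ngram_sizes)
    if T < n_max:
        raise ValueError("batch must be padded to at least the largest ngram size")
    lengths = np.maximum(np.asarray(lengths, dtype=np.int64), n_max)

    x = model.embedding[ids]  # (B, T, e)
    pooled_parts, loc_parts, cache_parts = [], [], []
    for s, n in enumerate(cfg.ngram_sizes):
        P = T - n + 1
        sw = sliding_window_view(x, n, axis=1)  # (B, P, e, n)
        windows = np.ascontiguousarray(sw.transpose(0, 1, 3, 2)).reshape(B, P, n * cfg.embed_dim)
        acts = windows @ model.conv_weights[s].reshape(cfg.filters_per_size, -1).T
        acts += model.kernel_biases[s]
        n_valid = lengths - n + 1  # windows fully inside each padded document
        invalid = np.arange(P)[None, :] >= n_valid[:, None]
        acts[invalid] = -np.inf
        loc = acts.argmax(axis=1)  # first max wins ties
        pooled = np.take_along_axis(acts, loc[:, None, :], axis=1)[:, 0, :]
        pooled_parts.append(pooled)
        loc_parts.append(loc)
        if return_cache:
            cache_parts.append({"windows": windows, "invalid": invalid})
    pooled_all = np.concatenate(pooled_parts, axis=1)  # (B, K)
    locations = np.concatenate(loc_parts, axis=1)
    post = np.maximum(pooled_all, 0.0) if cfg.pre_fc_relu else pooled_all
    per_filter = post * model.fc_weights[None, :]
    sample_logits = per_filter.sum(axis=1) + model.fc_bias
    if return_cache:
        cache = {"ids": ids, "pooled": pooled_all, "post": post, "parts": cache_parts, "locations": locations}
        return sample_logits, per_filter, locations, cache
    return sample_logits, per_filter, locations


def forward(model: TextCNNModel, token_ids) -> tuple[float, np.ndarray, np.ndarray]:
    """Forward pass on one document.

    Returns the sample logit, the K per-filter logits
    ``l_k = pooled_k * FC_k`` and the K max-pool window locations
    (0-based token index of each window start; smallest index wins ties).
    """
    ids = _pad_ids(model, token_ids)
    logits, per_filter, locs = forward_batch(model, ids[None, :], np.array([ids.size]))
    return float(logits[0]), per_filter[0], locs[0]


def predict_probability(sample_logit: float) -> float:
    """Patient-class probability of a sample logit L: e^L / (e^-L + e^L).

    Equivalent to a softmax over the logit and its negation (and to
    sigmoid(2L)); strictly increasing in L.
    """
    L = float(sample_logit)
    if not np.isfinite(L):
        raise ValueError("sample logit must be finite")
    return float(1.0 / (1.0 + np.exp(-2.0 * L)))


def convert_two_logit_head(head: TwoLogitHead) -> tuple[np.ndarray, float]:
    """Convert a trained two-logit FC layer to the single-logit form.

    The single-logit weights are element-wise halfway distances,
    ``(class1 - class0) / 2``, so that the converted logit equals
    ``logit_1 - logit_mu`` and the two-logit softmax probability equals
    :func:`predict_probability` of the converted logit for every pooled
    activation vector.
    """
    w = (head.fc_weights_class1 - head.fc_weights_class0) / 2.0
    b = (head.fc_bias_class1 - head.fc_bias_class0) / 2.0
    return w, float(b)


def filter_importance(model: TextCNNModel, filter_index: int) -> tuple[float, int]:
    """Sample-independent importance ``Imp_k = ||w_k|| * |FC_k|`` and class sign.

    The sign of ``FC_k`` assigns the filter to the patient (+1, red) or
    control (-1, blue) class; an exactly-zero FC weight is reported as +1
    with a warning.
    """
    s, f = model.filter_coords(filter_index)
    fc_k = float(model.fc_weights[filter_index])
    imp = float(np.linalg.norm(model.conv_weights[s][f]) * abs(fc_k))
    if fc_k == 0.0:
        warnings.warn(f"filter {filter_index} has FC weight 0; class sign reported as +1")
        return imp, 1
    return imp, 1 if fc_k > 0 else -1


def decompose_filter_logit(model: TextCNNModel, token_ids, filter_index: int) -> LogitDecomposition:
    """Split one filter's logit on one document into its four components.

    Locates the max-pool window, then reports the cosine between the
    flattened window embedding and the filter weights, the window
    embedding magnitude, ``Imp_k``, ``sign(FC_k)`` and the explicit
    kernel-bias term ``b_k * FC_k``. Satisfies

        l_k = cosine * magnitude * Imp_k * sign + kernel_bias_term

    exactly (up to float rounding). When the window embedding has zero
    magnitude (e.g. all pad tokens) the cosine is 0 by convention and the
    filter logit reduces to the kernel-bias term. ``filter_logit`` is the
    un-clamped value ``(window . w_k + b_k) * FC_k``; with ``pre_fc_relu``
    enabled the model's effective contribution is that value clamped
    below at the kernel-bias-scaled floor of zero pooled activation.
    """
    s, f = model.filter_coords(filter_index)
    n = model.config.ngram_sizes[s]
    ids = _pad_ids(model, token_ids)
    _, _, locs = forward(model, ids)
    j = int(locs[filter_index])
    window_ids = ids[j : j + n]
    x_flat = model.embedding[window_ids].ravel()
    w_flat = model.conv_weights[s][f].ravel()
    mag = float(np.linalg.norm(x_flat))
    w_norm = float(np.linalg.norm(w_flat))
    fc_k = float(model.fc_weights[filter_index])
    imp, sign = filter_importance(model, filter_index)
    if mag == 0.0 or w_norm == 0.0:
        cosine = 0.0
    else:
        cosine = float(np.dot(x_flat, w_flat) / (mag * w_norm))
        cosine = max(-1.0, min(1.0, cosine))
    kb_term = float(model.kernel_biases[s][f]) * fc_k
    filter_logit = float((np.dot(x_flat, w_flat) + model.kernel_biases[s][f]) * fc_k)
    return LogitDecomposition(
        filter_index=int(filter_index),
        location=j,
        ngram_tokens=tuple(int(t) for t in window_ids),
        cosine=cosine,
        embedding_magnitude=mag,
        importance=imp,
        class_sign=sign,
        kernel_bias_term=kb_term,
        filter_logit=filter_logit,
    )


def save_checkpoint(model: TextCNNModel, path) -> None:
    """Write a self-describing checkpoint (config + all weight arrays).

    The weight round-trip is bit-exact.
    """
    arrays = {
        "embedding": model.embedding,
        "fc_weights": model.fc_weights,
        "fc_bias": np.array(model.fc_bias, dtype=np.float64),
    }
    for n, w, b in zip(model.config.ngram_sizes, model.conv_weights, model.kernel_biases):
        arrays[f"conv_weights_{n}"] = w
        arrays[f"kernel_biases_{n}"] = b
    cfg = asdict(model.config)
    cfg["ngram_sizes"] = list(cfg["ngram_sizes"])
    arrays["config_json"] = np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> TextCNNModel:
    """Read a checkpoint written by :func:`save_checkpoint`."""
    with open(path, "rb") as fh:
        data = np.load(io.BytesIO(fh.read()))
    cfg_dict = json.loads(bytes(data["config_json"]).decode())
    cfg_dict["ngram_sizes"] = tuple(cfg_dict["ngram_sizes"])
    config = ModelConfig(**cfg_dict)
    conv_w = [data[f"conv_weights_{n}"] for n in config.ngram_sizes]
    conv_b = [data[f"kernel_biases_{n}"] for n in config.ngram_sizes]
    return TextCNNModel(
        config=config,
        embedding=data["embedding"],
        conv_weights=conv_w,
        kernel_biases=conv_b,
        fc_weights=data["fc_weights"],
        fc_bias=float(data["fc_bias"]),
    )
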