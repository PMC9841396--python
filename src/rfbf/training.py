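"""Patient-stratified splitting and 1-Cycle training of the single-logit TextCNN.

The loss is binary cross-entropy on the patient-class probability
``P1 = e^L / (e^-L + e^L)`` of the sample logit L (equivalently
``sigmoid(2L)``). Gradients are computed analytically: the max pool
routes each filter's gradient to its argmax window, whose embedding rows
and filter weights receive the corresponding outer-product updates.
Optimisation is Adam with decoupled weight decay under a 1-Cycle
learning-rate schedule: linear warm-up to the peak over the first half
of the steps, linear anneal over the second half. The pad embedding row
stays frozen at zero throughout.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .config import ModelConfig, SplitSpec, TrainSpec
from .model import TextCNNModel, forward_batch
from .text import Document, Vocabulary, build_vocabulary, encode_documents

__all__ = [
    "CorpusSplit",
    "patient_stratified_split",
    "train_one_cycle",
    "evaluate_logits",
    "evaluate_auc",
    "IterationResults",
    "run_experiment_iterations",
    "one_cycle_schedule",
]

LEAK_SUFFIX = "#leak"  # flags documents planted into train by forced_overlap


@dataclass
class CorpusSplit:
    train: list[Document]
    validate: list[Document]
    holdout: list[Document]
    leaked_patient_ids: tuple[str, ...] = ()


def patient_stratified_split(documents: Sequence[Document], spec: SplitSpec) -> CorpusSplit:
    """Partition *patients* (not documents) into train/validate/holdout.

    Patients are shuffled under ``spec.seed`` and assigned by the split
    fractions. With ``forced_overlap > 0``, ``round(forced_overlap *
    n_holdout_patients)`` holdout patients additionally have *copies* of
    their documents planted into the train split (doc ids flagged with
    ``#leak``); the holdout split itself is unchanged. With
    ``forced_overlap == 0`` the three splits are pairwise
    patient-disjoint.
    """
    patient_ids = sorted({doc.patient_id for doc in documents})
    n_pat = len(patient_ids)
    if n_pat < 3:
        raise ValueError(f"need at least 3 patients to split, got {n_pat}")
    rng = np.random.default_rng(spec.seed)
    order = [patient_ids[i] for i in rng.permutation(n_pat)]
    n_hold = max(1, round(spec.holdout_fraction * n_pat))
    n_val = max(1, round(spec.validate_fraction * n_pat))
    if n_hold + n_val >= n_pat:
        raise ValueError("split fractions leave no train patients")
    train_p = set(order[: n_pat - n_val - n_hold])
    val_p = set(order[n_pat - n_val - n_hold : n_pat - n_hold])
    hold_p = order[n_pat - n_hold :]

    by_split: dict[str, list[Document]] = {"train": [], "validate": [], "holdout": []}
    for doc in documents:
        if doc.patient_id in train_p:
            by_split["train"].append(doc)
        elif doc.patient_id in val_p:
            by_split["validate"].append(doc)
        else:
            by_split["holdout"].append(doc)

    leaked: tuple[str, ...] = ()
    if spec.forced_overlap > 0:
        n_leak = round(spec.forced_overlap * n_hold)
        leak_idx = rng.choice(n_hold, size=n_leak, replace=False)
        leaked = tuple(sorted(hold_p[i] for i in leak_idx))
        leak_set = set(leaked)
        for doc in documents:
            if doc.patient_id in leak_set:
                by_split["train"].append(dataclasses.replace(doc, doc_id=doc.doc_id + LEAK_SUFFIX))
    return CorpusSplit(by_split["train"], by_split["validate"], by_split["holdout"], leaked)


def one_cycle_schedule(total_steps: int, max_lr: float, start_div: float = 25.0, final_div: float = 1e4) -> np.ndarray:
    """Per-step learning rates: linear warm-up to ``max_lr`` over the
    first half of the steps, linear anneal over the second half."""
    if total_steps < 1:
        raise ValueError("total_steps must be >= 1")
    peak = max(1, total_steps // 2)
    lrs = np.empty(total_steps)
    for t in range(total_steps):
        if t <= peak:
            frac = t / peak
            lrs[t] = max_lr / start_div + frac * (max_lr - max_lr / start_div)
        else:
            frac = (t - peak) / max(1, total_steps - 1 - peak)
            lrs[t] = max_lr + frac * (max_lr / final_div - max_lr)
    return lrs


def _pad_batch(encoded: list[np.ndarray], idx: np.ndarray, n_max: int, pad_id: int):
    T = max(n_max, max(encoded[i].size for i in idx))
    ids = np.full((len(idx), T), pad_id, dtype=np.int64)
    lengths = np.empty(len(idx), dtype=np.int64)
    for row, i in enumerate(idx):
        seq = encoded[i]
        ids[row, : seq.size] = seq
        lengths[row] = seq.size
    return ids, lengths


class _Adam:
    """Minimal Adam with decoupled weight decay."""

    def __init__(self, shapes: dict, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float, weight_decay: float, decay_keys: set):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for key, g in grads.items():
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g * g
            m_hat = self.m[key] / (1 - b1 ** self.t)
            v_hat = self.v[key] / (1 - b2 ** self.t)
            params[key] -= lr * m_hat / (np.sqrt(v_hat) + self.eps)
            if weight_decay and key in decay_keys:
                params[key] -= lr * weight_decay * params[key]


def train_one_cycle(
    model: TextCNNModel,
    train: Sequence[Document],
    validate: Sequence[Document],
    spec: TrainSpec,
    vocab: Vocabulary,
) -> tuple[TextCNNModel, dict]:
    """Train a copy of ``model`` and return it with a history dict.

    ``history['epochs']`` records loss and validate AUC per epoch;
    ``history['learning_rates']`` is the realised per-step 1-Cycle
    schedule. Fully deterministic under ``spec.seed``.
    """
    if not train or not validate:
        raise ValueError("train and validate sets must be non-empty")
    y_train = np.array([d.label for d in train], dtype=np.float64)
    if len(set(y_train.tolist())) < 2:
        raise ValueError("train set must contain both classes")
    model = model.copy()
    cfg = model.config
    n_max = max(cfg.ngram_sizes)
    enc_train = encode_documents(train, vocab)
    rng = np.random.default_rng(spec.seed)

    n_batches = int(np.ceil(len(train) / spec.batch_size))
    total_steps = spec.epochs * n_batches
    lrs = one_cycle_schedule(total_steps, spec.max_learning_rate)

    params = {"embedding": model.embedding, "fc_weights": model.fc_weights,
              "fc_bias": np.array([model.fc_bias])}
    for s, n in enumerate(cfg.ngram_sizes):
        params[f"conv_w_{s}"] = model.conv_weights[s]
        params[f"conv_b_{s}"] = model.kernel_biases[s]
    decay_keys = {"embedding", "fc_weights"} | {f"conv_w_{s}" for s in range(len(cfg.ngram_sizes))}
    opt = _Adam({k: p.shape for k, p in params.items()})

    F = cfg.filters_per_size
    history: dict = {"epochs": [], "learning_rates": lrs.tolist()}
    step = 0
    for epoch in range(spec.epochs):
        perm = rng.permutation(len(train))
        epoch_loss = 0.0
        for b in range(n_batches):
            idx = perm[b * spec.batch_size : (b + 1) * spec.batch_size]
            ids, lengths = _pad_batch(enc_train, idx, n_max, vocab.pad_id)
            y = y_train[idx]
            B = len(idx)
            model.fc_bias = float(params["fc_bias"][0])
            logits, _, locations, cache = forward_batch(model, ids, lengths, return_cache=True)

            ysign = 2.0 * y - 1.0
            epoch_loss += float(np.logaddexp(0.0, -2.0 * logits * ysign).sum())
            p1 = 1.0 / (1.0 + np.exp(-2.0 * logits))
            g = 2.0 * (p1 - y) / B  # dLoss/dlogit, mean reduction

            grads: dict[str, np.ndarray] = {}
            grads["fc_bias"] = np.array([g.sum()])
            grads["fc_weights"] = g @ cache["post"]
            d_post = g[:, None] * model.fc_weights[None, :]
            if cfg.pre_fc_relu:
                d_pooled = d_post * (cache["pooled"] > 0)
            else:
                d_pooled = d_post
            T = ids.shape[1]
            d_x = np.zeros((B, T, cfg.embed_dim))
            bidx = np.arange(B)[:, None]
            for s, n in enumerate(cfg.ngram_sizes):
                dp = d_pooled[:, s * F : (s + 1) * F]  # (B, F)
                loc = locations[:, s * F : (s + 1) * F]
                windows = cache["parts"][s]["windows"]  # (B, P, n*e)
                P = windows.shape[1]
                grads[f"conv_b_{s}"] = dp.sum(axis=0)
                winsel = np.take_along_axis(windows, loc[:, :, None], axis=1)  # (B, F, n*e)
                grads[f"conv_w_{s}"] = np.einsum("bf,bfd->fd", dp, winsel).reshape(F, n, cfg.embed_dim)
                contrib = dp[:, :, None] * model.conv_weights[s].reshape(F, -1)[None, :, :]
                dz = np.zeros((B, P, n * cfg.embed_dim))
                np.add.at(dz, (bidx, loc), contrib)
                dz = dz.reshape(B, P, n, cfg.embed_dim)
                for i in range(n):
                    d_x[:, i : i + P, :] += dz[:, :, i, :]
            grad_emb = np.zeros_like(model.embedding)
            np.add.at(grad_emb, ids.ravel(), d_x.reshape(-1, cfg.embed_dim))
            grad_emb[cfg.pad_token_index] = 0.0
            grads["embedding"] = grad_emb

            opt.step(params, grads, lrs[step], spec.weight_decay, decay_keys)
            params["embedding"][cfg.pad_token_index] = 0.0
            step += 1
        model.fc_bias = float(params["fc_bias"][0])
        val_auc = evaluate_auc(model, validate, vocab)
        history["epochs"].append(
            {"epoch": epoch, "loss": epoch_loss / len(train), "validate_auc": val_auc}
        )
    return model, history


def evaluate_logits(model: TextCNNModel, documents: Sequence[Document], vocab: Vocabulary,
                    chunk_size: int = 256) -> np.ndarray:
    """Sample logits for a document collection (batched forward passes)."""
    enc = encode_documents(documents, vocab)
    n_max = max(model.config.ngram_sizes)
    out = np.empty(len(documents))
    for start in range(0, len(documents), chunk_size):
        idx = np.arange(start, min(start + chunk_size, len(documents)))
        ids, lengths = _pad_batch(enc, idx, n_max, vocab.pad_id)
        logits, _, _ = forward_batch(model, ids, lengths)
        out[idx] = logits
    return out


def evaluate_auc(model: TextCNNModel, documents: Sequence[Document], vocab: Vocabulary) -> float:
    labels = np.array([d.label for d in documents])
    if len(set(labels.tolist())) < 2:
        return float("nan")
    return float(roc_auc_score(labels, evaluate_logits(model, documents, vocab)))


@dataclass
class IterationResults:
    """Holdout AUCs across repeated split/train/evaluate iterations."""

    holdout_aucs: list[float] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.holdout_aucs))

    @property
    def sd(self) -> float:
        return float(np.std(self.holdout_aucs, ddof=1)) if len(self.holdout_aucs) > 1 else 0.0


def run_experiment_iterations(
    documents: Sequence[Document],
    model_config: ModelConfig | None,
    train_spec: TrainSpec,
    split_spec: SplitSpec,
    min_count: int = 1,
) -> IterationResults:
    """Repeat split -> train -> holdout-evaluate ``n_iterations`` times.

    Each iteration uses distinct seeds derived from the specs' seeds.
    ``model_config`` may be None, in which case a default architecture is
    sized to each iteration's vocabulary. Returns per-iteration holdout
    AUCs with their mean and standard deviation.
    """
    results = IterationResults()
    for it in range(train_spec.n_iterations):
        split_seed = (split_spec.seed * 1009 + it) % (2**31)
        train_seed = (train_spec.seed * 2003 + it) % (2**31)
        split = patient_stratified_split(documents, dataclasses.replace(split_spec, seed=split_seed))
        vocab = build_vocabulary(split.train, min_count=min_count)
        if model_config is None:
            cfg = ModelConfig(vocab_size=len(vocab), seed=train_seed)
        else:
            cfg = dataclasses.replace(model_config, vocab_size=len(vocab), seed=train_seed)
        model = TextCNNModel.initialize(cfg)
        trained, _ = train_one_cycle(
            model, split.train, split.validate, dataclasses.replace(train_spec, seed=train_seed), vocab
        )
        results.holdout_aucs.append(evaluate_auc(trained, split.holdout, vocab))
    return results
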