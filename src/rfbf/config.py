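"""Configuration dataclasses for the model, training loop and data splits.

All configuration is plain data so that runs can be described by a single
YAML file and reproduced exactly from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the single-logit TextCNN.

    Parameters
    ----------
    vocab_size
        Number of rows in the embedding table (including the reserved pad
        and out-of-vocabulary entries).
    embed_dim
        Embedding dimensionality ``e``.
    ngram_sizes
        Convolution kernel lengths, one sub-layer per length. Must be
        strictly increasing. The default mirrors the reference
        architecture: unigram, bigram, trigram and 5-gram sub-layers.
    filters_per_size
        Number of filters in each sub-layer. With the defaults the model
        has ``K = 4 * 36 = 144`` filters.
    pre_fc_relu
        If true, negative max-pooled activations are clamped to zero
        before the classification-layer scaling.
    pad_token_index
        Embedding row used for padding; frozen at zero during training.
    seed
        Seed for weight initialisation.
    """

    vocab_size: int
    embed_dim: int = 50
    ngram_sizes: tuple[int, ...] = (1, 2, 3, 5)
    filters_per_size: int = 36
    pre_fc_relu: bool = False
    pad_token_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.vocab_size <= 0:
            raise ValueError("vocab_size must be positive")
        if self.embed_dim <= 0:
            raise ValueError("embed_dim must be positive")
        sizes = tuple(int(n) for n in self.ngram_sizes)
        object.__setattr__(self, "ngram_sizes", sizes)
        if not sizes or any(n < 1 for n in sizes):
            raise ValueError("ngram sizes must all be >= 1")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("ngram_sizes must be strictly increasing")
        if self.filters_per_size <= 0:
            raise ValueError("filters_per_size must be positive")
        if not 0 <= self.pad_token_index < self.vocab_size:
            raise ValueError("pad_token_index out of range")

    @property
    def n_filters(self) -> int:
        """Total filter count K."""
        return len(self.ngram_sizes) * self.filters_per_size


@dataclass(frozen=True)
class SplitSpec:
    """Patient-stratified train/validate/holdout split proportions.

    ``forced_overlap`` is the fraction of holdout *patients* whose notes
    are additionally planted (copied) into the train split, used to
    simulate information leakage. With ``forced_overlap == 0`` the three
    splits are pairwise patient-disjoint.
    """

    train_fraction: float = 0.75
    validate_fraction: float = 0.15
    holdout_fraction: float = 0.10
    forced_overlap: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.train_fraction, self.validate_fraction, self.holdout_fraction)
        if any(f <= 0 for f in fracs):
            raise ValueError("split fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not 0.0 <= self.forced_overlap <= 1.0:
            raise ValueError("forced_overlap must be in [0, 1]")


@dataclass(frozen=True)
class TrainSpec:
    """Hyperparameters of the 1-Cycle training loop."""

    max_learning_rate: float = 5e-3
    epochs: int = 10
    batch_size: int = 32
    weight_decay: float = 1e-4
    n_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_learning_rate <= 0:
            raise ValueError("max_learning_rate must be positive")
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be nonnegative")
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be positive")


def _filtered_kwargs(cls, mapping: dict) -> dict:
    names = {f for f in cls.__dataclass_fields__}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    for key in ("ngram_sizes",):
        if key in kwargs and isinstance(kwargs[key], Sequence):
            kwargs[key] = tuple(kwargs[key])
    return kwargs


def load_config(path) -> dict:
    """Read a YAML config file with optional ``model``/``train``/``split`` sections.

    Returns a dict with whichever of the keys ``model`` (ModelConfig,
    requires ``vocab_size``), ``train`` (TrainSpec) and ``split``
    (SplitSpec) are present in the file.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    if "model" in raw:
        out["model"] = ModelConfig(**_filtered_kwargs(ModelConfig, raw["model"]))
    if "train" in raw:
        out["train"] = TrainSpec(**_filtered_kwargs(TrainSpec, raw["train"]))
    if "split" in raw:
        out["split"] = SplitSpec(**_filtered_kwargs(SplitSpec, raw["split"]))
    return out


def dump_config(sections: dict, path) -> None:
    """Write config dataclasses back to YAML (inverse of :func:`load_config`)."""
    raw = {}
    for key, value in sections.items():
        d = asdict(value)
        if "ngram_sizes" in d:
            d["ngram_sizes"] = list(d["ngram_sizes"])
        raw[key] = d
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)
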