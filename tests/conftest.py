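import numpy as np
import pytest
from hypothesis import settings

from rfbf import ModelConfig, TextCNNModel

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def build_random_model(
    vocab_size=12,
    embed_dim=4,
    ngram_sizes=(1, 2),
    filters_per_size=2,
    seed=0,
    pre_fc_relu=False,
) -> TextCNNModel:
    """Toy model with dense random weights (nonzero kernel biases and fc bias)."""
    cfg = ModelConfig(
        vocab_size=vocab_size,
        embed_dim=embed_dim,
        ngram_sizes=tuple(ngram_sizes),
        filters_per_size=filters_per_size,
        pre_fc_relu=pre_fc_relu,
        seed=seed,
    )
    model = TextCNNModel.initialize(cfg)
    rng = np.random.default_rng(seed + 1)
    for s in range(len(cfg.ngram_sizes)):
        model.kernel_biases[s][:] = rng.normal(0, 0.3, size=cfg.filters_per_size)
    model.fc_weights[:] = rng.normal(0, 1.0, size=cfg.n_filters)
    model.fc_bias = float(rng.normal(0, 0.5))
    return model


@pytest.fixture
def toy_model():
    return build_random_model()


def brute_force_filter_logits(model, token_ids):
    """Independent oracle: enumerate every window of every filter directly."""
    cfg = model.config
    ids = np.asarray(token_ids, dtype=np.int64)
    n_max = max(cfg.ngram_sizes)
    if ids.size < n_max:
        ids = np.concatenate([ids, np.full(n_max - ids.size, cfg.pad_token_index)])
    K = cfg.n_filters
    logits = np.zeros(K)
    locs = np.zeros(K, dtype=int)
    for k in range(K):
        s, f = divmod(k, cfg.filters_per_size)
        n = cfg.ngram_sizes[s]
        best, best_j = -np.inf, 0
        for j in range(ids.size - n + 1):
            window = model.embedding[ids[j : j + n]].ravel()
            act = float(window @ model.conv_weights[s][f].ravel()) + float(model.kernel_biases[s][f])
            if act > best:
                best, best_j = act, j
        if cfg.pre_fc_relu:
            best = max(best, 0.0)
        logits[k] = best * model.fc_weights[k]
        locs[k] = best_j
    sample = logits.sum() + model.fc_bias
    return sample, logits, locs
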