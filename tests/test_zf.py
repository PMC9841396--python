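"""ZF dictionaries, logit deltas, per-filter AUC, ranking and ngram counts."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rfbf import (
    FilterMetrics,
    ModelConfig,
    TextCNNModel,
    Vocabulary,
    build_vocabulary,
    calc_zf_dict,
    compute_filter_metrics,
    count_ngram_instances,
    filter_auc,
    logit_delta,
    make_document,
    rank_filters,
)
from rfbf.text import PAD_TOKEN

from conftest import build_random_model, brute_force_filter_logits


def docs_from_texts(texts, labels):
    return [
        make_document(f"d{i}", t, y, f"p{i}")
        for i, (t, y) in enumerate(zip(texts, labels))
    ]


@pytest.fixture
def small_corpus():
    texts = [
        "alpha beta gamma delta",
        "beta beta alpha epsilon",
        "gamma delta alpha beta",
        "delta epsilon beta gamma alpha",
        "epsilon alpha alpha beta",
    ]
    return docs_from_texts(texts, [1, 1, 0, 0, 1])


class TestCalcZFDict:
    def test_default_model_has_keys_0_to_143(self, small_corpus):
        vocab = build_vocabulary(small_corpus)
        model = TextCNNModel.initialize(ModelConfig(vocab_size=len(vocab), embed_dim=8))
        zf = calc_zf_dict(model, small_corpus, vocab)
        assert list(zf.keys()) == list(range(144))
        assert zf.n_filters == 144

    def test_single_document_yields_single_top_entry(self, small_corpus):
        vocab = build_vocabulary(small_corpus)
        model = build_random_model(vocab_size=len(vocab), seed=4)
        zf = calc_zf_dict(model, small_corpus[:1], vocab)
        for k in zf.keys():
            assert len(zf[k].top_activations) == 1
            j = int(zf[k].sample_locations[0])
            n = model.filter_ngram_size(k)
            toks = small_corpus[0].tokens + [PAD_TOKEN] * 2
            assert zf[k].top_activations[0].ngram_tokens == tuple(toks[j : j + n])

    def test_top4_matches_brute_force_ranking(self, small_corpus):
        vocab = build_vocabulary(small_corpus)
        model = build_random_model(
            vocab_size=len(vocab), ngram_sizes=(1, 2), filters_per_size=1, seed=9
        )
        zf = calc_zf_dict(model, small_corpus, vocab)
        for k in range(model.n_filters):
            n = model.filter_ngram_size(k)
            best = {}
            for doc in small_corpus:
                _, logits, locs = brute_force_filter_logits(model, vocab.encode(doc.tokens))
                j = int(locs[k])
                window = tuple((doc.tokens + [PAD_TOKEN] * 2)[j : j + n])
                if window not in best or logits[k] > best[window]:
                    best[window] = logits[k]
            expected = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))[:4]
            got = [(a.ngram_tokens, a.logit) for a in zf[k].top_activations]
            assert [w for w, _ in expected] == [w for w, _ in got]
            np.testing.assert_allclose([v for _, v in expected], [v for _, v in got], atol=1e-10)

    def test_counts_and_labels_are_consistent(self, small_corpus):
        vocab = build_vocabulary(small_corpus)
        model = build_random_model(vocab_size=len(vocab), seed=2)
        zf = calc_zf_dict(model, small_corpus, vocab)
        labels = [d.label for d in small_corpus]
        for k in zf.keys():
            assert zf[k].sample_labels.tolist() == labels
            for act in zf[k].top_activations:
                p, c = count_ngram_instances(act.ngram_tokens, small_corpus)
                assert (act.patient_count, act.control_count) == (p, c)

    def test_empty_dataset_rejected(self, small_corpus):
        vocab = build_vocabulary(small_corpus)
        model = build_random_model(vocab_size=len(vocab))
        with pytest.raises(ValueError, match="empty"):
            calc_zf_dict(model, [], vocab)

    def test_vocabulary_mismatch_rejected(self, small_corpus):
        model = build_random_model(vocab_size=99)
        with pytest.raises(ValueError, match="vocab"):
            calc_zf_dict(model, small_corpus, build_vocabulary(small_corpus))

    def test_serialization_round_trip_and_determinism(self, small_corpus, tmp_path):
        vocab = build_vocabulary(small_corpus)
        model = build_random_model(vocab_size=len(vocab), seed=6)
        zf = calc_zf_dict(model, small_corpus, vocab, "train")
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        zf.to_jsonl(p1)
        calc_zf_dict(model, small_corpus, vocab, "train").to_jsonl(p2)
        assert p1.read_bytes() == p2.read_bytes()
        back = type(zf).from_jsonl(p1)
        assert back.dataset_name == "train"
        for k in zf.keys():
            assert back[k].top_activations == zf[k].top_activations
            np.testing.assert_array_equal(back[k].sample_logits, zf[k].sample_logits)


class TestLogitDelta:
    def test_identical_lists_give_zero(self):
        assert logit_delta([1.0, 2.0], [1.0, 2.0], "median") == 0.0

    def test_median_delta(self):
        assert logit_delta([2, 4, 6], [1, 1, 1], "median") == pytest.approx(3.0)

    def test_even_length_median_is_midpoint(self):
        assert logit_delta([1, 2, 3, 10], [0, 0], "median") == pytest.approx(2.5)

    @given(
        st.lists(st.floats(-5, 5), min_size=1, max_size=10),
        st.lists(st.floats(-5, 5), min_size=1, max_size=10),
        st.sampled_from(["median", "mean"]),
    )
    def test_antisymmetry(self, a, b, mode):
        assert logit_delta(a, b, mode) == pytest.approx(-logit_delta(b, a, mode))

    def test_empty_class_names_the_class(self):
        with pytest.raises(ValueError, match="patient"):
            logit_delta([], [1.0])
        with pytest.raises(ValueError, match="control"):
            logit_delta([1.0], [])


def brute_force_auc(logits, labels):
    pos = [x for x, y in zip(logits, labels) if y == 1]
    neg = [x for x, y in zip(logits, labels) if y == 0]
    total = 0.0
    for p, c in itertools.product(pos, neg):
        total += 1.0 if p > c else (0.5 if p == c else 0.0)
    return total / (len(pos) * len(neg))


class TestFilterAUC:
    def test_perfect_separation(self):
        assert filter_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_interleaved(self):
        assert filter_auc([1, 3, 2], [1, 1, 0]) == pytest.approx(0.5)

    def test_all_ties(self):
        assert filter_auc([2.0] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    @given(
        st.lists(st.integers(-3, 3), min_size=2, max_size=30),
        st.data(),
    )
    def test_matches_all_pairs_count(self, logits, data):
        n = len(logits)
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        assert filter_auc(logits, labels) == pytest.approx(brute_force_auc(logits, labels))

    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=30),
        st.data(),
    )
    def test_negating_logits_flips_auc(self, logits, data):
        n = len(logits)
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        if len(set(labels)) < 2:
            labels[0], labels[-1] = 0, 1
        a = filter_auc(logits, labels)
        b = filter_auc([-x for x in logits], labels)
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            filter_auc([1, 2], [1, 1])


class TestComputeFilterMetrics:
    def test_zero_weight_model_is_uninformative(self):
        texts = ["alpha beta", "beta gamma", "gamma alpha"]
        docs = docs_from_texts(texts, [1, 0, 1])
        vocab = build_vocabulary(docs)
        model = build_random_model(vocab_size=len(vocab), seed=0)
        for s in range(len(model.config.ngram_sizes)):
            model.conv_weights[s][:] = 0.0
            model.kernel_biases[s][:] = 0.0
        zf = calc_zf_dict(model, docs, vocab)
        metrics = compute_filter_metrics(zf, model)
        for m in metrics:
            assert m.auc == pytest.approx(0.5)
            assert m.delta_mean == pytest.approx(0.0)
            assert m.delta_median == pytest.approx(0.0)

    def test_hand_computed_example(self, small_corpus):
        vocab = build_vocabulary(small_corpus)
        model = build_random_model(vocab_size=len(vocab), seed=11)
        zf = calc_zf_dict(model, small_corpus, vocab)
        metrics = compute_filter_metrics(zf, model, central_statistic="mean")
        assert len(metrics) == model.n_filters
        y = zf[0].sample_labels
        lg = zf[0].sample_logits
        assert metrics[0].delta_mean == pytest.approx(lg[y == 1].mean() - lg[y == 0].mean())
        assert metrics[0].patient_central == pytest.approx(lg[y == 1].mean())
        assert metrics[0].auc == pytest.approx(brute_force_auc(lg.tolist(), y.tolist()))


def make_metrics(values, key="delta_mean"):
    out = []
    for k, v in enumerate(values):
        fields = dict(auc=0.5, delta_median=0.0, delta_mean=0.0, patient_central=0.0,
                      control_central=0.0, importance=0.0, class_sign=1)
        fields[key] = v
        out.append(FilterMetrics(filter_index=k, **fields))
    return out


class TestRankFilters:
    def test_single_filter(self):
        m = make_metrics([1.0])
        for key in ("delta_mean", "delta_median", "auc", "importance"):
            assert rank_filters(m, m, key, "first") == [0]

    def test_sort_on_switches_dataset(self):
        a = make_metrics([2.0, 1.0])
        b = make_metrics([1.0, 2.0])
        assert rank_filters(a, b, "delta_mean", "first") == [0, 1]
        assert rank_filters(a, b, "delta_mean", "second") == [1, 0]

    @pytest.mark.parametrize("key", ["delta_mean", "delta_median", "auc", "importance"])
    def test_matches_stable_sort_oracle(self, key):
        rng = np.random.default_rng(17)
        vals = rng.choice([0.1, 0.5, 0.9], size=20)  # duplicates force tie-breaks
        m = make_metrics(vals.tolist(), key)
        expected = [k for k, _ in sorted(enumerate(vals), key=lambda kv: (-kv[1], kv[0]))]
        assert rank_filters(m, m, key, "first") == expected

    def test_unknown_key_rejected(self):
        m = make_metrics([1.0])
        with pytest.raises(ValueError, match="unknown rank key"):
            rank_filters(m, m, "logit", "first")


class TestCountNgramInstances:
    def test_absent_ngram(self, small_corpus):
        assert count_ngram_instances(["zeta"], small_corpus) == (0, 0)

    def test_hand_planted_overlapping_counts(self):
        docs = docs_from_texts(["a a a b", "a a c"], [1, 0])
        assert count_ngram_instances(["a", "a"], docs) == (2, 1)
        assert count_ngram_instances(["a"], docs) == (3, 2)
        assert count_ngram_instances(["a", "a", "a"], docs) == (1, 0)

    def test_counts_partition_total(self, small_corpus):
        for ngram in (["alpha"], ["beta", "gamma"], ["alpha", "beta"]):
            p, c = count_ngram_instances(ngram, small_corpus)
            total = sum(
                sum(
                    1
                    for j in range(len(d.tokens) - len(ngram) + 1)
                    if d.tokens[j : j + len(ngram)] == ngram
                )
                for d in small_corpus
            )
            assert p + c == total
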