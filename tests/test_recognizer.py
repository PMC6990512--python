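"""BiLSTM-CRF recognizer: CRF algebra, features, decoding, post-processing."""

import itertools

import numpy as np
import pytest

from bioidtn.corpus_io import Document, MentionSpan, Token, tokenize
from bioidtn.recognizer import (ContextualCombiner, RecognizerConfig,
                                RecognizerModel, combine_contextual_layers,
                                crf_log_likelihood, crf_sequence_score,
                                post_process, train_recognizer,
                                viterbi_decode)
from bioidtn.vectors import WordVectors


# ---------------------------------------------------------------------------
# contextual combination
# ---------------------------------------------------------------------------

class TestContextualCombiner:
    def test_equal_weights_give_layer_mean(self):
        rng = np.random.default_rng(0)
        layers = rng.normal(0, 1, (2, 5, 4))
        combiner = ContextualCombiner(2)
        out = combine_contextual_layers(layers, combiner)
        assert np.allclose(out, layers.mean(axis=0), atol=1e-12)

    def test_zero_gamma_gives_zero(self):
        combiner = ContextualCombiner(3)
        combiner.gamma.data = np.array(0.0)
        layers = np.random.default_rng(1).normal(0, 1, (3, 4, 6))
        assert np.allclose(combine_contextual_layers(layers, combiner), 0.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            L, n, w = rng.integers(1, 5), rng.integers(1, 6), rng.integers(2, 8)
            layers = rng.normal(0, 1, (L, n, w))
            combiner = ContextualCombiner(L, gamma=float(rng.normal(1, 0.5)))
            combiner.layer_logits.data = rng.normal(0, 1, L)
            weights = combiner.weights()
            expected = np.zeros((n, w))
            for j in range(L):
                for t in range(n):
                    for d in range(w):
                        expected[t, d] += weights[j] * layers[j, t, d]
            expected *= combiner.gamma.data
            got = combine_contextual_layers(layers, combiner)
            assert np.allclose(got, expected, atol=1e-8)
            assert weights.sum() == pytest.approx(1.0, abs=1e-12)

    def test_width_mismatch_raises(self):
        combiner = ContextualCombiner(2)
        with pytest.raises(ValueError):
            combine_contextual_layers(np.zeros((3, 4, 5)), combiner)


# ---------------------------------------------------------------------------
# CRF
# ---------------------------------------------------------------------------

class TestCRF:
    def test_single_step_score_is_emission(self):
        P = np.array([[1.5, -0.5]])
        T = np.zeros((4, 4))
        assert crf_sequence_score(P, T, [0]) == pytest.approx(1.5)

    def test_zero_emissions_score_is_transition_sum(self):
        rng = np.random.default_rng(3)
        T = rng.normal(0, 1, (5, 5))
        P = np.zeros((3, 3))
        y = [2, 0, 1]
        expected = T[3, 2] + T[2, 0] + T[0, 1] + T[1, 4]
        assert crf_sequence_score(P, T, y) == pytest.approx(expected)

    def test_score_matches_term_sum_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n, k = int(rng.integers(1, 7)), int(rng.integers(1, 5))
            P = rng.normal(0, 2, (n, k))
            T = rng.normal(0, 2, (k + 2, k + 2))
            y = rng.integers(0, k, n)
            expected = T[k, y[0]] + P[0, y[0]]
            for i in range(1, n):
                expected += T[y[i - 1], y[i]] + P[i, y[i]]
            expected += T[y[-1], k + 1]
            assert crf_sequence_score(P, T, y) == pytest.approx(expected,
                                                                abs=1e-10)

    def test_single_label_log_likelihood_is_zero(self):
        rng = np.random.default_rng(5)
        P = rng.normal(0, 1, (4, 1))
        T = rng.normal(0, 1, (3, 3))
        assert crf_log_likelihood(P, T, [0, 0, 0, 0]) == pytest.approx(
            0.0, abs=1e-10)

    def test_single_step_is_log_softmax(self):
        rng = np.random.default_rng(6)
        P = rng.normal(0, 1, (1, 4))
        T = np.zeros((6, 6))
        for y in range(4):
            expected = P[0, y] - np.log(np.exp(P[0]).sum())
            assert crf_log_likelihood(P, T, [y]) == pytest.approx(expected,
                                                                  abs=1e-10)

    def test_forward_and_viterbi_match_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n, k = int(rng.integers(1, 6)), int(rng.integers(1, 5))
            P = rng.normal(0, 2, (n, k))
            T = rng.normal(0, 2, (k + 2, k + 2))
            paths = list(itertools.product(range(k), repeat=n))
            scores = np.array([crf_sequence_score(P, T, y) for y in paths])
            logz = np.log(np.exp(scores - scores.max()).sum()) + scores.max()
            y = paths[int(rng.integers(len(paths)))]
            ll = crf_sequence_score(P, T, y) - logz
            assert crf_log_likelihood(P, T, y) == pytest.approx(ll, abs=1e-8)
            path, best = viterbi_decode(P, T)
            assert best == pytest.approx(scores.max(), abs=1e-8)
            assert crf_sequence_score(P, T, path) == pytest.approx(
                scores.max(), abs=1e-8)

    def test_partition_dominates_any_path(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n, k = int(rng.integers(1, 6)), int(rng.integers(2, 5))
            P = rng.normal(0, 3, (n, k))
            T = rng.normal(0, 3, (k + 2, k + 2))
            y = rng.integers(0, k, n)
            assert crf_log_likelihood(P, T, y) <= 1e-12

    def test_viterbi_invariant_to_per_step_emission_shift(self):
        rng = np.random.default_rng(9)
        P = rng.normal(0, 1, (5, 3))
        T = rng.normal(0, 1, (5, 5))
        path1, _ = viterbi_decode(P, T)
        shifted = P + rng.normal(0, 5, (5, 1))
        path2, _ = viterbi_decode(shifted, T)
        assert path1 == path2

    def test_empty_sequence(self):
        path, score = viterbi_decode(np.zeros((0, 3)), np.zeros((5, 5)))
        assert path == [] and score == 0.0

    def test_strongly_favored_path_is_returned(self):
        P = np.array([[10.0, 0, 0], [0, 10.0, 0], [0, 0, 10.0]])
        path, _ = viterbi_decode(P, np.zeros((5, 5)))
        assert path == [0, 1, 2]


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

def _tiny_model(word_dim=12, **overrides):
    rng = np.random.default_rng(10)
    words = ["vegf", "level", "the", "rises"]
    wv = WordVectors({w: rng.normal(0, 1, word_dim) for w in words})
    cfg = RecognizerConfig(seed=0, char_emb_dim=8, char_hidden=4, pos_dim=4,
                           chunk_dim=3, kf_dim=5, elmo_width=6, hidden=8,
                           **overrides)
    return RecognizerModel(cfg, wv, words, list("abcdefghvl"),
                           ["NN", "SYM"], ["B-NP", "O"])


class TestFeatures:
    def test_full_scale_concatenated_dimension(self):
        rng = np.random.default_rng(11)
        words = ["vegf"]
        wv = WordVectors({w: rng.normal(0, 1, 200) for w in words})
        model = RecognizerModel(RecognizerConfig(seed=0), wv, words,
                                ["v"], ["NN"], ["O"])
        assert model.input_dim == 200 + 50 + 25 + 10 + 15 + 32

    def test_feature_purity_and_slices(self):
        model = _tiny_model()
        tokens = tokenize("vegf level rises")
        x1 = model.build_features(tokens, ["B-kf", "O", "O"]).data
        x2 = model.build_features(tokens, ["B-kf", "O", "O"]).data
        assert np.array_equal(x1, x2)
        word_part = x1[:, :12]
        unk = len(model.vocab)
        widx = [model.vocab.get(t.text, unk) for t in tokens]
        assert np.allclose(word_part, model.word_emb.table.data[widx])
        kf_lo = 12 + 8 + 4 + 3
        kf_part = x1[:, kf_lo:kf_lo + 5]
        assert np.allclose(kf_part[0], model.kf_emb.table.data[1])
        assert np.allclose(kf_part[1], model.kf_emb.table.data[0])

    def test_char_encoder_is_order_sensitive(self):
        model = _tiny_model()
        fwd = model._char_vectors([Token("abcd", 0, 4)]).data
        rev = model._char_vectors([Token("dcba", 0, 4)]).data
        assert not np.allclose(fwd, rev)


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

class TestPostProcess:
    def test_repeat_rule_tags_second_occurrence(self):
        text = "Miro1 binds ΔEF and later Miro1 appears"
        doc = Document("d", text, [])
        spans = [MentionSpan(0, 5, "Miro1", "gene")]
        out = post_process(spans, doc)
        assert [(s.start, s.end) for s in out] == [(0, 5), (26, 31)]

    def test_bracket_rule_extends_to_closing(self):
        text = "the GFP(S65T mutant) construct"
        doc = Document("d", text, [])
        spans = [MentionSpan(4, 12, "GFP(S65T", "gene")]
        out = post_process(spans, doc)
        assert out[0].surface == "GFP(S65T mutant)"

    def test_idempotence_on_random_outputs(self):
        rng = np.random.default_rng(12)
        words = ["aa", "bb(x", "cc", "dd)", "ee"]
        for _ in range(50):
            chosen = [words[rng.integers(len(words))]
                      for _ in range(rng.integers(3, 9))]
            text = " ".join(chosen)
            doc = Document("d", text, [])
            spans, pos = [], 0
            for w in chosen:
                if rng.random() < 0.3:
                    spans.append(MentionSpan(pos, pos + len(w), w, "gene"))
                pos += len(w) + 1
            kept = []
            for s in spans:
                if not any(s.overlaps(k) for k in kept):
                    kept.append(s)
            once = post_process(kept, doc)
            twice = post_process(once, doc)
            assert [(s.start, s.end) for s in once] == \
                [(s.start, s.end) for s in twice]


# ---------------------------------------------------------------------------
# training (small-scale)
# ---------------------------------------------------------------------------

def test_training_is_deterministic_given_seed():
    from bioidtn.presets import desk_recognizer_config, desk_synth_config
    from bioidtn.synthetic_data import generate_corpus, generate_kb
    import dataclasses
    from bioidtn.knowledge_kb import build_kb
    cfg = dataclasses.replace(desk_synth_config(seed=3), n_documents=24)
    records = generate_kb(cfg)
    docs, wv = generate_corpus(records, cfg)
    kb = build_kb(records)
    rc = desk_recognizer_config(seed=4, max_epochs=2, patience=2)
    m1 = train_recognizer(docs, kb, rc, wv)
    m2 = train_recognizer(docs, kb, rc, wv)
    for a, b in zip(m1.state_arrays(), m2.state_arrays()):
        assert np.array_equal(a, b)
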