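"""Context extraction, attention/gating algebra and candidate ranking."""

import numpy as np
import pytest

from bioidtn import nn
from bioidtn.corpus_io import Document, MentionSpan, strip_punctuation, tokenize
from bioidtn.disambiguator import (AttentionParams, DisambiguationSample,
                                   DisambiguatorConfig, DisambiguatorModel,
                                   GateParams, STOP_WORDS, extract_contexts,
                                   gate_combine, knowledge_attention,
                                   negative_samples, score_candidate,
                                   self_attention, train_disambiguator)
from bioidtn.knowledge_kb import CandidateSet
from bioidtn.vectors import WordVectors


class TestExtractContexts:
    def test_mention_at_start_has_empty_left(self):
        doc = Document("d", "VEGF rises sharply", [])
        m = MentionSpan(0, 4, "VEGF", "gene")
        left, right = extract_contexts(doc, m, n2=10)
        assert left == [] and right == ["rises", "sharply"]

    def test_short_side_stays_short(self):
        doc = Document("d", "alpha beta gamma VEGF", [])
        m = MentionSpan(17, 21, "VEGF", "gene")
        left, _ = extract_contexts(doc, m, n2=10)
        assert left == ["alpha", "beta", "gamma"]

    def test_eligibility_matches_filter_oracle(self):
        rng = np.random.default_rng(0)
        words = ["the", "kinase", ",", "binds", "of", "p53", "-", "signal"]
        for _ in range(50):
            chosen = [words[rng.integers(len(words))]
                      for _ in range(rng.integers(4, 14))]
            text = " ".join(chosen)
            doc = Document("d", text, [])
            tokens = tokenize(doc)
            i = int(rng.integers(len(tokens)))
            m = MentionSpan(tokens[i].start, tokens[i].end,
                            tokens[i].text, "gene")
            n2 = int(rng.integers(1, 5))
            left, right = extract_contexts(doc, m, n2)
            ok = [t.text for t in tokens
                  if t.text.lower() not in STOP_WORDS
                  and not strip_punctuation(t.text)]
            left_ok = [t.text for t in tokens if t.end <= m.start
                       and t.text.lower() not in STOP_WORDS
                       and not strip_punctuation(t.text)]
            right_ok = [t.text for t in tokens if t.start >= m.end
                        and t.text.lower() not in STOP_WORDS
                        and not strip_punctuation(t.text)]
            assert left == left_ok[-n2:] and right == right_ok[:n2]


def _params(d_h, d_id, seed=0):
    return AttentionParams(np.random.default_rng(seed), d_h, d_id)


class TestAttention:
    def test_identical_states_give_uniform_weights(self):
        h = np.tile(np.array([1.0, -2.0, 0.5]), (4, 1))
        o, alpha = knowledge_attention(h, np.ones(3), _params(3, 3))
        assert np.allclose(alpha.data, 0.25)
        assert np.allclose(o.data, h[0])

    def test_single_step_gets_weight_one(self):
        h = np.array([[0.3, 0.7]])
        o, alpha = knowledge_attention(h, np.zeros(2), _params(2, 2))
        assert np.allclose(alpha.data, [1.0]) and np.allclose(o.data, h[0])

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            knowledge_attention(np.zeros((0, 3)), np.zeros(3), _params(3, 3))

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            T, d_h, d_id = rng.integers(1, 7), rng.integers(2, 6), 4
            h = rng.normal(0, 1, (int(T), int(d_h)))
            s = rng.normal(0, 1, d_id)
            p = _params(int(d_h), d_id, seed=int(rng.integers(100)))
            o, alpha = knowledge_attention(h, s, p)
            e = np.array([np.tanh(p.W_a.data @ h[t] + p.V_a.data @ s
                                  + p.b_a.data) for t in range(int(T))])
            a = np.exp(e) / np.exp(e).sum()
            expected = sum(a[t] * h[t] for t in range(int(T)))
            assert np.allclose(alpha.data, a, atol=1e-8)
            assert np.allclose(o.data, expected, atol=1e-8)
            assert alpha.data.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(alpha.data >= 0)

    def test_self_attention_equals_knowledge_at_zero_va(self):
        rng = np.random.default_rng(2)
        h = rng.normal(0, 1, (5, 4))
        p = _params(4, 4, seed=3)
        p.V_a.data[:] = 0.0
        o1, a1 = knowledge_attention(h, rng.normal(0, 1, 4), p)
        o2, a2 = self_attention(h, p)
        assert np.allclose(o1.data, o2.data, atol=1e-12)
        assert np.allclose(a1.data, a2.data, atol=1e-12)

    def test_self_attention_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            h = rng.normal(0, 2, (int(rng.integers(1, 8)), 5))
            _, alpha = self_attention(h, _params(5, 5, seed=4))
            assert alpha.data.sum() == pytest.approx(1.0, abs=1e-12)


class TestGate:
    def test_zero_parameters_give_exact_mean(self):
        rng = np.random.default_rng(4)
        p = GateParams(rng, 6)
        p.W_g.data[:] = 0.0
        p.V_g.data[:] = 0.0
        oL, oR = rng.normal(0, 1, 6), rng.normal(0, 1, 6)
        z, g = gate_combine(oL, oR, p)
        assert g.data == pytest.approx(0.5)
        assert np.allclose(z.data, (oL + oR) / 2, atol=1e-12)

    def test_large_bias_saturates_to_left(self):
        rng = np.random.default_rng(5)
        p = GateParams(rng, 4)
        p.W_g.data[:] = 0.0
        p.V_g.data[:] = 0.0
        p.b_g.data = np.array(20.0)
        oL, oR = rng.normal(0, 1, 4), rng.normal(0, 1, 4)
        z, _ = gate_combine(oL, oR, p)
        assert np.allclose(z.data, oL, atol=1e-6)

    def test_matches_loop_oracle_and_envelope(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            d = int(rng.integers(2, 8))
            p = GateParams(rng, d)
            oL, oR = rng.normal(0, 1, d), rng.normal(0, 1, d)
            z, g = gate_combine(oL, oR, p)
            gv = 1 / (1 + np.exp(-(p.W_g.data @ oL + p.V_g.data @ oR
                                   + p.b_g.data)))
            assert g.data == pytest.approx(gv, abs=1e-8)
            assert np.allclose(z.data, gv * oL + (1 - gv) * oR, atol=1e-8)
            assert 0 < gv < 1
            lo, hi = np.minimum(oL, oR), np.maximum(oL, oR)
            assert np.all(z.data >= lo - 1e-12)
            assert np.all(z.data <= hi + 1e-12)


def _toy_model(attention="knowledge", encoder="BiGRU", seed=0):
    rng = np.random.default_rng(7)
    wv = WordVectors({w: rng.normal(0, 1, 6)
                      for w in ["kinase", "binds", "p53", "signal"]})
    ids = {f"ID:{i}": rng.normal(0, 1, 5) for i in range(4)}
    cfg = DisambiguatorConfig(seed=seed, encoder=encoder, attention=attention,
                              hidden=4, fc_hidden=8, n2=4, elmo_width=3)
    return DisambiguatorModel(cfg, wv, ids)


class TestScoring:
    def test_softmax_outputs_sum_to_one_and_purity(self):
        model = _toy_model()
        s = DisambiguationSample(["kinase"], ["binds", "p53"], "ID:1", 1)
        out = model.forward(s).data
        assert out.sum() == pytest.approx(1.0, abs=1e-12)
        assert score_candidate(s, model) == pytest.approx(
            score_candidate(s, model))

    def test_classifier_matches_matrix_oracle(self):
        model = _toy_model(attention="none")
        s = DisambiguationSample(["kinase"], ["p53"], "ID:2", 1)
        xL = model._context_matrix(s.left_context)
        xR = model._context_matrix(s.right_context)
        _, lastL = model.enc_left(nn.Tensor(xL[:, None, :]))
        _, lastR = model.enc_right(nn.Tensor(xR[:, None, :]))
        oL, oR = lastL.data[0], lastR.data[0]
        g = 1 / (1 + np.exp(-(model.gate.W_g.data @ oL
                              + model.gate.V_g.data @ oR
                              + model.gate.b_g.data)))
        z = g * oL + (1 - g) * oR
        feat = np.concatenate([z, model.id_vector("ID:2")])
        h1 = np.maximum(feat @ model.fc1.W.data + model.fc1.b.data, 0)
        h2 = np.maximum(h1 @ model.fc2.W.data + model.fc2.b.data, 0)
        logits = h2 @ model.out.W.data + model.out.b.data
        expected = np.exp(logits) / np.exp(logits).sum()
        assert np.allclose(model.forward(s).data, expected, atol=1e-8)

    def test_hierconvnet_width_is_four_times_maps(self):
        model = _toy_model(encoder="HierConvNet")
        assert model.enc_left.out_width == 4 * model.config.conv_maps

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(8)
        wv = WordVectors({w: rng.normal(0, 1, 6)
                          for w in ["kinase", "binds", "p53", "signal"]})
        ids = {f"ID:{i}": rng.normal(0, 1, 5) for i in range(3)}
        samples = [DisambiguationSample(["kinase"], ["p53"], f"ID:{i % 3}",
                                        i % 2) for i in range(12)]
        cfg = DisambiguatorConfig(seed=9, hidden=4, fc_hidden=8, n2=3,
                                  elmo_width=3, epochs=3)
        m1 = train_disambiguator(samples, cfg, wv, ids)
        m2 = train_disambiguator(samples, cfg, wv, ids)
        for a, b in zip(m1.state_arrays(), m2.state_arrays()):
            assert np.array_equal(a, b)


class TestNegativeSampling:
    def test_gold_only_candidates_give_no_negatives(self):
        rng = np.random.default_rng(0)
        cands = CandidateSet("m", ["ID:g"], [1.0])
        assert negative_samples(([], []), "ID:g", cands, 2, rng) == []

    def test_single_non_gold_is_forced(self):
        rng = np.random.default_rng(0)
        cands = CandidateSet("m", ["ID:g", "ID:a"], [1.0, 0.5])
        out = negative_samples((["x"], ["y"]), "ID:g", cands, 1, rng)
        assert len(out) == 1 and out[0].candidate_id == "ID:a"
        assert out[0].label == 0
        assert out[0].left_context == ["x"] and out[0].right_context == ["y"]

    def test_draws_are_uniform_within_three_sigma(self):
        cands = CandidateSet("m", ["ID:g", "ID:a", "ID:b", "ID:c"],
                             [4.0, 3.0, 2.0, 1.0])
        counts = {"ID:a": 0, "ID:b": 0, "ID:c": 0}
        n = 10_000
        for seed in range(n):
            rng = np.random.default_rng(seed)
            out = negative_samples(([], []), "ID:g", cands, 1, rng)
            counts[out[0].candidate_id] += 1
        p = 1 / 3
        sigma = np.sqrt(n * p * (1 - p))
        for c in counts.values():
            assert abs(c - n * p) < 3 * sigma
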