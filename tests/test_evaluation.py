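"""Recognition/normalization scoring, error taxonomy, corpus stats, curve fit."""

import numpy as np
import pytest

from bioidtn.corpus_io import Document, MentionSpan
from bioidtn.evaluation import (CATEGORIES, breakdown_from_counts,
                                corpus_stats, error_breakdown,
                                fit_learning_curve, score_nen, score_ner)


def span(start, end, etype="gene", gold=None, pred=None):
    return MentionSpan(start, end, "x" * (end - start), etype, gold, pred)


class TestScoreNER:
    def test_identical_sets_are_perfect(self):
        gold = [[span(0, 4), span(10, 15)]]
        assert score_ner(gold, gold, "strict").f1 == 1.0
        assert score_ner(gold, gold, "overlap").f1 == 1.0

    def test_partial_overlap_distinguishes_modes(self):
        gold = [[span(0, 5)]]
        pred = [[span(2, 7)]]
        assert score_ner(gold, pred, "strict").f1 == 0.0
        assert score_ner(gold, pred, "overlap").f1 == 1.0

    def test_strict_never_exceeds_overlap(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            gold = [[span(s, s + rng.integers(1, 5))
                     for s in rng.choice(40, rng.integers(0, 5),
                                         replace=False) ]]
            pred = [[span(s, s + rng.integers(1, 5))
                     for s in rng.choice(40, rng.integers(0, 5),
                                         replace=False)]]
            assert score_ner(gold, pred, "strict").f1 <= \
                score_ner(gold, pred, "overlap").f1 + 1e-12

    def test_greedy_matches_optimal_on_disjoint_gold(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            starts = np.sort(rng.choice(50, rng.integers(1, 6),
                                        replace=False)) * 10
            gold = [[span(int(s), int(s) + 5) for s in starts]]
            pred = [[span(int(s) + int(rng.integers(-3, 4)),
                          int(s) + 5 + int(rng.integers(-3, 4)))
                     for s in starts if rng.random() < 0.7]]
            got = score_ner(gold, pred, "overlap")
            # brute-force maximum bipartite matching on the overlap graph
            import itertools
            g, p = gold[0], pred[0]
            best = 0
            for perm in itertools.permutations(range(len(g)),
                                               min(len(g), len(p))):
                ok = sum(1 for pi, gi in enumerate(perm)
                         if g[gi].start < p[pi].end
                         and p[pi].start < g[gi].end)
                best = max(best, ok)
            assert got.tp == best


class TestScoreNEN:
    def test_micro_arithmetic(self):
        # tp=4, fp=4, fn=6 pooled over two documents
        gold = [[span(i * 10, i * 10 + 4, gold=f"ID:{i}") for i in range(5)],
                [span(i * 10, i * 10 + 4, gold=f"ID:{i + 5}")
                 for i in range(5)]]
        pred = [[span(i * 10, i * 10 + 4, pred=f"ID:{i}") for i in range(4)]
                + [span(90, 94, pred="ID:wrong1"), span(80, 84,
                                                        pred="ID:wrong2")],
                [span(0, 4, pred="ID:nope"), span(70, 74, pred="ID:nope2")]]
        r = score_nen(gold, pred, "micro")
        assert (r.tp, r.fp, r.fn) == (4, 4, 6)
        assert r.precision == pytest.approx(0.5)
        assert r.recall == pytest.approx(0.4)
        assert r.f1 == pytest.approx(0.444, abs=5e-4)

    def test_macro_averages_per_document(self):
        gold = [[span(0, 4, gold="ID:1")], [span(0, 4, gold="ID:2")]]
        pred = [[span(0, 4, pred="ID:1")], []]
        r = score_nen(gold, pred, "macro")
        assert r.precision == pytest.approx(0.5)
        assert r.recall == pytest.approx(0.5)

    def test_generic_ids_are_not_evaluated(self):
        gold = [[span(0, 4, gold="ID:1")]]
        pred = [[span(0, 4, pred="GENERIC:gene"), span(8, 12, pred="ID:1")]]
        r = score_nen(gold, pred, "micro")
        assert r.fp == 1  # only the normalized (non-generic) prediction

    def test_micro_matches_pooled_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            gold, pred = [], []
            for _ in range(rng.integers(1, 4)):
                g = [span(int(s) * 10, int(s) * 10 + 4,
                          gold=f"ID:{rng.integers(4)}")
                     for s in rng.choice(8, rng.integers(0, 5),
                                         replace=False)]
                p = [span(m.start, m.end, pred=f"ID:{rng.integers(4)}")
                     for m in g if rng.random() < 0.8]
                gold.append(g)
                pred.append(p)
            r = score_nen(gold, pred, "micro")
            gp = {(d, m.start, m.end, m.gold_id)
                  for d, doc in enumerate(gold) for m in doc}
            pp = {(d, m.start, m.end, m.predicted_id)
                  for d, doc in enumerate(pred) for m in doc}
            assert r.tp == len(gp & pp)
            assert r.fp == len(pp - gp)
            assert r.fn == len(gp - pp)


class TestErrorBreakdown:
    def test_zero_errors(self):
        b = breakdown_from_counts(0, 0, 0, 0)
        assert all(v == 0.0 for v in b.percentages.values())

    def test_percentages_sum_to_hundred(self):
        b = breakdown_from_counts(995, 2561, 1376, 725)
        assert sum(b.percentages.values()) == pytest.approx(100.0, abs=0.02)

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            gold, pred, cands = [], [], []
            for _ in range(rng.integers(1, 3)):
                g, p, c = [], [], {}
                for s in rng.choice(10, rng.integers(0, 6), replace=False):
                    s = int(s) * 10
                    gid = f"ID:{rng.integers(4)}"
                    g.append(span(s, s + 4, gold=gid))
                    if rng.random() < 0.7:
                        pid = f"ID:{rng.integers(4)}"
                        p.append(span(s, s + 4, pred=pid))
                        pool = [f"ID:{i}" for i in range(4)
                                if rng.random() < 0.6]
                        c[(s, s + 4, "gene")] = pool
                if rng.random() < 0.3:
                    p.append(span(990, 994, pred="ID:0"))
                    c[(990, 994, "gene")] = ["ID:0"]
                gold.append(g)
                pred.append(p)
                cands.append(c)
            b = error_breakdown(gold, pred, cands)
            # independent recount of distinct errors
            n_err = 0
            for g, p, c in zip(gold, pred, cands):
                gkeys = {(m.start, m.end) for m in g}
                pkeys = {(m.start, m.end) for m in p}
                n_err += len(pkeys - gkeys) + len(gkeys - pkeys)
                for m in p:
                    if (m.start, m.end) in gkeys:
                        gm = next(x for x in g
                                  if (x.start, x.end) == (m.start, m.end))
                        if m.predicted_id != gm.gold_id:
                            n_err += 1
            assert b.total == n_err
            assert sum(b.counts.values()) == b.total
            assert set(b.counts) == set(CATEGORIES)


class TestCorpusStats:
    def test_all_monosemous_flags_undefined_rate(self):
        docs = [Document("d", "aa bb", [
            MentionSpan(0, 2, "aa", "gene", gold_id="ID:1"),
            MentionSpan(3, 5, "bb", "gene", gold_id="ID:2")])]
        s = corpus_stats(docs)
        assert s.n_polysemous == 0 and s.ambiguity_rate == 0.0
        assert not s.ambiguity_defined

    def test_two_mentions_simple_case(self):
        text = "aa bb aa"
        docs = [Document("d", text, [
            MentionSpan(0, 2, "aa", "gene", gold_id="ID:A"),
            MentionSpan(3, 5, "bb", "gene", gold_id="ID:A"),
            MentionSpan(6, 8, "aa", "gene", gold_id="ID:B")])]
        s = corpus_stats(docs)
        assert s.n_monosemous == 1 and s.n_polysemous == 1
        assert s.ambiguity_rate == pytest.approx(2.0)
        # ID:A is named by two surfaces -> synonymy rate 2
        assert s.n_multi_var == 1 and s.synonymy_rate == pytest.approx(2.0)

    def test_matches_group_by_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            docs = []
            pairs = []
            for d in range(rng.integers(1, 4)):
                mentions = []
                for k in range(rng.integers(0, 6)):
                    surf = f"m{rng.integers(4)}"
                    gid = f"ID:{rng.integers(4)}"
                    mentions.append(MentionSpan(k * 3, k * 3 + 2, surf,
                                                "gene", gold_id=gid))
                    pairs.append((surf, gid))
                text = " " * 100
                docs.append(Document(f"d{d}", text, [
                    MentionSpan(m.start, m.end,
                                text[m.start:m.end], m.entity_type,
                                m.gold_id) for m in mentions]))
            # surfaces in the oracle follow the text slices actually stored
            pairs = [(m.surface, m.gold_id)
                     for doc in docs for m in doc.mentions]
            s = corpus_stats(docs)
            by_m, by_id = {}, {}
            for surf, gid in pairs:
                by_m.setdefault(surf, set()).add(gid)
                by_id.setdefault(gid, set()).add(surf)
            poly = [len(v) for v in by_m.values() if len(v) > 1]
            multi = [len(v) for v in by_id.values() if len(v) > 1]
            assert s.n_mentions == len(by_m)
            assert s.n_polysemous == len(poly)
            if poly:
                assert s.ambiguity_rate == pytest.approx(np.mean(poly))
            if multi:
                assert s.synonymy_rate == pytest.approx(np.mean(multi))


class TestLearningCurve:
    def test_constant_points_recover_constant(self):
        fit = fit_learning_curve([(n, 0.75) for n in range(1, 9)])
        assert fit.i == pytest.approx(0.75, abs=1e-9)
        assert fit.residual == pytest.approx(0.0, abs=1e-10)

    def test_recovers_random_parameters_noiselessly(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            i = rng.uniform(0.3, 0.9)
            j = rng.uniform(-0.3, -0.05)
            m = rng.uniform(0.3, 0.95)
            pts = [(n, i + j * m ** n) for n in range(1, 9)]
            fit = fit_learning_curve(pts)
            assert fit.i == pytest.approx(i, abs=1e-4)
            assert fit.j == pytest.approx(j, abs=1e-3)
            assert fit.m == pytest.approx(m, abs=1e-4)
            assert fit.residual < 1e-10

    def test_requires_four_points(self):
        with pytest.raises(ValueError):
            fit_learning_curve([(1, 0.5), (2, 0.6), (3, 0.65)])
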