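"""Metric functions checked against hand computations and small oracles."""

import numpy as np
import pytest

from relmine.corpus import Corpus, Document, Mention, Relation, Span
from relmine.evaluation import (BootstrapResult, MatchCounts, bootstrap_f1_diff,
                                corpus_stats, dominant_relation_share,
                                f1_from_pr, match_el, match_ner,
                                match_ner_corpus, match_relations, mcnemar_test,
                                prf_from_counts, re_error_breakdown, round2,
                                topk_accuracy)


class TestPRF:
    def test_hand_computed_example(self):
        prf = prf_from_counts(MatchCounts(tp=3, fp=1, fn=2))
        assert prf.rounded() == (75.0, 60.0, 66.67)

    def test_degenerate_all_zero(self):
        assert prf_from_counts(MatchCounts()).rounded() == (0.0, 0.0, 0.0)

    def test_perfect(self):
        assert prf_from_counts(MatchCounts(tp=7)).rounded() == (100.0, 100.0, 100.0)

    @pytest.mark.parametrize("p,r,f1", [
        (94.05, 93.01, 93.53),  # overall NER row of the multi-corpus model
        (68.60, 62.10, 65.19),  # overall RE row with gold entities
        (100.0, 100.0, 100.0),
    ])
    def test_harmonic_mean_reproduces_reported_f1(self, p, r, f1):
        assert f1_from_pr(p, r) == f1

    def test_zero_denominator(self):
        assert f1_from_pr(0.0, 0.0) == 0.0

    def test_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tp, fp, fn = rng.integers(0, 30, size=3)
            prf = prf_from_counts(MatchCounts(int(tp), int(fp), int(fn)))
            assert 0.0 <= prf.precision <= 100.0
            assert 0.0 <= prf.recall <= 100.0
            assert 0.0 <= prf.f1 <= 100.0


def mk_doc(doc_id, mentions, relations=()):
    return Document(doc_id, "t" * 200, "", list(mentions), list(relations))


class TestMatchNER:
    def test_identical_sets(self):
        ms = [Mention(Span(0, 5), "ttttt", "Gene", ("G1",))]
        res = match_ner(ms, ms)
        assert (res.counts.tp, res.counts.fp, res.counts.fn) == (1, 0, 0)

    def test_shifted_span_counts_partial(self):
        gold = [Mention(Span(0, 5), "ttttt", "Gene")]
        pred = [Mention(Span(1, 5), "tttt", "Gene")]
        res = match_ner(gold, pred)
        assert (res.counts.tp, res.counts.fp, res.counts.fn) == (0, 1, 1)
        assert res.partial == 1 and res.missed == 0

    def test_empty_predictions(self):
        gold = [Mention(Span(0, 5), "ttttt", "Gene"),
                Mention(Span(6, 9), "ttt", "Disease")]
        res = match_ner(gold, [])
        assert res.counts.fn == 2 and res.counts.tp == 0
        assert res.missed == 2

    def test_micro_counts_sum_per_type(self, world, dev_predictions):
        res = match_ner_corpus(world.dev, dev_predictions)
        assert res.counts.tp == sum(c.tp for c in res.per_type.values())
        assert res.counts.fp == sum(c.fp for c in res.per_type.values())
        assert res.counts.fn == sum(c.fn for c in res.per_type.values())


class TestMatchEL:
    def test_identical_tuple_sets(self):
        docs = [mk_doc("1", [Mention(Span(0, 5), "ttttt", "Gene", ("G1",))])]
        counts = match_el(Corpus(docs), Corpus([d.copy() for d in docs]))
        prf = prf_from_counts(counts["All"])
        assert (prf.precision, prf.recall) == (100.0, 100.0)

    def test_composite_mention_expands_to_tuples(self):
        gold = Corpus([mk_doc("1", [Mention(Span(0, 5), "ttttt", "Disease", ("D1",))])])
        pred = Corpus([mk_doc("1", [Mention(Span(0, 5), "ttttt", "Disease", ("D1", "D2"))])])
        counts = match_el(gold, pred)["Disease"]
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 0)

    def test_repeated_mentions_collapse_to_one_tuple(self):
        gold = Corpus([mk_doc("1", [Mention(Span(i * 6, i * 6 + 5), "ttttt",
                                            "Gene", ("G1",)) for i in range(5)])])
        pred = Corpus([mk_doc("1", [Mention(Span(0, 5), "ttttt", "Gene", ("G1",))])])
        counts = match_el(gold, pred)["Gene"]
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)


class TestMatchRelations:
    def pairify(self, rtype_gold, rtype_pred, novelty_gold=None, novelty_pred=None):
        m = [Mention(Span(0, 5), "ttttt", "Gene", ("G1",)),
             Mention(Span(6, 9), "ttt", "Gene", ("G2",))]
        gold = Corpus([mk_doc("1", m, [Relation(("G1", "G2"), rtype_gold, novelty_gold)])])
        pred = Corpus([mk_doc("1", m, [Relation(("G2", "G1"), rtype_pred, novelty_pred)])])
        return gold, pred

    def test_wrong_type_strict_is_error(self):
        gold, pred = self.pairify("Bind", "Association")
        c = match_relations(gold, pred, require_type=True)
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_wrong_type_agnostic_is_match(self):
        gold, pred = self.pairify("Bind", "Association")
        c = match_relations(gold, pred, require_type=False)
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_reversed_pair_still_matches(self):
        gold, pred = self.pairify("Bind", "Bind")
        assert match_relations(gold, pred).tp == 1

    def test_novelty_required(self):
        gold, pred = self.pairify("Bind", "Bind", "Novel", "No")
        c = match_relations(gold, pred, require_novelty=True)
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)


class TestTopK:
    def test_gold_always_first(self):
        cands = [[("A", 0.9), ("B", 0.1)]] * 4
        acc = topk_accuracy(cands, ["A"] * 4)
        assert all(v == 1.0 for v in acc.values())

    def test_monotone_in_k(self):
        rng = np.random.default_rng(0)
        idents = [f"X{i}" for i in range(25)]
        cands, gold = [], []
        for i in range(30):
            order = list(rng.permutation(idents))
            cands.append([(x, 1.0 - j / 30) for j, x in enumerate(order)])
            gold.append(idents[int(rng.integers(0, 25))])
        acc = topk_accuracy(cands, gold)
        assert acc[1] <= acc[5] <= acc[10] <= acc[20]

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(1)
        idents = [f"X{i}" for i in range(10)]
        cands, gold = [], []
        for i in range(30):
            order = list(rng.permutation(idents))
            cands.append([(x, -float(j)) for j, x in enumerate(order)])
            gold.append(idents[int(rng.integers(0, 10))])
        acc = topk_accuracy(cands, gold, ks=(1, 5))
        for k in (1, 5):
            manual = sum(g in [i for i, _ in c[:k]]
                         for c, g in zip(cands, gold)) / 30
            assert acc[k] == pytest.approx(manual)


class TestCorpusStats:
    def test_per_type_totals_sum(self, world):
        stats = corpus_stats(world.train)
        assert stats["total_mentions"] == sum(stats["mentions"].values())
        assert stats["total_relations"] == sum(stats["relations"].values())

    def test_independent_recount_on_generated_corpus(self, world):
        from collections import Counter
        mention_tally = Counter()
        relation_tally = Counter()
        for doc in world.dev:
            for m in doc.mentions:
                mention_tally[m.etype] += 1
            for r in doc.relations:
                relation_tally[r.rtype] += 1
        stats = corpus_stats(world.dev)
        assert stats["mentions"] == {t: mention_tally.get(t, 0)
                                     for t in stats["mentions"]}
        assert stats["relations"] == {t: relation_tally.get(t, 0)
                                      for t in stats["relations"]}

    def test_dominant_share_of_reported_relation_distribution(self):
        # distribution over the eight relation types in the benchmark corpus
        counts = {"Association": 6146, "Positive_Correlation": 3517,
                  "Negative_Correlation": 2342, "Cotreatment": 227,
                  "Bind": 225, "Comparison": 52, "Conversion": 17,
                  "Drug_Interaction": 13}
        assert sum(counts.values()) == 12539
        assert dominant_relation_share(counts) == 95.74


class TestBootstrap:
    def make_preds(self, world, damage=0):
        rng = np.random.default_rng(0)
        pred = world.dev.copy()
        for doc in pred:
            doc.relations = []
            if damage:
                doc.mentions = doc.mentions[:-damage]
        return pred

    def test_identical_systems_zero_difference(self, world):
        pred = self.make_preds(world)
        res = bootstrap_f1_diff(world.dev, pred, pred, n_samples=50,
                                sample_size=20, seed=1)
        assert res.mean_diff == 0.0 and (res.ci_low, res.ci_high) == (0.0, 0.0)

    def test_seeded_determinism(self, world):
        a = self.make_preds(world)
        b = self.make_preds(world, damage=1)
        r1 = bootstrap_f1_diff(world.dev, a, b, n_samples=100, sample_size=30, seed=9)
        r2 = bootstrap_f1_diff(world.dev, a, b, n_samples=100, sample_size=30, seed=9)
        assert r1 == r2
        assert r1.mean_diff > 0  # a is strictly better

    def test_matches_independent_reimplementation(self, world):
        """Same seed stream, re-implemented from scratch on a 10-doc fixture."""
        from relmine.evaluation import match_ner, prf_from_counts

        gold = Corpus(list(world.dev)[:10])
        a = Corpus([d.copy() for d in gold])
        b = Corpus([d.copy() for d in gold])
        for doc in b:
            doc.mentions = doc.mentions[:-1]
        res = bootstrap_f1_diff(gold, a, b, n_samples=40, sample_size=10, seed=5)

        doc_ids = [d.doc_id for d in gold]
        rng = np.random.default_rng(5)
        diffs = []
        for _ in range(40):
            drawn = rng.choice(len(doc_ids), size=10, replace=True)
            ta = MatchCounts(); tb = MatchCounts()
            for i in drawn:
                g = gold.by_id(doc_ids[i])
                ta += match_ner(g.mentions, a.by_id(doc_ids[i]).mentions).counts
                tb += match_ner(g.mentions, b.by_id(doc_ids[i]).mentions).counts
            diffs.append(prf_from_counts(ta).f1 - prf_from_counts(tb).f1)
        low, high = np.percentile(diffs, [2.5, 97.5])
        assert res.mean_diff == pytest.approx(np.mean(diffs))
        assert (res.ci_low, res.ci_high) == pytest.approx((low, high))


class TestMcNemar:
    def test_exact_p_for_three_one(self):
        # 2 * P(X <= 1 | n=4, p=1/2) = 10/16
        assert mcnemar_test(3, 1) == pytest.approx(0.625)

    def test_no_discordance_p_one(self):
        assert mcnemar_test(0, 0) == 1.0

    def test_symmetric_counts_maximize_p(self):
        for total in range(2, 12, 2):
            p_sym = mcnemar_test(total // 2, total // 2)
            for k in range(total // 2):
                assert p_sym >= mcnemar_test(k, total - k) - 1e-12

    def test_agrees_with_statsmodels_exact(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        for n01, n10 in [(3, 1), (10, 2), (7, 7), (0, 5)]:
            table = [[0, n01], [n10, 0]]
            want = sm.mcnemar(table, exact=True).pvalue
            assert mcnemar_test(n01, n10) == pytest.approx(want, abs=1e-12)

    def test_chi_square_variant(self):
        p = mcnemar_test(30, 10, exact=False)
        assert 0 < p < 0.01


class TestErrorBreakdown:
    def test_no_errors(self):
        m = [Mention(Span(0, 5), "ttttt", "Gene", ("G1",)),
             Mention(Span(6, 9), "ttt", "Gene", ("G2",))]
        c = Corpus([mk_doc("1", m, [Relation(("G1", "G2"), "Bind")])])
        out = re_error_breakdown(c, Corpus([d.copy() for d in c]))
        assert out["fp"]["n"] == 0 and out["fn"]["n"] == 0

    def test_half_type_confused_half_spurious(self):
        m = [Mention(Span(0, 5), "ttttt", "Gene", (i,)) for i in ("G1", "G2", "G3")]
        gold = Corpus([mk_doc("1", m, [Relation(("G1", "G2"), "Bind")])])
        pred = Corpus([mk_doc("1", m, [Relation(("G1", "G2"), "Association"),
                                       Relation(("G1", "G3"), "Bind")])])
        out = re_error_breakdown(gold, pred)
        assert out["fp"] == {"type_confusion": 0.5, "non_related": 0.5, "n": 2}

    def test_fractions_partition(self, world, dev_predictions):
        out = re_error_breakdown(world.dev, dev_predictions)
        for side in ("fp", "fn"):
            if out[side]["n"]:
                assert out[side]["type_confusion"] + out[side]["non_related"] == \
                    pytest.approx(1.0)


def test_round2_half_up():
    assert round2(66.665) == 66.67
    assert round2(2.675) == 2.68
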