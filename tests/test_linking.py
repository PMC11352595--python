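"""Synonym-index retrieval, ResCNN encoder behaviour and hybrid linking."""

import numpy as np
import pytest

from relmine.corpus import Corpus, Document, Mention, Span
from relmine.encoder import TinyEncoder, TinyEncoderSpec
from relmine.linking import (ResCNN, ResCNNConfig, augment_index_with_training,
                             build_synonym_index, build_lookup, fit_rescnn,
                             hybrid_link, normalize_text, retrieve_topk)
from relmine.tokenization import Vocabulary


def small_cfg(**kw):
    base = dict(pooling="max", learning_rate=1e-3, n_encoder_blocks=2,
                feature_size=32, dropout=0.0, n_filters=16, epochs=0,
                eval_every=5)
    base.update(kw)
    return ResCNNConfig(**base)


@pytest.fixture
def toy_rescnn():
    rows = [(f"D{i:03d}", w) for i, w in enumerate(
        ["migra", "coltra", "zemina", "batoke", "ferlis", "nodyne",
         "pexin", "ralave", "sumod", "tivara"])]
    vocab = Vocabulary.from_texts([w for _, w in rows])
    encoder = TinyEncoder(vocab, TinyEncoderSpec(seed=5))
    return ResCNN(encoder, small_cfg(), seed=0), rows


class TestEncoder:
    def test_eval_determinism(self, toy_rescnn):
        model, _ = toy_rescnn
        assert np.array_equal(model.encode("migra pain"), model.encode("migra pain"))

    def test_output_dim_independent_of_length(self, toy_rescnn):
        model, _ = toy_rescnn
        for text in ["migra", "migra coltra zemina batoke", "x"]:
            assert model.encode(text).shape == (32,)

    def test_max_pool_equals_columnwise_max_of_prepool(self, toy_rescnn):
        model, _ = toy_rescnn
        text = "migra coltra zemina"
        acts = model.prepool_activations(text)
        assert np.allclose(model.encode(text), acts.max(axis=0))

    def test_empty_text_rejected(self, toy_rescnn):
        model, _ = toy_rescnn
        with pytest.raises(ValueError):
            model.encode("  !! ")

    def test_pooling_variants_shapes(self, toy_rescnn):
        _, rows = toy_rescnn
        for pooling in ("mean", "attention"):
            vocab = Vocabulary.from_texts([w for _, w in rows])
            enc = TinyEncoder(vocab, TinyEncoderSpec(seed=5))
            model = ResCNN(enc, small_cfg(pooling=pooling), seed=0)
            assert model.encode("migra coltra").shape == (32,)


class TestNormalize:
    @pytest.mark.parametrize("raw,expected", [
        ("  Colon   Cancer ", "colon cancer"),
        ("(migraine)", "migraine"),
        ("HIV-1,", "hiv-1"),
    ])
    def test_normalization(self, raw, expected):
        assert normalize_text(raw) == expected


class TestIndex:
    def test_entry_counting_and_dedup(self, toy_rescnn):
        model, _ = toy_rescnn
        rows = [("A", "one"), ("A", "two"), ("B", "three"), ("B", "four"),
                ("C", "five"), ("C", "six"), ("A", "one")]
        index = build_synonym_index(rows, model)
        assert len(index) == 6

    def test_vectors_unit_norm(self, toy_rescnn):
        model, rows = toy_rescnn
        index = build_synonym_index(rows, model)
        norms = np.linalg.norm(index.vectors, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-6)

    def test_empty_table_rejected(self, toy_rescnn):
        model, _ = toy_rescnn
        with pytest.raises(ValueError):
            build_synonym_index([], model)

    def test_augmentation_appends_and_never_removes(self, toy_rescnn):
        model, rows = toy_rescnn
        index = build_synonym_index(rows, model)
        doc = Document("1", "Novel surface here .", "x",
                       [Mention(Span(0, 5), "Novel", "Disease", ("D000",))])
        grown = augment_index_with_training(index, Corpus([doc]))
        assert len(grown) == len(index) + 1
        assert grown.entries[: len(index)] == index.entries

    def test_augmentation_with_unlinked_mentions_only(self, toy_rescnn):
        model, rows = toy_rescnn
        index = build_synonym_index(rows, model)
        doc = Document("1", "loose span .", "x",
                       [Mention(Span(0, 5), "loose", "Disease")])
        assert len(augment_index_with_training(index, Corpus([doc]))) == len(index)


class TestRetrieve:
    def test_exact_synonym_scores_one(self, toy_rescnn):
        model, rows = toy_rescnn
        index = build_synonym_index(rows, model)
        ident, score = retrieve_topk("zemina", index, 1)[0]
        assert ident == "D002"
        assert score == pytest.approx(1.0, abs=1e-6)

    def test_k_larger_than_identifiers_returns_all(self, toy_rescnn):
        model, rows = toy_rescnn
        index = build_synonym_index(rows, model)
        assert len(retrieve_topk("migra", index, 50)) == 10

    def test_matches_brute_force_cosine_oracle(self, toy_rescnn):
        model, rows = toy_rescnn
        # 5 synonyms per identifier -> a 50-entry index
        rows5 = [(ident, f"{name} {suffix}") for ident, name in rows
                 for suffix in ("a", "b", "c", "d", "e")]
        index = build_synonym_index(rows5, model)
        for query in ["migra c", "sumod", "pexin coltra", "unseen thing"]:
            got = retrieve_topk(query, index, 4)
            # independent brute force: per-entry cosine, best per identifier
            q = model.encode(query)
            q = q / np.linalg.norm(q)
            best = {}
            for e in index.entries:
                v = model.encode(e.name)
                cos = float(v @ q / np.linalg.norm(v))
                if e.identifier not in best or cos > best[e.identifier]:
                    best[e.identifier] = cos
            want = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))[:4]
            assert [i for i, _ in got] == [i for i, _ in want]
            assert np.allclose([s for _, s in got], [s for _, s in want], atol=1e-9)

    def test_scores_non_increasing(self, toy_rescnn):
        model, rows = toy_rescnn
        index = build_synonym_index(rows, model)
        scores = [s for _, s in retrieve_topk("migra coltra", index, 10)]
        assert all(a >= b for a, b in zip(scores, scores[1:]))


class TestTraining:
    def test_zero_epochs_is_identity(self, toy_rescnn):
        model, rows = toy_rescnn
        index = build_synonym_index(rows, model)
        before = [p.data.copy() for p in model.parameters()]
        fit_rescnn([("migra", "D000")], index, small_cfg(epochs=0), seed=0)
        after = [p.data for p in model.parameters()]
        assert all(np.array_equal(b, a) for b, a in zip(before, after))

    def test_training_improves_heldout_variants(self, world):
        """Trained encoder beats the untrained one on text-only variants."""
        from relmine.evaluation import topk_accuracy
        from relmine.synthetic import make_tiny_encoder

        cfg = small_cfg(feature_size=64, n_filters=32, dropout=0.1, epochs=20)
        rows = [(i, s) for i, s in world.vocab_rows
                if world.entity_types.get(i) == "Disease"]
        rescnn = ResCNN(make_tiny_encoder(world, TinyEncoderSpec(seed=2)), cfg, seed=0)
        index = build_synonym_index(rows, rescnn)
        indexed_names = {e.name for e in index.entries}
        pairs = sorted({(m.surface, m.identifiers[0]) for d in world.train
                        for m in d.mentions
                        if m.etype == "Disease" and len(m.identifiers) == 1})
        held_out = [(s, g) for s, g in
                    {(m.surface, m.identifiers[0]) for d in world.dev
                     for m in d.mentions
                     if m.etype == "Disease" and len(m.identifiers) == 1}
                    if normalize_text(s) not in indexed_names]
        assert held_out, "generator must produce text-only variants"

        def top1():
            cands = [retrieve_topk(s, index, 1) for s, _ in held_out]
            return topk_accuracy(cands, [g for _, g in held_out], ks=(1,))[1]

        untrained = top1()
        losses = fit_rescnn(pairs, index, cfg, seed=0).history
        trained = top1()
        assert trained > untrained
        assert trained >= 0.95
        # loss trend over the first evaluation blocks
        assert np.mean(losses[-5:]) < np.mean(losses[:5])

    def test_missing_identifier_skipped_with_warning(self, toy_rescnn, caplog):
        model, rows = toy_rescnn
        index = build_synonym_index(rows, model)
        with caplog.at_level("WARNING"):
            fit_rescnn([("migra", "D000"), ("odd", "MISSING")], index,
                       small_cfg(epochs=1), seed=0)
        assert any("missing from index" in r.message for r in caplog.records)


class TestHybridLink:
    def external(self):
        doc = Document("7", "x" * 30, "y",
                       [Mention(Span(12, 25), "x" * 13, "Gene", ("672",)),
                        Mention(Span(0, 4), "xxxx", "Species", ("9606",))])
        return Corpus([doc])

    def test_partial_overlap_same_type_links(self):
        ours = [Mention(Span(10, 25), "x" * 15, "Gene")]
        linked = hybrid_link("7", ours, self.external(), {}, {})
        assert linked[0].identifiers == ("672",)
        assert linked[0].span == Span(10, 25)  # span untouched

    def test_exact_span_match_preferred(self):
        ours = [Mention(Span(12, 25), "x" * 13, "Gene")]
        linked = hybrid_link("7", ours, self.external(), {}, {})
        assert linked[0].identifiers == ("672",)

    def test_type_mismatch_prevents_span_link(self):
        ours = [Mention(Span(12, 25), "x" * 13, "Variant")]
        linked = hybrid_link("7", ours, self.external(), {}, {})
        assert linked[0].identifiers == ()

    def test_lookup_dictionary_fallback(self):
        external = self.external()
        lookup = build_lookup(external)
        ours = [Mention(Span(26, 30), "xxxx", "Species")]  # no overlap
        linked = hybrid_link("7", ours, external, {}, lookup)
        assert linked[0].identifiers == ("9606",)

    def test_unresolvable_stays_unlinked(self):
        ours = [Mention(Span(26, 30), "zzzz", "CellLine")]
        linked = hybrid_link("7", ours, self.external(), {}, {})
        assert linked[0].identifiers == ()

    def test_dense_retrieval_for_disease(self, toy_rescnn):
        model, rows = toy_rescnn
        index = build_synonym_index(rows, model)
        ours = [Mention(Span(0, 5), "migra", "Disease")]
        linked = hybrid_link("7", ours, Corpus([]), {"Disease": index}, {})
        assert linked[0].identifiers == ("D000",)
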