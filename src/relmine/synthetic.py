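"""Seeded synthetic corpora, vocabularies and a tiny encoder.

These generators emulate the *structure* of a document-level biomedical
relation-extraction benchmark — titled abstracts with offset-anchored
mentions of six entity types, undirected typed relations between entity
identifiers with binary novelty labels, an identifier/synonym vocabulary
with surface variants, and an external linker's prediction file — at a size
where every stage of the pipeline trains on one CPU in minutes. They make no
attempt at realistic biomedical language: entity surfaces are unique
pronounceable pseudo-words, relations are cued by per-type trigger phrases
placed between two mentions, and novelty is cued by a lexical marker
("as previously reported" => not novel), so each task is learnable by the
bundled tiny encoder while exercising the same code paths as real corpora.

Relation-type frequencies default to the heavily skewed regime of real data
(three dominant types covering ~95% of relations), so class imbalance is
exercised.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .corpus import (ENTITY_TYPES, RELATION_TYPES, Corpus, Document, Mention,
                     Relation, Span)
from .encoder import TinyEncoder, TinyEncoderSpec
from .tokenization import Vocabulary

__all__ = ["SyntheticSpec", "SyntheticWorld", "make_vocabulary", "make_corpus",
           "make_world", "make_tiny_encoder", "make_external_predictions",
           "trigger_oracle_extract", "TRIGGERS", "ALLOWED_TYPE_PAIRS"]

TRIGGERS: dict[str, str] = {
    "Association": "is associated with",
    "Positive_Correlation": "positively upregulates",
    "Negative_Correlation": "markedly suppresses",
    "Bind": "binds directly to",
    "Comparison": "is compared against",
    "Conversion": "is converted into",
    "Cotreatment": "is coadministered with",
    "Drug_Interaction": "interacts adversely with",
}

ALLOWED_TYPE_PAIRS: set[frozenset] = {
    frozenset(p) for p in [
        ("Chemical", "Disease"), ("Chemical", "Gene"), ("Gene", "Disease"),
        ("Gene",), ("Chemical",), ("Variant", "Disease"), ("Gene", "Variant"),
        ("Chemical", "Variant"),
    ]
}

_FILLER = ("the role of this pathway remains unclear in most patients",
           "further clinical studies are required to confirm these results",
           "we analysed expression levels across the treatment groups",
           "samples were collected from the enrolled study participants")

_MENTION_TEMPLATES = ("{m} was detected in several patients .",
                      "elevated levels of {m} were observed in this cohort .",
                      "{m} showed a significant effect in the analysis .",
                      "the function of {m} was examined in detail .")

_TYPE_SUFFIX = {"Disease": ("syndrome", "deficiency", "disorder"),
                "Chemical": ("acid", "amine", "compound"),
                "Gene": (), "Species": (), "Variant": (), "CellLine": ("cells",)}

_ID_PREFIX = {"Gene": "G", "Disease": "D", "Chemical": "C",
              "Species": "S", "Variant": "V", "CellLine": "L"}

# sizes follow the real benchmark's ordering (genes most frequent, cell
# lines rare), scaled down to a toy inventory
_DEFAULT_INVENTORY = {"Gene": 12, "Disease": 10, "Chemical": 8,
                      "Species": 4, "Variant": 5, "CellLine": 3}

_TYPE_WEIGHTS = {"Gene": 0.30, "Disease": 0.25, "Chemical": 0.20,
                 "Species": 0.08, "Variant": 0.12, "CellLine": 0.05}

# skew mirroring the dominance of association/correlation relations
_RELATION_WEIGHTS = {"Association": 0.47, "Positive_Correlation": 0.28,
                     "Negative_Correlation": 0.19, "Bind": 0.02,
                     "Comparison": 0.01, "Conversion": 0.01,
                     "Cotreatment": 0.01, "Drug_Interaction": 0.01}


@dataclass
class SyntheticSpec:
    """Seeded parameters of the toy-corpus generator."""

    seed: int = 7
    n_docs: int = 200
    n_dev_docs: int = 50
    inventory: dict = field(default_factory=lambda: dict(_DEFAULT_INVENTORY))
    synonyms_range: tuple = (2, 5)
    relations_per_doc: tuple = (1, 3)
    entities_per_doc: tuple = (3, 5)
    extra_mentions_range: tuple = (0, 2)  # extra mentions per entity beyond its first
    relation_weights: dict = field(default_factory=lambda: dict(_RELATION_WEIGHTS))
    p_not_novel: float = 0.4
    novelty_cue: str = "as previously reported"
    unlinkable_rate: float = 0.05  # per-document chance of an unlinked mention
    span_jitter: float = 0.0  # chance a mention span is trimmed by one char
    external_drop_rate: float = 0.08  # external linker misses this share


@dataclass
class _Entity:
    identifier: str
    etype: str
    surfaces: list[str]  # all surface variants, first entry is canonical
    index_synonyms: list[str] = field(default_factory=list)  # subset listed in the vocabulary


@dataclass
class SyntheticWorld:
    """A full generated study: corpora, vocabulary and ground truth."""

    spec: SyntheticSpec
    train: Corpus
    dev: Corpus
    vocab_rows: list[tuple[str, str]]  # Disease/Chemical (identifier, synonym)
    variant_map: dict[str, list[str]]  # identifier -> all surface variants
    entity_types: dict[str, str]
    external_train: Corpus
    external_dev: Corpus
    allowed_pairs: set = field(default_factory=lambda: set(ALLOWED_TYPE_PAIRS))


# ----------------------------------------------------------------------
# word & entity generation
# ----------------------------------------------------------------------

_CONS = "bcdfgklmnprstvz"
_VOWS = "aeiou"


def _fresh_word(rng: np.random.Generator, used: set[str], n_syll=(2, 4)) -> str:
    while True:
        k = rng.integers(n_syll[0], n_syll[1] + 1)
        word = "".join(_CONS[rng.integers(len(_CONS))] + _VOWS[rng.integers(len(_VOWS))]
                       for _ in range(k))
        if word not in used:
            used.add(word)
            return word


def _make_entities(spec: SyntheticSpec, rng: np.random.Generator) -> list[_Entity]:
    used: set[str] = set()
    # reserve trigger/filler/template words so entity surfaces never collide
    for text in (list(TRIGGERS.values()) + list(_FILLER)
                 + list(_MENTION_TEMPLATES) + [spec.novelty_cue]):
        used.update(re.findall(r"[a-z]+", text.lower()))
    entities: list[_Entity] = []
    lo, hi = spec.synonyms_range
    for etype in ENTITY_TYPES:
        for i in range(spec.inventory.get(etype, 0)):
            base = _fresh_word(rng, used)
            n_syn = int(rng.integers(lo, hi + 1))
            # vocabulary synonyms share the base word (canonical, cased,
            # suffixed forms); plural and abbreviated forms occur only in
            # running text, so the linker must learn them from training
            # mentions rather than by exact lookup
            easy_pool = [base.capitalize()] + [f"{base} {s}" for s in _TYPE_SUFFIX[etype]]
            synonyms = [base]
            order = rng.permutation(len(easy_pool))
            for j in order:
                if len(synonyms) >= n_syn:
                    break
                synonyms.append(easy_pool[j])
            hard = [base + "s"]
            if len(base) >= 4:
                abbrev = base[:4].upper()
                if abbrev.lower() not in used:
                    used.add(abbrev.lower())
                    hard.append(abbrev)
            entities.append(_Entity(f"{_ID_PREFIX[etype]}{i:03d}", etype,
                                    synonyms + hard, synonyms))
    return entities


def make_vocabulary(spec: SyntheticSpec) -> tuple[list[tuple[str, str]], dict[str, list[str]]]:
    """Disease/Chemical (identifier, synonym) rows plus the full variant map."""
    rng = np.random.default_rng(spec.seed)
    entities = _make_entities(spec, rng)
    rows = [(e.identifier, s) for e in entities
            if e.etype in ("Disease", "Chemical") for s in e.index_synonyms]
    variant_map = {e.identifier: list(e.surfaces) for e in entities}
    return rows, variant_map


# ----------------------------------------------------------------------
# document generation
# ----------------------------------------------------------------------

def _weighted_choice(rng, items, weights):
    w = np.array([weights[i] for i in items], dtype=float)
    return items[rng.choice(len(items), p=w / w.sum())]


def _make_document(doc_id: str, entities: list[_Entity], spec: SyntheticSpec,
                   rng: np.random.Generator, used_words: set[str]) -> Document:
    n_ent = int(rng.integers(spec.entities_per_doc[0], spec.entities_per_doc[1] + 1))
    # draw entities until at least one allowed type pair exists
    for _ in range(50):
        weights = np.array([_TYPE_WEIGHTS[e.etype] for e in entities])
        chosen_idx = rng.choice(len(entities), size=n_ent, replace=False,
                                p=weights / weights.sum())
        chosen = [entities[i] for i in chosen_idx]
        pairs = [(a, b) for i, a in enumerate(chosen) for b in chosen[i + 1:]
                 if frozenset((a.etype, b.etype)) in ALLOWED_TYPE_PAIRS]
        if pairs:
            break
    rng.shuffle(pairs)
    n_rel = min(int(rng.integers(spec.relations_per_doc[0],
                                 spec.relations_per_doc[1] + 1)), len(pairs))
    rel_pairs = pairs[:n_rel]

    relations: list[Relation] = []
    sentences: list[tuple[str, list[tuple[int, int, _Entity]]]] = []

    def mention_sentence(template: str, ent: _Entity) -> None:
        surface = ent.surfaces[int(rng.integers(len(ent.surfaces)))]
        pre, post = template.split("{m}")
        text = pre + surface + post
        sentences.append((text, [(len(pre), len(pre) + len(surface), ent)]))

    for a, b in rel_pairs:
        rtype = _weighted_choice(rng, RELATION_TYPES, spec.relation_weights)
        novelty = "No" if rng.random() < spec.p_not_novel else "Novel"
        sa = a.surfaces[int(rng.integers(len(a.surfaces)))]
        sb = b.surfaces[int(rng.integers(len(b.surfaces)))]
        trigger = TRIGGERS[rtype]
        if novelty == "No":
            text = f"{sa} {trigger} {sb} {spec.novelty_cue} ."
        else:
            text = f"{sa} {trigger} {sb} ."
        spans = [(0, len(sa), a),
                 (len(sa) + len(trigger) + 2, len(sa) + len(trigger) + 2 + len(sb), b)]
        sentences.append((text, spans))
        relations.append(Relation((a.identifier, b.identifier), rtype, novelty))

    mentioned = {e.identifier for _, spans in sentences for _, _, e in spans}
    for ent in chosen:
        extra = int(rng.integers(spec.extra_mentions_range[0],
                                 spec.extra_mentions_range[1] + 1))
        if ent.identifier not in mentioned:
            extra = max(extra, 1)
        for _ in range(extra):
            mention_sentence(
                _MENTION_TEMPLATES[int(rng.integers(len(_MENTION_TEMPLATES)))], ent)

    for _ in range(int(rng.integers(1, 3))):
        sentences.append((_FILLER[int(rng.integers(len(_FILLER)))] + " .", []))

    if rng.random() < spec.unlinkable_rate:
        stray = _Entity("", ENTITY_TYPES[int(rng.integers(len(ENTITY_TYPES)))],
                        [_fresh_word(rng, used_words)])
        mention_sentence(
            _MENTION_TEMPLATES[int(rng.integers(len(_MENTION_TEMPLATES)))], stray)

    order = rng.permutation(len(sentences))
    sentences = [sentences[i] for i in order]

    title_ent = chosen[0]
    t_surface = title_ent.surfaces[int(rng.integers(len(title_ent.surfaces)))]
    title = f"Study of {t_surface} in clinical cases ."
    title_spans = [(9, 9 + len(t_surface), title_ent)]

    mentions: list[Mention] = []
    full = title
    for start, end, ent in title_spans:
        mentions.append(_mention(ent, title, start, end, spec, rng, offset=0))
    abstract_parts: list[str] = []
    offset = len(title) + 1
    for text, spans in sentences:
        for start, end, ent in spans:
            mentions.append(_mention(ent, text, start, end, spec, rng, offset))
        abstract_parts.append(text)
        offset += len(text) + 1
    abstract = " ".join(abstract_parts)
    doc = Document(doc_id, title, abstract,
                   sorted(mentions, key=lambda m: m.span.start), relations)
    return doc


def _mention(ent: _Entity, sentence: str, start: int, end: int,
             spec: SyntheticSpec, rng: np.random.Generator, offset: int) -> Mention:
    surface = sentence[start:end]
    if spec.span_jitter > 0 and rng.random() < spec.span_jitter and end - start > 2:
        start += 1  # trimmed boundary, surface kept in sync
        surface = sentence[start:end]
    ids = (ent.identifier,) if ent.identifier else ()
    return Mention(Span(offset + start, offset + end), surface, ent.etype, ids)


def make_corpus(spec: SyntheticSpec, n_docs: int | None = None,
                doc_prefix: str = "10", rng: np.random.Generator | None = None,
                entities: list[_Entity] | None = None) -> Corpus:
    """Generate a corpus of ``n_docs`` documents (defaults to spec.n_docs)."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if entities is None:
        entities = _make_entities(spec, np.random.default_rng(spec.seed))
    used_words: set[str] = {s for e in entities for v in e.surfaces
                            for s in v.lower().split()}
    n = n_docs if n_docs is not None else spec.n_docs
    docs = [_make_document(f"{doc_prefix}{i:05d}", entities, spec, rng, used_words)
            for i in range(n)]
    return Corpus(docs)


def make_external_predictions(corpus: Corpus, spec: SyntheticSpec,
                              rng: np.random.Generator) -> Corpus:
    """Emulate an external linker's PubTator output: gold links with misses."""
    out = corpus.copy()
    for doc in out:
        doc.relations = []
        doc.mentions = [m for m in doc.mentions
                        if m.identifiers and rng.random() >= spec.external_drop_rate]
    return out


def make_world(spec: SyntheticSpec | None = None) -> SyntheticWorld:
    """Generate the complete deterministic study: train/dev + vocab + external."""
    spec = spec or SyntheticSpec()
    entities = _make_entities(spec, np.random.default_rng(spec.seed))
    rng = np.random.default_rng([spec.seed, 1])
    train = make_corpus(spec, spec.n_docs, doc_prefix="20", rng=rng, entities=entities)
    dev = make_corpus(spec, spec.n_dev_docs, doc_prefix="30", rng=rng, entities=entities)
    vocab_rows, variant_map = make_vocabulary(spec)
    ext_rng = np.random.default_rng([spec.seed, 2])
    return SyntheticWorld(
        spec=spec, train=train, dev=dev, vocab_rows=vocab_rows,
        variant_map=variant_map,
        entity_types={e.identifier: e.etype for e in entities},
        external_train=make_external_predictions(train, spec, ext_rng),
        external_dev=make_external_predictions(dev, spec, ext_rng),
    )


def make_tiny_encoder(world: SyntheticWorld,
                      enc_spec: TinyEncoderSpec | None = None) -> TinyEncoder:
    """A tiny encoder whose word vocabulary covers the generated world."""
    texts = [d.text for d in world.train] + [d.text for d in world.dev]
    texts += [syn for _, syn in world.vocab_rows]
    texts += [s for variants in world.variant_map.values() for s in variants]
    return TinyEncoder(Vocabulary.from_texts(texts), enc_spec)


# ----------------------------------------------------------------------
# oracle extractor (upper-bound sanity for generated corpora)
# ----------------------------------------------------------------------

def trigger_oracle_extract(doc: Document) -> list[Relation]:
    """Rule-based reference extractor reading the planted trigger phrases.

    On a zero-noise generated document this recovers the gold relations
    exactly; it is used as an upper-bound sanity check of the generator.
    """
    text = doc.text
    relations = []
    for rtype, trigger in TRIGGERS.items():
        for m in re.finditer(re.escape(trigger), text):
            left = [mn for mn in doc.mentions
                    if mn.identifiers and mn.span.end <= m.start()]
            right = [mn for mn in doc.mentions
                     if mn.identifiers and mn.span.start >= m.end()]
            if not left or not right:
                continue
            e1 = max(left, key=lambda mn: mn.span.end)
            e2 = min(right, key=lambda mn: mn.span.start)
            if e1.identifiers[0] != e2.identifiers[0]:
                relations.append(
                    Relation((e1.identifiers[0], e2.identifiers[0]), rtype))
    # dedupe on (pair, type)
    seen, out = set(), []
    for r in relations:
        key = (r.pair, r.rtype)
        if key not in seen:
            seen.add(key)
            out.append(r)
    return out
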