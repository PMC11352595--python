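"""Document-level evaluation: tuple-matching micro P/R/F1 for all four tasks,
top-k retrieval accuracy, corpus statistics, bootstrap resampling and
McNemar significance testing, and a relation error breakdown.

Conventions: metrics are computed in full precision and reported on the
percent scale at two decimals (half-up). Mention matching is exact
(boundaries and type); span-overlapping same-type non-exact pairs are
reported separately as partial matches but count as errors. Entity-linking
evaluation matches (doc, entity type, identifier) tuples as document-level
sets, with composite mentions expanding to multiple tuples. Relation
matching is undirected (identifier pairs canonicalized by sorting).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .corpus import ENTITY_TYPES, RELATION_TYPES, Corpus, Mention

__all__ = [
    "MatchCounts", "PRF", "BootstrapResult", "round2",
    "prf_from_counts", "f1_from_pr", "match_ner", "match_ner_corpus",
    "match_el", "match_relations", "topk_accuracy", "corpus_stats",
    "bootstrap_f1_diff", "mcnemar_test", "re_error_breakdown",
]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (table-reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class PRF:
    """Micro precision/recall/F1 on the percent scale (full precision)."""

    precision: float
    recall: float
    f1: float

    def rounded(self) -> tuple[float, float, float]:
        return (round2(self.precision), round2(self.recall), round2(self.f1))


def prf_from_counts(c: MatchCounts) -> PRF:
    p = 100.0 * c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    r = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return PRF(p, r, f1)


def f1_from_pr(p: float, r: float) -> float:
    """Harmonic mean of table-scale precision and recall, reported at 2 dp."""
    if p + r == 0:
        return 0.0
    return round2(2 * p * r / (p + r))


# ----------------------------------------------------------------------
# NER matching
# ----------------------------------------------------------------------

@dataclass
class NERMatchResult:
    counts: MatchCounts
    per_type: dict[str, MatchCounts]
    exact: int = 0
    partial: int = 0
    missed: int = 0


def match_ner(gold: list[Mention], pred: list[Mention]) -> NERMatchResult:
    """Exact span+type matching with a partial/miss error categorization."""
    gold_keys = {(m.span.start, m.span.end, m.etype) for m in gold}
    pred_keys = {(m.span.start, m.span.end, m.etype) for m in pred}
    per_type = {t: MatchCounts() for t in ENTITY_TYPES}
    for key in gold_keys & pred_keys:
        per_type[key[2]].tp += 1
    for key in pred_keys - gold_keys:
        per_type[key[2]].fp += 1
    for key in gold_keys - pred_keys:
        per_type[key[2]].fn += 1

    # categorize unmatched gold mentions: partial (overlapping same-type
    # prediction) vs complete miss
    unmatched_pred = [m for m in pred if (m.span.start, m.span.end, m.etype) not in gold_keys]
    partial = missed = 0
    used: set[int] = set()
    for g in gold:
        gkey = (g.span.start, g.span.end, g.etype)
        if gkey in pred_keys:
            continue
        hit = None
        for i, p in enumerate(unmatched_pred):
            if i in used or p.etype != g.etype:
                continue
            if p.span.overlaps(g.span):
                hit = i
                break
        if hit is not None:
            used.add(hit)
            partial += 1
        else:
            missed += 1
    counts = MatchCounts(sum(c.tp for c in per_type.values()),
                         sum(c.fp for c in per_type.values()),
                         sum(c.fn for c in per_type.values()))
    return NERMatchResult(counts, per_type, exact=counts.tp, partial=partial, missed=missed)


def match_ner_corpus(gold: Corpus, pred: Corpus) -> NERMatchResult:
    per_type = {t: MatchCounts() for t in ENTITY_TYPES}
    exact = partial = missed = 0
    for gdoc in gold:
        pdoc_mentions = pred.by_id(gdoc.doc_id).mentions if _has(pred, gdoc.doc_id) else []
        res = match_ner(gdoc.mentions, pdoc_mentions)
        for t in ENTITY_TYPES:
            per_type[t] += res.per_type[t]
        exact += res.exact
        partial += res.partial
        missed += res.missed
    counts = MatchCounts(sum(c.tp for c in per_type.values()),
                         sum(c.fp for c in per_type.values()),
                         sum(c.fn for c in per_type.values()))
    return NERMatchResult(counts, per_type, exact, partial, missed)


def _has(corpus: Corpus, doc_id: str) -> bool:
    return any(d.doc_id == doc_id for d in corpus)


# ----------------------------------------------------------------------
# EL matching: (doc, entity type, identifier) tuples
# ----------------------------------------------------------------------

def _el_tuples(corpus: Corpus) -> set[tuple[str, str, str]]:
    tuples: set[tuple[str, str, str]] = set()
    for doc in corpus:
        for m in doc.mentions:
            for ident in m.identifiers:  # composite mentions expand
                tuples.add((doc.doc_id, m.etype, ident))
    return tuples


def match_el(gold: Corpus, pred: Corpus) -> dict[str, MatchCounts]:
    """Per-type counts plus an 'All' total; duplicates collapse per document."""
    gold_t = _el_tuples(gold)
    pred_t = _el_tuples(pred)
    out = {t: MatchCounts() for t in ENTITY_TYPES}
    for tup in gold_t & pred_t:
        out[tup[1]].tp += 1
    for tup in pred_t - gold_t:
        out[tup[1]].fp += 1
    for tup in gold_t - pred_t:
        out[tup[1]].fn += 1
    out["All"] = MatchCounts(sum(c.tp for t, c in out.items() if t != "All"),
                             sum(c.fp for t, c in out.items() if t != "All"),
                             sum(c.fn for t, c in out.items() if t != "All"))
    return out


# ----------------------------------------------------------------------
# relation matching
# ----------------------------------------------------------------------

def _rel_keys(corpus: Corpus, require_type: bool, require_novelty: bool) -> set:
    keys = set()
    for doc in corpus:
        for r in doc.relations:
            key = [doc.doc_id, tuple(sorted(r.pair))]
            if require_type:
                key.append(r.rtype)
            if require_novelty:
                key.append(r.novelty)
            keys.add(tuple(key))
    return keys


def match_relations(gold: Corpus, pred: Corpus, require_type: bool = True,
                    require_novelty: bool = False) -> MatchCounts:
    gold_k = _rel_keys(gold, require_type, require_novelty)
    pred_k = _rel_keys(pred, require_type, require_novelty)
    return MatchCounts(len(gold_k & pred_k), len(pred_k - gold_k), len(gold_k - pred_k))


# ----------------------------------------------------------------------
# retrieval accuracy
# ----------------------------------------------------------------------

def topk_accuracy(candidate_lists: list[list[tuple[str, float]]],
                  gold_identifiers: list[str],
                  ks: tuple = (1, 5, 10, 20)) -> dict[int, float]:
    """Fraction of mentions whose gold identifier appears in the top k."""
    if len(candidate_lists) != len(gold_identifiers):
        raise ValueError("one candidate list per gold mention required")
    n = len(gold_identifiers)
    out = {}
    for k in ks:
        hits = sum(1 for cands, gold in zip(candidate_lists, gold_identifiers)
                   if gold in [ident for ident, _ in cands[:k]])
        out[k] = hits / n if n else 0.0
    return out


# ----------------------------------------------------------------------
# corpus statistics
# ----------------------------------------------------------------------

def corpus_stats(corpus: Corpus) -> dict:
    """Mention/relation tallies, unique-entity counts and percent shares."""
    mention_counts = {t: 0 for t in ENTITY_TYPES}
    unique_ids = {t: set() for t in ENTITY_TYPES}
    relation_counts = {t: 0 for t in RELATION_TYPES}
    for doc in corpus:
        for m in doc.mentions:
            mention_counts[m.etype] += 1
            for ident in m.identifiers:
                unique_ids[m.etype].add(ident)
        for r in doc.relations:
            relation_counts[r.rtype] += 1
    n_rel = sum(relation_counts.values())
    n_unique = sum(len(s) for s in unique_ids.values())
    return {
        "n_documents": len(corpus),
        "mentions": dict(mention_counts),
        "total_mentions": sum(mention_counts.values()),
        "relations": dict(relation_counts),
        "total_relations": n_rel,
        "unique_entities": {t: len(s) for t, s in unique_ids.items()},
        "total_unique_entities": n_unique,
        "unique_entity_share": {
            t: round2(100.0 * len(s) / n_unique) if n_unique else 0.0
            for t, s in unique_ids.items()},
        "relation_share": {
            t: round2(100.0 * c / n_rel) if n_rel else 0.0
            for t, c in relation_counts.items()},
    }


def dominant_relation_share(counts: dict[str, int], top: int = 3) -> float:
    """Percent of relations in the ``top`` most frequent types, at 2 dp."""
    total = sum(counts.values())
    dominant = sum(sorted(counts.values(), reverse=True)[:top])
    return round2(100.0 * dominant / total) if total else 0.0


# ----------------------------------------------------------------------
# significance tests
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class BootstrapResult:
    mean_diff: float
    ci_low: float
    ci_high: float
    n_samples: int
    sample_size: int
    seed: int


def bootstrap_f1_diff(gold: Corpus, pred_a: Corpus, pred_b: Corpus,
                      n_samples: int = 1000, sample_size: int = 100,
                      seed: int = 0, match_fn=None) -> BootstrapResult:
    """Percentile bootstrap of the overall-F1 difference (system A - B).

    Each replicate draws ``sample_size`` document ids with replacement and
    scores both systems on the pooled counts of the sampled documents
    (duplicates counted as often as drawn). Default metric: exact-match NER F1.
    """
    if match_fn is None:
        def match_fn(gdoc, pdoc_mentions):
            return match_ner(gdoc.mentions, pdoc_mentions).counts

    doc_ids = [d.doc_id for d in gold]
    per_doc = {}
    for doc_id in doc_ids:
        gdoc = gold.by_id(doc_id)
        ca = match_fn(gdoc, pred_a.by_id(doc_id).mentions if _has(pred_a, doc_id) else [])
        cb = match_fn(gdoc, pred_b.by_id(doc_id).mentions if _has(pred_b, doc_id) else [])
        per_doc[doc_id] = (ca, cb)

    rng = np.random.default_rng(seed)
    diffs = np.empty(n_samples)
    for s in range(n_samples):
        drawn = rng.choice(len(doc_ids), size=sample_size, replace=True)
        tot_a, tot_b = MatchCounts(), MatchCounts()
        for i in drawn:
            ca, cb = per_doc[doc_ids[i]]
            tot_a += ca
            tot_b += cb
        diffs[s] = prf_from_counts(tot_a).f1 - prf_from_counts(tot_b).f1
    low, high = np.percentile(diffs, [2.5, 97.5])
    return BootstrapResult(float(diffs.mean()), float(low), float(high),
                           n_samples, sample_size, seed)


def mcnemar_test(n01: int, n10: int, exact: bool = True) -> float:
    """McNemar's test on discordant counts; exact binomial by default."""
    n = n01 + n10
    if n == 0:
        return 1.0
    if exact:
        return float(stats.binomtest(min(n01, n10), n, 0.5, alternative="two-sided").pvalue)
    chi2 = (abs(n01 - n10) - 1) ** 2 / n
    return float(stats.chi2.sf(chi2, df=1))


# ----------------------------------------------------------------------
# RE error breakdown
# ----------------------------------------------------------------------

def re_error_breakdown(gold: Corpus, pred: Corpus) -> dict:
    """Among fp (and fn): fraction that confuse the type of a truly related
    pair vs involve a pair with no gold (or no predicted) relation at all."""
    gold_typed = _rel_keys(gold, require_type=True, require_novelty=False)
    pred_typed = _rel_keys(pred, require_type=True, require_novelty=False)
    gold_pairs = _rel_keys(gold, require_type=False, require_novelty=False)
    pred_pairs = _rel_keys(pred, require_type=False, require_novelty=False)

    def breakdown(err_keys, other_pairs):
        confusion = sum(1 for k in err_keys if (k[0], k[1]) in other_pairs)
        total = len(err_keys)
        if total == 0:
            return {"type_confusion": 0.0, "non_related": 0.0, "n": 0}
        return {"type_confusion": confusion / total,
                "non_related": (total - confusion) / total, "n": total}

    return {
        "fp": breakdown(pred_typed - gold_typed, gold_pairs),
        "fn": breakdown(gold_typed - pred_typed, pred_pairs),
    }
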