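"""Entity linking: dense synonym retrieval with a residual CNN mention encoder.

Disease and Chemical mentions are normalized by encoding the mention string
and every (identifier, synonym) vocabulary entry into a shared space and
retrieving the nearest synonyms by cosine similarity. The mention encoder is
a light residual CNN: a frozen token-embedding lookup (taken from the
pluggable contextual model), a stack of blocks each holding a multi-width
convolution bank, a position-wise feed-forward projection and a residual
connection, and a final pooling layer (max, mean or attention).

The remaining entity types (Gene, Species, Variant, CellLine) are linked by
aligning spans against an external linker's predictions (exact match first,
then partial overlap of the same type), with an exact-surface lookup
dictionary built from those predictions as a last resort — the hybrid scheme
of :func:`hybrid_link`.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor, concat, softmax
from .corpus import Corpus, Mention
from .encoder import EncoderContract

logger = logging.getLogger(__name__)

__all__ = [
    "SynonymEntry", "SynonymIndex", "ResCNNConfig", "ResCNN", "CandidateList",
    "normalize_text", "build_synonym_index", "augment_index_with_training",
    "retrieve_topk", "fit_rescnn", "hybrid_link", "link_corpus", "build_lookup",
    "read_vocab_tsv",
]


def normalize_text(text: str) -> str:
    """Lowercase, collapse whitespace, strip outer punctuation."""
    text = " ".join(text.lower().split())
    return text.strip(string.punctuation + " ")


@dataclass(frozen=True)
class SynonymEntry:
    identifier: str
    name: str
    source: str = "vocab"


@dataclass
class ResCNNConfig:
    """Defaults follow the tuned optima for the disease model; use
    :meth:`chemical` for the chemical-model optimum."""

    pooling: str = "attention"  # max | mean | attention
    learning_rate: float = 1e-3
    n_encoder_blocks: int = 4
    feature_size: int = 256
    dropout: float = 0.25
    n_filters: int = 300
    epochs: int = 100
    eval_every: int = 5
    conv_widths: tuple = (1, 3, 5)
    margin: float = 0.2
    batch_size: int = 16

    @classmethod
    def disease(cls) -> "ResCNNConfig":
        return cls(pooling="attention", n_encoder_blocks=4)

    @classmethod
    def chemical(cls) -> "ResCNNConfig":
        return cls(pooling="max", n_encoder_blocks=3)


class ResCNN:
    """Residual convolutional mention encoder over frozen token embeddings."""

    def __init__(self, base_encoder: EncoderContract, cfg: ResCNNConfig, seed: int = 0):
        self.cfg = cfg
        self.vocab = base_encoder.vocab
        # frozen token embeddings from the contextual model (not trained here)
        self.frozen_emb = np.array(base_encoder.parameters()[0].data, copy=True)
        rng = np.random.default_rng(seed)
        d_in = self.frozen_emb.shape[1]
        F, nf = cfg.feature_size, cfg.n_filters

        def xavier(a, b):
            return Tensor(rng.normal(0.0, np.sqrt(2.0 / (a + b)), size=(a, b)))

        self.proj = xavier(d_in, F)
        self.blocks = []
        bank_out = nf * len(cfg.conv_widths)
        for _ in range(cfg.n_encoder_blocks):
            block = {
                "convs": [xavier(w * F, nf) for w in cfg.conv_widths],
                "conv_bs": [Tensor(np.zeros(nf)) for _ in cfg.conv_widths],
                "ffn_w": xavier(bank_out, F),
                "ffn_b": Tensor(np.zeros(F)),
            }
            self.blocks.append(block)
        self.attn_vec = xavier(F, 1)  # used only with attention pooling
        self._rng = rng
        self.history: list[float] = []

    def parameters(self) -> list[Tensor]:
        params = [self.proj, self.attn_vec]
        for b in self.blocks:
            params.extend(b["convs"])
            params.extend(b["conv_bs"])
            params.extend([b["ffn_w"], b["ffn_b"]])
        return params

    # ------------------------------------------------------------------
    def _conv(self, x: Tensor, weight: Tensor, bias: Tensor, width: int) -> Tensor:
        """Same-length 1-D convolution via shifted matmuls on a padded input."""
        T, F = x.shape
        pad = width // 2
        if pad:
            zeros = Tensor(np.zeros((pad, F)))
            xp = concat([zeros, x, zeros], axis=0)
        else:
            xp = x
        nf = weight.shape[1] // 1
        w3 = weight.reshape(width, F, weight.shape[1])
        out = None
        for j in range(width):
            term = xp[j:j + T] @ w3[j]
            out = term if out is None else out + term
        return out + bias

    def encode_tensor(self, text: str, train: bool = False) -> Tensor:
        """Encode a mention string to a feature_size-dim vector (unnormalized)."""
        norm = normalize_text(text)
        if not norm:
            raise ValueError("mention text empty after normalization")
        tokens = norm.split()
        ids = np.asarray(self.vocab.encode(tokens), dtype=np.intp)
        h = Tensor(self.frozen_emb[ids]) @ self.proj
        cfg = self.cfg
        for block in self.blocks:
            bank = concat(
                [self._conv(h, w, b, width).relu()
                 for w, b, width in zip(block["convs"], block["conv_bs"], cfg.conv_widths)],
                axis=1)
            ff = bank @ block["ffn_w"] + block["ffn_b"]
            if train and cfg.dropout > 0:
                mask = (self._rng.random(ff.shape) >= cfg.dropout) / (1.0 - cfg.dropout)
                ff = ff * Tensor(mask)
            h = h + ff
        if cfg.pooling == "max":
            idx = np.argmax(h.data, axis=0)
            pooled = h[(idx, np.arange(h.shape[1]))]
        elif cfg.pooling == "mean":
            pooled = h.mean(axis=0)
        elif cfg.pooling == "attention":
            weights = softmax((h @ self.attn_vec).T, axis=-1)  # (1, T)
            pooled = (weights @ h).reshape(-1)
        else:
            raise ValueError(f"unknown pooling {cfg.pooling!r}")
        return pooled

    def encode(self, text: str) -> np.ndarray:
        """Deterministic eval-mode embedding as a plain array."""
        return self.encode_tensor(text, train=False).data

    def prepool_activations(self, text: str) -> np.ndarray:
        """Position-wise activations entering the pooling layer (for checks)."""
        norm = normalize_text(text)
        tokens = norm.split()
        ids = np.asarray(self.vocab.encode(tokens), dtype=np.intp)
        h = Tensor(self.frozen_emb[ids]) @ self.proj
        for block in self.blocks:
            bank = concat(
                [self._conv(h, w, b, width).relu()
                 for w, b, width in zip(block["convs"], block["conv_bs"], self.cfg.conv_widths)],
                axis=1)
            h = h + (bank @ block["ffn_w"] + block["ffn_b"])
        return h.data


def rescnn_encode(model: ResCNN, text: str) -> np.ndarray:
    """Functional alias for :meth:`ResCNN.encode`."""
    return model.encode(text)


# ----------------------------------------------------------------------
# synonym index
# ----------------------------------------------------------------------

@dataclass
class SynonymIndex:
    entries: list[SynonymEntry]
    vectors: np.ndarray  # (N, feature_size), rows unit-norm
    encoder: ResCNN

    def __len__(self):
        return len(self.entries)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / np.maximum(n, 1e-12)


def _encode_entries(entries: list[SynonymEntry], encoder: ResCNN) -> np.ndarray:
    if not entries:
        return np.zeros((0, encoder.cfg.feature_size))
    return _unit(np.stack([encoder.encode(e.name) for e in entries]))


def build_synonym_index(rows: list[tuple[str, str]], encoder: ResCNN,
                        source: str = "vocab") -> SynonymIndex:
    """One entry per distinct (identifier, normalized synonym) pair."""
    if not rows:
        raise ValueError("empty vocabulary table")
    seen: set[tuple[str, str]] = set()
    entries: list[SynonymEntry] = []
    for ident, name in rows:
        norm = normalize_text(name)
        if not norm:
            continue
        key = (ident, norm)
        if key in seen:
            continue
        seen.add(key)
        entries.append(SynonymEntry(ident, norm, source))
    return SynonymIndex(entries, _encode_entries(entries, encoder), encoder)


def augment_index_with_training(index: SynonymIndex, corpus: Corpus) -> SynonymIndex:
    """Append (identifier, mention surface) pairs observed in a gold corpus."""
    existing = {(e.identifier, e.name) for e in index.entries}
    new_entries: list[SynonymEntry] = []
    for doc in corpus:
        for m in doc.mentions:
            norm = normalize_text(m.surface)
            if not norm:
                continue
            for ident in m.identifiers:
                key = (ident, norm)
                if key not in existing:
                    existing.add(key)
                    new_entries.append(SynonymEntry(ident, norm, "training"))
    if not new_entries:
        return SynonymIndex(list(index.entries), index.vectors.copy(), index.encoder)
    vectors = np.concatenate(
        [index.vectors, _encode_entries(new_entries, index.encoder)], axis=0)
    return SynonymIndex(list(index.entries) + new_entries, vectors, index.encoder)


def refresh_index(index: SynonymIndex) -> SynonymIndex:
    """Re-encode all entries with the index's (possibly retrained) encoder."""
    return SynonymIndex(list(index.entries),
                        _encode_entries(index.entries, index.encoder), index.encoder)


CandidateList = list  # ranked (identifier, cosine score) pairs, descending


def retrieve_topk(text: str, index: SynonymIndex, k: int) -> CandidateList:
    """Top-k identifiers by cosine; per-identifier best synonym; ties by id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    query = _unit(index.encoder.encode(text))
    scores = index.vectors @ query
    best: dict[str, float] = {}
    for entry, s in zip(index.entries, scores):
        if entry.identifier not in best or s > best[entry.identifier]:
            best[entry.identifier] = float(s)
    ranked = sorted(best.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


# ----------------------------------------------------------------------
# training (online hard-negative triplet loss on cosine similarity)
# ----------------------------------------------------------------------

def fit_rescnn(pairs: list[tuple[str, str]], index: SynonymIndex,
               cfg: ResCNNConfig, seed: int = 0) -> ResCNN:
    """Train the index's encoder on (mention, identifier) pairs.

    Objective: for each mention, pull it toward its identifier's best-scoring
    synonym and push it from the best-scoring other-identifier synonym (the
    hard negative under the current index), with a cosine margin.
    """
    encoder = index.encoder
    if cfg.epochs == 0:
        return encoder
    by_id: dict[str, list[int]] = {}
    for i, e in enumerate(index.entries):
        by_id.setdefault(e.identifier, []).append(i)
    usable = []
    for mention, ident in pairs:
        if ident not in by_id:
            logger.warning("training identifier %s missing from index; pair skipped", ident)
            continue
        if not normalize_text(mention):
            continue
        usable.append((mention, ident))
    if not usable:
        raise ValueError("no usable training pairs")

    opt = Adam(encoder.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(seed)
    order = np.arange(len(usable))
    vectors = index.vectors
    for epoch in range(cfg.epochs):
        if epoch % cfg.eval_every == 0:
            vectors = _encode_entries(index.entries, encoder)  # refresh negatives
        rng.shuffle(order)
        epoch_loss, n = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            batch = [usable[i] for i in order[lo:lo + cfg.batch_size]]
            opt.zero_grad()
            loss = Tensor(0.0)
            for mention, ident in batch:
                anchor_np = _unit(encoder.encode(mention))
                scores = vectors @ anchor_np
                pos_rows = by_id[ident]
                pos_i = pos_rows[int(np.argmax(scores[pos_rows]))]
                neg_mask = np.ones(len(scores), dtype=bool)
                neg_mask[pos_rows] = False
                if not neg_mask.any():
                    continue
                neg_i = int(np.flatnonzero(neg_mask)[np.argmax(scores[neg_mask])])

                a = encoder.encode_tensor(mention, train=True)
                p = encoder.encode_tensor(index.entries[pos_i].name, train=True)
                ng = encoder.encode_tensor(index.entries[neg_i].name, train=True)

                def cos(u, v):
                    return (u * v).sum() * (((u * u).sum() * (v * v).sum()) ** -0.5)

                margin_term = cfg.margin - cos(a, p) + cos(a, ng)
                loss = loss + margin_term.relu()
            loss = loss * (1.0 / len(batch))
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n += 1
        encoder.history.append(epoch_loss / max(n, 1))
        logger.debug("ResCNN epoch %d loss %.4f", epoch, encoder.history[-1])
    # leave index vectors in sync with the trained encoder
    index.vectors = _encode_entries(index.entries, encoder)
    return encoder


# ----------------------------------------------------------------------
# hybrid linking
# ----------------------------------------------------------------------

DENSE_TYPES = ("Disease", "Chemical")


def build_lookup(external: Corpus) -> dict[tuple[str, str], tuple[str, ...]]:
    """Exact-surface lookup dictionary from external-linker predictions."""
    lookup: dict[tuple[str, str], tuple[str, ...]] = {}
    for doc in external:
        for m in doc.mentions:
            if not m.identifiers:
                continue
            key = (normalize_text(m.surface), m.etype)
            lookup.setdefault(key, m.identifiers)
    return lookup


def hybrid_link(doc_id: str, mentions: list[Mention], external: Corpus,
                indexes: dict[str, SynonymIndex],
                lookup: dict[tuple[str, str], tuple[str, ...]],
                score_floor: float | None = None) -> list[Mention]:
    """Link mentions; spans and types are never altered, only identifiers.

    Disease/Chemical go through dense retrieval (top-1, optional score floor);
    other types are span-matched against the external predictions (exact span
    first, then the largest/leftmost same-type partial overlap); anything
    still unlinked falls back to the exact-surface lookup dictionary.
    """
    try:
        ext_mentions = external.by_id(doc_id).mentions
    except KeyError:
        ext_mentions = []
    linked: list[Mention] = []
    for m in mentions:
        identifiers: tuple[str, ...] = ()
        if m.etype in indexes and normalize_text(m.surface):
            top = retrieve_topk(m.surface, indexes[m.etype], k=1)
            if top and (score_floor is None or top[0][1] >= score_floor):
                identifiers = (top[0][0],)
        else:
            exact = [e for e in ext_mentions
                     if e.etype == m.etype and e.identifiers and e.span == m.span]
            if exact:
                identifiers = exact[0].identifiers
            else:
                overlaps = []
                for e in ext_mentions:
                    if e.etype != m.etype or not e.identifiers:
                        continue
                    ov = min(m.span.end, e.span.end) - max(m.span.start, e.span.start)
                    if ov >= 1:
                        overlaps.append((-ov, e.span.start, e))
                if overlaps:
                    overlaps.sort(key=lambda t: (t[0], t[1]))
                    identifiers = overlaps[0][2].identifiers
        if not identifiers:
            identifiers = lookup.get((normalize_text(m.surface), m.etype), ())
        linked.append(Mention(m.span, m.surface, m.etype, identifiers))
    return linked


def link_corpus(corpus: Corpus, external: Corpus, indexes: dict[str, SynonymIndex],
                score_floor: float | None = None) -> Corpus:
    """Apply :func:`hybrid_link` to every document of a corpus."""
    lookup = build_lookup(external)
    out = corpus.copy()
    for doc in out:
        doc.mentions = hybrid_link(doc.doc_id, doc.mentions, external,
                                   indexes, lookup, score_floor)
    return out


def read_vocab_tsv(path) -> list[tuple[str, str]]:
    """Read an identifier<TAB>synonym table (MEDIC / CTD chemical exports are
    adapted to this two-column form)."""
    rows: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 2:
                rows.append((parts[0], parts[1]))
    return rows
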