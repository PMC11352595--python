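"""Span-classification NER head.

All token spans up to a maximum width are enumerated and classified into one
of the six entity types or "none". A span is represented by the concatenation
of its start-token vector, end-token vector and a learned width embedding,
fed to a two-layer feed-forward network. Overlaps among accepted spans are
resolved greedily by classifier confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor, concat, cross_entropy
from .corpus import ENTITY_TYPES, Document, Mention, Span
from .encoder import EncoderContract
from .tokenization import PreToken, pre_tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "SpanCandidate", "SpanNERConfig", "SpanNERModel",
    "enumerate_spans", "span_representation", "fit_span_ner", "classify_spans",
]

NONE_LABEL = "none"
SPAN_CLASSES = list(ENTITY_TYPES) + [NONE_LABEL]


@dataclass(frozen=True)
class SpanCandidate:
    """Token-index span; ``token_end`` is inclusive."""

    token_start: int
    token_end: int

    @property
    def width(self) -> int:
        return self.token_end - self.token_start + 1


@dataclass
class SpanNERConfig:
    learning_rate: float = 1e-5
    epochs: int = 39
    batch_size: int = 32
    max_span_len: int = 30
    width_embedding_dim: int = 16
    hidden_dim: int = 64
    # candidate spans explode quadratically; cap negatives at this multiple of
    # the positive count per instance (seeded subsample)
    negative_ratio: int = 4


def enumerate_spans(n_tokens: int, max_span_len: int) -> list[SpanCandidate]:
    """All spans of width <= max_span_len; count = sum_{w<=min(L,n)} (n-w+1)."""
    if n_tokens < 1:
        raise ValueError("n_tokens must be >= 1")
    return [SpanCandidate(s, s + w - 1)
            for w in range(1, min(max_span_len, n_tokens) + 1)
            for s in range(n_tokens - w + 1)]


def span_representation(states: Tensor, span: SpanCandidate, width_emb: Tensor) -> Tensor:
    """[start vector; end vector; width embedding] — fixed width 2*dim + w_dim."""
    start = states[span.token_start].reshape(1, -1)
    end = states[span.token_end].reshape(1, -1)
    w = width_emb[span.width - 1].reshape(1, -1)
    return concat([start, end, w], axis=1)


class SpanNERModel:
    """Two-layer feed-forward classifier over span representations."""

    def __init__(self, encoder: EncoderContract, cfg: SpanNERConfig, seed: int = 0):
        self.encoder = encoder
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        d_in = 2 * encoder.dim + cfg.width_embedding_dim
        h, C = cfg.hidden_dim, len(SPAN_CLASSES)

        def xavier(a, b):
            return Tensor(rng.normal(0.0, np.sqrt(2.0 / (a + b)), size=(a, b)))

        self.width_emb = Tensor(rng.normal(0.0, 0.1, size=(cfg.max_span_len, cfg.width_embedding_dim)))
        self.w1, self.b1 = xavier(d_in, h), Tensor(np.zeros(h))
        self.w2, self.b2 = xavier(h, C), Tensor(np.zeros(C))
        self.history: list[float] = []

    def parameters(self) -> list[Tensor]:
        return [self.width_emb, self.w1, self.b1, self.w2, self.b2] + self.encoder.parameters()

    def span_logits(self, states: Tensor, spans: list[SpanCandidate]) -> Tensor:
        reps = concat([span_representation(states, s, self.width_emb) for s in spans], axis=0)
        return (reps @ self.w1 + self.b1).relu() @ self.w2 + self.b2


def _gold_span_labels(tokens: list[PreToken], mentions: list[Mention]) -> dict[tuple[int, int], str]:
    labels: dict[tuple[int, int], str] = {}
    for m in mentions:
        idx = [i for i, t in enumerate(tokens)
               if t.start < m.span.end and t.end > m.span.start]
        if idx:
            labels[(idx[0], idx[-1])] = m.etype
    return labels


def fit_span_ner(docs: list[Document], encoder: EncoderContract, cfg: SpanNERConfig,
                 seed: int = 0) -> SpanNERModel:
    if not docs:
        raise ValueError("no training documents")
    model = SpanNERModel(encoder, cfg, seed=seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(seed)

    # precompute per-document candidate/label sets
    prepared = []
    for doc in docs:
        tokens = pre_tokenize(doc.text)[: encoder.max_len]
        gold = _gold_span_labels(tokens, doc.mentions)
        spans = enumerate_spans(len(tokens), cfg.max_span_len)
        positives = [s for s in spans if (s.token_start, s.token_end) in gold]
        negatives = [s for s in spans if (s.token_start, s.token_end) not in gold]
        prepared.append((tokens, gold, positives, negatives))

    label_index = {c: i for i, c in enumerate(SPAN_CLASSES)}
    order = np.arange(len(prepared))
    for epoch in range(cfg.epochs):
        rng.shuffle(order)
        epoch_loss, n_seen = 0.0, 0
        for di in order:
            tokens, gold, positives, negatives = prepared[di]
            cap = max(cfg.negative_ratio * max(len(positives), 1), 1)
            if len(negatives) > cap:
                chosen = rng.choice(len(negatives), size=cap, replace=False)
                sampled_neg = [negatives[i] for i in chosen]
            else:
                sampled_neg = negatives
            batch_spans = positives + sampled_neg
            targets = np.array(
                [label_index[gold.get((s.token_start, s.token_end), NONE_LABEL)]
                 for s in batch_spans])
            opt.zero_grad()
            ids = encoder.encode_ids([t.text for t in tokens])
            _, states = encoder.forward(ids)
            logits = model.span_logits(states, batch_spans)
            loss = cross_entropy(logits, targets)
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_seen += 1
        model.history.append(epoch_loss / max(n_seen, 1))
        logger.debug("span NER epoch %d loss %.4f", epoch, model.history[-1])
    return model


def classify_spans(model: SpanNERModel, doc: Document) -> list[Mention]:
    """Score all candidate spans; greedy non-overlapping selection."""
    encoder = model.encoder
    tokens = pre_tokenize(doc.text)[: encoder.max_len]
    if not tokens:
        return []
    spans = enumerate_spans(len(tokens), model.cfg.max_span_len)
    ids = encoder.encode_ids([t.text for t in tokens])
    _, states = encoder.forward(ids)
    logits = model.span_logits(states, spans).data
    # softmax confidence of the argmax class
    shifted = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(shifted) / np.exp(shifted).sum(axis=1, keepdims=True)
    best = np.argmax(logits, axis=1)
    keep = [(probs[i, best[i]], i) for i in range(len(spans))
            if SPAN_CLASSES[best[i]] != NONE_LABEL]
    keep.sort(key=lambda t: (-t[0], t[1]))
    accepted: list[tuple[SpanCandidate, str]] = []
    for _, i in keep:
        cand = spans[i]
        if any(not (cand.token_end < a.token_start or a.token_end < cand.token_start)
               for a, _ in accepted):
            continue
        accepted.append((cand, SPAN_CLASSES[best[i]]))
    mentions = []
    for cand, etype in sorted(accepted, key=lambda t: t[0].token_start):
        start = tokens[cand.token_start].start
        end = tokens[cand.token_end].end
        mentions.append(Mention(Span(start, end), doc.text[start:end], etype))
    return mentions
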