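"""Novelty detection for extracted relations.

A relation already known from prior literature is labeled ``No``; a new
finding of the abstract is ``Novel``. Unlike relation extraction — which
selects the single best mention pair — novelty classification weighs *all*
mentions of each entity by pooling their marker embeddings coordinate-wise
with logsumexp (a smooth version of max pooling). The two pooled entity
vectors are concatenated (entity order canonicalized by sorted identifier so
the representation is well defined) and passed to a binary classifier.

Training uses only instances carrying a gold relation: the input pairs are
assumed related, so no negative (NoRelation) examples exist.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Adam, Tensor, concat, cross_entropy, logsumexp as t_logsumexp
from .corpus import NOVELTY_LABELS, Document, Relation
from .encoder import EncoderContract
from .relations import (CLOSE_MARKER, NO_RELATION, OPEN_MARKER, PairInstance,
                        insert_entity_markers)
from .tokenization import PreToken, pre_tokenize

logger = logging.getLogger(__name__)

__all__ = ["NDConfig", "NDModel", "logsumexp_pool", "nd_representation",
           "fit_nd", "predict_novelty"]


@dataclass
class NDConfig:
    epochs: int = 4
    learning_rate: float = 2e-5
    batch_size: int = 32
    max_len: int = 512


def logsumexp_pool(vectors: np.ndarray) -> np.ndarray:
    """Coordinate-wise log(sum(exp .)) over a non-empty stack of vectors.

    Stabilized by max-shifting, so ``pool(x)`` lies in
    ``[max(x), max(x) + ln n]`` coordinate-wise.
    """
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim == 1:
        vectors = vectors[None, :]
    if vectors.shape[0] == 0:
        raise ValueError("cannot pool an empty list of vectors")
    m = vectors.max(axis=0)
    return m + np.log(np.exp(vectors - m).sum(axis=0))


def nd_representation(M1: np.ndarray, M2: np.ndarray) -> np.ndarray:
    """[logsumexp_pool(M1); logsumexp_pool(M2)] — width 2*dim."""
    return np.concatenate([logsumexp_pool(M1), logsumexp_pool(M2)])


class NDModel:
    """Binary classifier over pooled marker embeddings of both entities."""

    def __init__(self, encoder: EncoderContract, seed: int = 0):
        self.encoder = encoder
        rng = np.random.default_rng(seed)
        d = 2 * encoder.dim
        C = len(NOVELTY_LABELS)
        self.w = Tensor(rng.normal(0.0, np.sqrt(2.0 / (d + C)), size=(d, C)))
        self.b = Tensor(np.zeros(C))
        self.history: list[float] = []

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b] + self.encoder.parameters()

    def instance_logits(self, instance: PairInstance, doc_tokens: list[PreToken],
                        max_len: int = 512) -> Tensor | None:
        marked = insert_entity_markers(doc_tokens, instance)
        tokens = marked.tokens[:max_len]
        open1 = [p for p in marked.open1 if p < len(tokens)]
        open2 = [p for p in marked.open2 if p < len(tokens)]
        if not open1 or not open2:
            raise ValueError(
                f"relation {instance.pair} has no tagged mentions in window")
        ids = self.encoder.encode_ids([t.text for t in tokens])
        _, h = self.encoder.forward(ids)
        # canonical entity order: instance.pair is sorted, entity 1 = lower id
        pooled1 = t_logsumexp(h[open1], axis=0)
        pooled2 = t_logsumexp(h[open2], axis=0)
        rep = concat([pooled1.reshape(1, -1), pooled2.reshape(1, -1)], axis=1)
        return rep @ self.w + self.b


def fit_nd(doc_instances: list[tuple[Document, list[PairInstance]]],
           encoder: EncoderContract, cfg: NDConfig, seed: int = 0) -> NDModel:
    """Train on gold-relation instances only (no NoRelation examples)."""
    encoder.add_special_tokens([OPEN_MARKER, CLOSE_MARKER])
    model = NDModel(encoder, seed=seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(seed)

    flat: list[tuple[list[PreToken], PairInstance]] = []
    for doc, instances in doc_instances:
        tokens = pre_tokenize(doc.text)
        for inst in instances:
            if inst.label == NO_RELATION:
                raise ValueError("novelty training must not see NoRelation instances")
            if inst.novelty is None:
                continue
            flat.append((tokens, inst))
    if not flat:
        raise ValueError("no usable training instances")
    label_index = {lab: i for i, lab in enumerate(NOVELTY_LABELS)}

    order = np.arange(len(flat))
    for epoch in range(cfg.epochs):
        rng.shuffle(order)
        epoch_loss, seen = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            batch = [flat[i] for i in order[lo:lo + cfg.batch_size]]
            opt.zero_grad()
            loss = Tensor(0.0)
            for tokens, inst in batch:
                logits = model.instance_logits(inst, tokens, cfg.max_len)
                loss = loss + cross_entropy(
                    logits, np.array([label_index[inst.novelty]]))
            loss = loss * (1.0 / len(batch))
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            seen += 1
        model.history.append(epoch_loss / max(seen, 1))
        logger.debug("ND epoch %d loss %.4f", epoch, model.history[-1])
    return model


def predict_novelty(model: NDModel, doc: Document,
                    relations: list[Relation], max_len: int = 512) -> list[Relation]:
    """Attach a novelty label to each relation (entities must have mentions)."""
    from .corpus import group_mentions_by_entity

    tokens = pre_tokenize(doc.text)
    groups = group_mentions_by_entity(doc)
    out: list[Relation] = []
    for rel in relations:
        id1, id2 = rel.pair
        if id1 not in groups or id2 not in groups:
            raise ValueError(f"relation {rel.pair} has no tagged mentions")
        inst = PairInstance(doc.doc_id, rel.pair, ("", ""), label=rel.rtype,
                            mentions1=groups[id1], mentions2=groups[id2])
        logits = model.instance_logits(inst, tokens, max_len)
        label = NOVELTY_LABELS[int(np.argmax(logits.data))]
        out.append(Relation(rel.pair, rel.rtype, label))
    return out
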