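"""Document-level, bidirectional, marker-based relation extraction.

For each candidate entity pair, every mention of both entities is enclosed in
a single untyped marker pair ``[E] ... [/E]``; the open-marker final-layer
vector represents its mention. Because an entity may be mentioned many times,
the (mention-of-entity-1, mention-of-entity-2) pair with the highest dot
product is selected (max pooling over mention pairs). Relations here are
undirected, so the classifier sees two directional representations —
``[e1; e2; e1*e2]`` and ``[e2; e1; e2*e1]`` — is trained on the sum of both
cross entropies, and predicts from the summed logits, making predictions
invariant under exchanging the two entities.

Training optionally adds projected-gradient-descent adversarial perturbation
of the input token embeddings: three ascent steps within an L2 ball, then one
update on the perturbed loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .autodiff import Adam, Tensor, concat, cross_entropy
from .corpus import RELATION_TYPES, Corpus, Document, Mention, Relation, group_mentions_by_entity
from .encoder import EncoderContract
from .tokenization import PreToken, pre_tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "NO_RELATION", "RE_LABELS", "PairInstance", "MarkedSequence", "REConfig",
    "AdversarialConfig", "REModel", "generate_candidate_pairs",
    "insert_entity_markers", "strip_markers", "select_mention_pair",
    "pair_logits", "re_loss", "predict_relation", "pgd_step", "fit_re",
    "predict_doc_relations", "allowed_type_pairs_from_corpus",
]

NO_RELATION = "NoRelation"
RE_LABELS = list(RELATION_TYPES) + [NO_RELATION]  # NoRelation last (tie rule)
OPEN_MARKER = "[E]"
CLOSE_MARKER = "[/E]"


@dataclass
class PairInstance:
    doc_id: str
    pair: tuple[str, str]  # sorted identifiers
    types: tuple[str, str]
    label: str = NO_RELATION
    novelty: str | None = None
    mentions1: list[Mention] = field(default_factory=list)
    mentions2: list[Mention] = field(default_factory=list)

    def __post_init__(self):
        self.pair = tuple(sorted(self.pair))


@dataclass
class MarkedSequence:
    tokens: list[PreToken]
    open1: list[int]  # open-marker positions for entity 1's mentions
    open2: list[int]


@dataclass
class REConfig:
    epochs: int = 5
    learning_rate: float = 3e-5
    batch_size: int = 32
    max_len: int = 512
    hidden_dim: int | None = None  # None = linear classifier head


@dataclass
class AdversarialConfig:
    n_steps: int = 3
    step_size: float = 0.3
    radius: float = 1.0
    norm: str = "l2"


# ----------------------------------------------------------------------
# candidate generation & marking
# ----------------------------------------------------------------------

def allowed_type_pairs_from_corpus(corpus: Corpus) -> set[frozenset]:
    """Type combinations with at least one gold relation in the corpus."""
    allowed: set[frozenset] = set()
    for doc in corpus:
        types = _entity_types(doc)
        for r in doc.relations:
            if r.pair[0] in types and r.pair[1] in types:
                allowed.add(frozenset((types[r.pair[0]], types[r.pair[1]])))
    return allowed


def _entity_types(doc: Document) -> dict[str, str]:
    types: dict[str, str] = {}
    for m in doc.mentions:
        for ident in m.identifiers:
            types.setdefault(ident, m.etype)
    return types


def generate_candidate_pairs(doc: Document,
                             allowed: set[frozenset]) -> list[PairInstance]:
    """One instance per unordered identifier pair with an allowed type combo."""
    groups = group_mentions_by_entity(doc)
    types = _entity_types(doc)
    gold = {r.pair: r for r in doc.relations}
    instances: list[PairInstance] = []
    for id1, id2 in combinations(sorted(groups), 2):
        if frozenset((types[id1], types[id2])) not in allowed:
            continue
        rel = gold.get(tuple(sorted((id1, id2))))
        instances.append(PairInstance(
            doc_id=doc.doc_id, pair=(id1, id2), types=(types[id1], types[id2]),
            label=rel.rtype if rel else NO_RELATION,
            novelty=rel.novelty if rel else None,
            mentions1=groups[id1], mentions2=groups[id2]))
    return instances


def insert_entity_markers(tokens: list[PreToken], instance: PairInstance) -> MarkedSequence:
    """Wrap every mention of both entities with [E] ... [/E] markers.

    Marker tokens carry the sentinel span (-1, -1); stripping them recovers
    the original token sequence. Overlapping mentions nest.
    """
    def token_range(m: Mention):
        idx = [i for i, t in enumerate(tokens)
               if t.start < m.span.end and t.end > m.span.start]
        return (idx[0], idx[-1]) if idx else None

    events_open: dict[int, list[tuple]] = {}
    events_close: dict[int, list[tuple]] = {}
    for ent_no, mentions in ((1, instance.mentions1), (2, instance.mentions2)):
        for m in mentions:
            rng = token_range(m)
            if rng is None:
                continue
            ts, te = rng
            events_open.setdefault(ts, []).append((ent_no, te))
            events_close.setdefault(te, []).append((ent_no, ts))

    out: list[PreToken] = []
    open1: list[int] = []
    open2: list[int] = []
    for i, tok in enumerate(tokens):
        for ent_no, te in sorted(events_open.get(i, []), key=lambda e: -e[1]):
            (open1 if ent_no == 1 else open2).append(len(out))
            out.append(PreToken(OPEN_MARKER, -1, -1))
        out.append(tok)
        for ent_no, ts in sorted(events_close.get(i, []), key=lambda e: -e[1]):
            out.append(PreToken(CLOSE_MARKER, -1, -1))
    return MarkedSequence(out, open1, open2)


def strip_markers(tokens: list[PreToken]) -> list[PreToken]:
    return [t for t in tokens if (t.start, t.end) != (-1, -1)]


# ----------------------------------------------------------------------
# pair representation & scoring
# ----------------------------------------------------------------------

def select_mention_pair(M1: np.ndarray, M2: np.ndarray) -> tuple[int, int]:
    """Indices (i, j) maximizing dot(M1[i], M2[j]) over the cross product."""
    if len(M1) == 0 or len(M2) == 0:
        raise ValueError("both mention sets must be non-empty")
    dots = M1 @ M2.T
    flat = int(np.argmax(dots))
    return flat // dots.shape[1], flat % dots.shape[1]


def directional_representations(e1: Tensor, e2: Tensor) -> tuple[Tensor, Tensor]:
    """v_fwd = [e1; e2; e1*e2], v_rev = [e2; e1; e2*e1] (shared product block)."""
    prod = e1 * e2
    v_fwd = concat([e1.reshape(1, -1), e2.reshape(1, -1), prod.reshape(1, -1)], axis=1)
    v_rev = concat([e2.reshape(1, -1), e1.reshape(1, -1), prod.reshape(1, -1)], axis=1)
    return v_fwd, v_rev


def pair_logits(v_fwd: Tensor, v_rev: Tensor, w: Tensor, b: Tensor) -> tuple[Tensor, Tensor]:
    return (v_fwd @ w + b), (v_rev @ w + b)


def re_loss(logits_fwd: Tensor, logits_rev: Tensor, gold_index: int) -> Tensor:
    """Sum of the two directional cross entropies."""
    target = np.array([gold_index])
    return cross_entropy(logits_fwd, target) + cross_entropy(logits_rev, target)


def predict_relation(logits_fwd: np.ndarray, logits_rev: np.ndarray) -> str:
    """Argmax of summed logits; ties go to the lowest label index."""
    summed = np.asarray(logits_fwd).reshape(-1) + np.asarray(logits_rev).reshape(-1)
    return RE_LABELS[int(np.argmax(summed))]


def pgd_step(grad: np.ndarray, cfg: AdversarialConfig,
             delta: np.ndarray) -> np.ndarray:
    """One ascent step along the loss gradient, then L2-ball projection."""
    gnorm = np.linalg.norm(grad)
    if gnorm > 0:
        delta = delta + cfg.step_size * grad / gnorm
    dnorm = np.linalg.norm(delta)
    if dnorm > cfg.radius:
        delta = delta * (cfg.radius / dnorm)
    return delta


# ----------------------------------------------------------------------
# model
# ----------------------------------------------------------------------

class REModel:
    """Encoder + linear classifier over directional pair representations."""

    def __init__(self, encoder: EncoderContract, seed: int = 0,
                 allowed: set[frozenset] | None = None,
                 hidden_dim: int | None = None):
        self.encoder = encoder
        self.allowed = allowed or set()
        rng = np.random.default_rng(seed)
        d = 3 * encoder.dim
        C = len(RE_LABELS)
        if hidden_dim:
            self.wh = Tensor(rng.normal(0.0, np.sqrt(2.0 / (d + hidden_dim)),
                                        size=(d, hidden_dim)))
            self.bh = Tensor(np.zeros(hidden_dim))
            d = hidden_dim
        else:
            self.wh = self.bh = None
        self.w = Tensor(rng.normal(0.0, np.sqrt(2.0 / (d + C)), size=(d, C)))
        self.b = Tensor(np.zeros(C))
        self.history: list[float] = []

    def classify(self, v: Tensor) -> Tensor:
        if self.wh is not None:
            v = (v @ self.wh + self.bh).relu()
        return v @ self.w + self.b

    def parameters(self) -> list[Tensor]:
        head = [self.w, self.b]
        if self.wh is not None:
            head += [self.wh, self.bh]
        return head + self.encoder.parameters()

    def _marked_ids(self, instance: PairInstance, doc_tokens: list[PreToken],
                    max_len: int) -> tuple[np.ndarray, list[int], list[int]]:
        marked = insert_entity_markers(doc_tokens, instance)
        tokens = marked.tokens
        if len(tokens) > max_len:
            logger.warning("marked sequence of %d tokens truncated to %d",
                           len(tokens), max_len)
            tokens = tokens[:max_len]
        open1 = [p for p in marked.open1 if p < len(tokens)]
        open2 = [p for p in marked.open2 if p < len(tokens)]
        ids = self.encoder.encode_ids([t.text for t in tokens])
        return ids, open1, open2

    def instance_logits(self, instance: PairInstance, doc_tokens: list[PreToken],
                        delta: np.ndarray | None = None,
                        max_len: int = 512):
        """Return (loss-ready fwd/rev logit tensors, embedding node X)."""
        ids, open1, open2 = self._marked_ids(instance, doc_tokens, max_len)
        if not open1 or not open2:
            return None
        X = self.encoder.embed(ids)
        Xp = X + Tensor(delta) if delta is not None else X
        h = self.encoder.forward_from(Xp)
        M1 = h.data[open1]
        M2 = h.data[open2]
        i, j = select_mention_pair(M1, M2)
        e1 = h[open1[i]]
        e2 = h[open2[j]]
        v_fwd, v_rev = directional_representations(e1, e2)
        lf, lr = self.classify(v_fwd), self.classify(v_rev)
        return lf, lr, Xp


def fit_re(doc_instances: list[tuple[Document, list[PairInstance]]],
           encoder: EncoderContract, cfg: REConfig,
           adv: AdversarialConfig | None = None, seed: int = 0,
           allowed: set[frozenset] | None = None) -> REModel:
    """Train end-to-end on candidate pairs; PGD adversarial loss if configured."""
    encoder.add_special_tokens([OPEN_MARKER, CLOSE_MARKER])
    model = REModel(encoder, seed=seed, allowed=allowed, hidden_dim=cfg.hidden_dim)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(seed)

    flat: list[tuple[list[PreToken], PairInstance]] = []
    for doc, instances in doc_instances:
        tokens = pre_tokenize(doc.text)
        for inst in instances:
            flat.append((tokens, inst))
    if not flat:
        raise ValueError("no training instances")
    label_index = {lab: i for i, lab in enumerate(RE_LABELS)}

    order = np.arange(len(flat))
    for epoch in range(cfg.epochs):
        rng.shuffle(order)
        epoch_loss, seen = 0.0, 0
        for lo in range(0, len(order), cfg.batch_size):
            batch = [flat[i] for i in order[lo:lo + cfg.batch_size]]

            def batch_loss(deltas=None):
                total = Tensor(0.0)
                embeds = []
                count = 0
                for bi, (tokens, inst) in enumerate(batch):
                    delta = None if deltas is None else deltas[bi]
                    out = model.instance_logits(inst, tokens, delta, cfg.max_len)
                    if out is None:
                        embeds.append(None)
                        continue
                    lf, lr, X = out
                    total = total + re_loss(lf, lr, label_index[inst.label])
                    embeds.append(X)
                    count += 1
                return total * (1.0 / max(count, 1)), embeds

            # clean update
            opt.zero_grad()
            loss, _ = batch_loss()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            seen += 1

            if adv is not None and adv.n_steps > 0:
                deltas: list[np.ndarray | None] = [None] * len(batch)
                for step in range(adv.n_steps):
                    opt.zero_grad()
                    aloss, embeds = batch_loss(
                        [d if d is not None else 0.0 for d in deltas])
                    aloss.backward()
                    for bi, X in enumerate(embeds):
                        if X is None or X.grad is None:
                            continue
                        prev = deltas[bi] if deltas[bi] is not None else np.zeros_like(X.data)
                        deltas[bi] = pgd_step(X.grad, adv, prev)
                # train on the final perturbed input
                opt.zero_grad()
                aloss, _ = batch_loss([d if d is not None else 0.0 for d in deltas])
                aloss.backward()
                opt.step()
        model.history.append(epoch_loss / max(seen, 1))
        logger.debug("RE epoch %d loss %.4f", epoch, model.history[-1])
    return model


def predict_doc_relations(model: REModel, doc: Document,
                          allowed: set[frozenset] | None = None,
                          max_len: int = 512) -> list[Relation]:
    """Emit one Relation per candidate pair not classified NoRelation."""
    allowed = allowed if allowed is not None else model.allowed
    tokens = pre_tokenize(doc.text)
    relations: list[Relation] = []
    for inst in generate_candidate_pairs(doc, allowed):
        out = model.instance_logits(inst, tokens, max_len=max_len)
        if out is None:
            continue
        lf, lr, _ = out
        label = predict_relation(lf.data, lr.data)
        if label != NO_RELATION:
            relations.append(Relation(inst.pair, label))
    return relations
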