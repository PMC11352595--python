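"""Sequence-labeling NER with task-oriented dataset tags.

Tokens are labeled with the BIO scheme (``B-Type`` / ``I-Type``), but instead
of one generic outside label, each training corpus contributes a *typed*
outside label scoped by a task tag (``O-ALL``, ``O-GENE``,
``O-CHEMICAL-DISEASE`` ...). Each instance is additionally wrapped in special
tokens (``<ALL> ... </ALL>``) announcing which entity types that corpus
annotates, so corpora annotating different subsets of the six entity types
can be merged into a single training set without the unannotated types of one
corpus acting as false negatives for another.

The classifier is a linear softmax head over the contextual encoder's
per-token final-layer vectors, trained with cross entropy. Rule-based
post-processing merges adjacent fragments of predicted mentions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, cross_entropy
from .corpus import ENTITY_TYPES, Corpus, Document, Mention, Span
from .encoder import EncoderContract
from .tokenization import PreToken, pre_tokenize, split_sentences

logger = logging.getLogger(__name__)

__all__ = [
    "TaskTag", "TagLabel", "TokenNERConfig", "NERInstance", "TokenNERModel",
    "encode_bio", "decode_bio", "wrap_task_tokens", "strip_task_tokens",
    "merge_corpora", "fit_token_ner", "predict_mentions", "postprocess_mentions",
]


@dataclass(frozen=True)
class TaskTag:
    """Scope marker telling the model which entity types an instance annotates."""

    name: str
    covered_types: frozenset = frozenset(ENTITY_TYPES)

    def __post_init__(self):
        object.__setattr__(self, "covered_types", frozenset(self.covered_types))
        if (self.name == "ALL") != (self.covered_types == frozenset(ENTITY_TYPES)):
            raise ValueError("tag ALL iff all six entity types are covered")

    @property
    def open_token(self) -> str:
        return f"<{self.name}>"

    @property
    def close_token(self) -> str:
        return f"</{self.name}>"


ALL_TAG = TaskTag("ALL")


@dataclass(frozen=True)
class TagLabel:
    """A BIO label: B/I carry an entity type, O carries a task-tag scope."""

    role: str  # "B" | "I" | "O"
    etype: str | None = None
    o_scope: str | None = None

    def __post_init__(self):
        if self.role in ("B", "I"):
            if self.etype is None or self.o_scope is not None:
                raise ValueError("B/I labels carry etype and no o_scope")
        elif self.role == "O":
            if self.o_scope is None or self.etype is not None:
                raise ValueError("O labels carry o_scope and no etype")
        else:
            raise ValueError(f"bad role {self.role!r}")

    def __str__(self):
        return f"O-{self.o_scope}" if self.role == "O" else f"{self.role}-{self.etype}"

    @classmethod
    def parse(cls, s: str) -> "TagLabel":
        role, _, rest = s.partition("-")
        if role == "O":
            return cls("O", o_scope=rest)
        return cls(role, etype=rest)


@dataclass
class TokenNERConfig:
    learning_rate: float = 3e-5
    batch_size: int = 16
    epochs: int = 22
    max_len: int = 512
    # instance granularity: whole abstracts for the ALL-tag corpus, sentences
    # for single/dual-type auxiliary corpora
    abstract_granularity_tags: tuple = ("ALL",)


@dataclass
class NERInstance:
    doc_id: str
    tokens: list[PreToken]
    labels: list[TagLabel]
    tag: TaskTag
    loss_mask: list[bool] = field(default_factory=list)  # False = excluded from loss


# ----------------------------------------------------------------------
# BIO encoding / decoding
# ----------------------------------------------------------------------

def encode_bio(tokens: list[PreToken], mentions: list[Mention], tag: TaskTag) -> list[TagLabel]:
    """One label per token; mentions of types outside the tag's scope stay O."""
    labels = [TagLabel("O", o_scope=tag.name) for _ in tokens]
    for m in sorted(mentions, key=lambda m: (m.span.start, m.span.end)):
        if m.etype not in tag.covered_types:
            continue
        overlapping = [i for i, t in enumerate(tokens)
                       if t.start < m.span.end and t.end > m.span.start]
        if not overlapping:
            continue
        first = tokens[overlapping[0]]
        if first.start != m.span.start or tokens[overlapping[-1]].end != m.span.end:
            logger.warning("mention %r (%d,%d) not token-aligned; snapping to tokens",
                           m.surface, m.span.start, m.span.end)
        if any(labels[i].role != "O" for i in overlapping):
            logger.warning("overlapping mention %r skipped in BIO encoding", m.surface)
            continue
        labels[overlapping[0]] = TagLabel("B", etype=m.etype)
        for i in overlapping[1:]:
            labels[i] = TagLabel("I", etype=m.etype)
    return labels


def decode_bio(tokens: list[PreToken], labels: list[TagLabel], text: str) -> list[Mention]:
    """Turn a (possibly ill-formed) label sequence into offset mentions.

    Repair rules: an orphan I- run starts a mention; a type change inside a
    run splits it. Never emits overlapping mentions.
    """
    mentions: list[Mention] = []
    run_start: int | None = None
    run_type: str | None = None

    def close(last_idx: int):
        nonlocal run_start, run_type
        if run_start is not None:
            start = tokens[run_start].start
            end = tokens[last_idx].end
            mentions.append(Mention(Span(start, end), text[start:end], run_type))
        run_start = run_type = None

    for i, lab in enumerate(labels):
        if lab.role == "O":
            close(i - 1)
        elif lab.role == "B":
            close(i - 1)
            run_start, run_type = i, lab.etype
        else:  # I
            if run_start is None or lab.etype != run_type:
                close(i - 1)  # orphan I or type break: start a fresh mention
                run_start, run_type = i, lab.etype
    close(len(labels) - 1)
    return mentions


# ----------------------------------------------------------------------
# task-token wrapping
# ----------------------------------------------------------------------

_WRAPPER_SPAN = (-1, -1)  # sentinel char span for synthetic wrapper tokens


def wrap_task_tokens(tokens: list[PreToken], tag: TaskTag,
                     max_len: int = 512) -> list[PreToken]:
    if len(tokens) + 2 > max_len:
        logger.warning("sequence of %d tokens truncated to max_len=%d",
                       len(tokens) + 2, max_len)
        tokens = tokens[: max_len - 2]
    return ([PreToken(tag.open_token, *_WRAPPER_SPAN)] + list(tokens)
            + [PreToken(tag.close_token, *_WRAPPER_SPAN)])


def strip_task_tokens(tokens: list[PreToken]) -> list[PreToken]:
    return [t for t in tokens if (t.start, t.end) != _WRAPPER_SPAN]


# ----------------------------------------------------------------------
# multi-corpus merging
# ----------------------------------------------------------------------

def build_label_space(tags: list[TaskTag]) -> list[str]:
    """Unified label inventory: B-/I- per entity type plus one O per tag name."""
    labels = [f"{role}-{t}" for t in ENTITY_TYPES for role in ("B", "I")]
    labels += [f"O-{name}" for name in sorted({t.name for t in tags})]
    return labels


def document_instances(doc: Document, tag: TaskTag, cfg: TokenNERConfig) -> list[NERInstance]:
    tokens = pre_tokenize(doc.text)
    if tag.name in cfg.abstract_granularity_tags:
        chunks = [tokens]
    else:
        chunks = split_sentences(tokens)
    instances = []
    for chunk in chunks:
        if not chunk:
            continue
        labels = encode_bio(chunk, doc.mentions, tag)
        wrapped = wrap_task_tokens(chunk, tag, cfg.max_len)
        n_body = len(wrapped) - 2
        wlabels = ([TagLabel("O", o_scope=tag.name)] + labels[:n_body]
                   + [TagLabel("O", o_scope=tag.name)])
        mask = [False] + [True] * n_body + [False]  # wrapper tokens excluded from loss
        instances.append(NERInstance(doc.doc_id, wrapped, wlabels, tag, mask))
    return instances


def merge_corpora(datasets: list[tuple[Corpus, TaskTag]],
                  cfg: TokenNERConfig | None = None) -> tuple[list[NERInstance], list[str]]:
    """Flatten (corpus, tag) pairs into training instances + unified labels."""
    cfg = cfg or TokenNERConfig()
    instances: list[NERInstance] = []
    for corpus, tag in datasets:
        for doc in corpus:
            instances.extend(document_instances(doc, tag, cfg))
    label_space = build_label_space([tag for _, tag in datasets])
    return instances, label_space


# ----------------------------------------------------------------------
# model
# ----------------------------------------------------------------------

class TokenNERModel:
    """Linear softmax head over per-token encoder states."""

    def __init__(self, encoder: EncoderContract, label_space: list[str], seed: int = 0):
        self.encoder = encoder
        self.label_space = list(label_space)
        self.label_index = {lab: i for i, lab in enumerate(self.label_space)}
        rng = np.random.default_rng(seed)
        d, C = encoder.dim, len(label_space)
        self.w = Tensor(rng.normal(0.0, np.sqrt(2.0 / (d + C)), size=(d, C)))
        self.b = Tensor(np.zeros(C))
        self.history: list[float] = []

    def parameters(self) -> list[Tensor]:
        return [self.w, self.b] + self.encoder.parameters()

    def logits(self, tokens: list[str]) -> Tensor:
        ids = self.encoder.encode_ids(tokens)
        _, h = self.encoder.forward(ids)
        return h @ self.w + self.b

    def instance_loss(self, inst: NERInstance) -> Tensor:
        logits = self.logits([t.text for t in inst.tokens])
        n = logits.shape[0]  # may be < len(labels) after truncation
        targets = np.array([self.label_index[str(lab)] for lab in inst.labels[:n]])
        mask = np.array(inst.loss_mask[:n], dtype=bool)
        return cross_entropy(logits, targets, mask)


def fit_token_ner(instances: list[NERInstance], encoder: EncoderContract,
                  cfg: TokenNERConfig, seed: int = 0,
                  label_space: list[str] | None = None) -> TokenNERModel:
    if not instances:
        raise ValueError("no training instances")
    tags = {inst.tag for inst in instances}
    encoder.add_special_tokens(sorted(t.open_token for t in tags)
                               + sorted(t.close_token for t in tags))
    if label_space is None:
        label_space = build_label_space(sorted(tags, key=lambda t: t.name))
    model = TokenNERModel(encoder, label_space, seed=seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(seed)
    order = np.arange(len(instances))
    for epoch in range(cfg.epochs):
        rng.shuffle(order)
        epoch_loss = 0.0
        for lo in range(0, len(order), cfg.batch_size):
            batch = [instances[i] for i in order[lo:lo + cfg.batch_size]]
            opt.zero_grad()
            loss = Tensor(0.0)
            for inst in batch:
                loss = loss + model.instance_loss(inst)
            loss = loss * (1.0 / len(batch))
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(batch)
        model.history.append(epoch_loss / len(order))
        logger.debug("NER epoch %d loss %.4f", epoch, model.history[-1])
    return model


def predict_mentions(model: TokenNERModel, doc: Document, tag: TaskTag) -> list[Mention]:
    """Wrap -> classify -> strip -> decode into offset-anchored mentions."""
    tokens = pre_tokenize(doc.text)
    wrapped = wrap_task_tokens(tokens, tag, model.encoder.max_len)
    logits = model.logits([t.text for t in wrapped])
    pred_ids = np.argmax(logits.data, axis=1)
    labels = [TagLabel.parse(model.label_space[i]) for i in pred_ids]
    body = [(tok, lab) for tok, lab in zip(wrapped, labels)
            if (tok.start, tok.end) != _WRAPPER_SPAN]
    body_labels = [lab if lab.role != "O" else TagLabel("O", o_scope=tag.name)
                   for _, lab in body]
    return decode_bio([tok for tok, _ in body], body_labels, doc.text)


# ----------------------------------------------------------------------
# post-processing
# ----------------------------------------------------------------------

def postprocess_mentions(doc: Document, mentions: list[Mention]) -> list[Mention]:
    """Merge fragmented predictions, repeating until a fixpoint.

    Rule 1: two same-type mentions with zero characters between them merge.
    Rule 2: two Disease mentions separated by exactly one character that is
    not "/" merge. Merged mentions reset identifiers (linking is downstream).
    """
    text = doc.text
    current = sorted(mentions, key=lambda m: (m.span.start, m.span.end))
    while True:
        merged: list[Mention] = []
        changed = False
        i = 0
        while i < len(current):
            m = current[i]
            if i + 1 < len(current):
                nxt = current[i + 1]
                gap = text[m.span.end:nxt.span.start]
                rule1 = gap == "" and m.etype == nxt.etype
                rule2 = (len(gap) == 1 and gap != "/" and
                         m.etype == "Disease" and nxt.etype == "Disease")
                if m.span.end <= nxt.span.start and (rule1 or rule2):
                    span = Span(m.span.start, nxt.span.end)
                    merged.append(Mention(span, text[span.start:span.end], m.etype))
                    i += 2
                    changed = True
                    continue
            merged.append(m)
            i += 1
        current = merged
        if not changed:
            return current
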