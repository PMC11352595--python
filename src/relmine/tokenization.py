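"""Whitespace + punctuation pre-tokenization with character-offset tracking.

Every downstream model (sequence labeling, span classification, marker-based
pair classification, mention encoding) consumes pre-tokens that remember their
character span in the source text, so predictions can always be mapped back to
offset-exact annotations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


@dataclass(frozen=True)
class PreToken:
    """A surface token with its half-open character span in the source text."""

    text: str
    start: int
    end: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def pre_tokenize(text: str) -> list[PreToken]:
    """Split ``text`` into word/punctuation tokens, keeping offsets."""
    return [PreToken(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def split_sentences(tokens: list[PreToken]) -> list[list[PreToken]]:
    """Group pre-tokens into sentences, breaking after '.', '!' or '?'."""
    sentences: list[list[PreToken]] = []
    current: list[PreToken] = []
    for tok in tokens:
        current.append(tok)
        if tok.text in {".", "!", "?"}:
            sentences.append(current)
            current = []
    if current:
        sentences.append(current)
    return sentences


class Vocabulary:
    """Token-string to id mapping with special-token support.

    Lookup is case-insensitive for ordinary tokens (they are lowercased on
    both registration and lookup); special tokens (e.g. ``<ALL>``, ``[E]``)
    are matched verbatim.
    """

    PAD = "[PAD]"
    UNK = "[UNK]"

    def __init__(self):
        self._tok2id: dict[str, int] = {}
        self._specials: set[str] = set()
        self.add_special(self.PAD)
        self.add_special(self.UNK)

    def __len__(self) -> int:
        return len(self._tok2id)

    def __contains__(self, token: str) -> bool:
        return token in self._specials or token.lower() in self._tok2id

    def add(self, token: str) -> int:
        key = token.lower()
        if key not in self._tok2id:
            self._tok2id[key] = len(self._tok2id)
        return self._tok2id[key]

    def add_special(self, token: str) -> int:
        if token not in self._tok2id:
            self._tok2id[token] = len(self._tok2id)
            self._specials.add(token)
        return self._tok2id[token]

    def id_of(self, token: str) -> int:
        if token in self._specials:
            return self._tok2id[token]
        return self._tok2id.get(token.lower(), self._tok2id[self.UNK])

    def encode(self, tokens: list[str]) -> list[int]:
        return [self.id_of(t) for t in tokens]

    @classmethod
    def from_texts(cls, texts: list[str]) -> "Vocabulary":
        vocab = cls()
        for text in texts:
            for tok in pre_tokenize(text):
                vocab.add(tok.text)
        return vocab
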