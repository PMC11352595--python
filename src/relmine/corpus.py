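"""Offset-anchored document/annotation model and PubTator-format I/O.

A document is a PubMed title + abstract with character-offset entity mentions
(six biomedical types), document-level undirected typed relations between
entity identifiers, and optional binary novelty labels. The interchange format
is the line-oriented PubTator dialect::

    PMID|t|<title>
    PMID|a|<abstract>
    PMID<TAB>start<TAB>end<TAB>surface<TAB>type<TAB>ids
    PMID<TAB>rtype<TAB>id1<TAB>id2[<TAB>novelty]
    <blank line between documents>

Offsets index into ``title + " " + abstract`` (the NCBI convention: abstract
offsets start at ``len(title) + 1``). Mention lines are written sorted by
start offset; composite mentions join identifiers with ","; unlinked mentions
carry the identifier "-". Entity-type and novelty spellings found in corpus
releases vary, so parsing goes through configurable alias tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ENTITY_TYPES", "RELATION_TYPES", "NOVELTY_LABELS",
    "Span", "Mention", "Relation", "Document", "Corpus", "Violation",
    "PubTatorParseError", "parse_pubtator", "write_pubtator",
    "validate_document", "group_mentions_by_entity",
]

ENTITY_TYPES = ("Gene", "Disease", "Chemical", "Species", "Variant", "CellLine")

RELATION_TYPES = (
    "Association", "Positive_Correlation", "Negative_Correlation", "Bind",
    "Comparison", "Conversion", "Cotreatment", "Drug_Interaction",
)

NOVELTY_LABELS = ("Novel", "No")

# Spellings used across corpus releases, mapped onto the closed internal sets.
DEFAULT_TYPE_ALIASES: dict[str, str] = {
    **{t: t for t in ENTITY_TYPES},
    "GeneOrGeneProduct": "Gene",
    "DiseaseOrPhenotypicFeature": "Disease",
    "ChemicalEntity": "Chemical",
    "OrganismTaxon": "Species",
    "SequenceVariant": "Variant",
    "Cell_Line": "CellLine",
    "CellLine": "CellLine",
}

DEFAULT_NOVELTY_ALIASES: dict[str, str] = {"Novel": "Novel", "No": "No", "None": "No"}


class PubTatorParseError(ValueError):
    """Raised for malformed PubTator input; carries the offending line number."""

    def __init__(self, lineno: int, reason: str):
        super().__init__(f"line {lineno}: {reason}")
        self.lineno = lineno
        self.reason = reason


@dataclass(frozen=True)
class Span:
    """Half-open character span, 0-based."""

    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span ({self.start}, {self.end})")

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Mention:
    """An entity mention anchored in the document text.

    ``identifiers`` is empty for unlinked mentions and has length > 1 for
    composite mentions (one surface string grounded to several concepts).
    """

    span: Span
    surface: str
    etype: str
    identifiers: tuple[str, ...] = ()

    def __post_init__(self):
        if self.etype not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.etype!r}")
        object.__setattr__(self, "identifiers", tuple(self.identifiers))


@dataclass(frozen=True)
class Relation:
    """An undirected, typed relation between two entity identifiers."""

    pair: tuple[str, str]
    rtype: str
    novelty: str | None = None

    def __post_init__(self):
        a, b = self.pair
        if a == b:
            raise ValueError("relation pair members must be distinct")
        object.__setattr__(self, "pair", tuple(sorted((a, b))))
        if self.rtype not in RELATION_TYPES:
            raise ValueError(f"unknown relation type {self.rtype!r}")
        if self.novelty is not None and self.novelty not in NOVELTY_LABELS:
            raise ValueError(f"unknown novelty label {self.novelty!r}")


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str
    mentions: list[Mention] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)

    @property
    def text(self) -> str:
        """Full text: title + one separator space + abstract."""
        return self.title + " " + self.abstract if self.abstract else self.title

    def copy(self) -> "Document":
        return Document(self.doc_id, self.title, self.abstract,
                        list(self.mentions), list(self.relations))


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)

    def __post_init__(self):
        ids = [d.doc_id for d in self.documents]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate doc_ids in corpus")

    def __iter__(self):
        return iter(self.documents)

    def __len__(self):
        return len(self.documents)

    def by_id(self, doc_id: str) -> Document:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)

    def copy(self) -> "Corpus":
        return Corpus([d.copy() for d in self.documents])


@dataclass(frozen=True)
class Violation:
    doc_id: str
    kind: str
    detail: str


# ----------------------------------------------------------------------
# parsing / writing
# ----------------------------------------------------------------------

def parse_pubtator(stream, type_aliases: dict[str, str] | None = None,
                   novelty_aliases: dict[str, str] | None = None) -> Corpus:
    """Parse PubTator-format text (a string or an iterable of lines)."""
    type_aliases = type_aliases or DEFAULT_TYPE_ALIASES
    novelty_aliases = novelty_aliases or DEFAULT_NOVELTY_ALIASES
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]

    documents: list[Document] = []
    current: Document | None = None

    def flush():
        nonlocal current
        if current is not None:
            documents.append(current)
            current = None

    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            flush()
            continue
        if "|" in line and "\t" not in line:
            parts = line.split("|", 2)
            if len(parts) != 3 or parts[1] not in ("t", "a"):
                raise PubTatorParseError(lineno, f"malformed header line: {line!r}")
            doc_id, kind, text = parts
            if kind == "t":
                flush()
                current = Document(doc_id, text, "")
            else:
                if current is None or current.doc_id != doc_id:
                    raise PubTatorParseError(lineno, "abstract line without matching title")
                current.abstract = text
            continue
        cols = line.split("\t")
        if current is None or cols[0] != current.doc_id:
            raise PubTatorParseError(lineno, "annotation line outside its document block")
        if len(cols) == 6 and cols[1].isdigit() and cols[2].isdigit():
            _, start, end, surface, raw_type, ids = cols
            etype = type_aliases.get(raw_type)
            if etype is None:
                raise PubTatorParseError(lineno, f"unknown entity type {raw_type!r}")
            identifiers = () if ids == "-" else tuple(ids.split(","))
            try:
                span = Span(int(start), int(end))
            except ValueError as exc:
                raise PubTatorParseError(lineno, str(exc)) from None
            current.mentions.append(Mention(span, surface, etype, identifiers))
        elif len(cols) in (4, 5):
            _, raw_rtype, id1, id2 = cols[:4]
            novelty = None
            if len(cols) == 5:
                novelty = novelty_aliases.get(cols[4])
                if novelty is None:
                    raise PubTatorParseError(lineno, f"unknown novelty label {cols[4]!r}")
            if raw_rtype not in RELATION_TYPES:
                raise PubTatorParseError(lineno, f"unknown relation type {raw_rtype!r}")
            try:
                current.relations.append(Relation((id1, id2), raw_rtype, novelty))
            except ValueError as exc:
                raise PubTatorParseError(lineno, str(exc)) from None
        else:
            raise PubTatorParseError(lineno, f"unrecognized annotation line: {line!r}")
    flush()
    return Corpus(documents)


def write_pubtator(corpus: Corpus) -> str:
    """Serialize a corpus; inverse of :func:`parse_pubtator` on valid input."""
    blocks: list[str] = []
    for doc in corpus:
        lines = [f"{doc.doc_id}|t|{doc.title}", f"{doc.doc_id}|a|{doc.abstract}"]
        for m in sorted(doc.mentions, key=lambda m: (m.span.start, m.span.end)):
            ids = ",".join(m.identifiers) if m.identifiers else "-"
            lines.append(f"{doc.doc_id}\t{m.span.start}\t{m.span.end}\t{m.surface}\t{m.etype}\t{ids}")
        for r in doc.relations:
            cols = [doc.doc_id, r.rtype, r.pair[0], r.pair[1]]
            if r.novelty is not None:
                cols.append(r.novelty)
            lines.append("\t".join(cols))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


# ----------------------------------------------------------------------
# validation & grouping
# ----------------------------------------------------------------------

def validate_document(doc: Document) -> list[Violation]:
    """Report invariant violations (total function; never raises)."""
    violations: list[Violation] = []
    text = doc.text
    linked_ids: set[str] = set()
    for m in doc.mentions:
        linked_ids.update(m.identifiers)
        if m.span.end > len(text):
            violations.append(Violation(doc.doc_id, "offset overflow",
                                        f"span {m.span} beyond text length {len(text)}"))
            continue
        actual = text[m.span.start:m.span.end]
        if actual != m.surface:
            violations.append(Violation(doc.doc_id, "surface mismatch",
                                        f"span {m.span}: {actual!r} != {m.surface!r}"))
    for r in doc.relations:
        for ident in r.pair:
            if ident not in linked_ids:
                violations.append(Violation(doc.doc_id, "dangling relation id",
                                            f"{ident} not carried by any mention"))
    return violations


def validate_corpus(corpus: Corpus) -> list[Violation]:
    out: list[Violation] = []
    for doc in corpus:
        out.extend(validate_document(doc))
    return out


def group_mentions_by_entity(doc: Document) -> dict[str, list[Mention]]:
    """Map identifier -> mentions carrying it.

    A composite mention (k identifiers) contributes to k groups; unlinked
    mentions are excluded.
    """
    groups: dict[str, list[Mention]] = {}
    for m in doc.mentions:
        for ident in m.identifiers:
            groups.setdefault(ident, []).append(m)
    return groups
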