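"""Documents with character-offset entity annotations.

Reads and writes two equivalent dialects — BioC XML and a mirrored JSON
format — tokenizes passages with a pluggable provider, and converts between
mention spans and BIO tag sequences.

Offsets are 0-based, half-open, counted in Unicode characters; every reader
and writer validates that each span's surface equals ``text[start:end]``.
"""

from __future__ import annotations

import json
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from hashlib import md5
from pathlib import Path

from lxml import etree

logger = logging.getLogger(__name__)

GENERIC_PREFIX = "GENERIC"


class FormatError(ValueError):
    """Input does not parse in the named dialect."""


class ValidationError(ValueError):
    """Parsed annotations violate span/text consistency."""


class ContractViolation(ValueError):
    """A pluggable provider returned ill-formed output."""


@dataclass
class MentionSpan:
    start: int
    end: int
    surface: str
    entity_type: str = "gene"
    gold_id: str | None = None
    predicted_id: str | None = None

    def overlaps(self, other: "MentionSpan") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Token:
    text: str
    start: int
    end: int
    pos: str = "NN"
    chunk: str = "O"


@dataclass
class Document:
    doc_id: str
    text: str
    mentions: list[MentionSpan] = field(default_factory=list)

    def __post_init__(self):
        self.mentions = sorted(self.mentions, key=lambda m: (m.start, m.end))


@dataclass
class TagSequence:
    """BIO labels over one token sequence; ``O`` or ``B-<type>``/``I-<type>``."""

    tags: list[str]

    def __len__(self):
        return len(self.tags)

    def __iter__(self):
        return iter(self.tags)

    def __eq__(self, other):
        if isinstance(other, TagSequence):
            return self.tags == other.tags
        return self.tags == other

    def shorthand(self) -> str:
        """Compact string of first letters, e.g. ``OOBIO``."""
        return "".join(t[0] for t in self.tags)

    def is_valid(self) -> bool:
        prev = "O"
        for t in self.tags:
            if t.startswith("I"):
                if prev == "O" or prev[1:] != t[1:]:
                    return False
            prev = t
        return True


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_document(doc: Document) -> None:
    bad = []
    for m in doc.mentions:
        if not (0 <= m.start < m.end <= len(doc.text)):
            bad.append(f"span ({m.start},{m.end}) outside text of length "
                       f"{len(doc.text)}")
        elif doc.text[m.start:m.end] != m.surface:
            bad.append(f"span ({m.start},{m.end}) surface {m.surface!r} != "
                       f"text slice {doc.text[m.start:m.end]!r}")
    if bad:
        raise ValidationError(
            f"document {doc.doc_id!r}: " + "; ".join(bad))


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

def _doc_to_json(doc: Document) -> dict:
    return {
        "doc_id": doc.doc_id,
        "text": doc.text,
        "annotations": [
            {"start": m.start, "end": m.end, "surface": m.surface,
             "type": m.entity_type,
             **({"gold_id": m.gold_id} if m.gold_id else {}),
             **({"predicted_id": m.predicted_id} if m.predicted_id else {})}
            for m in doc.mentions
        ],
    }


def _doc_from_json(obj: dict) -> Document:
    mentions = [
        MentionSpan(a["start"], a["end"], a["surface"],
                    a.get("type", "gene"), a.get("gold_id"),
                    a.get("predicted_id"))
        for a in obj.get("annotations", [])
    ]
    return Document(obj["doc_id"], obj["text"], mentions)


# ---------------------------------------------------------------------------
# BioC XML dialect
# ---------------------------------------------------------------------------

def _doc_to_bioc(doc: Document, parent: etree._Element) -> None:
    d = etree.SubElement(parent, "document")
    etree.SubElement(d, "id").text = doc.doc_id
    p = etree.SubElement(d, "passage")
    etree.SubElement(p, "offset").text = "0"
    etree.SubElement(p, "text").text = doc.text
    for i, m in enumerate(doc.mentions):
        a = etree.SubElement(p, "annotation", id=str(i))
        etree.SubElement(a, "infon", key="type").text = m.entity_type
        if m.gold_id:
            etree.SubElement(a, "infon", key="gold_id").text = m.gold_id
        if m.predicted_id:
            etree.SubElement(a, "infon", key="predicted_id").text = m.predicted_id
        etree.SubElement(a, "location", offset=str(m.start),
                         length=str(m.end - m.start))
        etree.SubElement(a, "text").text = m.surface


def _doc_from_bioc(d: etree._Element) -> Document:
    doc_id = d.findtext("id") or ""
    passage = d.find("passage")
    if passage is None:
        raise FormatError(f"document {doc_id!r} has no passage")
    base = int(passage.findtext("offset") or 0)
    text = passage.findtext("text") or ""
    mentions = []
    for a in passage.findall("annotation"):
        loc = a.find("location")
        if loc is None:
            raise FormatError(f"annotation without location in {doc_id!r}")
        start = int(loc.get("offset")) - base
        length = int(loc.get("length"))
        infons = {i.get("key"): i.text for i in a.findall("infon")}
        mentions.append(MentionSpan(
            start, start + length, a.findtext("text") or "",
            infons.get("type", "gene"), infons.get("gold_id"),
            infons.get("predicted_id")))
    return Document(doc_id, text, mentions)


# ---------------------------------------------------------------------------
# public reader/writer
# ---------------------------------------------------------------------------

def read_documents(path, format: str | None = None) -> list[Document]:
    """Read documents from a BioC XML or JSON file.

    ``format`` is ``"bioc_xml"`` or ``"json"``; when omitted it is inferred
    from the file suffix.  Malformed spans raise :class:`ValidationError`
    naming the offending annotation; parse failures raise
    :class:`FormatError` naming the position.
    """
    path = Path(path)
    if format is None:
        format = "bioc_xml" if path.suffix.lower() == ".xml" else "json"
    raw = path.read_text(encoding="utf-8")
    if format == "json":
        try:
            payload = json.loads(raw)
        except json.JSONDecodeError as e:
            raise FormatError(f"{path}: JSON parse error at byte {e.pos}: "
                              f"{e.msg}") from e
        docs = [_doc_from_json(o) for o in payload.get("documents", [])]
    elif format == "bioc_xml":
        try:
            root = etree.fromstring(raw.encode("utf-8"))
        except etree.XMLSyntaxError as e:
            raise FormatError(f"{path}: XML parse error at line "
                              f"{e.lineno}, column {e.offset}: {e.msg}") from e
        docs = [_doc_from_bioc(d) for d in root.findall(".//document")]
    else:
        raise ValueError(f"unknown format {format!r}")
    for doc in docs:
        validate_document(doc)
    return docs


def write_documents(docs: list[Document], path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "bioc_xml" if path.suffix.lower() == ".xml" else "json"
    for doc in docs:
        validate_document(doc)
    if format == "json":
        payload = {"documents": [_doc_to_json(d) for d in docs]}
        path.write_text(json.dumps(payload, ensure_ascii=False, indent=1),
                        encoding="utf-8")
    elif format == "bioc_xml":
        root = etree.Element("collection")
        etree.SubElement(root, "source").text = "bioidtn"
        for doc in docs:
            _doc_to_bioc(doc, root)
        path.write_bytes(etree.tostring(root, xml_declaration=True,
                                        encoding="UTF-8", pretty_print=True))
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)

_POS_TAGS = ["NN", "NNS", "JJ", "VB", "VBD", "IN", "DT", "CD", "SYM"]
_CHUNK_TAGS = ["B-NP", "I-NP", "B-VP", "O"]


def _stable_hash(s: str) -> int:
    return int.from_bytes(md5(s.encode("utf-8")).digest()[:4], "big")


class RuleBasedProvider:
    """Default tokenizer: whitespace/punctuation split, punctuation kept.

    POS and chunk tags come from a deterministic stub (a stable hash of the
    lowercased token into a fixed tag inventory) so the pipeline runs without
    an external tagger; real taggers plug in through the same interface.
    """

    def __call__(self, text: str) -> list[Token]:
        tokens = []
        for match in _TOKEN_RE.finditer(text):
            t = match.group()
            h = _stable_hash(t.lower())
            if not t[0].isalnum():
                pos, chunk = "SYM", "O"
            else:
                pos = _POS_TAGS[h % len(_POS_TAGS)]
                chunk = _CHUNK_TAGS[(h // 7) % len(_CHUNK_TAGS)]
            tokens.append(Token(t, match.start(), match.end(), pos, chunk))
        return tokens


DEFAULT_PROVIDER = RuleBasedProvider()


def tokenize(document: Document | str, provider=None) -> list[Token]:
    """Tokenize a document (or raw string) with the given provider.

    The provider contract — tokens ordered, non-overlapping, and offsets
    indexing into the text — is verified; a violation raises
    :class:`ContractViolation`.
    """
    text = document.text if isinstance(document, Document) else document
    provider = provider or DEFAULT_PROVIDER
    tokens = provider(text)
    prev_end = 0
    for t in tokens:
        if t.start < prev_end or t.end > len(text) or t.start >= t.end:
            raise ContractViolation(
                f"provider returned ill-formed token {t!r}")
        if text[t.start:t.end] != t.text:
            raise ContractViolation(
                f"token text {t.text!r} != text[{t.start}:{t.end}]")
        prev_end = t.end
    return tokens


# ---------------------------------------------------------------------------
# spans <-> BIO
# ---------------------------------------------------------------------------

def _snap(mention: MentionSpan, tokens: list[Token]) -> tuple[int, int] | None:
    """Indices of the covering token run, snapping boundaries outward."""
    idx = [i for i, t in enumerate(tokens)
           if t.start < mention.end and mention.start < t.end]
    if not idx:
        return None
    first, last = idx[0], idx[-1]
    if tokens[first].start != mention.start or tokens[last].end != mention.end:
        logger.warning(
            "mention (%d,%d) %r snapped outward to token span (%d,%d)",
            mention.start, mention.end, mention.surface,
            tokens[first].start, tokens[last].end)
    return first, last


def spans_to_bio(tokens: list[Token], mentions: list[MentionSpan]) -> TagSequence:
    """BIO-encode mention spans over a token sequence.

    The first token of each mention is tagged ``B-<type>``, subsequent
    tokens ``I-<type>``; mentions whose boundaries fall inside a token are
    snapped outward to the covering tokens (recall-favouring), with a
    logged warning.
    """
    tags = ["O"] * len(tokens)
    for m in sorted(mentions, key=lambda m: (m.start, m.end)):
        span = _snap(m, tokens)
        if span is None:
            logger.warning("mention (%d,%d) %r covers no token; dropped from "
                           "tagging", m.start, m.end, m.surface)
            continue
        first, last = span
        tags[first] = f"B-{m.entity_type}"
        for i in range(first + 1, last + 1):
            tags[i] = f"I-{m.entity_type}"
    return TagSequence(tags)


def bio_to_spans(tokens: list[Token], tags: TagSequence | list[str],
                 text: str | None = None) -> list[MentionSpan]:
    """Decode a BIO sequence back to mention spans.

    An orphan ``I`` (after ``O`` or a different type) is repaired to ``B``,
    the standard lenient reading.  Surfaces come from ``text`` when given,
    else from the token run joined on single spaces.
    """
    tag_list = list(tags)
    spans: list[MentionSpan] = []
    run_start = None
    run_type = ""

    def flush(last_idx):
        if run_start is None:
            return
        start = tokens[run_start].start
        end = tokens[last_idx].end
        surface = (text[start:end] if text is not None
                   else " ".join(t.text for t in tokens[run_start:last_idx + 1]))
        spans.append(MentionSpan(start, end, surface, run_type))

    for i, tag in enumerate(tag_list):
        if tag == "O":
            flush(i - 1)
            run_start = None
        else:
            kind, _, etype = tag.partition("-")
            if kind == "B" or run_start is None or etype != run_type:
                flush(i - 1)
                run_start, run_type = i, etype
    flush(len(tag_list) - 1)
    return spans


def strip_punctuation(text: str) -> bool:
    """True when every character is Unicode punctuation."""
    return all(unicodedata.category(c).startswith("P") for c in text)
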