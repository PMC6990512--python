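"""Mention-Variant-ID knowledge and the features derived from it.

A knowledge base is a table of (entity ID, variant term, canonical mention)
records, as in UniProt / NCBI Gene: one ID may own several variants
(synonymy) and one mention surface may reach several IDs through different
variants (ambiguity).  This module builds indexed structures over such
records and derives two things from them:

* knowledge features (KFs): BIO tags marking the longest left-to-right
  matches between a token sequence and KB variant terms, and
* candidate ID sets: the top-k IDs retrieved for a mention surface by a
  deterministic local scoring cascade.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_io import TagSequence, Token

logger = logging.getLogger(__name__)

_BRACKETED = re.compile(r"\([^()]*\)")
_TOKEN_RE = re.compile(r"\w+|[^\w\s]", re.UNICODE)


class KBError(ValueError):
    pass


@dataclass(frozen=True)
class KBRecord:
    entity_id: str
    variant: str
    mention: str


@dataclass
class CandidateSet:
    mention_surface: str
    candidates: list[str] = field(default_factory=list)
    scores: list[float] = field(default_factory=list)

    def __len__(self):
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)

    def __contains__(self, entity_id):
        return entity_id in self.candidates


def normalize_tokens(text: str, strip_brackets: bool = True) -> tuple[str, ...]:
    """Lowercased token sequence; bracketed qualifiers optionally removed.

    Stripping ``(human)``-style qualifiers from index keys lets the surface
    "VEGF" recall the variant "VEGF (human)"; exact-match scoring keeps the
    full form so exact hits still rank first.  Idempotent by construction.
    """
    if strip_brackets:
        text = _BRACKETED.sub(" ", text)
    return tuple(m.group().lower() for m in _TOKEN_RE.finditer(text))


@dataclass
class KnowledgeBase:
    records: list[KBRecord]
    variant_index: dict[tuple[str, ...], set[str]] = field(default_factory=dict)
    mention_index: dict[str, set[str]] = field(default_factory=dict)
    _exact_variant: dict[str, set[str]] = field(default_factory=dict)
    _exact_mention: dict[str, set[str]] = field(default_factory=dict)
    _max_key_len: int = 0

    def ids(self) -> set[str]:
        return {r.entity_id for r in self.records}


def build_kb(records: list[KBRecord]) -> KnowledgeBase:
    """Index validated records; duplicate (id, variant) pairs collapse.

    ``variant_index`` maps normalized variant token sequences (both the full
    form and the bracket-stripped form) to the set of entity IDs reachable
    through them.
    """
    if not records:
        raise KBError("a knowledge base must contain at least one record")
    seen: set[tuple[str, str]] = set()
    kept: list[KBRecord] = []
    for r in records:
        if not (r.entity_id and r.variant and r.mention):
            raise KBError(f"record with empty field: {r}")
        key = (r.entity_id, r.variant)
        if key in seen:
            logger.warning("duplicate (id, variant) pair collapsed: %s", key)
            continue
        seen.add(key)
        kept.append(r)

    kb = KnowledgeBase(records=kept)
    for r in kept:
        for strip in (False, True):
            toks = normalize_tokens(r.variant, strip_brackets=strip)
            if toks:
                kb.variant_index.setdefault(toks, set()).add(r.entity_id)
        mention_key = " ".join(normalize_tokens(r.mention))
        kb.mention_index.setdefault(mention_key, set()).add(r.variant)
        kb._exact_variant.setdefault(r.variant, set()).add(r.entity_id)
        kb._exact_mention.setdefault(r.mention, set()).add(r.entity_id)
    kb._max_key_len = max(len(k) for k in kb.variant_index)
    return kb


# ---------------------------------------------------------------------------
# knowledge features
# ---------------------------------------------------------------------------

def knowledge_feature_tags(tokens: list[Token], kb: KnowledgeBase) -> TagSequence:
    """Greedy left-to-right longest match of tokens against KB variants.

    At each position the longest variant-term match wins (maximal munch);
    matched runs are tagged ``B-kf``/``I-kf``, everything else ``O``.
    Matches never overlap.
    """
    texts = [t.text.lower() for t in tokens]
    tags = ["O"] * len(tokens)
    i = 0
    while i < len(tokens):
        matched = 0
        for length in range(min(kb._max_key_len, len(tokens) - i), 0, -1):
            if tuple(texts[i:i + length]) in kb.variant_index:
                matched = length
                break
        if matched:
            tags[i] = "B-kf"
            for j in range(i + 1, i + matched):
                tags[j] = "I-kf"
            i += matched
        else:
            i += 1
    return TagSequence(tags)


# ---------------------------------------------------------------------------
# candidate ID generation
# ---------------------------------------------------------------------------

_TIER_EXACT_VARIANT = 4.0
_TIER_EXACT_MENTION = 3.0
_TIER_NORMALIZED = 2.0


def _jaccard(a: set, b: set) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / len(a | b)


def kb_retrieve(mention_surface: str, kb: KnowledgeBase,
                k: int = 5) -> CandidateSet:
    """Top-k candidate entity IDs for a mention surface.

    Candidate generation is treated as retrieval with the mention as query.
    The local scoring cascade ranks: exact variant match > exact canonical
    mention match > case-insensitive normalized match > token-overlap
    Jaccard; ties break on lexicographic entity ID, so the result is a pure
    function of (query, kb).  An empty result is allowed — downstream
    assigns the generic ID.
    """
    if not mention_surface:
        raise ValueError("mention_surface must be non-empty")
    scores: dict[str, float] = {}

    def bump(entity_id: str, score: float):
        if score > scores.get(entity_id, 0.0):
            scores[entity_id] = score

    for entity_id in kb._exact_variant.get(mention_surface, ()):
        bump(entity_id, _TIER_EXACT_VARIANT)
    for entity_id in kb._exact_mention.get(mention_surface, ()):
        bump(entity_id, _TIER_EXACT_MENTION)
    for strip in (False, True):
        key = normalize_tokens(mention_surface, strip_brackets=strip)
        for entity_id in kb.variant_index.get(key, ()):
            bump(entity_id, _TIER_NORMALIZED)
    query_tokens = set(normalize_tokens(mention_surface))
    for r in kb.records:
        j = _jaccard(query_tokens, set(normalize_tokens(r.variant)))
        if j > 0:
            bump(r.entity_id, j)

    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:k]
    return CandidateSet(mention_surface,
                        [entity_id for entity_id, _ in ranked],
                        [s for _, s in ranked])


# ---------------------------------------------------------------------------
# TSV dump format
# ---------------------------------------------------------------------------

_HEADER = ["entity_id", "variant", "mention"]


def read_kb_tsv(path) -> list[KBRecord]:
    with Path(path).open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != _HEADER:
            raise KBError(f"{path}: expected header {_HEADER}, got {header}")
        return [KBRecord(*row[:3]) for row in reader if row]


def write_kb_tsv(records: list[KBRecord], path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HEADER)
        for r in records:
            writer.writerow([r.entity_id, r.variant, r.mention])
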