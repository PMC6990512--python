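"""Synthetic KBs, word vectors and annotated corpora for desk-scale runs.

The generator imitates the structures the real task exhibits: a
Mention-Variant-ID knowledge base with controlled ambiguity (one mention
surface reaching several IDs through species-qualified variants, as in
"VEGF (human)" vs "VEGF (pig)") and synonymy (one ID owning alias
variants), plus caption-like documents in which every entity occurrence
uses a KB variant surface and each gold ID co-occurs with a planted
context keyword with configurable probability.  Stop words, punctuation
and distractor keywords are injected so context-window filtering and
candidate-conditioned attention are genuinely exercised.

Everything is driven by one seed and is bit-reproducible.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np

from .corpus_io import Document, MentionSpan
from .knowledge_kb import KBRecord, KnowledgeBase, build_kb, kb_retrieve
from .vectors import WordVectors

SPECIES = ("human", "mouse", "rat", "pig", "bovine", "yeast", "zebrafish",
           "chicken", "frog", "fly")

STOP_SAMPLE = ("the", "of", "in", "and", "to", "with", "for", "on", "at",
               "by", "is", "was")

PUNCT_SAMPLE = (",", ".", ";", ":", "-")


class GenerationError(ValueError):
    pass


@dataclass
class SynthConfig:
    seed: int = 0
    n_ids: int = 50
    target_ambiguity_rate: float = 2.5
    target_synonymy_rate: float = 2.4
    ambiguous_id_fraction: float = 0.4     # share of IDs reached ambiguously
    multi_variant_fraction: float = 0.4    # share of IDs with alias variants
    n_documents: int = 100
    tokens_per_document: int = 20
    entity_density: float = 0.15
    vector_dim: int = 32
    planted_signal_strength: float = 0.9
    distractor_rate: float = 0.3

    def __post_init__(self):
        if self.target_ambiguity_rate < 1 or self.target_synonymy_rate < 1:
            raise GenerationError("rates must be >= 1")
        if not (0 <= self.entity_density < 1):
            raise GenerationError("entity_density must be in [0, 1)")
        if not (0 <= self.planted_signal_strength <= 1):
            raise GenerationError("planted_signal_strength must be in [0, 1]")


def _name(prefix: str, i: int) -> str:
    letters = string.ascii_lowercase
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = letters[r] + out
    return prefix + out


def fig1_records() -> list[KBRecord]:
    """The four-record VEGF example: one ID with three variants (synonymy)
    and one surface reaching two IDs (ambiguity)."""
    return [
        KBRecord("NCBI Gene:7422", "VEGF (human)", "VEGF"),
        KBRecord("NCBI Gene:7422", "MVCD1", "MVCD1"),
        KBRecord("NCBI Gene:7422", "VPF", "VPF"),
        KBRecord("NCBI Gene:397157", "VEGF (pig)", "VEGF"),
    ]


def _count_mix(n: int, mean: float, minimum: int) -> list[int]:
    """n integers >= minimum averaging ``mean`` (floor/ceil mix)."""
    base = int(np.floor(mean))
    n_ceil = int(round((mean - base) * n))
    counts = [base + 1] * n_ceil + [base] * (n - n_ceil)
    return [max(c, minimum) for c in counts]


def generate_kb(config: SynthConfig) -> list[KBRecord]:
    """Emit Mention-Variant-ID records realizing the configured rates.

    Ambiguous mentions reach their IDs through species-qualified variants;
    synonymy comes from alias variants attached to a subset of IDs.  The
    realized ambiguity and synonymy rates match the targets up to integer
    rounding of the count mixture (well within 10%).
    """
    rng = np.random.default_rng(config.seed)
    n_ids = config.n_ids
    if n_ids < 1:
        raise GenerationError("need at least one ID")
    r_a = config.target_ambiguity_rate
    if r_a > 1 and n_ids < 2:
        raise GenerationError("ambiguity > 1 needs at least 2 IDs")

    ids = [f"NCBI Gene:{7000 + i}" for i in range(n_ids)]
    records: list[KBRecord] = []
    consumed = 0
    mention_no = 0
    if r_a > 1:
        n_ambiguous_ids = max(2, int(round(config.ambiguous_id_fraction
                                           * n_ids)))
        n_amb_mentions = max(1, int(round(n_ambiguous_ids / r_a)))
        counts = _count_mix(n_amb_mentions, r_a, 2)
        for c in counts:
            c = min(c, n_ids - consumed)
            if c < 2:
                break
            surface = _name("gn", mention_no)
            mention_no += 1
            species = rng.permutation(len(SPECIES))[:c]
            for k in range(c):
                records.append(KBRecord(ids[consumed],
                                        f"{surface} ({SPECIES[species[k]]})",
                                        surface))
                consumed += 1
    while consumed < n_ids:
        surface = _name("gn", mention_no)
        mention_no += 1
        records.append(KBRecord(ids[consumed], surface, surface))
        consumed += 1

    r_s = config.target_synonymy_rate
    if r_s > 1:
        n_multi = max(1, int(round(config.multi_variant_fraction * n_ids)))
        extra = _count_mix(n_multi, r_s - 1, 1)
        # alias variants go to ambiguously-reached IDs first: that mirrors
        # the canonical example (the ambiguous ID is the one with aliases)
        # and is what makes sibling IDs structurally distinguishable
        ambiguous = [i for i in range(n_ids)
                     if any(r.entity_id == ids[i] and "(" in r.variant
                            for r in records)]
        rest = [i for i in range(n_ids) if i not in set(ambiguous)]
        rest_perm = [rest[int(i)] for i in rng.permutation(len(rest))] \
            if rest else []
        order = ambiguous + rest_perm
        alias_no = 0
        for idx, n_extra in zip(order[:n_multi], extra):
            for _ in range(n_extra):
                alias = _name("al", alias_no)
                alias_no += 1
                records.append(KBRecord(ids[int(idx)], alias, alias))
    return records


def kb_rates(records: list[KBRecord]) -> tuple[float, float]:
    """Realized (ambiguity, synonymy) rates of a record table."""
    mention_ids: dict[str, set[str]] = {}
    id_variants: dict[str, set[str]] = {}
    for r in records:
        mention_ids.setdefault(r.mention, set()).add(r.entity_id)
        id_variants.setdefault(r.entity_id, set()).add(r.variant)
    poly = [len(s) for s in mention_ids.values() if len(s) >= 2]
    multi = [len(s) for s in id_variants.values() if len(s) >= 2]
    return (float(np.mean(poly)) if poly else 1.0,
            float(np.mean(multi)) if multi else 1.0)


# ---------------------------------------------------------------------------
# word vectors
# ---------------------------------------------------------------------------

def _keyword(entity_id: str) -> str:
    return "ctx" + entity_id.rsplit(":", 1)[-1]


def generate_word_vectors(kb_records: list[KBRecord],
                          config: SynthConfig) -> WordVectors:
    """Random Gaussian vectors for every word the corpus can emit."""
    rng = np.random.default_rng(config.seed + 7)
    vocab: set[str] = set()
    for r in kb_records:
        vocab.update(w.lower() for w in r.variant.replace("(", " ")
                     .replace(")", " ").split())
        vocab.add(r.mention.lower())
        vocab.add(_keyword(r.entity_id))
    vocab.update(_name("w", i) for i in range(80))
    vocab.update(STOP_SAMPLE)
    table = {w: rng.normal(0.0, 1.0 / np.sqrt(config.vector_dim),
                           config.vector_dim)
             for w in sorted(vocab)}
    return WordVectors(table)


# ---------------------------------------------------------------------------
# corpus
# ---------------------------------------------------------------------------

def generate_corpus(kb: KnowledgeBase | list[KBRecord], config: SynthConfig,
                    records: list[KBRecord] | None = None,
                    word_vectors: WordVectors | None = None,
                    seed_offset: int = 0
                    ) -> tuple[list[Document], WordVectors]:
    """Documents with gold spans/IDs plus a matching word-vector table.

    Every entity occurrence uses a KB variant surface; the gold ID's
    planted keyword lands inside the mention's context window with
    probability ``planted_signal_strength``, and distractor keywords of
    non-candidate IDs are injected at ``distractor_rate`` so candidate-
    conditioned attention has something to ignore.  ``records`` restricts
    which variants occur (e.g. to hold out surfaces for ablations).
    """
    if isinstance(kb, list):
        all_records = kb
        kb = build_kb(kb)
    else:
        all_records = kb.records
    pool = records if records is not None else all_records
    wv = word_vectors or generate_word_vectors(all_records, config)
    rng = np.random.default_rng(config.seed + 1000 + seed_offset)
    candidate_cache: dict[str, list[str]] = {}
    all_ids = sorted({r.entity_id for r in all_records})

    documents = []
    for doc_no in range(config.n_documents):
        words: list[str] = []
        pending: list[tuple[int, int, str, str]] = []  # token-index spans
        while len(words) < config.tokens_per_document:
            roll = rng.random()
            if roll < config.entity_density and pool:
                r = pool[int(rng.integers(len(pool)))]
                start = len(words)
                words.extend(r.variant.replace("(", "( ")
                             .replace(")", " )").split())
                pending.append((start, len(words), r.variant, r.entity_id))
                if rng.random() < config.planted_signal_strength:
                    words.append(_keyword(r.entity_id))
                if rng.random() < config.distractor_rate:
                    if r.mention not in candidate_cache:
                        candidate_cache[r.mention] = list(
                            kb_retrieve(r.mention, kb))
                    excluded = set(candidate_cache[r.mention])
                    safe = [i for i in all_ids if i not in excluded]
                    if safe:
                        words.append(_keyword(
                            safe[int(rng.integers(len(safe)))]))
            elif roll < config.entity_density + 0.12:
                words.append(STOP_SAMPLE[int(rng.integers(len(STOP_SAMPLE)))])
            elif roll < config.entity_density + 0.17:
                words.append(PUNCT_SAMPLE[int(rng.integers(len(PUNCT_SAMPLE)))])
            else:
                words.append(_name("w", int(rng.integers(80))))

        text_parts: list[str] = []
        char_pos = []
        pos = 0
        for w in words:
            char_pos.append(pos)
            text_parts.append(w)
            pos += len(w) + 1
        text = " ".join(text_parts)
        mentions = []
        for tok_start, tok_end, variant, entity_id in pending:
            start = char_pos[tok_start]
            end = char_pos[tok_end - 1] + len(words[tok_end - 1])
            surface = text[start:end]
            mentions.append(MentionSpan(start, end, surface, "gene",
                                        gold_id=entity_id))
        documents.append(Document(f"synth-{doc_no:04d}", text, mentions))
    return documents, wv
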