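"""Scoring for recognition and normalization, error taxonomy, corpus
statistics, and the learning-curve extrapolation model.

Recognition is scored under two criteria: *strict* (character offsets and
type must be identical) and *overlap* (any character overlap with the same
type counts).  Normalization is scored micro (pooled counts) and macro
(per-document unweighted mean).  The learning-curve model F1 = i + j*m^n
extrapolates performance as training parts n grow; i is the asymptote.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .corpus_io import Document, GENERIC_PREFIX, MentionSpan

SpanKey = tuple[int, int, str]


@dataclass
class PRF:
    tp: float
    fp: float
    fn: float

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def _spans_match(gold: MentionSpan, pred: MentionSpan, mode: str) -> bool:
    if gold.entity_type != pred.entity_type:
        return False
    if mode == "strict":
        return gold.start == pred.start and gold.end == pred.end
    if mode == "overlap":
        return gold.start < pred.end and pred.start < gold.end
    raise ValueError(f"unknown mode {mode!r}")


def match_spans(gold: list[MentionSpan], pred: list[MentionSpan],
                mode: str) -> list[tuple[int, int]]:
    """Greedy leftmost one-to-one matching; returns (gold_idx, pred_idx)."""
    pairs = []
    used = set()
    pred_order = sorted(range(len(pred)),
                        key=lambda i: (pred[i].start, pred[i].end))
    gold_order = sorted(range(len(gold)),
                        key=lambda i: (gold[i].start, gold[i].end))
    for pi in pred_order:
        for gi in gold_order:
            if gi in used:
                continue
            if _spans_match(gold[gi], pred[pi], mode):
                pairs.append((gi, pi))
                used.add(gi)
                break
    return pairs


def score_ner(gold_docs: list[list[MentionSpan]],
              pred_docs: list[list[MentionSpan]], mode: str = "strict") -> PRF:
    """Span-level P/R/F1 under strict or overlap matching, pooled over
    documents."""
    tp = fp = fn = 0
    for gold, pred in zip(gold_docs, pred_docs, strict=True):
        matched = match_spans(gold, pred, mode)
        tp += len(matched)
        fp += len(pred) - len(matched)
        fn += len(gold) - len(matched)
    return PRF(tp, fp, fn)


# ---------------------------------------------------------------------------
# normalization scoring
# ---------------------------------------------------------------------------

def _normalized_pairs(spans: list[MentionSpan], which: str) -> set[tuple]:
    pairs = set()
    for m in spans:
        entity_id = m.gold_id if which == "gold" else m.predicted_id
        if entity_id and not entity_id.startswith(GENERIC_PREFIX):
            pairs.add((m.start, m.end, m.entity_type, entity_id))
    return pairs


def _pair_counts(gold: list[MentionSpan], pred: list[MentionSpan]) -> PRF:
    g = _normalized_pairs(gold, "gold")
    p = _normalized_pairs(pred, "pred")
    return PRF(len(g & p), len(p - g), len(g - p))


def score_nen(gold_docs: list[list[MentionSpan]],
              pred_docs: list[list[MentionSpan]],
              averaging: str = "micro") -> PRF | "MacroPRF":
    """(span, ID) pair scoring; only normalized (non-generic) predicted IDs
    are evaluated.  ``micro`` pools counts globally; ``macro`` averages
    per-document P/R/F1 with equal weight."""
    per_doc = [_pair_counts(g, p)
               for g, p in zip(gold_docs, pred_docs, strict=True)]
    if averaging == "micro":
        return PRF(sum(d.tp for d in per_doc), sum(d.fp for d in per_doc),
                   sum(d.fn for d in per_doc))
    if averaging == "macro":
        return MacroPRF(
            precision=float(np.mean([d.precision for d in per_doc])),
            recall=float(np.mean([d.recall for d in per_doc])),
            f1=float(np.mean([d.f1 for d in per_doc])))
    raise ValueError(f"unknown averaging {averaging!r}")


@dataclass
class MacroPRF:
    precision: float
    recall: float
    f1: float


# ---------------------------------------------------------------------------
# error taxonomy
# ---------------------------------------------------------------------------

CATEGORIES = ("ner_fp", "ner_fn", "missed_id", "incorrect_id")


@dataclass
class ErrorBreakdown:
    """Four-way partition of normalization errors.

    ``ner_fp``: normalization FPs caused by spurious recognized spans;
    ``ner_fn``: normalization FNs caused by unrecognized entities;
    ``missed_id``: recognized entities whose gold ID is absent from the
    retrieved candidates; ``incorrect_id``: recognized entities whose gold
    ID was retrieved but not chosen.
    """

    counts: dict[str, int]
    percentages: dict[str, float] = field(init=False)
    total: int = field(init=False)

    def __post_init__(self):
        self.total = sum(self.counts.values())
        self.percentages = {
            k: round(100.0 * v / self.total, 2) if self.total else 0.0
            for k, v in self.counts.items()}


def breakdown_from_counts(ner_fp: int, ner_fn: int, missed_id: int,
                          incorrect_id: int) -> ErrorBreakdown:
    return ErrorBreakdown(dict(zip(CATEGORIES,
                                   (ner_fp, ner_fn, missed_id, incorrect_id))))


def error_breakdown(gold_docs: list[list[MentionSpan]],
                    pred_docs: list[list[MentionSpan]],
                    candidate_sets: list[dict[SpanKey, list[str]]]
                    ) -> ErrorBreakdown:
    """Attribute every erroneous ID assignment to exactly one category.

    ``candidate_sets`` gives, per document, the retrieved candidate IDs
    keyed by predicted span (start, end, type).  Recognition uses strict
    matching; predicted spans matching no gold span are recognition FPs,
    unmatched gold spans are recognition FNs, and matched spans with a
    wrong assignment split on whether the gold ID was retrieved at all.
    """
    counts = {k: 0 for k in CATEGORIES}
    for gold, pred, cands in zip(gold_docs, pred_docs, candidate_sets,
                                 strict=True):
        matched = match_spans(gold, pred, "strict")
        matched_gold = {gi for gi, _ in matched}
        matched_pred = {pi for _, pi in matched}
        counts["ner_fp"] += len(pred) - len(matched_pred)
        counts["ner_fn"] += len(gold) - len(matched_gold)
        for gi, pi in matched:
            g, p = gold[gi], pred[pi]
            if g.gold_id is None or p.predicted_id == g.gold_id:
                continue
            key = (p.start, p.end, p.entity_type)
            if g.gold_id not in cands.get(key, []):
                counts["missed_id"] += 1
            else:
                counts["incorrect_id"] += 1
    return ErrorBreakdown(counts)


# ---------------------------------------------------------------------------
# corpus statistics
# ---------------------------------------------------------------------------

@dataclass
class CorpusStats:
    n_mentions: int
    n_monosemous: int
    n_polysemous: int
    ambiguity_rate: float
    n_ids: int
    n_single_var: int
    n_multi_var: int
    synonymy_rate: float
    ambiguity_defined: bool = True
    synonymy_defined: bool = True


def corpus_stats(documents: list[Document]) -> CorpusStats:
    """Ambiguity and synonymy rates over gold annotations.

    Ambiguity rate: mean distinct-ID count over mention surfaces with >= 2
    IDs.  Synonymy rate: mean distinct-surface count over IDs with >= 2
    surfaces.  A rate with an empty denominator reports 0 with its
    ``*_defined`` flag cleared.
    """
    mention_ids: dict[str, set[str]] = {}
    id_variants: dict[str, set[str]] = {}
    for doc in documents:
        for m in doc.mentions:
            if not m.gold_id or m.gold_id.startswith(GENERIC_PREFIX):
                continue
            mention_ids.setdefault(m.surface, set()).add(m.gold_id)
            id_variants.setdefault(m.gold_id, set()).add(m.surface)
    poly = [len(s) for s in mention_ids.values() if len(s) >= 2]
    multi = [len(s) for s in id_variants.values() if len(s) >= 2]
    return CorpusStats(
        n_mentions=len(mention_ids),
        n_monosemous=sum(1 for s in mention_ids.values() if len(s) == 1),
        n_polysemous=len(poly),
        ambiguity_rate=float(np.mean(poly)) if poly else 0.0,
        n_ids=len(id_variants),
        n_single_var=sum(1 for s in id_variants.values() if len(s) == 1),
        n_multi_var=len(multi),
        synonymy_rate=float(np.mean(multi)) if multi else 0.0,
        ambiguity_defined=bool(poly),
        synonymy_defined=bool(multi),
    )


# ---------------------------------------------------------------------------
# learning curve
# ---------------------------------------------------------------------------

@dataclass
class LearningCurveFit:
    i: float          # asymptote
    j: float          # amplitude
    m: float          # decay base in (0, 1)
    residual: float   # sum of squared residuals

    def predict(self, n) -> np.ndarray:
        return self.i + self.j * self.m ** np.asarray(n, dtype=float)


def fit_learning_curve(points: list[tuple[int, float]]) -> LearningCurveFit:
    """Nonlinear least squares for F1 = i + j*m^n with m in (0, 1).

    For fixed m the model is linear in (i, j), so the profile residual is a
    1-D function of m; it is scanned on a fixed grid and refined with
    bounded scalar minimization, making the fit deterministic.
    """
    if len(points) < 4:
        raise ValueError("need at least 4 (n, F1) points")
    n = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.any(n <= 0):
        raise ValueError("n must be positive")

    def profile(m: float) -> tuple[float, float, float]:
        X = np.column_stack([np.ones_like(n), m ** n])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = float(np.sum((X @ coef - y) ** 2))
        return resid, coef[0], coef[1]

    grid = np.linspace(0.01, 0.99, 197)
    residuals = [profile(m)[0] for m in grid]
    best = int(np.argmin(residuals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(lambda m: profile(m)[0], bounds=(lo, hi),
                          method="bounded",
                          options={"xatol": 1e-12, "maxiter": 500})
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"learning-curve fit did not converge: {res}")
    resid, i, j = profile(float(res.x))
    return LearningCurveFit(i=float(i), j=float(j), m=float(res.x),
                            residual=resid)
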