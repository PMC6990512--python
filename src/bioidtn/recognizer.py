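"""BiLSTM-CRF protein/gene mention recognizer.

Each token is represented by the concatenation of six parts — pre-trained
word embedding, character-level BiLSTM output, POS, chunk and knowledge-
feature embeddings, and a combined contextual (biLM) representation

    x_t = [x_w; x_c; x_pos; x_chunk; x_kf; x_elmo],

where the contextual part is a scaled softmax-weighted sum of biLM layer
states, x_elmo = gamma * sum_j l_j h_{t,j}.  A BiLSTM over the sequence
feeds a two-layer feed-forward scorer P = V tanh(W h + b) producing
per-token label scores, and a linear-chain CRF with transition matrix T
(size k+2 with start/end states) scores tag paths

    score(X, y) = sum_i ( T[y_{i-1}, y_i] + P[i, y_i] ).

Training maximizes the CRF log-likelihood with RMSProp (lr 1e-3,
mini-batch 8, dropout 0.5); decoding uses Viterbi, followed by rule-based
post-processing (bracket completion and same-document surface repeats).
"""

from __future__ import annotations

import copy
import logging
import re
from dataclasses import dataclass, replace

import numpy as np

from . import nn
from .corpus_io import (Document, MentionSpan, TagSequence, Token,
                        bio_to_spans, spans_to_bio, tokenize)
from .knowledge_kb import KnowledgeBase, knowledge_feature_tags
from .vectors import StubContextualProvider, WordVectors

logger = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# contextual layer combination
# ---------------------------------------------------------------------------

class ContextualCombiner(nn.Module):
    """Learned scaled softmax-weighted sum of biLM layer states."""

    def __init__(self, n_layers: int, gamma: float = 1.0):
        self.layer_logits = nn.Tensor(np.zeros(n_layers), requires_grad=True)
        self.gamma = nn.Tensor(np.array(gamma), requires_grad=True)
        self.n_layers = n_layers

    def weights(self) -> np.ndarray:
        return nn.softmax(self.layer_logits, axis=0).data

    def __call__(self, layer_states) -> nn.Tensor:
        layers = layer_states if isinstance(layer_states, nn.Tensor) \
            else nn.Tensor(np.asarray(layer_states, dtype=np.float64))
        if layers.shape[0] != self.n_layers:
            raise ValueError(f"expected {self.n_layers} layers, "
                             f"got {layers.shape[0]}")
        w = nn.softmax(self.layer_logits, axis=0)
        weighted = (w.reshape(self.n_layers, 1, 1) * layers).sum(axis=0)
        return self.gamma * weighted


def combine_contextual_layers(layer_states: np.ndarray,
                              combiner: ContextualCombiner) -> np.ndarray:
    """(L, n, w) layer states -> (n, w) combined contextual vectors."""
    widths = {s.shape[-1] for s in np.asarray(layer_states)}
    if len(widths) != 1:
        raise ValueError(f"layer width mismatch: {widths}")
    return combiner(layer_states).data


# ---------------------------------------------------------------------------
# CRF primitives (emission matrix P: n x k, transitions T: (k+2) x (k+2))
# ---------------------------------------------------------------------------

def _start_end(k: int) -> tuple[int, int]:
    return k, k + 1


def crf_sequence_score(P, T, y) -> float:
    """Path score: transitions (incl. start/end) plus emissions along y."""
    P, T = np.asarray(P, float), np.asarray(T, float)
    y = np.asarray(list(y), dtype=int)
    n, k = P.shape
    if len(y) != n:
        raise ValueError("tag sequence length != emission rows")
    if n == 0:
        return 0.0
    if np.any(y < 0) or np.any(y >= k):
        raise ValueError("invalid tag index")
    start, end = _start_end(k)
    score = T[start, y[0]] + P[0, y[0]]
    for i in range(1, n):
        score += T[y[i - 1], y[i]] + P[i, y[i]]
    return float(score + T[y[-1], end])


def _forward_logz(P, T):
    n, k = P.shape
    start, end = _start_end(k)
    alpha = T[start, :k] + P[0]
    for i in range(1, n):
        alpha = _lse(alpha[:, None] + T[:k, :k], axis=0) + P[i]
    return _lse(alpha + T[:k, end], axis=0)


def _lse(x, axis):
    m = np.max(x, axis=axis, keepdims=True)
    return np.squeeze(np.log(np.sum(np.exp(x - m), axis=axis,
                                    keepdims=True)) + m, axis=axis)


def crf_log_likelihood(P, T, y) -> float:
    """log P(y | X) = score(X, y) - log Z, by the forward recursion."""
    P, T = np.asarray(P, float), np.asarray(T, float)
    if P.shape[0] == 0:
        return 0.0
    return crf_sequence_score(P, T, y) - float(_forward_logz(P, T))


def _crf_nll_tensor(P: nn.Tensor, T: nn.Tensor, y: np.ndarray) -> nn.Tensor:
    """Differentiable negative log-likelihood for training."""
    n, k = P.shape
    start, end = _start_end(k)
    idx = np.arange(n)
    emit = P[idx, y].sum()
    prev = np.concatenate([[start], y[:-1]])
    trans = T[prev, y].sum() + T[y[-1], end]
    alpha = T[start, np.arange(k)] + P[0]
    for i in range(1, n):
        alpha = nn.logsumexp(alpha.reshape(k, 1) + T[:k, :k], axis=0) + P[i]
    logz = nn.logsumexp(alpha + T[np.arange(k), end], axis=0)
    return logz - emit - trans


def viterbi_decode(P, T) -> tuple[list[int], float]:
    """Highest-scoring tag path and its score (ties -> lowest tag index)."""
    P, T = np.asarray(P, float), np.asarray(T, float)
    n, k = P.shape
    if n == 0:
        return [], 0.0
    start, end = _start_end(k)
    delta = T[start, :k] + P[0]
    back = np.zeros((n, k), dtype=int)
    for i in range(1, n):
        cand = delta[:, None] + T[:k, :k]
        back[i] = np.argmax(cand, axis=0)
        delta = cand[back[i], np.arange(k)] + P[i]
    delta = delta + T[:k, end]
    best = int(np.argmax(delta))
    path = [best]
    for i in range(n - 1, 0, -1):
        best = int(back[i, best])
        path.append(best)
    path.reverse()
    return path, float(np.max(delta))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class RecognizerConfig:
    seed: int = 0
    word_dim: int | None = None       # inferred from the word-vector table
    char_emb_dim: int = 50
    char_hidden: int = 25             # per direction -> 50-dim x_c
    pos_dim: int = 25
    chunk_dim: int = 10
    kf_dim: int = 15
    elmo_width: int = 32
    elmo_layers: int = 3
    hidden: int = 100                 # BiLSTM hidden per direction (d2)
    lr: float = 1e-3
    batch_size: int = 8
    dropout: float = 0.5
    max_epochs: int = 30
    patience: int = 5
    use_kf: bool = True
    use_elmo: bool = True
    use_linguistic: bool = True       # POS + chunk features
    entity_types: tuple[str, ...] = ("gene",)
    grad_clip: float = 5.0


def bio_labels(entity_types) -> list[str]:
    labels = ["O"]
    for t in entity_types:
        labels += [f"B-{t}", f"I-{t}"]
    return labels


class RecognizerModel(nn.Module):
    def __init__(self, config: RecognizerConfig, word_vectors: WordVectors,
                 vocab: list[str], char_vocab: list[str],
                 pos_vocab: list[str], chunk_vocab: list[str]):
        cfg = replace(config, word_dim=word_vectors.dim)
        self.config = cfg
        self.word_vectors = word_vectors
        self.vocab = {w: i for i, w in enumerate(vocab)}
        self.char_vocab = {c: i for i, c in enumerate(char_vocab)}
        self.pos_vocab = {p: i for i, p in enumerate(pos_vocab)}
        self.chunk_vocab = {c: i for i, c in enumerate(chunk_vocab)}
        self.kf_vocab = {"O": 0, "B-kf": 1, "I-kf": 2}
        self.labels = bio_labels(cfg.entity_types)
        k = len(self.labels)

        rng = np.random.default_rng(cfg.seed)
        self.word_emb = nn.Embedding(rng, len(vocab), cfg.word_dim,
                                     init=word_vectors.matrix(vocab))
        self.char_emb = nn.Embedding(rng, len(char_vocab), cfg.char_emb_dim)
        self.char_rnn = nn.BiRecurrent(rng, cfg.char_emb_dim, cfg.char_hidden)
        self.pos_emb = nn.Embedding(rng, len(pos_vocab), cfg.pos_dim)
        self.chunk_emb = nn.Embedding(rng, len(chunk_vocab), cfg.chunk_dim)
        self.kf_emb = nn.Embedding(rng, 3, cfg.kf_dim)
        self.provider = StubContextualProvider(
            cfg.word_dim, cfg.elmo_width, cfg.elmo_layers)
        self.combiner = ContextualCombiner(cfg.elmo_layers)

        d_in = cfg.word_dim + 2 * cfg.char_hidden
        if cfg.use_linguistic:
            d_in += cfg.pos_dim + cfg.chunk_dim
        if cfg.use_kf:
            d_in += cfg.kf_dim
        if cfg.use_elmo:
            d_in += cfg.elmo_width
        self.input_dim = d_in
        self.rnn = nn.BiRecurrent(rng, d_in, cfg.hidden)
        self.fc_hidden = nn.Linear(rng, 2 * cfg.hidden, cfg.hidden)
        self.fc_out = nn.Linear(rng, cfg.hidden, k)
        self.transitions = nn.Tensor(rng.normal(0, 0.1, (k + 2, k + 2)),
                                     requires_grad=True)
        self._drop_rng = np.random.default_rng(cfg.seed + 1)

    # -- feature construction ------------------------------------------------
    def _char_vectors(self, tokens: list[Token]) -> nn.Tensor:
        """Character BiLSTM final states, batched over equal-length words."""
        unk = len(self.char_vocab)
        out: list = [None] * len(tokens)
        by_len: dict[int, list[int]] = {}
        for i, t in enumerate(tokens):
            by_len.setdefault(len(t.text), []).append(i)
        for length, idxs in by_len.items():
            ids = np.array([[self.char_vocab.get(c, unk)
                             for c in tokens[i].text] for i in idxs])
            emb = self.char_emb(ids.T)            # (length, batch, emb)
            _, last = self.char_rnn(emb)          # (batch, 2*char_hidden)
            for row, i in enumerate(idxs):
                out[i] = last[row]
        return nn.stack(out, axis=0)

    def build_features(self, tokens: list[Token],
                       kf_tags: TagSequence | list[str],
                       train: bool = False) -> nn.Tensor:
        """Per-token concatenation [x_w; x_c; x_pos; x_chunk; x_kf; x_elmo]."""
        cfg = self.config
        unk_w = len(self.vocab)
        widx = np.array([self.vocab.get(t.text, unk_w) for t in tokens])
        parts = [self.word_emb(widx), self._char_vectors(tokens)]
        if cfg.use_linguistic:
            unk_p, unk_c = len(self.pos_vocab), len(self.chunk_vocab)
            parts.append(self.pos_emb(
                np.array([self.pos_vocab.get(t.pos, unk_p) for t in tokens])))
            parts.append(self.chunk_emb(
                np.array([self.chunk_vocab.get(t.chunk, unk_c)
                          for t in tokens])))
        if cfg.use_kf:
            kidx = np.array([self.kf_vocab.get(t, 0) for t in kf_tags])
            parts.append(self.kf_emb(kidx))
        if cfg.use_elmo:
            static = np.stack([self.word_vectors.get(t.text) for t in tokens])
            layers = self.provider(static)
            parts.append(self.combiner(layers))
        x = nn.concat(parts, axis=-1)
        return nn.dropout(x, cfg.dropout, self._drop_rng, train)

    def emissions(self, tokens, kf_tags, train: bool = False) -> nn.Tensor:
        x = self.build_features(tokens, kf_tags, train)
        hs, _ = self.rnn(x)
        hs = nn.dropout(hs, self.config.dropout, self._drop_rng, train)
        return self.fc_out(nn.tanh(self.fc_hidden(hs)))

    # -- inference -----------------------------------------------------------
    def decode(self, tokens, kf_tags) -> TagSequence:
        if not tokens:
            return TagSequence([])
        P = self.emissions(tokens, kf_tags, train=False).data
        path, _ = viterbi_decode(P, self.transitions.data)
        return TagSequence([self.labels[i] for i in path])

    def predict_document(self, doc: Document, kb: KnowledgeBase | None,
                         post: bool = True) -> list[MentionSpan]:
        tokens = tokenize(doc)
        kf = (knowledge_feature_tags(tokens, kb) if kb is not None
              else TagSequence(["O"] * len(tokens)))
        spans = bio_to_spans(tokens, self.decode(tokens, kf), text=doc.text)
        return post_process(spans, doc) if post else spans

    def sentence_nll(self, tokens, kf_tags, tags: TagSequence,
                     train: bool = True) -> nn.Tensor:
        y = np.array([self.labels.index(t) for t in tags])
        P = self.emissions(tokens, kf_tags, train=train)
        return _crf_nll_tensor(P, self.transitions, y)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _prepare(documents: list[Document], kb: KnowledgeBase | None):
    items = []
    for doc in documents:
        tokens = tokenize(doc)
        if not tokens:
            continue
        kf = (knowledge_feature_tags(tokens, kb) if kb is not None
              else TagSequence(["O"] * len(tokens)))
        items.append((doc, tokens, kf, spans_to_bio(tokens, doc.mentions)))
    return items


def _vocabularies(items, extra_words=()):
    words, chars, pos, chunk = set(extra_words), set(), set(), set()
    for _, tokens, _, _ in items:
        for t in tokens:
            words.add(t.text)
            chars.update(t.text)
            pos.add(t.pos)
            chunk.add(t.chunk)
    return sorted(words), sorted(chars), sorted(pos), sorted(chunk)


def validation_f1(model: RecognizerModel, items) -> float:
    from .evaluation import score_ner
    gold = [doc.mentions for doc, *_ in items]
    pred = [bio_to_spans(tokens, model.decode(tokens, kf), text=doc.text)
            for doc, tokens, kf, _ in items]
    return score_ner(gold, pred, "strict").f1


def train_recognizer(corpus: list[Document], kb: KnowledgeBase | None,
                     config: RecognizerConfig,
                     word_vectors: WordVectors,
                     val_corpus: list[Document] | None = None
                     ) -> RecognizerModel:
    """Train a BiLSTM-CRF tagger; the checkpoint with the best validation
    strict F1 is returned (early stopping with the configured patience).

    When ``val_corpus`` is not given, a random 80/20 train/validation split
    of ``corpus`` is drawn from the configured seed.
    """
    rng = np.random.default_rng(config.seed)
    if val_corpus is None:
        order = rng.permutation(len(corpus))
        cut = max(1, int(0.8 * len(corpus)))
        train_docs = [corpus[i] for i in order[:cut]]
        val_docs = [corpus[i] for i in order[cut:]] or train_docs
    else:
        train_docs, val_docs = list(corpus), list(val_corpus)

    train_items = _prepare(train_docs, kb)
    val_items = _prepare(val_docs, kb)
    vocabs = _vocabularies(train_items)
    model = RecognizerModel(config, word_vectors, *vocabs)
    opt = nn.RMSProp(model.parameters(), lr=config.lr)

    best_f1, best_state, patience_left = -1.0, None, config.patience
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_items))
        total = 0.0
        for lo in range(0, len(order), config.batch_size):
            batch = [train_items[i] for i in order[lo:lo + config.batch_size]]
            opt.zero_grad()
            losses = [model.sentence_nll(tokens, kf, tags)
                      for _, tokens, kf, tags in batch]
            loss = nn.stack(losses).mean()
            value = loss.item()
            if not np.isfinite(value):
                raise TrainingError(
                    f"non-finite loss at epoch {epoch}; emissions or "
                    f"transitions diverged")
            loss.backward()
            opt.clip_grad_norm(config.grad_clip)
            opt.step()
            total += value * len(batch)
        f1 = validation_f1(model, val_items)
        logger.info("epoch %d: train nll %.4f, val strict F1 %.4f",
                    epoch, total / len(train_items), f1)
        if f1 > best_f1:
            best_f1, patience_left = f1, config.patience
            best_state = copy.deepcopy(model.state_arrays())
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.best_val_f1 = best_f1
    return model


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def _extend_brackets(span: MentionSpan, text: str) -> MentionSpan:
    surface = text[span.start:span.end]
    end = span.end
    while surface.count("(") > surface.count(")"):
        nxt = text.find(")", end)
        if nxt == -1 or nxt - end > 40:
            break
        end = nxt + 1
        surface = text[span.start:end]
    if end != span.end:
        return MentionSpan(span.start, end, surface, span.entity_type,
                           span.gold_id, span.predicted_id)
    return span


def _repeat_spans(spans: list[MentionSpan], text: str) -> list[MentionSpan]:
    out = list(spans)
    for surface in sorted({s.surface for s in spans}, key=len, reverse=True):
        if not surface or not any(c.isalnum() for c in surface):
            continue
        etype = next(s.entity_type for s in out if s.surface == surface)
        for m in re.finditer(re.escape(surface), text):
            cand = MentionSpan(m.start(), m.end(), surface, etype)
            boundary_ok = (
                (m.start() == 0 or not (text[m.start() - 1].isalnum()
                                        and surface[0].isalnum()))
                and (m.end() == len(text)
                     or not (text[m.end()].isalnum()
                             and surface[-1].isalnum())))
            if boundary_ok and not any(cand.overlaps(s) for s in out):
                out.append(cand)
    return sorted(out, key=lambda s: (s.start, s.end))


def post_process(predicted: list[MentionSpan], document: Document
                 ) -> list[MentionSpan]:
    """Correct raw Viterbi spans with two rules, applied to a fixed point:
    extend spans with an unclosed opening bracket to the closing bracket,
    and re-tag exact same-document repeats of an already-predicted surface.
    Idempotent by construction.
    """
    spans = sorted(predicted, key=lambda s: (s.start, s.end))
    for _ in range(10):
        extended = [_extend_brackets(s, document.text) for s in spans]
        dedup: list[MentionSpan] = []
        for s in sorted(extended, key=lambda s: (s.start, s.end)):
            if not any(s.start == d.start and s.end == d.end for d in dedup):
                dedup.append(s)
        new = _repeat_spans(dedup, document.text)
        if [(s.start, s.end) for s in new] == [(s.start, s.end) for s in spans]:
            return new
        spans = new
    return spans
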