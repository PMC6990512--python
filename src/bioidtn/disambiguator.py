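"""Candidate-ID ranking for recognized mentions.

For each mention the model sees its left and right contexts (the nearest
n2 = 10 non-stopword, non-punctuation words per side) and one candidate ID
embedding s.  Each side is encoded by a sequence encoder (LSTM, GRU,
BiLSTM, BiGRU or a hierarchical ConvNet); *knowledge-based attention*
scores each hidden state against the candidate ID,

    e_t = tanh(W_a h_t + V_a s + b_a),   alpha = softmax(e),
    o = sum_t alpha_t h_t,

while *self-attention* omits the V_a s term.  A sigmoid gate fuses the two
context summaries, z = g * o_L + (1 - g) * o_R with
g = sigma(W_g o_L + V_g o_R + b_g), and a two-layer ReLU classifier over
[z; s] yields a two-way softmax: the probability the candidate is the
correct assignment.  Training uses cross-entropy with uniformly drawn
corrupt candidates as negatives (Adagrad, lr 5e-4, mini-batch 8).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np

from . import nn
from .corpus_io import (Document, GENERIC_PREFIX, MentionSpan, Token,
                        strip_punctuation, tokenize)
from .knowledge_kb import CandidateSet, KnowledgeBase, kb_retrieve
from .vectors import StubContextualProvider, WordVectors

logger = logging.getLogger(__name__)

STOP_WORDS = frozenset("""
a an and are as at be but by for from has have in is it its of on or that the
their this to was were which with without not no we our they he she you i
""".split())

ENCODER_KINDS = ("LSTM", "GRU", "BiLSTM", "BiGRU", "HierConvNet")


class TrainingError(RuntimeError):
    pass


@dataclass
class DisambiguationSample:
    left_context: list[str]       # nearest-first order preserved, <= n2 words
    right_context: list[str]
    candidate_id: str
    label: int                    # 1 = correct, 0 = corrupt
    mention_surface: str = ""


def extract_contexts(document: Document, mention: MentionSpan, n2: int = 10,
                     stoplist: frozenset = STOP_WORDS
                     ) -> tuple[list[str], list[str]]:
    """Nearest n2 eligible tokens on each side of the mention, in text order.

    Stop words and pure-punctuation tokens are excluded; a side with fewer
    than n2 eligible tokens is simply shorter (padding happens at
    vectorization).
    """
    tokens = tokenize(document)

    def eligible(t: Token) -> bool:
        return t.text.lower() not in stoplist and not strip_punctuation(t.text)

    left = [t.text for t in tokens if t.end <= mention.start and eligible(t)]
    right = [t.text for t in tokens if t.start >= mention.end and eligible(t)]
    return left[-n2:], right[:n2]


# ---------------------------------------------------------------------------
# attention and gating
# ---------------------------------------------------------------------------

class AttentionParams(nn.Module):
    """Score parameters: W_a (1 x d_h), V_a (1 x d_id), scalar bias."""

    def __init__(self, rng, d_hidden: int, d_id: int):
        self.W_a = nn.Tensor(nn.glorot(rng, d_hidden, 1)[:, 0],
                             requires_grad=True)
        self.V_a = nn.Tensor(nn.glorot(rng, d_id, 1)[:, 0],
                             requires_grad=True)
        self.b_a = nn.Tensor(np.array(0.0), requires_grad=True)


def knowledge_attention(hidden_states, s, params: AttentionParams):
    """Candidate-conditioned soft attention over encoder states."""
    hs = hidden_states if isinstance(hidden_states, nn.Tensor) \
        else nn.Tensor(np.asarray(hidden_states, float))
    if hs.shape[0] == 0:
        raise ValueError("attention over an empty sequence is undefined")
    sv = s if isinstance(s, nn.Tensor) else nn.Tensor(np.asarray(s, float))
    scores = nn.tanh(hs @ params.W_a + (params.V_a @ sv) + params.b_a)
    alpha = nn.softmax(scores, axis=0)
    return alpha @ hs, alpha


def self_attention(hidden_states, params: AttentionParams):
    """Attention whose scores do not condition on the candidate ID."""
    hs = hidden_states if isinstance(hidden_states, nn.Tensor) \
        else nn.Tensor(np.asarray(hidden_states, float))
    if hs.shape[0] == 0:
        raise ValueError("attention over an empty sequence is undefined")
    scores = nn.tanh(hs @ params.W_a + params.b_a)
    alpha = nn.softmax(scores, axis=0)
    return alpha @ hs, alpha


class GateParams(nn.Module):
    def __init__(self, rng, d: int):
        self.W_g = nn.Tensor(nn.glorot(rng, d, 1)[:, 0], requires_grad=True)
        self.V_g = nn.Tensor(nn.glorot(rng, d, 1)[:, 0], requires_grad=True)
        self.b_g = nn.Tensor(np.array(0.0), requires_grad=True)


def gate_combine(o_left, o_right, params: GateParams):
    """Scalar-gated convex combination of the two context summaries."""
    oL = o_left if isinstance(o_left, nn.Tensor) \
        else nn.Tensor(np.asarray(o_left, float))
    oR = o_right if isinstance(o_right, nn.Tensor) \
        else nn.Tensor(np.asarray(o_right, float))
    g = nn.sigmoid(params.W_g @ oL + params.V_g @ oR + params.b_g)
    return g * oL + (1.0 - g) * oR, g


# ---------------------------------------------------------------------------
# encoders
# ---------------------------------------------------------------------------

class HierConvNet(nn.Module):
    """Four stacked same-padded 1-D conv layers; per-step states are the
    concatenated layer maps, and the sequence summary concatenates the four
    max-pooled layer summaries [u1; u2; u3; u4]."""

    def __init__(self, rng, d_in: int, n_maps: int = 64, width: int = 3):
        dims = [d_in] + [n_maps] * 4
        self.layers = [nn.Conv1d(rng, dims[i], dims[i + 1], width)
                       for i in range(4)]
        self.out_width = 4 * n_maps

    def __call__(self, xs: nn.Tensor):
        states, summaries = [], []
        h = xs
        for conv in self.layers:
            h = nn.relu(conv(h))
            states.append(h)
            summaries.append(h.max(axis=0))
        return nn.concat(states, axis=-1), nn.concat(summaries, axis=-1)


class SequenceEncoder(nn.Module):
    def __init__(self, rng, kind: str, d_in: int, hidden: int,
                 conv_maps: int = 64):
        if kind not in ENCODER_KINDS:
            raise ValueError(f"unknown encoder kind {kind!r}")
        self.kind = kind
        if kind == "LSTM":
            self.net = nn.LSTM(rng, d_in, hidden)
            self.out_width = hidden
        elif kind == "GRU":
            self.net = nn.GRU(rng, d_in, hidden)
            self.out_width = hidden
        elif kind in ("BiLSTM", "BiGRU"):
            self.net = nn.BiRecurrent(rng, d_in, hidden,
                                      "lstm" if kind == "BiLSTM" else "gru")
            self.out_width = 2 * hidden
        else:
            self.net = HierConvNet(rng, d_in, conv_maps)
            self.out_width = self.net.out_width

    def __call__(self, xs: nn.Tensor):
        """Returns (per-step states, sequence summary)."""
        if self.kind == "HierConvNet":
            return self.net(xs)
        hs, last = self.net(xs)
        return hs, last


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

@dataclass
class DisambiguatorConfig:
    seed: int = 0
    encoder: str = "BiGRU"
    attention: str = "knowledge"      # {"knowledge", "self", "none"}
    hidden: int = 32
    conv_maps: int = 64
    n2: int = 10
    n_neg: int = 2
    lr: float = 5e-4
    batch_size: int = 8
    epochs: int = 60
    fc_hidden: int = 64
    nil_threshold: float = 0.5
    use_elmo: bool = True
    elmo_width: int = 16
    grad_clip: float = 5.0


class DisambiguatorModel(nn.Module):
    def __init__(self, config: DisambiguatorConfig,
                 word_vectors: WordVectors,
                 id_embeddings: dict[str, np.ndarray]):
        self.config = config
        self.word_vectors = word_vectors
        self.id_embeddings = {k: np.asarray(v, float)
                              for k, v in id_embeddings.items()}
        self.d_id = next(iter(self.id_embeddings.values())).shape[0] \
            if self.id_embeddings else word_vectors.dim
        rng = np.random.default_rng(config.seed)
        d_ctx = word_vectors.dim + (config.elmo_width if config.use_elmo else 0)
        self.provider = StubContextualProvider(
            word_vectors.dim, config.elmo_width, n_layers=1) \
            if config.use_elmo else None
        self.enc_left = SequenceEncoder(rng, config.encoder, d_ctx,
                                        config.hidden, config.conv_maps)
        self.enc_right = SequenceEncoder(rng, config.encoder, d_ctx,
                                         config.hidden, config.conv_maps)
        d_h = self.enc_left.out_width
        self.att_left = AttentionParams(rng, d_h, self.d_id)
        self.att_right = AttentionParams(rng, d_h, self.d_id)
        self.gate = GateParams(rng, d_h)
        self.fc1 = nn.Linear(rng, d_h + self.d_id, config.fc_hidden)
        self.fc2 = nn.Linear(rng, config.fc_hidden, config.fc_hidden)
        self.out = nn.Linear(rng, config.fc_hidden, 2)

    # -- vectorization -------------------------------------------------------
    def _context_matrix(self, words: list[str]) -> np.ndarray:
        """(n2, d_ctx) matrix: real tokens then reserved zero pad vectors."""
        n2 = self.config.n2
        d = self.word_vectors.dim + (self.config.elmo_width
                                     if self.config.use_elmo else 0)
        padded = np.zeros((n2, d))
        if words:
            static = np.stack([self.word_vectors.get(w) for w in words])
            if self.provider is not None:
                static = np.concatenate([static, self.provider(static)[0]],
                                        axis=1)
            take = min(len(words), n2)
            padded[:take] = static[:take]
        return padded

    def id_vector(self, entity_id: str) -> np.ndarray:
        v = self.id_embeddings.get(entity_id)
        if v is None:
            logger.debug("no pre-trained embedding for %s; using zeros",
                         entity_id)
            v = np.zeros(self.d_id)
        return v

    # -- forward -------------------------------------------------------------
    def _batched_attention(self, hs: nn.Tensor, S: nn.Tensor,
                           params: AttentionParams) -> nn.Tensor:
        """hs: (T, B, d_h); S: (B, d_id) -> (B, d_h) context summaries."""
        T, B, d_h = hs.shape
        scores = (hs.reshape(T * B, d_h) @ params.W_a).reshape(T, B)
        if self.config.attention == "knowledge":
            scores = scores + (S @ params.V_a)
        e = nn.tanh(scores + params.b_a)
        alpha = nn.softmax(e, axis=0)
        return (alpha.reshape(T, B, 1) * hs).sum(axis=0)

    def forward_batch(self, samples: list[DisambiguationSample]) -> nn.Tensor:
        """(B, 2) softmax rows over (corrupt, correct)."""
        cfg = self.config
        B = len(samples)
        S = nn.Tensor(np.stack([self.id_vector(s.candidate_id)
                                for s in samples]))
        xL = nn.Tensor(np.stack([self._context_matrix(s.left_context)
                                 for s in samples], axis=1))
        xR = nn.Tensor(np.stack([self._context_matrix(s.right_context)
                                 for s in samples], axis=1))
        hL, lastL = self.enc_left(xL)
        hR, lastR = self.enc_right(xR)
        if cfg.attention in ("knowledge", "self"):
            oL = self._batched_attention(hL, S, self.att_left)
            oR = self._batched_attention(hR, S, self.att_right)
        elif cfg.attention == "none":
            oL, oR = lastL, lastR
        else:
            raise ValueError(f"unknown attention {cfg.attention!r}")
        g = nn.sigmoid(oL @ self.gate.W_g + oR @ self.gate.V_g
                       + self.gate.b_g).reshape(B, 1)
        z = g * oL + (1.0 - g) * oR
        feat = nn.concat([z, S], axis=-1)
        h = nn.relu(self.fc2(nn.relu(self.fc1(feat))))
        return nn.softmax(self.out(h), axis=-1)

    def forward(self, sample: DisambiguationSample) -> nn.Tensor:
        """Two-way softmax over (corrupt, correct)."""
        return self.forward_batch([sample]).reshape(2)

    def score(self, sample: DisambiguationSample) -> float:
        return float(self.forward(sample).data[1])

    def scores(self, samples: list[DisambiguationSample]) -> np.ndarray:
        return self.forward_batch(samples).data[:, 1]


def score_candidate(sample: DisambiguationSample,
                    model: DisambiguatorModel) -> float:
    """Probability that the candidate ID is the correct assignment."""
    return model.score(sample)


# ---------------------------------------------------------------------------
# negative sampling
# ---------------------------------------------------------------------------

def negative_samples(context: tuple[list[str], list[str]], gold_id: str,
                     candidates: CandidateSet | list[str], n_neg: int,
                     rng: np.random.Generator,
                     mention_surface: str = "") -> list[DisambiguationSample]:
    """Corrupt samples: same context, IDs drawn uniformly without
    replacement from the candidate set minus the gold ID."""
    pool = [c for c in candidates if c != gold_id]
    if not pool:
        return []
    take = min(n_neg, len(pool))
    chosen = rng.choice(len(pool), size=take, replace=False)
    left, right = context
    return [DisambiguationSample(left, right, pool[int(i)], 0,
                                 mention_surface)
            for i in chosen]


def build_training_samples(documents: list[Document], kb: KnowledgeBase,
                           n2: int = 10, n_neg: int = 2,
                           seed: int = 0) -> list[DisambiguationSample]:
    """Positive sample per gold-annotated mention plus sampled negatives."""
    rng = np.random.default_rng(seed)
    samples = []
    for doc in documents:
        for m in doc.mentions:
            if not m.gold_id or m.gold_id.startswith(GENERIC_PREFIX):
                continue
            context = extract_contexts(doc, m, n2)
            cands = kb_retrieve(m.surface, kb)
            samples.append(DisambiguationSample(
                context[0], context[1], m.gold_id, 1, m.surface))
            samples.extend(negative_samples(context, m.gold_id, cands,
                                            n_neg, rng, m.surface))
    return samples


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_disambiguator(samples: list[DisambiguationSample],
                        config: DisambiguatorConfig,
                        word_vectors: WordVectors,
                        id_embeddings: dict[str, np.ndarray],
                        held_out: list[DisambiguationSample] | None = None
                        ) -> DisambiguatorModel:
    """Cross-entropy training over correct/corrupt samples (Adagrad)."""
    model = DisambiguatorModel(config, word_vectors, id_embeddings)
    opt = nn.Adagrad(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed)
    best_state, best_acc = None, -1.0
    for epoch in range(config.epochs):
        order = rng.permutation(len(samples))
        total = 0.0
        for lo in range(0, len(order), config.batch_size):
            batch = [samples[i] for i in order[lo:lo + config.batch_size]]
            opt.zero_grad()
            probs = model.forward_batch(batch)
            labels = np.array([s.label for s in batch])
            picked = probs[np.arange(len(batch)), labels]
            loss = -(nn.log(picked + 1e-12).mean())
            value = loss.item()
            if not np.isfinite(value):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.clip_grad_norm(config.grad_clip)
            opt.step()
            total += value * len(batch)
        if held_out:
            acc = sample_accuracy(model, held_out)
            if acc > best_acc:
                best_acc = acc
                best_state = copy.deepcopy(model.state_arrays())
            logger.info("epoch %d: loss %.4f, held-out acc %.3f",
                        epoch, total / len(samples), acc)
        else:
            logger.info("epoch %d: loss %.4f", epoch, total / len(samples))
    if best_state is not None:
        model.load_state_arrays(best_state)
        model.best_held_out = best_acc
    return model


def sample_accuracy(model: DisambiguatorModel,
                    samples: list[DisambiguationSample]) -> float:
    """Binary accuracy of the correct/corrupt classifier."""
    if not samples:
        return 0.0
    hits = 0
    for lo in range(0, len(samples), 64):
        chunk = samples[lo:lo + 64]
        scores = model.scores(chunk)
        hits += int(sum((s >= 0.5) == bool(smp.label)
                        for s, smp in zip(scores, chunk)))
    return hits / len(samples)


# ---------------------------------------------------------------------------
# assignment
# ---------------------------------------------------------------------------

def assign_id(mention: MentionSpan, document: Document, kb: KnowledgeBase,
              model: DisambiguatorModel,
              nil_threshold: float | None = None) -> str:
    """Pick the highest-scoring candidate ID, or the generic fallback.

    An empty candidate set, or a best score below ``nil_threshold``, yields
    ``GENERIC:<type>``.  Ties break on candidate-set order (retrieval
    ranking).
    """
    if nil_threshold is None:
        nil_threshold = model.config.nil_threshold
    cands = kb_retrieve(mention.surface, kb)
    if not len(cands):
        return f"{GENERIC_PREFIX}:{mention.entity_type}"
    left, right = extract_contexts(document, mention, model.config.n2)
    scores = model.scores([DisambiguationSample(left, right, c, 1,
                                                mention.surface)
                           for c in cands.candidates])
    best = int(np.argmax(scores))
    if scores[best] < nil_threshold:
        return f"{GENERIC_PREFIX}:{mention.entity_type}"
    return cands.candidates[best]
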