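"""Entity-ID embeddings from Mention-Variant-ID structure via an autoencoder.

The model treats the KB as a bipartite graph: mention surfaces on one side,
entity IDs on the other, with an edge wherever a variant links them.  Its
two premises: an ID is the sum of its variants, and a mention is the sum of
its variants.  Encoding distributes each mention vector over its edges with
per-edge diagonal matrices E(i,j) constrained so that, per mention,
sum_j E(i,j) = I (each mention's activation mass is split, not created);
IDs are the sums of the incoming variant vectors.  Decoding runs the mirror
map with unconstrained diagonal matrices D(j,i), and training aligns both
the reconstructed mentions and the per-edge variant vectors from the two
directions:

    Loss = alpha * sum_i ||m_bar(i) - m(i)||^2
         + beta  * sum_(i,j) ||E(i,j) m(i) - D(j,i) s(j)||^2,

with alpha + beta = 1 and alpha = beta = 0.5 by default.  The constraint on
E is enforced structurally: E diagonals are a per-dimension softmax over
each mention's edges, so it holds exactly after every optimization step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .knowledge_kb import KnowledgeBase, normalize_tokens
from .vectors import WordVectors

logger = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    pass


@dataclass
class MentionVariantIDGraph:
    mentions: list[str]                       # mention surfaces, index i
    ids: list[str]                            # entity IDs, index j
    edges: list[tuple[int, int]]              # (i, j) pairs, one per variant link
    mention_vectors: np.ndarray               # (n_mentions, d)

    def __post_init__(self):
        for i, j in self.edges:
            if not (0 <= i < len(self.mentions) and 0 <= j < len(self.ids)):
                raise ValueError(f"edge ({i},{j}) references a missing node")

    def edges_of_mention(self, i: int) -> list[int]:
        return [e for e, (mi, _) in enumerate(self.edges) if mi == i]


def build_graph(kb: KnowledgeBase, word_vectors: WordVectors
                ) -> MentionVariantIDGraph:
    mentions = sorted({r.mention for r in kb.records})
    ids = sorted({r.entity_id for r in kb.records})
    m_idx = {m: i for i, m in enumerate(mentions)}
    id_idx = {s: j for j, s in enumerate(ids)}
    edge_set = sorted({(m_idx[r.mention], id_idx[r.entity_id])
                       for r in kb.records})
    vectors = np.stack([_mention_vector(m, word_vectors) for m in mentions])
    return MentionVariantIDGraph(mentions, ids, edge_set, vectors)


def _mention_vector(mention: str, wv: WordVectors) -> np.ndarray:
    words = [w for w in normalize_tokens(mention, strip_brackets=False)]
    in_vocab = [w for w in words if w in wv]
    if not in_vocab:
        logger.warning("mention %r has no in-vocabulary words; using UNK",
                       mention)
        return wv.get("<UNK>")
    return np.mean([wv.get(w) for w in in_vocab], axis=0)


def init_mention_embeddings(kb: KnowledgeBase, word_vectors: WordVectors
                            ) -> dict[str, np.ndarray]:
    """Mention vectors: the mean word vector of each mention's words."""
    return {m: _mention_vector(m, word_vectors)
            for m in sorted({r.mention for r in kb.records})}


class AutoencoderModel(nn.Module):
    """Per-edge diagonal encode/decode matrices over a bipartite graph.

    ``E`` diagonals are produced by a per-dimension softmax of ``e_logits``
    over each mention's edges, which makes sum_j E(i,j) = I structural.
    ``D`` diagonals are unconstrained.
    """

    def __init__(self, graph: MentionVariantIDGraph, alpha: float = 0.5,
                 beta: float = 0.5, seed: int = 0):
        if abs(alpha + beta - 1.0) > 1e-12:
            raise ValueError("alpha + beta must equal 1")
        rng = np.random.default_rng(seed)
        d = graph.mention_vectors.shape[1]
        n_edges = len(graph.edges)
        self.graph = graph
        self.alpha = alpha
        self.beta = beta
        self.e_logits = nn.Tensor(rng.normal(0, 0.01, (n_edges, d)),
                                  requires_grad=True)
        self.d_diag = nn.Tensor(np.ones((n_edges, d)), requires_grad=True)
        self._mention_edges = [graph.edges_of_mention(i)
                               for i in range(len(graph.mentions))]

    # -- structural E --------------------------------------------------------
    def encode_diagonals(self) -> nn.Tensor:
        """(n_edges, d) matrix of E diagonals, softmax-grouped by mention."""
        parts: list = [None] * len(self.graph.edges)
        for edges in self._mention_edges:
            block = nn.softmax(self.e_logits[np.asarray(edges)], axis=0)
            for row, e in enumerate(edges):
                parts[e] = block[row]
        return nn.stack(parts, axis=0)


def encode_ids(graph: MentionVariantIDGraph, model: AutoencoderModel,
               _tensors: bool = False):
    """Eq.-level encode: s(j) = sum_i E(i,j) m(i) over incident edges."""
    E = model.encode_diagonals()
    M = nn.Tensor(graph.mention_vectors)
    variant_vecs = E * M[np.asarray([i for i, _ in graph.edges])]
    cols = []
    for j in range(len(graph.ids)):
        incident = [e for e, (_, jj) in enumerate(graph.edges) if jj == j]
        cols.append(variant_vecs[np.asarray(incident)].sum(axis=0))
    S = nn.stack(cols, axis=0)
    if _tensors:
        return S, variant_vecs
    return S.data


def decode_mentions(graph: MentionVariantIDGraph, model: AutoencoderModel,
                    id_vectors=None, _tensors: bool = False):
    """Eq.-level decode: m_bar(i) = sum_j D(j,i) s(j); also returns the
    per-edge decoded variants v_bar(i,j) = D(j,i) s(j)."""
    if id_vectors is None or _tensors:
        S, _ = encode_ids(graph, model, _tensors=True)
    else:
        S = nn.Tensor(np.asarray(id_vectors))
    decoded_variants = model.d_diag * S[np.asarray([j for _, j in graph.edges])]
    rows = []
    for i in range(len(graph.mentions)):
        incident = [e for e, (ii, _) in enumerate(graph.edges) if ii == i]
        rows.append(decoded_variants[np.asarray(incident)].sum(axis=0))
    M_bar = nn.stack(rows, axis=0)
    if _tensors:
        return M_bar, decoded_variants
    return M_bar.data, decoded_variants.data


def autoencoder_loss(graph: MentionVariantIDGraph,
                     model: AutoencoderModel, _tensor: bool = False):
    """Weighted reconstruction + variant-alignment loss (squared L2)."""
    S, encoded_variants = encode_ids(graph, model, _tensors=True)
    decoded_variants = model.d_diag * S[np.asarray([j for _, j in graph.edges])]
    rows = []
    for i in range(len(graph.mentions)):
        incident = [e for e, (ii, _) in enumerate(graph.edges) if ii == i]
        rows.append(decoded_variants[np.asarray(incident)].sum(axis=0))
    M_bar = nn.stack(rows, axis=0)
    M = nn.Tensor(graph.mention_vectors)
    recon = ((M_bar - M) ** 2).sum()
    align = ((encoded_variants - decoded_variants) ** 2).sum()
    loss = model.alpha * recon + model.beta * align
    return loss if _tensor else loss.item()


def constraint_violation(model: AutoencoderModel) -> float:
    """max | sum_j E(i,j) - 1 | over mentions and dimensions."""
    E = model.encode_diagonals().data
    worst = 0.0
    for edges in model._mention_edges:
        worst = max(worst, float(np.max(np.abs(E[edges].sum(axis=0) - 1.0))))
    return worst


@dataclass
class AutoencoderConfig:
    seed: int = 0
    lr: float = 0.05
    epochs: int = 300
    alpha: float = 0.5
    beta: float = 0.5
    dim: int | None = None    # defaults to the word-vector dimension


def train_id_embeddings(kb: KnowledgeBase, word_vectors: WordVectors,
                        config: AutoencoderConfig | None = None
                        ) -> tuple[AutoencoderModel, dict[str, np.ndarray]]:
    """Fit the autoencoder on a KB; returns the model and ID vectors.

    Full-batch gradient descent with a fixed seed; the E constraint holds
    after every step by parameterization.  Divergence (non-finite loss)
    raises :class:`TrainingError`.
    """
    config = config or AutoencoderConfig()
    graph = build_graph(kb, word_vectors)
    model = AutoencoderModel(graph, config.alpha, config.beta, config.seed)
    opt = nn.SGD(model.parameters(), lr=config.lr)
    initial = autoencoder_loss(graph, model)
    last = initial
    for epoch in range(config.epochs):
        opt.zero_grad()
        loss = autoencoder_loss(graph, model, _tensor=True)
        value = loss.item()
        if not np.isfinite(value):
            raise TrainingError(
                f"autoencoder loss non-finite at epoch {epoch} "
                f"(last finite loss {last:.4g}; try a smaller lr)")
        loss.backward()
        opt.step()
        last = value
    logger.info("autoencoder: loss %.6g -> %.6g over %d epochs",
                initial, last, config.epochs)
    S = encode_ids(graph, model)
    return model, {entity_id: S[j] for j, entity_id in enumerate(graph.ids)}


def write_id_embeddings(vectors: dict[str, np.ndarray], path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for entity_id, vec in vectors.items():
            fh.write(entity_id + "\t" + "\t".join(f"{x:.6f}" for x in vec) + "\n")


def read_id_embeddings(path) -> dict[str, np.ndarray]:
    out = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out[parts[0]] = np.array([float(x) for x in parts[1:]])
    return out
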