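"""Word vectors in word2vec text format, plus the contextual-layer provider.

The contextual provider emulates the *interface* of a pre-trained multi-layer
bidirectional language model: per token it yields one vector per layer, which
the recognizer combines with a learned scaled softmax-weighted sum.  The
bundled default is a deterministic stub — a seeded random projection of a
growing window of word vectors — so the pipeline runs at desk scale without
an external biLM; externally computed layers plug in through the same
interface.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

UNK_TOKEN = "<UNK>"


class WordVectors:
    """In-memory word -> vector table with a fixed UNK fallback."""

    def __init__(self, table: dict[str, np.ndarray]):
        if not table:
            raise ValueError("empty word-vector table")
        dims = {v.shape[0] for v in table.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent vector dimensions: {dims}")
        self.dim = dims.pop()
        self.table = {w: np.asarray(v, dtype=np.float64)
                      for w, v in table.items()}
        if UNK_TOKEN not in self.table:
            rng = np.random.default_rng(12345)
            self.table[UNK_TOKEN] = rng.normal(0.0, 0.1, self.dim)

    def __contains__(self, word):
        return word in self.table or word.lower() in self.table

    def __len__(self):
        return len(self.table)

    def get(self, word: str) -> np.ndarray:
        v = self.table.get(word)
        if v is None:
            v = self.table.get(word.lower())
        return v if v is not None else self.table[UNK_TOKEN]

    def matrix(self, vocab: list[str]) -> np.ndarray:
        return np.stack([self.get(w) for w in vocab])


def read_word2vec(path) -> WordVectors:
    """Read the word2vec *text* format: a ``count dim`` header line, then
    one ``word v1 ... vD`` line per word."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header {header}")
        n, dim = int(header[0]), int(header[1])
        table = {}
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(f"{path}: row for {parts[0]!r} has "
                                 f"{len(parts) - 1} values, expected {dim}")
            table[parts[0]] = np.array([float(x) for x in parts[1:]])
    if len(table) != n:
        logger.warning("%s: header says %d words, read %d", path, n, len(table))
    return WordVectors(table)


def write_word2vec(table: dict[str, np.ndarray] | WordVectors, path) -> None:
    if isinstance(table, WordVectors):
        table = table.table
    dim = next(iter(table.values())).shape[0]
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(table)} {dim}\n")
        for word, vec in table.items():
            fh.write(word + " " + " ".join(f"{x:.6f}" for x in vec) + "\n")


class StubContextualProvider:
    """Deterministic stand-in for biLM layer states.

    Layer ``j`` is a fixed random projection (seeded, tanh-squashed) of the
    mean word vector in a +-``j`` token window, so deeper layers see wider
    context — enough structure to exercise the layer-combination math and
    keep every run bit-reproducible.
    """

    def __init__(self, dim_in: int, width: int = 32, n_layers: int = 3,
                 seed: int = 202):
        rng = np.random.default_rng(seed)
        self.width = width
        self.n_layers = n_layers
        self.projections = [rng.normal(0.0, 1.0 / np.sqrt(dim_in),
                                       size=(dim_in, width))
                            for _ in range(n_layers)]

    def __call__(self, word_vecs: np.ndarray) -> np.ndarray:
        """(n, dim_in) word vectors -> (n_layers, n, width) layer states."""
        n = word_vecs.shape[0]
        layers = []
        for j, proj in enumerate(self.projections):
            ctx = np.empty_like(word_vecs)
            for t in range(n):
                lo, hi = max(0, t - j), min(n, t + j + 1)
                ctx[t] = word_vecs[lo:hi].mean(axis=0)
            layers.append(np.tanh(ctx @ proj))
        return np.stack(layers)
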