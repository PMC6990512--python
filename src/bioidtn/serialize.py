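"""Single-file model checkpoints (numpy archive with embedded JSON config)."""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .disambiguator import DisambiguatorConfig, DisambiguatorModel
from .recognizer import RecognizerConfig, RecognizerModel
from .vectors import WordVectors


def _wv_arrays(wv: WordVectors):
    words = sorted(wv.table)
    return words, np.stack([wv.table[w] for w in words])


def _wv_restore(words, matrix) -> WordVectors:
    return WordVectors({w: matrix[i] for i, w in enumerate(words)})


def save_recognizer(model: RecognizerModel, path) -> None:
    words, matrix = _wv_arrays(model.word_vectors)
    meta = {
        "kind": "recognizer",
        "config": dataclasses.asdict(model.config),
        "vocab": sorted(model.vocab, key=model.vocab.get),
        "char_vocab": sorted(model.char_vocab, key=model.char_vocab.get),
        "pos_vocab": sorted(model.pos_vocab, key=model.pos_vocab.get),
        "chunk_vocab": sorted(model.chunk_vocab, key=model.chunk_vocab.get),
    }
    params = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=json.dumps(meta), wv_words=json.dumps(words),
             wv_matrix=matrix, **params)


def load_recognizer(path) -> RecognizerModel:
    archive = np.load(path, allow_pickle=False)
    meta = json.loads(str(archive["meta"]))
    if meta.get("kind") != "recognizer":
        raise ValueError(f"{path} is not a recognizer checkpoint")
    cfg = meta["config"]
    cfg["entity_types"] = tuple(cfg["entity_types"])
    wv = _wv_restore(json.loads(str(archive["wv_words"])),
                     archive["wv_matrix"])
    model = RecognizerModel(RecognizerConfig(**cfg), wv, meta["vocab"],
                            meta["char_vocab"], meta["pos_vocab"],
                            meta["chunk_vocab"])
    n = len(model.parameters())
    model.load_state_arrays([archive[f"param_{i}"] for i in range(n)])
    return model


def save_disambiguator(model: DisambiguatorModel, path) -> None:
    words, matrix = _wv_arrays(model.word_vectors)
    ids = sorted(model.id_embeddings)
    meta = {"kind": "disambiguator",
            "config": dataclasses.asdict(model.config), "ids": ids}
    id_matrix = (np.stack([model.id_embeddings[i] for i in ids])
                 if ids else np.zeros((0, model.d_id)))
    params = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=json.dumps(meta), wv_words=json.dumps(words),
             wv_matrix=matrix, id_matrix=id_matrix, **params)


def load_disambiguator(path) -> DisambiguatorModel:
    archive = np.load(path, allow_pickle=False)
    meta = json.loads(str(archive["meta"]))
    if meta.get("kind") != "disambiguator":
        raise ValueError(f"{path} is not a disambiguator checkpoint")
    wv = _wv_restore(json.loads(str(archive["wv_words"])),
                     archive["wv_matrix"])
    id_embeddings = {entity_id: archive["id_matrix"][i]
                     for i, entity_id in enumerate(meta["ids"])}
    model = DisambiguatorModel(DisambiguatorConfig(**meta["config"]), wv,
                               id_embeddings)
    n = len(model.parameters())
    model.load_state_arrays([archive[f"param_{i}"] for i in range(n)])
    return model
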