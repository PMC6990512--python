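"""End-to-end orchestration: feature extraction -> recognition -> normalization.

``run_pipeline`` executes the full workflow from one :class:`RunConfig`:
generate or load corpus/KB/vectors, learn ID embeddings, train the
recognizer and the disambiguator, predict on held-out documents, and score
recognition (strict/overlap) and normalization (micro/macro) together with
the four-way error breakdown and a random-candidate baseline.  One global
seed derives every stage seed, so a rerun is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .corpus_io import Document, GENERIC_PREFIX, read_documents, write_documents
from .disambiguator import (DisambiguatorConfig, assign_id,
                            build_training_samples, sample_accuracy,
                            train_disambiguator)
from .evaluation import (corpus_stats, error_breakdown, score_nen, score_ner)
from .id_embeddings import AutoencoderConfig, train_id_embeddings
from .knowledge_kb import build_kb, kb_retrieve, read_kb_tsv
from .recognizer import RecognizerConfig, train_recognizer
from .synthetic_data import SynthConfig, generate_corpus, generate_kb
from .vectors import read_word2vec

logger = logging.getLogger(__name__)


def _presets():
    from .presets import (desk_autoencoder_config, desk_disambiguator_config,
                          desk_recognizer_config, desk_synth_config)
    return (desk_synth_config(), desk_recognizer_config(),
            desk_autoencoder_config(), desk_disambiguator_config())


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    corpus_path: str | None = None
    kb_path: str | None = None
    vectors_path: str | None = None
    out_dir: str = "run_output"
    test_fraction: float = 0.2
    synth: SynthConfig = field(default_factory=lambda: _presets()[0])
    recognizer: RecognizerConfig = field(default_factory=lambda: _presets()[1])
    autoencoder: AutoencoderConfig = field(default_factory=lambda: _presets()[2])
    disambiguator: DisambiguatorConfig = field(
        default_factory=lambda: _presets()[3])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in payload:
                continue
            value = payload[f.name]
            if dataclasses.is_dataclass(f.type) or f.name in (
                    "synth", "recognizer", "autoencoder", "disambiguator"):
                sub = {"synth": SynthConfig, "recognizer": RecognizerConfig,
                       "autoencoder": AutoencoderConfig,
                       "disambiguator": DisambiguatorConfig}[f.name]
                value = sub(**value)
            kwargs[f.name] = value
        return cls(**kwargs)

    def resolved(self) -> dict:
        return asdict(self)


def _hash_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _derive(config: RunConfig) -> dict[str, int]:
    """Per-stage seeds derived deterministically from the global seed."""
    base = config.seed
    return {"synth": base * 31 + 1, "split": base * 31 + 2,
            "autoencoder": base * 31 + 3, "recognizer": base * 31 + 4,
            "sampling": base * 31 + 5, "disambiguator": base * 31 + 6,
            "baseline": base * 31 + 7}


@dataclass
class PipelineResult:
    reports: dict
    predictions: list[Document]
    out_dir: Path


def random_baseline_predictions(documents: list[Document], kb,
                                seed: int) -> list[Document]:
    """Gold spans with a uniformly random retrieved candidate as the ID."""
    rng = np.random.default_rng(seed)
    out = []
    for doc in documents:
        mentions = []
        for m in doc.mentions:
            cands = list(kb_retrieve(m.surface, kb))
            pred = (cands[int(rng.integers(len(cands)))] if cands
                    else f"{GENERIC_PREFIX}:{m.entity_type}")
            mentions.append(dataclasses.replace(m, predicted_id=pred))
        out.append(Document(doc.doc_id, doc.text, mentions))
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    seeds = _derive(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # ---- stage: inputs -----------------------------------------------------
    try:
        if config.corpus_path:
            documents = read_documents(config.corpus_path)
            records = read_kb_tsv(config.kb_path)
            word_vectors = read_word2vec(config.vectors_path)
            for name, p in (("corpus", config.corpus_path),
                            ("kb", config.kb_path),
                            ("vectors", config.vectors_path)):
                logger.info("input %s sha256=%s", name, _hash_file(p))
        else:
            synth = dataclasses.replace(config.synth, seed=seeds["synth"])
            records = generate_kb(synth)
            documents, word_vectors = generate_corpus(records, synth)
            logger.info("generated %d documents from synthetic preset",
                        len(documents))
        kb = build_kb(records)
    except Exception as e:                                  # noqa: BLE001
        raise StageError("inputs", e) from e

    rng = np.random.default_rng(seeds["split"])
    order = rng.permutation(len(documents))
    n_test = max(1, int(config.test_fraction * len(documents)))
    test_docs = [documents[i] for i in order[:n_test]]
    train_docs = [documents[i] for i in order[n_test:]]

    # ---- stage: ID representation learning ---------------------------------
    try:
        ae_cfg = dataclasses.replace(config.autoencoder,
                                     seed=seeds["autoencoder"])
        _, id_embeddings = train_id_embeddings(kb, word_vectors, ae_cfg)
    except Exception as e:                                  # noqa: BLE001
        raise StageError("id_embeddings", e) from e

    # ---- stage: recognition ------------------------------------------------
    try:
        rec_cfg = dataclasses.replace(config.recognizer,
                                      seed=seeds["recognizer"])
        recognizer = train_recognizer(train_docs, kb, rec_cfg, word_vectors)
    except Exception as e:                                  # noqa: BLE001
        raise StageError("recognizer", e) from e

    # ---- stage: disambiguation ---------------------------------------------
    try:
        dis_cfg = dataclasses.replace(config.disambiguator,
                                      seed=seeds["disambiguator"])
        samples = build_training_samples(train_docs, kb, dis_cfg.n2,
                                         dis_cfg.n_neg, seeds["sampling"])
        disambiguator = train_disambiguator(samples, dis_cfg, word_vectors,
                                            id_embeddings)
    except Exception as e:                                  # noqa: BLE001
        raise StageError("disambiguator", e) from e

    # ---- stage: prediction -------------------------------------------------
    try:
        predictions = []
        cand_sets = []
        for doc in test_docs:
            spans = recognizer.predict_document(doc, kb)
            doc_cands = {}
            for m in spans:
                cands = kb_retrieve(m.surface, kb)
                doc_cands[(m.start, m.end, m.entity_type)] = list(cands)
                m.predicted_id = assign_id(m, doc, kb, disambiguator)
            predictions.append(Document(doc.doc_id, doc.text, spans))
            cand_sets.append(doc_cands)
        write_documents(predictions, out_dir / "predictions.json")
    except Exception as e:                                  # noqa: BLE001
        raise StageError("prediction", e) from e

    # ---- stage: evaluation -------------------------------------------------
    try:
        gold = [d.mentions for d in test_docs]
        pred = [d.mentions for d in predictions]
        baseline_docs = random_baseline_predictions(test_docs, kb,
                                                    seeds["baseline"])
        base_pred = [d.mentions for d in baseline_docs]
        micro = score_nen(gold, pred, "micro")
        macro = score_nen(gold, pred, "macro")
        base_micro = score_nen(gold, base_pred, "micro")
        strict = score_ner(gold, pred, "strict")
        overlap = score_ner(gold, pred, "overlap")
        breakdown = error_breakdown(gold, pred, cand_sets)
        stats = corpus_stats(documents)
        reports = {
            "resolved_config": config.resolved(),
            "n_train_documents": len(train_docs),
            "n_test_documents": len(test_docs),
            "ner": {
                "strict": {"precision": strict.precision,
                           "recall": strict.recall, "f1": strict.f1},
                "overlap": {"precision": overlap.precision,
                            "recall": overlap.recall, "f1": overlap.f1},
                "best_val_f1": getattr(recognizer, "best_val_f1", None),
            },
            "nen": {
                "micro": {"precision": micro.precision, "recall": micro.recall,
                          "f1": micro.f1},
                "macro": {"precision": macro.precision, "recall": macro.recall,
                          "f1": macro.f1},
                "random_candidate_baseline_micro_f1": base_micro.f1,
            },
            "error_breakdown": {"counts": breakdown.counts,
                                "percentages": breakdown.percentages},
            "corpus_stats": dataclasses.asdict(stats),
            "wall_time_s": round(time.time() - t0, 1),
        }
        (out_dir / "report.json").write_text(json.dumps(reports, indent=1))
        (out_dir / "resolved_config.yaml").write_text(
            yaml.safe_dump(config.resolved()))
        _write_report_tsv(reports, out_dir / "report.tsv")
    except Exception as e:                                  # noqa: BLE001
        raise StageError("evaluation", e) from e

    return PipelineResult(reports, predictions, out_dir)


def _write_report_tsv(reports: dict, path: Path) -> None:
    rows = []
    for mode in ("strict", "overlap"):
        r = reports["ner"][mode]
        rows.append(("ner", mode, r["precision"], r["recall"], r["f1"]))
    for mode in ("micro", "macro"):
        r = reports["nen"][mode]
        rows.append(("nen", mode, r["precision"], r["recall"], r["f1"]))
    with path.open("w") as fh:
        fh.write("task\tmode\tprecision\trecall\tf1\n")
        for row in rows:
            fh.write("\t".join(
                f"{v:.4f}" if isinstance(v, float) else str(v)
                for v in row) + "\n")
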