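"""Desk-scale study presets.

The model-config classes default to the full-scale hyperparameters
(embedding dims 200/50/25/10/15, RMSProp 1e-3, Adagrad 5e-4, batch 8).
These presets are the package's canonical scaled-down conditions for the
bundled synthetic benchmark: smaller embedding widths sized to the
synthetic vocabulary, and a disambiguator learning rate scaled up to
compensate for having ~100x fewer gradient steps per epoch than a
corpus-scale run (a few hundred training samples at batch 8).
"""

from __future__ import annotations

from .disambiguator import DisambiguatorConfig
from .id_embeddings import AutoencoderConfig
from .recognizer import RecognizerConfig
from .synthetic_data import SynthConfig


def desk_synth_config(seed: int = 0) -> SynthConfig:
    """The planted-signal synthetic benchmark: 30 IDs, 200 caption-like
    documents, keyword co-occurrence 0.95."""
    return SynthConfig(seed=seed, n_ids=30, n_documents=200,
                       tokens_per_document=20, vector_dim=32,
                       entity_density=0.15, planted_signal_strength=0.95)


def desk_recognizer_config(seed: int = 0, **overrides) -> RecognizerConfig:
    base = dict(seed=seed, char_emb_dim=16, char_hidden=8, pos_dim=8,
                chunk_dim=4, kf_dim=8, elmo_width=16, hidden=32,
                max_epochs=8, patience=3)
    base.update(overrides)
    return RecognizerConfig(**base)


def desk_disambiguator_config(seed: int = 0, **overrides
                              ) -> DisambiguatorConfig:
    base = dict(seed=seed, encoder="BiGRU", attention="knowledge",
                hidden=24, fc_hidden=64, elmo_width=8, epochs=40, lr=0.03)
    base.update(overrides)
    return DisambiguatorConfig(**base)


def desk_autoencoder_config(seed: int = 0) -> AutoencoderConfig:
    return AutoencoderConfig(seed=seed, epochs=200)
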