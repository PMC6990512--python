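import numpy as np
import pytest

from bioidtn.corpus_io import Document, MentionSpan
from bioidtn.knowledge_kb import build_kb
from bioidtn.synthetic_data import fig1_records
from bioidtn.vectors import WordVectors

FIG5_TEXT = ("SyGCaMP5 and MtDsRed or myc - ΔEF - Miro1 - IRES - MtDsRed "
             "( ΔEF Miro ) with and without TTX treatments")


@pytest.fixture
def fig1_kb():
    return build_kb(fig1_records())


@pytest.fixture
def fig5_document():
    """The worked sentence: three annotated mentions over 22 tokens."""
    mentions = []
    for surface in ("myc", "Miro1", "TTX"):
        start = FIG5_TEXT.index(surface)
        mentions.append(MentionSpan(start, start + len(surface), surface,
                                    "gene"))
    return Document("fig5", FIG5_TEXT, mentions)


@pytest.fixture
def tiny_vectors():
    rng = np.random.default_rng(42)
    words = ["vegf", "(", "human", ")", "pig", "mvcd1", "vpf",
             "level", "the", "expression"]
    return WordVectors({w: rng.normal(0, 1, 8) for w in words})
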