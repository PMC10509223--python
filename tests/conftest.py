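"""Shared fixtures: a small hand-built isoform database and helpers."""
from __future__ import annotations

import numpy as np
import pytest

from sepepkit.proteome import ProteinRecord, ProteomeDatabase


@pytest.fixture
def tiny_db() -> ProteomeDatabase:
    """Three-isoform gene, single-isoform gene, and a two-gene shared peptide.

    GENEA isoforms share ``AAAWWWK``; ``CCCDDDK`` is specific to A.P1,
    ``EEEFFFK`` to A.P1/A.P2 (partial), and ``GGGHHHK`` occurs in both
    GENEA.P1 and GENEB.Q1 (multi-gene).
    """
    return ProteomeDatabase(
        [
            ProteinRecord("A.P1", "GENEA", "AAAWWWKCCCDDDKEEEFFFKGGGHHHK"),
            ProteinRecord("A.P2", "GENEA", "AAAWWWKEEEFFFK"),
            ProteinRecord("A.P3", "GENEA", "AAAWWWKMMMNNNK"),
            ProteinRecord("B.Q1", "GENEB", "GGGHHHKTTTSSSK"),
        ]
    )


def make_evidence_array(values):
    return np.asarray(values, dtype=float)
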