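"""Shared fixtures: toy transcripts, toy domain maps, and the independent
decision-table oracle used to cross-check the REC classifier.

The toy transcript has 5 exons (cDNA 1-600): exon 1 carries a 10-nt 5'UTR
plus 90 coding nt, exon 2 is in-frame on skip (150 coding nt), exons 3 and
4 frameshift on skip (127 and 113 coding nt), exon 5 carries the last 60
coding nt plus a 50-nt 3'UTR.  CDS = 540 nt -> 179-aa protein.
"""

from __future__ import annotations

import numpy as np
import pytest

from rb1rec.domains import DomainMap, Segment, SegmentKind
from rb1rec.transcript import Exon, TranscriptModel

STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = [
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in STOPS
]

TOY_EXONS = (
    Exon(1, 1, 100),
    Exon(2, 101, 250),
    Exon(3, 251, 377),
    Exon(4, 378, 490),
    Exon(5, 491, 600),
)
TOY_CDS_START = 11   # 10-nt 5'UTR
TOY_CDS_LEN = 540    # 179-aa protein + stop


def _toy_cds(seed: int = 11) -> str:
    rng = np.random.default_rng(seed)
    codons = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), TOY_CDS_LEN // 3 - 2)]
    return "ATG" + "".join(codons) + "TAA"


@pytest.fixture(scope="session")
def toy_transcript() -> TranscriptModel:
    tm = TranscriptModel(
        gene_symbol="TOY",
        exons=TOY_EXONS,
        cds_start_cdna=TOY_CDS_START,
        cds_end_cdna=TOY_CDS_START + TOY_CDS_LEN - 1,
        cds_sequence=_toy_cds(),
        version="toy",
    )
    assert tm.protein_length == 179
    # frame classes the splice tests rely on
    assert tm.coding_length_of_exon(2) % 3 == 0
    assert tm.coding_length_of_exon(3) % 3 != 0
    assert tm.coding_length_of_exon(4) % 3 != 0
    return tm


@pytest.fixture(scope="session")
def toy_transcript_noseq(toy_transcript) -> TranscriptModel:
    from dataclasses import replace

    return replace(toy_transcript, cds_sequence=None)


@pytest.fixture(scope="session")
def toy_domain_map() -> DomainMap:
    return DomainMap(
        protein_length=179,
        segments=(
            Segment("N-link", 1, 20, SegmentKind.LINKER),
            Segment("dom-A", 21, 90, SegmentKind.STRUCTURED),
            Segment("mid-link", 91, 110, SegmentKind.LINKER),
            Segment("dom-B", 111, 170, SegmentKind.STRUCTURED),
            Segment("C-tail", 171, 179, SegmentKind.STRUCTURED),
        ),
    )


# ---------------------------------------------------------------------------
# Independent helpers (oracle side)
# ---------------------------------------------------------------------------

def hand_first_stop(seq: str):
    """Codon-walk translation oracle: 1-based index of the first stop codon."""
    for i in range(0, len(seq) // 3 * 3, 3):
        if seq[i : i + 3] in STOPS:
            return i // 3 + 1
    return None


def brute_force_exon(c_base: int, tm: TranscriptModel) -> int:
    """Exon of a coding base by scanning a flat base->exon list."""
    t = c_base + tm.cds_start_cdna - 1
    lookup = []
    for ex in tm.exons:
        lookup.extend([ex.index] * (ex.cdna_end - ex.cdna_start + 1))
    return lookup[t - 1]
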