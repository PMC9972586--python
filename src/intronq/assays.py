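"""Published intronic GAPDH assay definitions.

These are the species-discriminating genomic qPCR oligo sets for human
and mouse GAPDH: each primer sits on an intron flanking a short exon
(human: introns 3/4; mouse: introns 1/2), so only genomic DNA amplifies.
Validating them end-to-end requires the real genomic regions
(GRCh38 chr12 for human GAPDH; GRCm39 chr6 for mouse Gapdh) and is left
to optional integration tests.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PublishedAssay", "HUMAN_GAPDH_INTRONIC", "MOUSE_GAPDH_INTRONIC", "PUBLISHED_ASSAYS"]


@dataclass(frozen=True)
class PublishedAssay:
    name: str
    species: str
    gene: str
    forward: str  # 5'->3'
    reverse: str  # 5'->3'
    probe: str | None
    expected_amplicon_len: int
    reporter: str = "FAM"
    quencher: str = "TAMRA"


HUMAN_GAPDH_INTRONIC = PublishedAssay(
    name="hGAPDH.int3F-int4R",
    species="human",
    gene="GAPDH",
    forward="CTGACTCAGCCCTGCAAAG",
    reverse="CCTGCCTTCCTCACCTGAT",
    probe="ACTGTCTGCTTCTCTGCTGTAGGCTCA",
    expected_amplicon_len=189,
)

MOUSE_GAPDH_INTRONIC = PublishedAssay(
    name="mGapdh.int1F-int2R",
    species="mouse",
    gene="Gapdh",
    forward="GGCCACGCTAATCTCATTTT",
    reverse="AAGGCGGAGTTACCAGAGGT",
    probe="CGAGCCATCGCCAGGTCCGAGC",
    expected_amplicon_len=260,
)

PUBLISHED_ASSAYS = (HUMAN_GAPDH_INTRONIC, MOUSE_GAPDH_INTRONIC)
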