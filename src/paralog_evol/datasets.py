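"""Published domain organisation of the human type IB topoisomerases.

Coordinates are 1-based inclusive residue positions on the human reference
proteins: TOP1 (765 aa, nuclear) and TOP1MT (601 aa, mitochondrially
targeted but nuclear-encoded). These tables are inputs to conservation and
variant-annotation analyses; region lengths are always computed from the
coordinates (end - start + 1), never taken on faith from any printed length.
"""

from __future__ import annotations

from .seqio import RegionAnnotation

TOP1_ID = "HUMAN_TOP1"
TOP1MT_ID = "HUMAN_TOP1MT"

TOP1_LENGTH = 765
TOP1MT_LENGTH = 601

#: Major domains of human TOP1 (CAP + Hinge + CAT form the core domain).
TOP1_DOMAINS = [
    RegionAnnotation("N-terminal", TOP1_ID, 1, 213),
    RegionAnnotation("CAP", TOP1_ID, 214, 427),
    RegionAnnotation("Hinge", TOP1_ID, 428, 432),
    RegionAnnotation("CAT", TOP1_ID, 433, 635),
    RegionAnnotation("Linker", TOP1_ID, 636, 714),
    RegionAnnotation("C-terminal", TOP1_ID, 715, 765),
]

#: Major domains of human TOP1MT.
TOP1MT_DOMAINS = [
    RegionAnnotation("N-terminal", TOP1MT_ID, 1, 49),
    RegionAnnotation("CAP", TOP1MT_ID, 50, 263),
    RegionAnnotation("Hinge", TOP1MT_ID, 264, 268),
    RegionAnnotation("CAT", TOP1MT_ID, 269, 470),
    RegionAnnotation("Linker", TOP1MT_ID, 471, 550),
    RegionAnnotation("C-terminal", TOP1MT_ID, 551, 601),
]

#: N-terminal sorting elements (overlap the N-terminal domain, so they are
#: kept separate from the non-overlapping domain lists above).
TOP1_NLS = [
    RegionAnnotation("NLS", TOP1_ID, 117, 146),
    RegionAnnotation("NLS-I", TOP1_ID, 59, 65),
    RegionAnnotation("NLS-II", TOP1_ID, 150, 156),
    RegionAnnotation("NLS-III", TOP1_ID, 174, 180),
    RegionAnnotation("NLS-IV", TOP1_ID, 192, 198),
]
TOP1MT_MTS = RegionAnnotation("MTS", TOP1MT_ID, 1, 40)

#: The fully conserved six-residue catalytic stretch of TOP1 (contains the
#: active-site arginine at 590).
CONSERVED_MOTIF = "AKVFRT"
CONSERVED_MOTIF_START = 586  # TOP1 reference positions 586-591

#: Published comparison counts: genes with two or more amino-acid changes
#: between present-day humans and Neanderthals, out of the human gene count.
GENES_WITH_MULTIPLE_AA_CHANGES = 68
HUMAN_GENE_COUNT = 19969


def fraction_genes_with_multiple_aa_changes() -> float:
    """Percentage of human genes with >= 2 human-Neanderthal amino-acid
    changes (68 of 19,969 genes)."""
    return 100.0 * GENES_WITH_MULTIPLE_AA_CHANGES / HUMAN_GENE_COUNT
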