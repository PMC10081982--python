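"""Readers and writers for every external format the pipeline touches.

All user-facing coordinates are 1-based inclusive (protein residue positions,
genomic positions); conversion to 0-based offsets happens only inside this
module. The gap symbol is ``-``; a ``.`` in inputs is normalised to ``-`` with
a warning.

Supported formats
-----------------
* FASTA sequences and alignments (via Bio.SeqIO)
* Newick trees (via Bio.Phylo)
* a plain-text SAM subset (mandatory 11 columns, CIGAR ops M/I/D/S only)
* an internal tab-separated read table (read_id, ref_start, bases)
* BED-like region TSV — name, ref_id, start, end, **1-based inclusive**
  (unlike true BED; documented here on purpose)
* CDS exon-model TSV (gene_id, exon_start, exon_end, strand)
* minimal VCF v4.2 output
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio import Phylo, SeqIO
from Bio.Phylo.BaseTree import Tree

from . import _codon
from .errors import (
    AlignmentLengthError,
    AlphabetError,
    CoordinateError,
    DuplicateIdError,
    FormatError,
    OrderingError,
    ParameterError,
    UnsupportedOperationError,
)

logger = logging.getLogger(__name__)

GAP = "-"
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX" + GAP)
NUCLEOTIDE_ALPHABET = frozenset("ACGTN" + GAP)

_ALPHABETS = {"protein": PROTEIN_ALPHABET, "nucleotide": NUCLEOTIDE_ALPHABET}


@dataclass
class SequenceRecord:
    """A named sequence over a declared alphabet."""

    id: str
    residues: str
    description: str = ""

    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """Equal-length gapped rows keyed by sequence id.

    The substrate of the conservation and selection analyses. Rows keep their
    input order; ``self.matrix`` is a (n_rows, n_columns) array of single
    characters for vectorised column work.
    """

    def __init__(self, rows: Sequence[SequenceRecord]):
        if len(rows) < 2:
            raise AlignmentLengthError(
                f"an alignment needs at least 2 rows, got {len(rows)}"
            )
        lengths = {len(r.residues) for r in rows}
        if len(lengths) != 1:
            bad = sorted({r.id for r in rows})
            raise AlignmentLengthError(
                "rows have unequal lengths: " + ", ".join(bad)
            )
        ids = [r.id for r in rows]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DuplicateIdError("duplicate row ids: " + ", ".join(dupes))
        for r in rows:
            if r.residues.count(GAP) == len(r.residues):
                raise AlignmentLengthError(f"row {r.id} is all gaps")
        self.rows = list(rows)
        self.n_columns = lengths.pop()
        self.matrix = np.array([list(r.residues) for r in rows], dtype="U1")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, ref_id: str) -> SequenceRecord:
        for r in self.rows:
            if r.id == ref_id:
                return r
        raise KeyError(f"no row with id {ref_id!r}")

    def column(self, column: int) -> list[str]:
        """Characters of a 1-based column."""
        if not 1 <= column <= self.n_columns:
            raise IndexError(
                f"column {column} out of range 1..{self.n_columns}"
            )
        return list(self.matrix[:, column - 1])


# kept as documented aliases for the two residue views
ProteinAlignment = Alignment


@dataclass
class RegionAnnotation:
    """A named protein region in 1-based inclusive reference-residue
    coordinates (e.g. CAP, Hinge, Linker)."""

    name: str
    ref_id: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise CoordinateError(
                f"region {self.name}: need 1 <= start <= end, "
                f"got {self.start}..{self.end}"
            )

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1


@dataclass
class AlignedRead:
    """A short read aligned to the reference, genomic orientation.

    ``cigar`` uses the M/I/D/S subset; ``None`` means fully matched.
    """

    read_id: str
    ref_start: int  # 1-based reference position of first aligned base
    bases: str
    cigar: str | None = None

    def __post_init__(self):
        if self.ref_start < 1:
            raise CoordinateError(f"read {self.read_id}: ref_start must be >= 1")
        if not self.bases:
            raise FormatError(f"read {self.read_id}: empty sequence")
        if self.cigar is not None:
            ops = parse_cigar(self.cigar)
            query = sum(n for n, op in ops if op in "MIS")
            if query != len(self.bases):
                raise FormatError(
                    f"read {self.read_id}: CIGAR {self.cigar} consumes {query} "
                    f"query bases but sequence has {len(self.bases)}"
                )


@dataclass
class CdsModel:
    """Exon structure and coding sequence of one gene.

    ``exons`` are 1-based inclusive genomic intervals sorted by start;
    ``reference_codons`` is the coding sequence in coding orientation (already
    reverse-complemented for minus-strand genes).
    """

    gene_id: str
    exons: list[tuple[int, int]]
    strand: str
    reference_codons: str = ""

    def __post_init__(self):
        if self.strand not in "+-":
            raise ParameterError(f"strand must be + or -, got {self.strand!r}")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise CoordinateError(f"exon {s}..{e} has start > end")
            if s <= prev_end:
                raise CoordinateError("exons overlap or are unsorted")
            prev_end = e
        if self.coding_length % 3:
            raise FormatError(
                f"gene {self.gene_id}: summed exon length {self.coding_length} "
                "not divisible by 3"
            )
        if self.reference_codons:
            aa = _codon.translate(self.reference_codons)
            if "*" in aa[:-1]:
                raise FormatError(
                    f"gene {self.gene_id}: internal stop codon in coding sequence"
                )

    @property
    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def extract_coding(self, reference: str) -> "CdsModel":
        """Fill ``reference_codons`` from a genomic reference sequence."""
        parts = [reference[s - 1:e] for s, e in self.exons]
        cds = "".join(parts)
        if self.strand == "-":
            cds = _codon.revcomp(cds)
        return CdsModel(self.gene_id, self.exons, self.strand, cds)

    def genomic_to_cds(self, position: int) -> int | None:
        """Map a 1-based genomic position to a 1-based coding position,
        honouring strand; ``None`` outside all exons."""
        offset = 0
        hit = None
        for s, e in self.exons:
            if s <= position <= e:
                hit = offset + (position - s)  # 0-based, plus orientation
                break
            offset += e - s + 1
        if hit is None:
            return None
        if self.strand == "+":
            return hit + 1
        return self.coding_length - hit


@dataclass
class VariantCall:
    """A single-nucleotide variant with its filter status and annotations."""

    position: int
    ref_base: str
    alt_base: str
    depth: int
    alt_fraction: float
    filter_status: list[str] = field(default_factory=list)  # empty == PASS
    effect: str | None = None  # silent | missense | nonsense | noncoding
    protein_position: int | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None
    domain: str | None = None
    lineage: str | None = None  # modern-human | archaic | ambiguous
    ancestral: str | None = None
    event: str | None = None  # "X > Y" with X ancestral

    @property
    def passed(self) -> bool:
        return not self.filter_status


# ---------------------------------------------------------------------------
# FASTA


def _clean_residues(raw: str, record_id: str) -> str:
    residues = raw.upper()
    if "." in residues:
        logger.warning("record %s: normalising '.' gaps to '-'", record_id)
        residues = residues.replace(".", GAP)
    return residues


def read_fasta(path, alphabet: str = "protein") -> list[SequenceRecord]:
    """Read FASTA into :class:`SequenceRecord` s, validating the alphabet.

    Raises a format error on an empty file, a duplicate-id error, and an
    alphabet error naming the offending character and 1-based offset.
    """
    allowed = _ALPHABETS[alphabet]
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = _clean_residues(str(rec.seq), rec.id)
        if not residues:
            raise FormatError(f"record {rec.id!r} has no residues")
        for offset, ch in enumerate(residues, start=1):
            if ch not in allowed:
                raise AlphabetError(
                    f"record {rec.id!r}: illegal {alphabet} character "
                    f"{ch!r} at offset {offset}"
                )
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(rec.id, residues, desc))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


def read_alignment(path, alphabet: str = "protein") -> Alignment:
    """Read an aligned FASTA; rows must be equal length and >= 2."""
    return Alignment(read_fasta(path, alphabet))


# ---------------------------------------------------------------------------
# Newick


def read_newick(path) -> Tree:
    try:
        tree = Phylo.read(str(path), "newick")
    except Exception as exc:  # NewickError carries the position in its message
        raise FormatError(f"cannot parse Newick file {path}: {exc}") from exc
    labels = [leaf.name for leaf in tree.get_terminals()]
    if len(labels) != len(set(labels)):
        raise DuplicateIdError("duplicate leaf labels in tree")
    for clade in tree.find_clades():
        if clade.branch_length is not None and clade.branch_length < 0:
            raise FormatError(
                f"negative branch length {clade.branch_length} in tree"
            )
    return tree


def write_newick(tree: Tree) -> str:
    buf = io.StringIO()
    Phylo.write(tree, buf, "newick", format_branch_length="%.10g")
    return buf.getvalue().strip()


def write_newick_file(tree: Tree, path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Reads

_CIGAR_RE = re.compile(r"(\d+)([A-Z=])")
_SUPPORTED_OPS = set("MIDS")


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) pairs, M/I/D/S only."""
    ops = _CIGAR_RE.findall(cigar)
    if not ops or "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise FormatError(f"malformed CIGAR {cigar!r}")
    parsed = []
    for n, op in ops:
        if op not in _SUPPORTED_OPS:
            raise UnsupportedOperationError(
                f"unsupported CIGAR operation {op!r} in {cigar!r} "
                "(supported: M, I, D, S)"
            )
        parsed.append((int(n), op))
    return parsed


def read_reads(path, dialect: str = "sam_subset") -> list[AlignedRead]:
    """Read aligned reads from a text SAM subset or the internal read table.

    Unmapped and secondary SAM records are skipped with a logged count.
    Coordinates stay 1-based as in the source.
    """
    if dialect == "read_table":
        reads = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise FormatError(
                        f"{path}:{lineno}: expected 3 tab-separated fields"
                    )
                read_id, ref_start, bases = parts[:3]
                reads.append(AlignedRead(read_id, int(ref_start), bases.upper()))
        return reads
    if dialect != "sam_subset":
        raise ParameterError(f"unknown read dialect {dialect!r}")

    reads = []
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                skipped += 1
                continue
            cigar = rec.cigarstring
            if cigar:
                parse_cigar(cigar)  # raises on unsupported ops
            reads.append(
                AlignedRead(
                    rec.query_name,
                    rec.reference_start + 1,
                    (rec.query_sequence or "").upper(),
                    cigar,
                )
            )
    if skipped:
        logger.info("skipped %d unmapped/secondary SAM records", skipped)
    return reads


def write_sam(reads: Iterable[AlignedRead], reference_name: str,
              reference_length: int, path) -> None:
    """Write reads as a minimal text SAM with an @SQ header."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": reference_name, "LN": int(reference_length)}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read.read_id
            rec.query_sequence = read.bases
            rec.flag = 0
            rec.reference_id = 0
            rec.reference_start = read.ref_start - 1
            rec.mapping_quality = 60
            rec.cigarstring = read.cigar or f"{len(read.bases)}M"
            out.write(rec)


# ---------------------------------------------------------------------------
# Regions and CDS models


def read_regions(path) -> list[RegionAnnotation]:
    """Read the BED-like region TSV (name, ref_id, start, end; 1-based
    inclusive — unlike true BED)."""
    regions = []
    names = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 fields")
            name, ref_id, start, end = parts[:4]
            if name in names:
                raise DuplicateIdError(f"duplicate region name {name!r}")
            names.add(name)
            regions.append(RegionAnnotation(name, ref_id, int(start), int(end)))
    return regions


def write_regions(regions: Iterable[RegionAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("#name\tref_id\tstart\tend\n")
        for r in regions:
            fh.write(f"{r.name}\t{r.ref_id}\t{r.start}\t{r.end}\n")


def read_cds_model(path) -> CdsModel:
    """Read a CDS exon-model TSV: gene_id, exon_start, exon_end, strand."""
    gene_id = None
    strand = None
    exons = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            g, s, e, st = line.split("\t")[:4]
            if gene_id is None:
                gene_id, strand = g, st
            elif g != gene_id or st != strand:
                raise FormatError("CDS model TSV mixes genes or strands")
            exons.append((int(s), int(e)))
    if gene_id is None:
        raise FormatError(f"no exon rows in {path}")
    exons.sort()
    return CdsModel(gene_id, exons, strand)


def write_cds_model(cds: CdsModel, path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\texon_start\texon_end\tstrand\n")
        for s, e in cds.exons:
            fh.write(f"{cds.gene_id}\t{s}\t{e}\t{cds.strand}\n")


# ---------------------------------------------------------------------------
# VCF

_VCF_FILTERS = {
    "MIN_DEPTH": "fewer reads than the minimum depth overlap the position",
    "MAX_FRACTION": "variant fraction of all reads not above the threshold",
    "READ_END": "all supporting bases fall at read ends",
}


def write_vcf(calls: Sequence[VariantCall], reference_name: str, path) -> None:
    """Write calls as minimal VCF v4.2.

    FILTER is PASS or the semicolon-joined failed-criterion tags; INFO carries
    DP, AF and any effect/domain/lineage annotation. Input must be sorted by
    position.
    """
    positions = [c.position for c in calls]
    if positions != sorted(positions):
        raise OrderingError("variant calls must be sorted by position")
    lines = [
        "##fileformat=VCFv4.2",
        "##source=paralog-evol",
        f"##contig=<ID={reference_name}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Variant allele fraction">',
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="Coding effect">',
        '##INFO=<ID=DOMAIN,Number=1,Type=String,Description="Protein domain">',
        '##INFO=<ID=LINEAGE,Number=1,Type=String,Description="Mutated lineage">',
    ]
    for tag, desc in _VCF_FILTERS.items():
        lines.append(f'##FILTER=<ID={tag},Description="{desc}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for c in calls:
        info = [f"DP={c.depth}", f"AF={c.alt_fraction:.4g}"]
        if c.effect:
            info.append(f"EFFECT={c.effect}")
        if c.domain:
            info.append(f"DOMAIN={c.domain}")
        if c.lineage:
            info.append(f"LINEAGE={c.lineage.replace(' ', '_')}")
        filt = "PASS" if c.passed else ";".join(c.filter_status)
        lines.append(
            f"{reference_name}\t{c.position}\t.\t{c.ref_base}\t{c.alt_base}"
            f"\t.\t{filt}\t{';'.join(info)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
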