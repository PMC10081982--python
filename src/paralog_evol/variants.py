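"""Pileup construction and three-criterion SNV calling for archaic-hominin
reads, with coding-effect, domain and lineage annotation.

A variable position is accepted (PASS) only when

1. at least ``min_depth`` reads overlap the position (default 2, counting
   every base including N);
2. the variant base is carried by **strictly more than** ``min_fraction`` of
   all overlapping reads (default 0.75 — 3 of 4 reads fails);
3. the difference is not only at read ends: at least one supporting base
   lies at least ``end_margin`` bases (default 5) from both ends of its read.

Failing candidates are still emitted, tagged MIN_DEPTH / MAX_FRACTION /
READ_END, so filters can be audited. Only substitutions are considered;
indels are out of scope.

Reads and pileups stay in genomic orientation throughout; reverse
complementation happens only at codon annotation for minus-strand genes, so
there is a single canonical coordinate system.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd

from ._codon import AA3, CODON_TABLE, COMPLEMENT
from .errors import AnnotationError, CoordinateError, ParameterError
from .seqio import (
    AlignedRead,
    CdsModel,
    RegionAnnotation,
    VariantCall,
    parse_cigar,
)

logger = logging.getLogger(__name__)


@dataclass
class CallerParams:
    """The three filtering criteria."""

    min_depth: int = 2
    min_fraction: float = 0.75  # strictly greater-than
    end_margin: int = 5

    def __post_init__(self):
        if self.min_depth < 1:
            raise ParameterError("min_depth must be >= 1")
        if not 0 < self.min_fraction <= 1:
            raise ParameterError("min_fraction must be in (0, 1]")
        if self.end_margin < 0:
            raise ParameterError("end_margin must be >= 0")


@dataclass
class PileupColumn:
    """Per-position base tally with the nearer-end offset of every base."""

    position: int
    base_counts: dict[str, int] = field(default_factory=dict)
    supporting_offsets: dict[str, list[int]] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(self.base_counts.values())

    def add(self, base: str, offset: int) -> None:
        self.base_counts[base] = self.base_counts.get(base, 0) + 1
        self.supporting_offsets.setdefault(base, []).append(offset)


def build_pileup(reads: list[AlignedRead],
                 region: tuple[int, int] | None = None,
                 reference_length: int | None = None,
                 ) -> dict[int, PileupColumn]:
    """Per-position base tallies from aligned reads.

    Walks each read's CIGAR: M consumes query and reference, I consumes query
    only (insertions are skipped), D consumes reference only (no base at
    deleted positions), S consumes query only. Nearer-end offsets are
    distances within the full read sequence, soft clips included.
    """
    columns: dict[int, PileupColumn] = {}
    lo, hi = region if region else (1, math.inf)
    for read in reads:
        ops = parse_cigar(read.cigar) if read.cigar else [(len(read.bases), "M")]
        qlen = len(read.bases)
        ref_pos = read.ref_start
        q = 0
        for length, op in ops:
            if op == "M":
                for k in range(length):
                    pos = ref_pos + k
                    if reference_length is not None and pos > reference_length:
                        raise CoordinateError(
                            f"read {read.read_id} extends past reference "
                            f"length {reference_length}"
                        )
                    if lo <= pos <= hi:
                        qi = q + k
                        offset = min(qi, qlen - 1 - qi)
                        columns.setdefault(pos, PileupColumn(pos)).add(
                            read.bases[qi], offset
                        )
                ref_pos += length
                q += length
            elif op == "D":
                ref_pos += length
            else:  # I or S: query only
                q += length
    return dict(sorted(columns.items()))


def call_variants(pileup: dict[int, PileupColumn], reference: str,
                  params: CallerParams | None = None) -> list[VariantCall]:
    """Apply the three criteria to every candidate position.

    A position is a candidate when any non-reference, non-N base is present;
    the majority such base is the variant. N bases count toward depth but
    never toward variant support.
    """
    params = params or CallerParams()
    calls = []
    for pos in sorted(pileup):
        col = pileup[pos]
        if pos > len(reference):
            raise CoordinateError(
                f"pileup position {pos} beyond reference length {len(reference)}"
            )
        ref_base = reference[pos - 1]
        alt_counts = {b: n for b, n in col.base_counts.items()
                      if b not in (ref_base, "N")}
        if not alt_counts:
            continue
        best = max(alt_counts.values())
        alt = min(b for b, n in alt_counts.items() if n == best)
        depth = col.depth
        fraction = alt_counts[alt] / depth
        tags = []
        if depth < params.min_depth:
            tags.append("MIN_DEPTH")
        if fraction <= params.min_fraction:
            tags.append("MAX_FRACTION")
        offsets = col.supporting_offsets.get(alt, [])
        if not any(o >= params.end_margin for o in offsets):
            tags.append("READ_END")
        calls.append(VariantCall(pos, ref_base, alt, depth, fraction, tags))
    return calls


def annotate_effect(call: VariantCall, cds: CdsModel) -> VariantCall:
    """Classify a call as silent / missense / nonsense via the CDS model.

    The genomic position is mapped to a coding position honouring strand
    (minus strand: alleles complemented, coordinate order reversed); the
    protein position is ceil(cds_position / 3). Positions outside all exons
    are classified ``noncoding`` and logged.
    """
    cds_pos = cds.genomic_to_cds(call.position)
    if cds_pos is None:
        logger.info("position %d outside %s exons: noncoding",
                    call.position, cds.gene_id)
        call.effect = "noncoding"
        return call
    if not cds.reference_codons:
        raise ParameterError(f"CDS model {cds.gene_id} lacks a coding sequence")
    alt = call.alt_base
    if cds.strand == "-":
        alt = alt.translate(COMPLEMENT)
    codon_idx = (cds_pos - 1) // 3
    within = (cds_pos - 1) % 3
    ref_codon = cds.reference_codons[3 * codon_idx:3 * codon_idx + 3]
    coding_ref = ref_codon[within]
    expected_genomic = (coding_ref.translate(COMPLEMENT)
                        if cds.strand == "-" else coding_ref)
    if expected_genomic != call.ref_base:
        logger.warning(
            "position %d: pileup reference %s disagrees with CDS base %s",
            call.position, call.ref_base, expected_genomic,
        )
    alt_codon = ref_codon[:within] + alt + ref_codon[within + 1:]
    aa_ref = CODON_TABLE[ref_codon]
    aa_alt = CODON_TABLE[alt_codon]
    call.protein_position = (cds_pos + 2) // 3
    call.aa_ref = aa_ref
    call.aa_alt = aa_alt
    if aa_alt == "*":
        call.effect = "nonsense"
    elif aa_ref == aa_alt:
        call.effect = "silent"
    else:
        call.effect = "missense"
    return call


def assign_lineage(call: VariantCall, sample_base: str,
                   other_lineage_base: str, outgroup_bases: list[str],
                   sample_label: str = "archaic",
                   other_label: str = "modern-human",
                   ) -> VariantCall:
    """Polarise a two-lineage difference with outgroup consensus.

    The ancestral state is the outgroup base only when all outgroups agree;
    the lineage carrying the derived base is labelled mutated and the event
    written ``"X > Y"`` with X ancestral. Disagreeing outgroups, or both
    lineages derived, give ``ambiguous``.
    """
    if not outgroup_bases:
        raise ParameterError("need at least one outgroup base")
    if len(set(outgroup_bases)) != 1:
        call.lineage = "ambiguous"
        return call
    ancestral = outgroup_bases[0]
    call.ancestral = ancestral
    sample_derived = sample_base != ancestral
    other_derived = other_lineage_base != ancestral
    if sample_derived and other_derived:
        call.lineage = "ambiguous"
    elif sample_derived:
        call.lineage = sample_label
        call.event = f"{ancestral} > {sample_base}"
    elif other_derived:
        call.lineage = other_label
        call.event = f"{ancestral} > {other_lineage_base}"
    else:
        call.lineage = "ambiguous"  # no derived allele at all
    return call


def map_call_to_domain(protein_position: int,
                       regions: list[RegionAnnotation]) -> str | None:
    """The unique region containing a protein position (inclusive ends)."""
    ordered = sorted(regions, key=lambda r: (r.start, r.end))
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise AnnotationError(
                f"regions {a.name} and {b.name} overlap"
            )
    for r in ordered:
        if r.start <= protein_position <= r.end:
            return r.name
    return None


# ---------------------------------------------------------------------------
# Model / Results


class VariantCallerModel:
    """Three-criterion SNV calling over a read pileup, with annotation.

    Parameters
    ----------
    reads : list of AlignedRead
        Aligned reads in genomic orientation (the archaic sample).
    reference : str
        Genomic reference sequence (the modern-human assembly), whose base
        at each call is the "other lineage" allele for polarisation.
    params : CallerParams, optional
    cds : CdsModel, optional
        Enables silent/missense/nonsense classification.
    regions : list of RegionAnnotation, optional
        Protein domains for placement of coding calls.
    outgroups : dict of str -> str, optional
        Outgroup genomic sequences (same coordinates as the reference) for
        lineage polarisation, e.g. bonobo and gorilla.
    """

    def __init__(self, reads, reference, params: CallerParams | None = None,
                 cds: CdsModel | None = None,
                 regions: list[RegionAnnotation] | None = None,
                 outgroups: dict[str, str] | None = None,
                 sample_label: str = "archaic",
                 other_label: str = "modern-human"):
        self.reads = list(reads)
        self.reference = reference
        self.params = params or CallerParams()
        self.cds = cds
        self.regions = list(regions) if regions else []
        self.outgroups = dict(outgroups) if outgroups else {}
        for name, seq in self.outgroups.items():
            if len(seq) != len(reference):
                raise ParameterError(
                    f"outgroup {name} length differs from the reference"
                )
        self.sample_label = sample_label
        self.other_label = other_label

    def fit(self) -> "VariantCallResults":
        pileup = build_pileup(self.reads, reference_length=len(self.reference))
        calls = call_variants(pileup, self.reference, self.params)
        for call in calls:
            if self.cds is not None:
                annotate_effect(call, self.cds)
            if self.outgroups:
                assign_lineage(
                    call,
                    sample_base=call.alt_base,
                    other_lineage_base=call.ref_base,
                    outgroup_bases=[seq[call.position - 1]
                                    for seq in self.outgroups.values()],
                    sample_label=self.sample_label,
                    other_label=self.other_label,
                )
            if self.regions and call.protein_position is not None:
                call.domain = map_call_to_domain(call.protein_position,
                                                 self.regions)
        return VariantCallResults(self, pileup, calls)


class VariantCallResults:
    """Called variants with their filters and annotations."""

    def __init__(self, model: VariantCallerModel,
                 pileup: dict[int, PileupColumn],
                 calls: list[VariantCall]):
        self.model = model
        self.pileup = pileup
        self.calls = calls

    @property
    def passed(self) -> list[VariantCall]:
        return [c for c in self.calls if c.passed]

    @property
    def table(self) -> pd.DataFrame:
        """Annotation table mirroring the published variant-table columns."""
        rows = []
        for c in self.calls:
            replacement = None
            if c.aa_ref is not None and c.aa_alt is not None:
                replacement = f"{AA3[c.aa_ref]}-{AA3[c.aa_alt]}"
            rows.append({
                "position": c.position,
                "ref": c.ref_base,
                "alt": c.alt_base,
                "depth": c.depth,
                "alt_fraction": round(c.alt_fraction, 4),
                "filter": "PASS" if c.passed else ";".join(c.filter_status),
                "effect": c.effect,
                "protein_position": c.protein_position,
                "aa_ref": c.aa_ref,
                "aa_alt": c.aa_alt,
                "replacement": replacement,
                "domain": c.domain,
                "ancestral": c.ancestral,
                "event": c.event,
                "lineage": c.lineage,
            })
        return pd.DataFrame(rows)

    def to_vcf(self, path, reference_name: str = "ref") -> None:
        from .seqio import write_vcf
        write_vcf(self.calls, reference_name, path)

    def summary(self) -> str:
        p = self.model.params
        n_pass = len(self.passed)
        lines = [
            "Three-criterion SNV calling",
            f"  reads: {len(self.model.reads)}   covered positions: "
            f"{len(self.pileup)}",
            f"  criteria: depth >= {p.min_depth}; fraction > "
            f"{p.min_fraction:g}; supporting base >= {p.end_margin} bp from "
            "read ends",
            f"  candidates: {len(self.calls)}   PASS: {n_pass}",
        ]
        for c in self.passed:
            bits = [f"    {c.position} {c.ref_base}>{c.alt_base} "
                    f"DP={c.depth} AF={c.alt_fraction:.2f}"]
            if c.effect:
                bits.append(c.effect)
            if c.protein_position:
                bits.append(f"p.{c.protein_position}")
            if c.domain:
                bits.append(c.domain)
            if c.lineage:
                bits.append(f"[{c.lineage}]")
            lines.append(" ".join(bits))
        return "\n".join(lines)
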