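"""Synthetic-data generators emulating the statistical structure of the
study inputs: codon alignments evolved on a tree under a fixed dN/dS (ω),
protein MSAs with region-structured conservation, and short-read pileups
with planted variants.

Every generator takes its randomness from a single integer seed and is
bit-reproducible. The codon simulator samples explicit mutation events along
branches (Gillespie-style, rejection at stop codons, nonsynonymous proposals
accepted with relative probability ω) rather than exponentiating a rate
matrix — transparent at desk scale and, crucially, it yields an exact event
log so estimators can be checked against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Phylo.BaseTree import Clade, Tree

from ._codon import CODON_TABLE, SENSE_CODONS, is_stop
from .conservation import AMINO_ACIDS
from .dnds import CodonAlignment, validate_codon_alignment
from .errors import ParameterError
from .seqio import AlignedRead, Alignment, RegionAnnotation, SequenceRecord

_BASES = "ACGT"
_TS = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SimulationConfig:
    """Study-condition knobs for all generators.

    Defaults mirror the analysed system: trees of 8 chordate-like taxa with
    exponential branch lengths of mean 0.1 substitutions/site, purifying
    ω in the 0.15–0.31 range (ω = 0.2 as a neutral-free default), transition
    bias κ = 2 (typical nuclear gene), 300 codons, 10x read coverage of
    50 bp reads at a 0.1% per-base error rate.
    """

    seed: int = 0
    tree: Tree | None = None
    n_taxa: int = 8
    branch_length_mean: float = 0.1
    omega: float = 0.2
    kappa: float = 2.0
    n_codons: int = 300
    region_profile: list[tuple[str, int, float]] = field(default_factory=list)
    n_rows: int = 48
    coverage: float = 10.0
    read_length: int = 50
    error_rate: float = 1e-3

    def __post_init__(self):
        if self.omega < 0:
            raise ParameterError("omega must be >= 0")
        if self.kappa <= 0:
            raise ParameterError("kappa must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ParameterError("error_rate must be in [0, 1)")


def random_tree(n_taxa: int, seed: int, branch_length_mean: float = 0.1) -> Tree:
    """Random coalescent-style rooted binary tree with exponential branch
    lengths; leaves named t1..tN. Deterministic given the seed."""
    if n_taxa < 3:
        raise ParameterError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    lineages = [Clade(branch_length=float(rng.exponential(branch_length_mean)),
                      name=f"t{i + 1}")
                for i in range(n_taxa)]
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        b = lineages.pop(j)
        a = lineages.pop(i)
        parent = Clade(branch_length=float(rng.exponential(branch_length_mean)),
                       clades=[a, b])
        lineages.append(parent)
    root = lineages[0]
    root.branch_length = None
    return Tree(root=root, rooted=True)


# ---------------------------------------------------------------------------
# Codon alignment simulator


def _mutate_branch(seq: list[str], branch_length: float, omega: float,
                   kappa: float, rng: np.random.Generator,
                   ) -> tuple[list[str], int, int]:
    """Evolve a codon sequence along one branch; returns (sequence,
    syn_events, nonsyn_events).

    Proposal rate is one single-nucleotide proposal per nucleotide site per
    unit branch length; targets drawn with κ transition bias; proposals
    creating stops are rejected; nonsynonymous proposals are accepted with
    relative probability ω.
    """
    seq = list(seq)
    n_nt = 3 * len(seq)
    n_events = rng.poisson(branch_length * n_nt)
    syn = nonsyn = 0
    p_ts = kappa / (kappa + 2.0)
    for _ in range(n_events):
        site = int(rng.integers(len(seq)))
        pos = int(rng.integers(3))
        codon = seq[site]
        ref = codon[pos]
        if rng.random() < p_ts:
            alt = _TS[ref]
        else:
            choices = [b for b in _BASES if b != ref and b != _TS[ref]]
            alt = choices[int(rng.integers(2))]
        mutant = codon[:pos] + alt + codon[pos + 1:]
        if is_stop(mutant):
            continue
        if CODON_TABLE[mutant] == CODON_TABLE[codon]:
            seq[site] = mutant
            syn += 1
        else:
            if rng.random() < omega:
                seq[site] = mutant
                nonsyn += 1
    return seq, syn, nonsyn


def simulate_codon_alignment(config: SimulationConfig,
                             ) -> tuple[CodonAlignment, pd.DataFrame]:
    """Evolve a codon alignment on a tree under fixed ω and κ.

    Returns the alignment and a true event log with one row per branch
    (child clade name or index, branch length, synonymous and nonsynonymous
    event counts).
    """
    rng = np.random.default_rng(config.seed)
    tree = config.tree or random_tree(config.n_taxa, int(rng.integers(2 ** 31)),
                                      config.branch_length_mean)
    root_seq = [SENSE_CODONS[i]
                for i in rng.integers(len(SENSE_CODONS), size=config.n_codons)]
    sequences: dict[int, list[str]] = {id(tree.root): root_seq}
    log_rows = []
    leaf_records = []
    counter = [0]

    def visit(clade: Clade):
        for child in clade.clades:
            bl = child.branch_length or 0.0
            child_seq, syn, nonsyn = _mutate_branch(
                sequences[id(clade)], bl, config.omega, config.kappa, rng
            )
            sequences[id(child)] = child_seq
            counter[0] += 1
            log_rows.append({
                "branch": child.name or f"node{counter[0]}",
                "branch_length": bl,
                "syn_events": syn,
                "nonsyn_events": nonsyn,
            })
            if child.is_terminal():
                leaf_records.append(
                    SequenceRecord(child.name, "".join(child_seq))
                )
            else:
                visit(child)

    visit(tree.root)
    calign = validate_codon_alignment(Alignment(leaf_records))
    return calign, pd.DataFrame(log_rows)


# ---------------------------------------------------------------------------
# Region-structured protein MSA simulator


def _column_sub_probability(target_pi: float) -> float:
    """Per-row substitution probability giving an expected pair identity of
    ``target_pi`` percent.

    Two rows match when neither mutated, (1-p)^2, or both mutated to the same
    of the 19 alternatives, p^2/19; solving (20/19)p^2 - 2p + (1 - q) = 0 for
    the root in [0, 1]."""
    q = target_pi / 100.0
    if not 0 < q <= 1:
        raise ParameterError("target identity must be in (0, 100]")
    a = 20.0 / 19.0
    disc = 4.0 - 4.0 * a * (1.0 - q)
    return (2.0 - np.sqrt(disc)) / (2.0 * a)


def simulate_region_msa(config: SimulationConfig,
                        invariant_block: tuple[int, str] | None = None,
                        ) -> tuple[Alignment, list[RegionAnnotation]]:
    """Protein MSA whose regions hit target pairwise identities.

    ``config.region_profile`` is a list of (name, length, target_identity%)
    concatenated in order; an ancestral sequence is drawn and each row
    mutates each column independently with the probability calibrated to the
    region's target. ``invariant_block`` = (reference start position,
    residues) plants a fully conserved motif (e.g. the AKVFRT catalytic
    stretch). No indels are simulated, so reference residue positions equal
    alignment columns; the first row (id ``reference``) anchors coordinates.
    """
    if not config.region_profile:
        raise ParameterError("region_profile must be non-empty")
    rng = np.random.default_rng(config.seed)
    total = sum(length for _, length, _ in config.region_profile)
    aa = np.array(list(AMINO_ACIDS))
    ancestor = aa[rng.integers(len(aa), size=total)]
    p_col = np.empty(total)
    regions = []
    offset = 0
    for name, length, target in config.region_profile:
        p_col[offset:offset + length] = _column_sub_probability(target)
        regions.append(RegionAnnotation(name, "reference", offset + 1,
                                        offset + length))
        offset += length
    if invariant_block is not None:
        start, motif = invariant_block
        if not 1 <= start <= total - len(motif) + 1:
            raise ParameterError("invariant block outside the profile")
        ancestor[start - 1:start - 1 + len(motif)] = list(motif)
        p_col[start - 1:start - 1 + len(motif)] = 0.0

    # every row (the reference included) mutates independently from the
    # ancestor, so all C(n,2) pairs share the calibrated identity
    rows = []
    for r in range(config.n_rows):
        mutate = rng.random(total) < p_col
        residues = ancestor.copy()
        if mutate.any():
            # draw a uniformly random *different* residue per mutated column
            shifts = rng.integers(1, len(aa), size=int(mutate.sum()))
            idx = np.searchsorted(aa, residues[mutate])
            residues[mutate] = aa[(idx + shifts) % len(aa)]
        name = "reference" if r == 0 else f"seq{r + 1}"
        rows.append(SequenceRecord(name, "".join(residues)))
    return Alignment(rows), regions


# ---------------------------------------------------------------------------
# Read simulator


def simulate_reads(reference: str,
                   planted_variants: list[tuple[int, str, float]],
                   config: SimulationConfig,
                   ) -> tuple[list[AlignedRead], pd.DataFrame]:
    """Tile reads over a reference with planted single-nucleotide variants.

    Read count is Poisson(coverage * L / read_length) with uniform start
    positions, so realised depth fluctuates around ``config.coverage``. A
    read overlapping a planted site carries the alt allele with the planted
    fraction (per-read coin flip). Sequencing errors are injected per base at
    ``config.error_rate`` but never at planted sites, keeping the truth table
    exact. The truth table records each planted site's realised depth, alt
    count, fraction, and the largest nearer-end offset among alt-supporting
    bases.
    """
    L = len(reference)
    for pos, alt, frac in planted_variants:
        if not 1 <= pos <= L:
            raise ParameterError(f"planted position {pos} outside reference")
        if not 0 < frac <= 1:
            raise ParameterError("planted fraction must be in (0, 1]")
        if alt == reference[pos - 1]:
            raise ParameterError(f"planted alt at {pos} equals the reference")
    rng = np.random.default_rng(config.seed)
    read_len = min(config.read_length, L)
    n_reads = rng.poisson(config.coverage * L / read_len)
    reads: list[AlignedRead] = []
    stats = {pos: {"depth": 0, "alt": 0, "max_offset": -1}
             for pos, _, _ in planted_variants}
    for i in range(n_reads):
        start = int(rng.integers(1, L - read_len + 2))
        bases = list(reference[start - 1:start - 1 + read_len])
        for pos, alt, frac in planted_variants:
            if start <= pos < start + read_len:
                stats[pos]["depth"] += 1
                if rng.random() < frac:
                    offset_in_read = pos - start
                    bases[offset_in_read] = alt
                    stats[pos]["alt"] += 1
                    near = min(offset_in_read, read_len - 1 - offset_in_read)
                    stats[pos]["max_offset"] = max(stats[pos]["max_offset"], near)
        if config.error_rate > 0:
            errs = np.flatnonzero(rng.random(read_len) < config.error_rate)
            for j in errs:
                if start + int(j) in stats:  # never at a planted site
                    continue
                alts = [b for b in _BASES if b != bases[j]]
                bases[j] = alts[int(rng.integers(3))]
        reads.append(AlignedRead(f"r{i + 1}", start, "".join(bases)))
    truth = pd.DataFrame([
        {
            "position": pos,
            "alt": alt,
            "planted_fraction": frac,
            "depth": stats[pos]["depth"],
            "alt_count": stats[pos]["alt"],
            "realized_fraction": (stats[pos]["alt"] / stats[pos]["depth"]
                                  if stats[pos]["depth"] else 0.0),
            "max_supporting_offset": stats[pos]["max_offset"],
        }
        for pos, alt, frac in planted_variants
    ])
    return reads, truth


def archaic_variant_fixture(seed: int = 0):
    """A minus-strand gene with three planted human/archaic differences.

    Emulates the polymorphism pattern reported between modern-human and
    archaic-hominin copies of the mitochondrially targeted topoisomerase
    gene: a silent third-position change at protein position 72 (Asp, CAP
    domain) that is derived in the modern-human lineage, and two archaic
    missense changes in the Linker at positions 533 (Gln→Arg) and 536
    (Gln→Lys). The gene body is 601 Ala codons on the minus strand, split
    over two exons, with the three informative codons substituted in
    (Asp GAC at 72, Gln CAA at 533 and 536).

    Returns a dict with keys ``reference`` (human genomic sequence),
    ``reads`` (archaic reads carrying the variants), ``cds`` (CdsModel with
    coding sequence filled), ``regions`` (the six protein domains),
    ``outgroups`` (two ape genomic sequences holding the ancestral alleles)
    and ``expected`` (DataFrame of the planted truth).
    """
    from . import datasets
    from ._codon import revcomp

    rng = np.random.default_rng(seed)
    n_codons = 601
    codons = ["GCT"] * n_codons
    codons[71] = "GAC"   # Asp72
    codons[532] = "CAA"  # Gln533
    codons[535] = "CAA"  # Gln536
    coding = "".join(codons)
    split = 900  # coding offset of the exon boundary
    flank = 100
    intron = "".join("ACGT"[i] for i in rng.integers(4, size=50))
    left = "".join("ACGT"[i] for i in rng.integers(4, size=flank))
    right = "".join("ACGT"[i] for i in rng.integers(4, size=flank))
    # minus strand: the genomically first exon holds the 3' part of the CDS
    exon_a_seq = revcomp(coding[split:])
    exon_b_seq = revcomp(coding[:split])
    reference = left + exon_a_seq + intron + exon_b_seq + right
    exon_a = (flank + 1, flank + len(exon_a_seq))
    exon_b_start = flank + len(exon_a_seq) + len(intron) + 1
    exon_b = (exon_b_start, exon_b_start + len(exon_b_seq) - 1)
    from .seqio import CdsModel
    cds = CdsModel("TOP1MT_like", [exon_a, exon_b], "-").extract_coding(reference)

    def genomic_of(cds_pos: int) -> int:
        hit = len(coding) - cds_pos  # 0-based plus-orientation offset
        if hit < len(exon_a_seq):
            return exon_a[0] + hit
        return exon_b[0] + (hit - len(exon_a_seq))

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    # (protein pos, cds position of the changed base, archaic coding base,
    #  expected effect, aa change, domain, mutated lineage)
    planted = [
        (72, 72 * 3, "T", "silent", "Asp-Asp", "CAP", "modern-human"),
        (533, (533 - 1) * 3 + 2, "G", "missense", "Gln-Arg", "Linker", "archaic"),
        (536, (536 - 1) * 3 + 1, "A", "missense", "Gln-Lys", "Linker", "archaic"),
    ]
    outgroups = {"bonobo": list(reference), "gorilla": list(reference)}
    archaic_allele = {}  # genomic position -> archaic base
    site_info = []
    for ppos, cds_pos, archaic_coding, effect, repl, domain, lineage in planted:
        gpos = genomic_of(cds_pos)
        archaic_allele[gpos] = comp[archaic_coding]  # minus-strand gene
        site_info.append((gpos, ppos, effect, repl, domain, lineage))
    reads: list[AlignedRead] = []
    rows = []
    read_len = 30
    for k, (gpos, ppos, effect, repl, domain, lineage) in enumerate(site_info):
        archaic_genomic = archaic_allele[gpos]
        human_genomic = reference[gpos - 1]
        # the ancestral allele is whichever base the non-mutated lineage keeps
        ancestral = archaic_genomic if lineage == "modern-human" else human_genomic
        for og in outgroups.values():
            og[gpos - 1] = ancestral
        for j in range(3):  # three interior archaic reads per site
            start = gpos - read_len // 2 - j
            bases = list(reference[start - 1:start - 1 + read_len])
            # the archaic sample is homozygous: every covered planted site
            # carries the archaic allele on every read
            for vpos, vbase in archaic_allele.items():
                if start <= vpos < start + read_len:
                    bases[vpos - start] = vbase
            reads.append(AlignedRead(f"a{k}_{j}", start, "".join(bases)))
        rows.append({
            "position": gpos,
            "ref": human_genomic,
            "alt": archaic_genomic,
            "protein_position": ppos,
            "effect": effect,
            "replacement": repl,
            "domain": domain,
            "lineage": lineage,
            "ancestral": ancestral,
        })
    reads.sort(key=lambda r: r.ref_start)
    regions = [RegionAnnotation(r.name, "TOP1MT_like", r.start, r.end)
               for r in datasets.TOP1MT_DOMAINS]
    return {
        "reference": reference,
        "reads": reads,
        "cds": cds,
        "regions": regions,
        "outgroups": {k: "".join(v) for k, v in outgroups.items()},
        "expected": pd.DataFrame(rows),
    }


def caller_factorial_fixture(reference: str, end_margin: int = 5,
                             read_length: int = 20,
                             ) -> tuple[list[AlignedRead], pd.DataFrame]:
    """Deterministic reads exercising the three variant-caller criteria.

    One planted site per feasible combination of criterion violations
    (depth >= 2; alt fraction strictly > 75%; at least one supporting base
    away from read ends). Depth-1 sites cannot simultaneously fail the
    fraction criterion (a lone read gives fraction 1), so the infeasible
    cells of the 2^3 factorial are omitted; an N-base depth case is added
    (N counts toward depth, never toward alt support). Returns the reads and
    a truth table of expected filter tags per site.
    """
    L = len(reference)
    combos = [
        ("PASS", True, True, True),
        ("MIN_DEPTH", False, True, True),
        ("MAX_FRACTION", True, False, True),
        ("READ_END", True, True, False),
        ("MIN_DEPTH;READ_END", False, True, False),
        ("MAX_FRACTION;READ_END", True, False, False),
    ]
    spacing = 3 * read_length
    reads: list[AlignedRead] = []
    rows = []
    rid = 0

    def add_read(start, length, mutations):
        nonlocal rid
        rid += 1
        bases = list(reference[start - 1:start - 1 + length])
        for pos, alt in mutations:
            bases[pos - start] = alt
        reads.append(AlignedRead(f"f{rid}", start, "".join(bases)))

    for k, (tags, depth_ok, frac_ok, end_ok) in enumerate(combos):
        pos = spacing * (k + 1)
        if pos + read_length >= L:
            raise ParameterError("reference too short for the factorial fixture")
        ref_base = reference[pos - 1]
        alt = "A" if ref_base != "A" else "G"
        interior = pos - read_length // 2  # site lands mid-read
        edge = pos - (end_margin - 1)      # site lands near the read start
        start = interior if end_ok else edge
        if not depth_ok:
            add_read(start, read_length, [(pos, alt)])
        elif not frac_ok:
            # 3 alt / 4 reads: fraction exactly 0.75, strictly-greater fails
            for _ in range(3):
                add_read(start, read_length, [(pos, alt)])
            add_read(start, read_length, [])
        else:
            for _ in range(3):
                add_read(start, read_length, [(pos, alt)])
        rows.append({"position": pos, "ref": ref_base, "alt": alt,
                     "expected_filter": tags})

    # N counts toward depth but not alt: 2 alt + 2 N -> fraction 2/4 fails
    pos = spacing * (len(combos) + 1)
    ref_base = reference[pos - 1]
    alt = "A" if ref_base != "A" else "G"
    start = pos - read_length // 2
    for _ in range(2):
        add_read(start, read_length, [(pos, alt)])
    for _ in range(2):
        add_read(start, read_length, [(pos, "N")])
    rows.append({"position": pos, "ref": ref_base, "alt": alt,
                 "expected_filter": "MAX_FRACTION"})
    reads.sort(key=lambda r: r.ref_start)
    return reads, pd.DataFrame(rows)
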