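"""Standard genetic code (translation table 1) helpers.

Both topoisomerase paralogues studied here are nuclear-encoded, so a single
code table serves the whole package. Kept private: public modules re-export
what they need.
"""

from __future__ import annotations

from .errors import ParameterError

BASES = "ACGT"

# transition partner for each base (A<->G purines, C<->T pyrimidines)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TABLE.items() if aa != "*"))

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    if len(cds) % 3:
        raise ParameterError(f"coding sequence length {len(cds)} not divisible by 3")
    return "".join(CODON_TABLE[cds[i:i + 3]] for i in range(0, len(cds), 3))


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_transition(a: str, b: str) -> bool:
    return TRANSITION[a] == b


def single_mutants(codon: str):
    """Yield (mutant_codon, position, is_transition) for all 9 single-nucleotide
    neighbours of ``codon``."""
    for pos in range(3):
        ref = codon[pos]
        for alt in BASES:
            if alt == ref:
                continue
            yield codon[:pos] + alt + codon[pos + 1:], pos, is_transition(ref, alt)
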