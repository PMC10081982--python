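"""Exception hierarchy.

Everything user-facing derives from :class:`ParalogEvolError` so callers (and
the CLI) can distinguish configuration problems (:class:`ConfigError`) from
malformed inputs (:class:`FormatError`) from bad parameters.
"""


class ParalogEvolError(Exception):
    """Base class for all package errors."""


class ConfigError(ParalogEvolError):
    """Invalid run configuration (missing files, unknown keys, absent ids)."""


class FormatError(ParalogEvolError):
    """Malformed input file."""


class DuplicateIdError(FormatError):
    """Two records share an id within one collection."""


class AlphabetError(FormatError):
    """A residue outside the declared alphabet; message names the character."""


class AlignmentLengthError(FormatError):
    """Ragged rows in an alignment; message lists offending ids."""


class UnsupportedOperationError(FormatError):
    """A CIGAR operation outside the supported M/I/D/S subset."""


class OrderingError(ParalogEvolError):
    """Records required to be sorted were not."""


class CoordinateError(ParalogEvolError):
    """A 1-based coordinate falls outside its reference."""


class ParameterError(ParalogEvolError):
    """An argument violates its documented domain."""


class CodonFrameError(FormatError):
    """Nucleotide alignment length not divisible by 3."""


class StopCodonError(FormatError):
    """Internal stop codon in a coding row; message names row and codon index."""


class GapPhaseError(FormatError):
    """Gaps in a codon alignment not in whole-codon units."""


class AnnotationError(ParalogEvolError):
    """Inconsistent region annotations (e.g. overlapping domains)."""
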