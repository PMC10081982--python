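"""Alignment conservation statistics based on pairwise identity (PI).

PI at a column is the percentage of identical unordered row pairs among all
counted pairs. Gap convention, stated prominently because absolute values
shift with it:

* a pair with exactly one gap counts as a **non-identical** pair;
* a pair of two gaps is **excluded** from numerator and denominator;
* the ambiguity character (``X`` for protein, ``N`` for nucleotide) never
  matches anything, including another ambiguity character;
* an all-gap column has no counted pairs and yields NaN (flagged missing).

Region-level PI pools pair counts over the region's columns rather than
averaging per-column percentages; pooling is invariant to subdividing a
region, the mean is not.

The model-level interface is :class:`ConservationModel` /
:class:`ConservationResults`; every statistic is also exposed as a plain
function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoordinateError, ParameterError
from .seqio import GAP, Alignment, RegionAnnotation, SequenceRecord

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: the ambiguity character that never matches anything: X in protein
#: columns; nucleotide callers pass {"N"} instead (N is Asn in protein)
PROTEIN_AMBIGUOUS = frozenset("X")


def _pair_counts(column: list[str],
                 ambiguous: frozenset = PROTEIN_AMBIGUOUS) -> tuple[int, int]:
    """(identical pairs, counted pairs) for one column under the gap rules."""
    n = len(column)
    n_gap = sum(1 for c in column if c == GAP)
    counted = n * (n - 1) // 2 - n_gap * (n_gap - 1) // 2
    identical = 0
    for ch in set(column):
        if ch == GAP or ch in ambiguous:
            continue
        c = column.count(ch)
        identical += c * (c - 1) // 2
    return identical, counted


def column_identity(alignment: Alignment, column: int) -> float:
    """PI (%) of one 1-based alignment column; NaN when no pair is counted."""
    identical, counted = _pair_counts(alignment.column(column))
    if counted == 0:
        return float("nan")
    return 100.0 * identical / counted


@dataclass
class RegionIdentityRow:
    """One row of a domain-conservation table: a region, its length computed
    from its coordinates, and its pooled PI."""

    region: RegionAnnotation
    n_residues: int
    pi_percent: float


def map_reference_to_columns(alignment: Alignment, ref_id: str,
                             start: int, end: int) -> list[int]:
    """Columns (1-based) holding the reference row's residues ``start..end``.

    The k-th returned column contains the reference's (start+k-1)-th non-gap
    residue; the list is strictly increasing but not necessarily contiguous
    when other rows insert columns.
    """
    if start < 1 or start > end:
        raise CoordinateError(f"need 1 <= start <= end, got {start}..{end}")
    row = alignment.row(ref_id).residues
    columns = []
    residue = 0
    for col, ch in enumerate(row, start=1):
        if ch == GAP:
            continue
        residue += 1
        if residue > end:
            break
        if residue >= start:
            columns.append(col)
    if residue < end:
        raise CoordinateError(
            f"residue {end} beyond ungapped length {residue} of row {ref_id!r}"
        )
    return columns


def region_identity(alignment: Alignment, region: RegionAnnotation) -> RegionIdentityRow:
    """Pooled PI over all columns of a reference-anchored region."""
    columns = map_reference_to_columns(
        alignment, region.ref_id, region.start, region.end
    )
    identical = counted = 0
    for col in columns:
        i, c = _pair_counts(alignment.column(col))
        identical += i
        counted += c
    pi = 100.0 * identical / counted if counted else float("nan")
    return RegionIdentityRow(region, region.n_residues, pi)


@dataclass
class ConservationProfile:
    """Per-column PI, optionally smoothed with a centred moving average."""

    per_column_pi: np.ndarray
    window: int

    def __post_init__(self):
        self.per_column_pi = np.asarray(self.per_column_pi, dtype=float)


def identity_profile(alignment: Alignment, window: int = 1) -> ConservationProfile:
    """Per-column PI smoothed with a centred moving average.

    Edge windows shrink symmetrically-truncated (the average runs over the
    columns that exist); ``window=1`` reproduces raw column PI. NaN columns
    are ignored inside a window (all-NaN windows stay NaN).
    """
    if window % 2 == 0 or window < 1:
        raise ParameterError(f"window must be odd and >= 1, got {window}")
    if window > alignment.n_columns:
        raise ParameterError("window larger than alignment")
    raw = np.array(
        [column_identity(alignment, c) for c in range(1, alignment.n_columns + 1)]
    )
    if window == 1:
        return ConservationProfile(raw, 1)
    half = window // 2
    smoothed = np.empty_like(raw)
    for i in range(len(raw)):
        lo, hi = max(0, i - half), min(len(raw), i + half + 1)
        seg = raw[lo:hi]
        smoothed[i] = np.nan if np.all(np.isnan(seg)) else np.nanmean(seg)
    return ConservationProfile(smoothed, window)


def _consensus(column: list[str]) -> str:
    counts: dict[str, int] = {}
    for ch in column:
        if ch != GAP and ch not in PROTEIN_AMBIGUOUS:
            counts[ch] = counts.get(ch, 0) + 1
    if not counts:
        return GAP
    best = max(counts.values())
    return min(c for c, n in counts.items() if n == best)


def find_conserved_runs(alignment: Alignment, ref_id: str,
                        min_length: int = 6, threshold: float = 100.0,
                        ) -> list[tuple[int, int, str]]:
    """Maximal runs of consecutive reference residues whose columns all have
    PI >= ``threshold``, reported as (ref_start, ref_end, consensus).

    Columns where the reference row is gapped (insertions relative to the
    reference) break runs, so every run maps to an uninterrupted stretch of
    the reference sequence.
    """
    if not 0 < threshold <= 100:
        raise ParameterError("threshold must be in (0, 100]")
    if min_length < 1:
        raise ParameterError("min_length must be >= 1")
    row = alignment.row(ref_id).residues
    runs: list[tuple[int, int, str]] = []
    run_start = None
    run_cons: list[str] = []
    residue = 0
    last_residue = 0

    def close():
        nonlocal run_start, run_cons
        if run_start is not None and last_residue - run_start + 1 >= min_length:
            runs.append((run_start, last_residue, "".join(run_cons)))
        run_start, run_cons = None, []

    for col, ch in enumerate(row, start=1):
        if ch == GAP:
            close()
            continue
        residue += 1
        column = alignment.column(col)
        pi = column_identity(alignment, col)
        if not np.isnan(pi) and pi >= threshold:
            if run_start is None:
                run_start = residue
            last_residue = residue
            run_cons.append(_consensus(column))
        else:
            close()
    close()
    return runs


@dataclass
class LogoMatrix:
    """Per-column amino-acid relative frequencies for a region, with per
    column information content (log2 20 minus Shannon entropy, bits).

    Gaps are excluded from the denominators; a column with no countable
    residue is flagged all-gap (frequencies and information NaN).
    """

    frequencies: pd.DataFrame  # index = AMINO_ACIDS, one column per position
    information: np.ndarray
    region: RegionAnnotation
    all_gap_columns: list[int] = field(default_factory=list)


def logo_matrix(alignment: Alignment, region: RegionAnnotation) -> LogoMatrix:
    columns = map_reference_to_columns(
        alignment, region.ref_id, region.start, region.end
    )
    max_info = np.log2(len(AMINO_ACIDS))
    freqs = np.zeros((len(AMINO_ACIDS), len(columns)))
    info = np.zeros(len(columns))
    all_gap = []
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for j, col in enumerate(columns):
        counts = np.zeros(len(AMINO_ACIDS))
        for ch in alignment.column(col):
            if ch in aa_index:
                counts[aa_index[ch]] += 1
        total = counts.sum()
        if total == 0:
            freqs[:, j] = np.nan
            info[j] = np.nan
            all_gap.append(region.start + j)
            continue
        p = counts / total
        freqs[:, j] = p
        nz = p[p > 0]
        info[j] = max_info + float((nz * np.log2(nz)).sum())
    positions = list(range(region.start, region.start + len(columns)))
    df = pd.DataFrame(freqs, index=list(AMINO_ACIDS), columns=positions)
    return LogoMatrix(df, info, region, all_gap)


def length_filter(records: list[SequenceRecord]) -> tuple[list[SequenceRecord],
                                                          list[SequenceRecord]]:
    """Drop sequences shorter than half the mean ungapped length.

    The mean is computed over **all** inputs in a single pass before any
    removal; order is preserved in both outputs.
    """
    if not records:
        raise ParameterError("length_filter needs at least one record")
    lengths = [len(r.ungapped()) for r in records]
    cutoff = 0.5 * (sum(lengths) / len(lengths))
    kept = [r for r, ln in zip(records, lengths) if ln >= cutoff]
    discarded = [r for r, ln in zip(records, lengths) if ln < cutoff]
    return kept, discarded


def mask_columns(alignment: Alignment, max_gap_fraction: float,
                 ) -> tuple[Alignment, list[int]]:
    """Remove columns whose gap fraction exceeds ``max_gap_fraction``.

    Returns the masked alignment and the kept-column map (original 1-based
    column indices) so downstream results can be reported in original
    coordinates. A simple stand-in for heavier alignment-trimming tools.
    """
    if not 0 <= max_gap_fraction <= 1:
        raise ParameterError("max_gap_fraction must be in [0, 1]")
    gap_frac = (alignment.matrix == GAP).mean(axis=0)
    kept = [i + 1 for i in range(alignment.n_columns)
            if gap_frac[i] <= max_gap_fraction]
    rows = [
        SequenceRecord(r.id, "".join(r.residues[c - 1] for c in kept), r.description)
        for r in alignment.rows
    ]
    return Alignment(rows), kept


# ---------------------------------------------------------------------------
# Model / Results


class ConservationModel:
    """Conservation analysis of a protein alignment.

    Parameters
    ----------
    alignment : Alignment
        Gapped protein MSA.
    regions : list of RegionAnnotation, optional
        Domain annotations in reference-residue coordinates (e.g. the
        CAP/Hinge/CAT/Linker organisation of type IB topoisomerases).
    reference : str, optional
        Row id anchoring reference coordinates; defaults to the ref_id of the
        first region, else the first row.
    """

    def __init__(self, alignment: Alignment,
                 regions: list[RegionAnnotation] | None = None,
                 reference: str | None = None):
        self.alignment = alignment
        self.regions = list(regions) if regions else []
        if reference is None:
            reference = (self.regions[0].ref_id if self.regions
                         else alignment.rows[0].id)
        alignment.row(reference)  # raises KeyError if absent
        self.reference = reference

    @classmethod
    def from_files(cls, alignment_path, regions_path=None, reference=None):
        from . import seqio
        aln = seqio.read_alignment(alignment_path, "protein")
        regions = seqio.read_regions(regions_path) if regions_path else None
        return cls(aln, regions, reference)

    def fit(self, window: int = 1, run_threshold: float = 100.0,
            run_min_length: int = 6) -> "ConservationResults":
        profile = identity_profile(self.alignment, window)
        rows = [region_identity(self.alignment, r) for r in self.regions]
        runs = find_conserved_runs(
            self.alignment, self.reference, run_min_length, run_threshold
        )
        return ConservationResults(self, profile, rows, runs,
                                   run_threshold, run_min_length)


class ConservationResults:
    """Fitted conservation statistics: per-column profile, per-region PI table
    and fully conserved runs."""

    def __init__(self, model: ConservationModel, profile: ConservationProfile,
                 region_rows: list[RegionIdentityRow],
                 runs: list[tuple[int, int, str]],
                 run_threshold: float, run_min_length: int):
        self.model = model
        self.profile = profile
        self.region_rows = region_rows
        self.runs = runs
        self.run_threshold = run_threshold
        self.run_min_length = run_min_length

    @property
    def region_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "region": r.region.name,
                    "start": r.region.start,
                    "end": r.region.end,
                    "length_aa": r.n_residues,
                    "pi_percent": r.pi_percent,
                }
                for r in self.region_rows
            ]
        )

    @property
    def runs_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.runs, columns=["ref_start", "ref_end", "consensus"]
        )

    def summary(self) -> str:
        lines = [
            "Conservation analysis",
            f"  alignment: {self.model.alignment.n_rows} rows x "
            f"{self.model.alignment.n_columns} columns",
            f"  reference: {self.model.reference}",
            f"  mean column PI: {np.nanmean(self.profile.per_column_pi):.1f}%",
            "  gap convention: one-gap pair = mismatch, two-gap pair excluded, "
            "X matches nothing",
        ]
        if self.region_rows:
            lines.append("  region\tstart\tend\tlength\tPI%")
            for r in self.region_rows:
                lines.append(
                    f"  {r.region.name}\t{r.region.start}\t{r.region.end}"
                    f"\t{r.n_residues}\t{r.pi_percent:.1f}"
                )
        lines.append(
            f"  conserved runs (PI >= {self.run_threshold:g}%, "
            f"length >= {self.run_min_length}): {len(self.runs)}"
        )
        for start, end, cons in self.runs:
            lines.append(f"    {start}-{end}\t{cons}")
        return "\n".join(lines)

    def plot_profile(self, ax=None):
        """Bar plot of the smoothed per-column PI (optional helper)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2.5))
        pi = self.profile.per_column_pi
        ax.bar(np.arange(1, len(pi) + 1), pi, width=1.0,
               color=np.where(pi >= np.nanmedian(pi), "sienna", "firebrick"))
        ax.set_xlabel("alignment column")
        ax.set_ylabel("PI (%)")
        ax.set_ylim(0, 100)
        return ax
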