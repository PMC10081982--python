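# Methods

This note documents the statistical models and procedures implemented in
`paralog_evol`, their assumptions, the defaults that matter, and the design
choices made where more than one reasonable option existed.

## Pairwise-identity conservation (conservation module)

**Statistic.** PI at an alignment column is the percentage of identical
unordered row pairs among counted pairs. Gap convention (it changes absolute
values, so it is stated in every report header):

* a pair with exactly one gap is a counted mismatch;
* a pair of two gaps is excluded from numerator and denominator;
* the ambiguity character never matches anything, including itself — `X` in
  protein columns; nucleotide routines treat `N` the same way (`N` is
  asparagine in protein columns and matches normally there);
* an all-gap column carries no information and reports NaN.

Region PI pools pair counts across the region's columns rather than
averaging column percentages. Pooling is exactly invariant to subdividing a
region (tested); a mean of percentages is not, and would weight sparse
columns equally with dense ones.

**Coordinates.** All user-facing positions are 1-based inclusive
reference-residue coordinates; `map_reference_to_columns` resolves them to
alignment columns by counting the reference row's non-gap characters.
Conserved-run detection reports runs in reference coordinates, and columns
where the reference is gapped break runs — a run is a claim about an
uninterrupted stretch of the reference protein.

**Profile smoothing** is a centred moving average with shrinking edge
windows; the default window is 1 (raw values), since no particular smoothing
is canonical. Sequence-logo matrices exclude gaps from the denominators and
report information content as `log2(20) − H` bits per column.

**Length filtering** of unaligned sequence sets drops sequences shorter
than half the arithmetic mean length of *all* inputs, computed once before
any removal (a single pass, not an iteration to a fixed point).

**Column masking** removes columns whose gap fraction exceeds a threshold
and returns a kept-column map so downstream results can be reported in the
original coordinates. It is deliberately simple plumbing, not a re-creation
of structure- or entropy-aware trimming tools.

## Counting-based dN/dS (dnds module)

**Model.** A SLAC-family counting estimator on a codon alignment and a
rooted tree. Both paralogues analysed here are nuclear-encoded, so the
standard nuclear genetic code is used throughout.

*Expected sites.* For a sense codon, the 9 single-nucleotide mutants are
enumerated; mutants creating stops are excluded from the mutational target;
with weight κ on transitions, synonymous sites are
`3 Σ_syn w / Σ_counted w` (and analogously nonsynonymous), so every sense
codon contributes exactly 3 sites regardless of stop exclusions. Worked
example: TGG (Trp) has two stop-adjacent mutants; the remaining 7 are all
nonsynonymous, giving (0, 3). Per-site ES/EN are the branch-parent codon
values averaged over the branches counted at that site.

*κ̂.* The transition/transversion ratio used in site weighting is estimated
from synonymous substitutions only — their observed ts/tv split divided by
the ts/tv split of synonymous mutational opportunity — which keeps κ̂
independent of selection on amino acids. Each rate is corrected for
multiple hits with the saturation form matching its chain (transitions
toggle a 2-state pair: `λ = −½ ln(1−2p)`; transversions move on a 3-state
set: `λ = −⅔ ln(1−3p/2)`), with 0.5 pseudocounts guarding empty classes.

*Ancestors and observed counts.* Ancestral codons come from unit-cost
parsimony over the observed codon states (gap codons are missing data;
subtrees without data are pruned). The default counting layer does **not**
commit to one reconstruction: per site, observed synonymous/nonsynonymous
counts are the expectation over all maximum-parsimony reconstructions, each
weighted by `ω̂^(number of nonsynonymous changes)`, computed by dynamic
programming (validated against exhaustive enumeration) and iterated with
ω̂ starting at 1 until it moves by less than 1e-3 (at most 8 rounds, and
typically 3–4). A hard tie-break necessarily biases the estimate in the
direction of its rule; weighting reconstruction ambiguity by the current
plausibility of amino-acid change is the counting-world analogue of the
likelihood-based ancestors used by SLAC implementations. A single-
reconstruction mode (`reconstruction="single"`) retains the deterministic
Fitch assignment with a documented tie-break (inherit the parent state when
possible, else minimise nonsynonymous change, then lexicographic order) for
exact, auditable counts.

*Multi-nucleotide codon changes* are averaged over all orderings of single
steps whose intermediates are sense codons (TTT→GTA: two stop-free paths,
averaging to 0.5 synonymous + 1.5 nonsynonymous changes). If every ordering
passes through a stop, the fallback counts one change classified by the
end-state amino acids.

*Saturation correction.* Counting parent/child differences misses multiple
hits at one position on one branch, which depresses dS (synonymous changes
saturate first) and biases the ratio upward. Each branch's observed
synonymous (nonsynonymous) total is therefore inflated by `λ/p` with
`λ = −¾ ln(1−4p/3)`, where p is the branch's observed changes per available
(κ-weighted) site — the correction Nei–Gojobori apply to pairwise
proportions, applied per branch. p is capped at 0.70 so the logarithm stays
finite on saturated branches. The correction is an option
(`saturation_correction`), on by default; raw counts (with which the
per-site totals equal the reconstruction's substitution count exactly) are
available by switching it off.

*Global estimate and uncertainty.* `dN = ΣON/ΣEN`, `dS = ΣOS/ΣES`,
`ratio = dN/dS` (flagged undefined when dS = 0). The 95 % CI is a
percentile bootstrap over codon sites (default 1000 replicates, fixed
default seed 20230118; replicates with dS = 0 are dropped and logged). The
bootstrap captures site-sampling variance, not tree or reconstruction
uncertainty.

*Per-site tests.* Each site with n = ON + OS observed changes is tested
two-tailed against Binomial(n, EN/(EN+ES)); fractional multi-hit counts are
rounded to the nearest integer for the test. Sites with p ≤ α are PSS on
ON-excess, NSS on OS-excess; α defaults to 0.05 with no multiple-testing
correction, following counting-method convention (stated in the output
metadata). Sites with n = 0 are uninformative and excluded.

*Tree input.* The phylogeny is an input; when absent, a neighbor-joining
tree on nucleotide p-distances is built as a fallback (deterministic,
negative branch lengths clamped to zero). Counting uses topology only.

**Accuracy under the study conditions** (8 taxa, 300 codons, exponential
branch lengths of mean 0.1, κ = 2): mean estimates across 20 seeded
replicates are within ±10 % of the generating ω at 0.154, 0.307 and 1.0,
with bootstrap-CI coverage of the truth in ≥ 17/20 runs — the test suite
and the acceptance script recompute these numbers. Residual upward bias of
a few percent at strong purifying selection comes from reconstruction
error on deep branches that no counting method removes.

## Archaic-variant calling (variants module)

**Pileup.** Reads stay in genomic orientation; CIGAR M consumes query and
reference, I and S consume query only, D consumes reference only (the
supported subset; spliced and hard-clip operations are rejected since the
intended inputs are short contig fragments). For every base the distance to
its read's nearer end is recorded.

**The three criteria.** A candidate position (any non-reference, non-N base
present; the majority such base is the variant) passes only if:

1. depth ≥ 2 — total overlapping reads, N included;
2. variant fraction strictly > 0.75 of all reads — 3 of 4 fails;
3. at least one supporting base lies ≥ 5 bases from both ends of its read.

"Distance from the read end" is not a standard quantity; the margin is a
parameter (`end_margin`, default 5) recorded in output metadata, not a
claim about any particular instrument. Failing candidates are emitted with
tags (MIN_DEPTH, MAX_FRACTION, READ_END) so the filter can be audited.
Indels are out of scope. N bases count toward depth but never toward
variant support.

**Annotation.** Effects come from a CDS exon model: the genomic position is
mapped through the exon structure honouring strand (minus strand: alleles
complemented, coordinate order reversed — reverse complementation happens
only here, keeping one canonical coordinate system), the codon rebuilt, and
the call classified silent/missense/nonsense; protein position is
`ceil(cds_position/3)`. Domain placement requires non-overlapping regions
and uses inclusive boundaries. Lineage polarisation takes the ancestral
state from outgroup consensus only when all outgroups agree; the lineage
carrying the derived allele is labelled mutated (`"X > Y"`, X ancestral);
disagreeing outgroups or doubly derived configurations give `ambiguous`.

## Synthetic-data generators (simulate module)

All generators are driven by one integer seed and are bit-reproducible.
They emulate the *statistical structure* of the real inputs, not their
biology: no indels, no rate heterogeneity across sites, no ancient-DNA
damage profiles, equal codon frequencies at the root, and independence
across columns. Passing tests therefore demonstrate correctness of the
algorithms under these idealised conditions, not performance on real
archaic reads or deep metazoan alignments.

* **Codon simulator** — explicit mutation events along each branch
  (Poisson with one proposal per nucleotide per unit branch length), κ-biased
  target choice, rejection of stops, nonsynonymous proposals accepted with
  probability ω; returns an exact per-branch event log used as ground truth.
  Defaults: 8 taxa, 300 codons, κ = 2, coalescent-style random trees with
  exponential branch lengths of mean 0.1 substitutions/site — a desk-scale
  stand-in for a chordate ortholog set.
* **Region-structured MSA** — per-column substitution probability p solved
  in closed form from the target pair identity q via
  `(20/19)p² − 2p + (1−q) = 0` (every row, the coordinate reference
  included, mutates independently from a random ancestor, so all pairs share
  the calibrated identity). An optional invariant block plants a fully
  conserved motif. Defaults mirror the published per-domain identity
  contrasts (e.g. divergent N-terminal vs conserved catalytic core).
* **Read simulator** — Poisson read counts at mean coverage 10, uniform
  starts, 50 bp reads, per-read coin flips at the planted allele fraction,
  sequencing errors at 10⁻³ per base. Errors are never injected at planted
  sites so the truth table (realised depth, alt count, end offsets per
  site) stays exact; realised fractions fluctuate around the planted value
  by design. A deterministic factorial fixture covers the caller's
  criterion combinations; the cells where a depth-1 site would also need a
  sub-75 % fraction are mathematically infeasible (one read gives fraction
  1) and are omitted.
* **Archaic scenario fixture** — a 601-codon minus-strand gene split over
  two exons with three planted human/archaic differences (silent Asp in the
  CAP domain derived in the modern-human lineage; archaic Gln→Arg and
  Gln→Lys in the Linker at positions 533/536), with two synthetic ape
  outgroup sequences carrying the ancestral alleles.

## Numerical and degenerate-input choices

* Bootstrap percentiles are 2.5/97.5 of finite replicate ratios.
* κ̂ falls back to 1 when there is no synonymous opportunity of either
  class; saturation proportions are capped (0.45 ts, 0.60 tv, 0.70 branch).
* Identical sequences give zero p-distances and a star-like NJ tree;
  negative NJ branch lengths are clamped to zero with a log note.
* All-gap alignment columns, all-gap logo columns and zero-information
  test sites are flagged rather than raised.
* Region lengths are always computed from coordinates (`end − start + 1`);
  annotation tables that print a different length are treated as
  typographical and never reproduced.

## Known limitations

* Parsimony-based ancestors (even averaged over reconstructions) undercount
  changes on long branches; the per-branch correction recovers same-branch
  multiple hits but not parallel changes collapsed into ancestors, leaving
  a small upward bias of the ratio under strong purifying selection.
* The bootstrap CI ignores tree and reconstruction uncertainty.
* The per-site binomial test on rounded counts is approximate for heavily
  averaged multi-hit sites.
* The caller has no damage model: C→T deamination artefacts in real
  ancient reads would need dedicated handling before trusting T alleles.
* PI is strict identity; no substitution-matrix similarity is offered.
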