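# paralog-evol

Comparative molecular-evolution toolkit for paralogous gene pairs, built
around the human type IB topoisomerases: nuclear **TOP1** (765 aa) and the
nuclear-encoded, mitochondrially targeted **TOP1MT** (601 aa). It bundles the
three analyses such a comparison needs, each as a statsmodels-style
Model/Results pair, plus seeded generators so every stage is testable
without downloading sequence databases.

1. **Conservation profiling** (`ConservationModel`) — per-column and
   per-domain pairwise identity (PI) of a protein alignment, sliding-window
   profiles, sequence-logo matrices, and detection of fully conserved runs
   (e.g. the invariant `AKVFRT` catalytic stretch at TOP1 positions
   586–591). PI at a column is
   `100 x (identical unordered row pairs) / (counted pairs)`, where a pair
   with one gap counts as a mismatch, a two-gap pair is excluded, and `X`
   matches nothing; region PI pools pair counts over columns.
2. **Counting-based dN/dS** (`DndsModel`) — a SLAC-family estimator:
   Nei–Gojobori 9-mutant site counts (κ-weighted, κ̂ estimated from
   synonymous transitions/transversions), ancestral codons by parsimony
   with substitution counts averaged over all maximum-parsimony
   reconstructions weighted by ω̂^(nonsynonymous changes), a per-branch
   multiple-hit correction, a percentile-bootstrap 95 % CI over codon
   sites, and per-site binomial tests for positively/negatively selected
   sites (PSS/NSS). `dN/dS = (ΣON/ΣEN)/(ΣOS/ΣES)`; values < 1 indicate
   purifying selection.
3. **Archaic-variant calling** (`VariantCallerModel`) — pileups from short
   aligned reads and a three-criterion SNV filter (depth ≥ 2, variant
   fraction strictly > 75 %, at least one supporting base ≥ 5 bp from both
   read ends), followed by strand-aware silent/missense/nonsense
   annotation from a CDS exon model, protein-domain placement, and
   outgroup-polarised lineage assignment ("which lineage mutated?").

## Worked example

```python
from paralog_evol import DndsModel, SimulationConfig
from paralog_evol.simulate import random_tree, simulate_codon_alignment

tree = random_tree(8, seed=500)
cfg = SimulationConfig(seed=1000, omega=0.154, n_codons=300, tree=tree)
alignment, truth = simulate_codon_alignment(cfg)

results = DndsModel(alignment, tree=tree).fit()
print(results.summary())
```

```
Counting-based dN/dS (parsimony-ancestor SLAC-style)
  sequences: 8   codon sites: 300   tree: user
  ancestors: expectation over omega-weighted parsimony reconstructions (3 iteration(s)); saturation correction: on
  kappa (ts/tv) used for expected sites: 1.913
  dN = 0.2724   dS = 1.5045
  global dN/dS = 0.181 [0.150-0.213]  (95% percentile bootstrap, 1000 replicates, seed 20230118)
  PSS: 0   NSS: 27   (binomial test, alpha = 0.05, no multiplicity correction)
  nucleotide pairwise identity: 83.8%
```

The alignment was simulated under ω = 0.154 (the purifying regime of a
slowly evolving nuclear paralogue); the estimator returns 0.181 with a CI
containing the truth, detects no positively selected sites, and flags many
negatively selected ones — exactly the signature expected under strong
purifying selection.

The same analyses are available from the shell:

```bash
paralog-evol conserve --alignment msa.fasta --regions domains.tsv --reference HUMAN_TOP1
paralog-evol dnds --codon-alignment cds.fasta --tree tree.nwk --ci-reps 1000
paralog-evol callvars --reads reads.sam --reference ref.fasta --cds cds.tsv \
    --regions domains.tsv --outgroups apes.fasta
paralog-evol simulate codons --seed 1 --out sim/
```

Each subcommand writes TSV reports with a `#`-prefixed metadata block
(version, seed, parameters, statistical conventions); reruns on identical
inputs are byte-identical. `paralog_evol.datasets` ships the published
domain coordinates of both human proteins for use as default annotations.

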