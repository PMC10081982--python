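"""End-to-end runs with machine-readable TSV reports.

Every report is a TSV preceded by a ``#``-prefixed metadata block recording
the tool version, seed, parameters and statistical conventions, so a run can
be reproduced from its own output. Re-running on identical inputs and seed
yields byte-identical reports (no timestamps).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import __version__, seqio
from .conservation import ConservationModel
from .dnds import DEFAULT_BOOTSTRAP_SEED, DndsModel
from .errors import ConfigError
from .variants import CallerParams, VariantCallerModel

logger = logging.getLogger(__name__)

GAP_CONVENTION = ("PI gap convention: one-gap pair = mismatch, "
                  "two-gap pair excluded, ambiguity matches nothing")


def _write_report(df: pd.DataFrame, path, metadata: dict) -> None:
    lines = [f"# {k}: {v}" for k, v in metadata.items()]
    header = "\n".join(["# paralog-evol " + __version__, *lines]) + "\n"
    Path(path).write_text(header + df.to_csv(sep="\t", index=False,
                                             float_format="%.6g"))


def run_conservation(alignment_path, regions_path=None, reference=None,
                     window: int = 1, run_threshold: float = 100.0,
                     run_min_length: int = 6, out_dir=".") -> "ConservationModel":
    """Region report + per-column profile + conserved-runs report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aln = seqio.read_alignment(alignment_path, "protein")
    regions = seqio.read_regions(regions_path) if regions_path else []
    if reference is not None and reference not in [r.id for r in aln.rows]:
        raise ConfigError(f"reference id {reference!r} not in the alignment")
    model = ConservationModel(aln, regions, reference)
    results = model.fit(window, run_threshold, run_min_length)
    meta = {
        "analysis": "conservation",
        "alignment": Path(alignment_path).name,
        "rows": aln.n_rows,
        "columns": aln.n_columns,
        "reference": model.reference,
        "window": window,
        "convention": GAP_CONVENTION,
    }
    _write_report(results.region_table, out / "regions.tsv", meta)
    profile_df = pd.DataFrame({
        "column": range(1, aln.n_columns + 1),
        "pi_percent": results.profile.per_column_pi,
    })
    _write_report(profile_df, out / "profile.tsv", meta)
    runs_meta = dict(meta, run_threshold=run_threshold,
                     run_min_length=run_min_length)
    _write_report(results.runs_table, out / "runs.tsv", runs_meta)
    return results


def run_dnds(alignment_path, tree_path=None, ci_replicates: int = 1000,
             seed: int = DEFAULT_BOOTSTRAP_SEED, alpha: float = 0.05,
             kappa="estimate", out_dir=".") -> "DndsResults":
    """Global dN/dS report (with CI and alignment PI) plus per-site table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = DndsModel.from_files(alignment_path, tree_path)
    results = model.fit(kappa=kappa, ci_replicates=ci_replicates,
                        seed=seed, alpha=alpha)
    e = results.estimate
    global_df = pd.DataFrame([{
        "n_sequences": model.calign.alignment.n_rows,
        "n_sites": e.n_sites,
        "substitution_model": "n/a - counting method",
        "kappa_used": results.kappa,
        "dn": e.dn,
        "ds": e.ds,
        "ratio": e.ratio,
        "ci_low": e.ci_low,
        "ci_high": e.ci_high,
        "n_pss": len(e.pss),
        "n_nss": len(e.nss),
        "pairwise_identity_percent": results.pairwise_identity,
    }])
    meta = {
        "analysis": "dnds",
        "alignment": Path(alignment_path).name,
        "tree": Path(tree_path).name if tree_path else "neighbor-joining fallback",
        "seed": seed,
        "ci_replicates": ci_replicates,
        "alpha": alpha,
        "method": "parsimony-ancestor counting (SLAC-style), "
                  "percentile bootstrap over codon sites",
        "convention": GAP_CONVENTION,
    }
    _write_report(global_df, out / "global.tsv", meta)
    _write_report(results.site_table, out / "sites.tsv", meta)
    return results


def run_callvars(reads_path, reference_path, cds_path=None, regions_path=None,
                 outgroups_path=None, min_depth: int = 2,
                 min_fraction: float = 0.75, end_margin: int = 5,
                 reads_dialect: str | None = None, out_dir=".",
                 ) -> "VariantCallResults":
    """Minimal VCF plus an annotation TSV mirroring the published variant
    table columns."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if reads_dialect is None:
        reads_dialect = ("sam_subset" if str(reads_path).endswith(".sam")
                         else "read_table")
    reads = seqio.read_reads(reads_path, reads_dialect)
    ref_records = seqio.read_fasta(reference_path, "nucleotide")
    reference = ref_records[0].residues
    reference_name = ref_records[0].id
    cds = None
    if cds_path:
        cds = seqio.read_cds_model(cds_path).extract_coding(reference)
    regions = seqio.read_regions(regions_path) if regions_path else None
    outgroups = None
    if outgroups_path:
        outgroups = {r.id: r.residues
                     for r in seqio.read_fasta(outgroups_path, "nucleotide")}
    params = CallerParams(min_depth, min_fraction, end_margin)
    model = VariantCallerModel(reads, reference, params, cds, regions, outgroups)
    results = model.fit()
    results.to_vcf(out / "calls.vcf", reference_name)
    meta = {
        "analysis": "callvars",
        "reads": Path(reads_path).name,
        "reference": reference_name,
        "min_depth": params.min_depth,
        "min_fraction": f"{params.min_fraction:g} (strictly greater-than)",
        "end_margin": f"{params.end_margin} bases from both read ends",
    }
    _write_report(results.table, out / "annotation.tsv", meta)
    return results
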