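"""Counting-based dN/dS estimation in the SLAC family.

The estimator works in four stages, each exposed as a function:

1. :func:`validate_codon_alignment` — frame, stop-codon and gap-phase checks
   on an in-frame nucleotide alignment.
2. :func:`fitch_ancestors` — per-site ancestral codons by Fitch parsimony on
   whole codons over the observed codon alphabet. Parsimony is a
   deterministic stand-in for likelihood-based ancestor reconstruction; the
   counting layer only consumes a parent/child codon per branch, so a
   likelihood provider can be swapped in.
3. :func:`count_substitutions` — per branch and site, observed substitutions
   classified synonymous/nonsynonymous (multi-hit codons averaged over all
   stop-free orderings of single steps) and expected synonymous/nonsynonymous
   site counts accumulated from branch parent codons.
4. :func:`global_dnds` / :func:`site_selection_test` — the global ratio
   dN/dS = (ΣON/ΣEN)/(ΣOS/ΣES) with a percentile-bootstrap 95% CI over codon
   sites, and per-site two-tailed binomial tests for positively/negatively
   selected sites (PSS/NSS).

Expected sites use Nei–Gojobori-style 9-mutant enumeration
(:func:`ng_site_counts`), optionally weighted by a transition/transversion
ratio κ. :class:`DndsModel` by default estimates κ̂ from synonymous
substitutions only (their ts/tv split against the ts/tv split of synonymous
mutational opportunity, each rate corrected for multiple hits with its
chain-appropriate saturation formula), which keeps expected sites consistent
with a transition-biased substitution process.

Two refinements beyond raw single-reconstruction counting, both on by
default in :meth:`DndsModel.fit` and both bypassable:

* **Expectation over reconstructions** — instead of committing to one
  tie-broken ancestor assignment, observed counts are averaged over *all*
  maximum-parsimony reconstructions, each weighted by ω̂ raised to its
  number of nonsynonymous changes, with ω̂ iterated from 1 to convergence.
  This approximates what likelihood-based ancestors provide: reconstruction
  ambiguity is resolved by how plausible amino-acid change currently looks,
  not by a fixed rule, and it removes the directional bias a hard tie-break
  imposes (toward low ω under a synonymous-preferring rule, toward high ω
  under an arbitrary one).
* **Per-branch saturation correction** — counting parent/child differences
  misses multiple hits at the same position on one branch. Each branch's
  observed synonymous (nonsynonymous) total is inflated by the
  Jukes-Cantor-style factor lambda/p with lambda = -3/4 ln(1 - 4p/3), where
  p is that branch's observed changes per available site — the same
  correction Nei-Gojobori apply to pairwise proportions, applied per branch.

The genetic code is the standard nuclear code throughout: both paralogues
studied here (the nuclear and the mitochondrially targeted topoisomerase I)
are nuclear-encoded genes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Phylo.BaseTree import Clade, Tree
from Bio.Phylo.TreeConstruction import DistanceMatrix, DistanceTreeConstructor
from scipy import stats

from ._codon import CODON_TABLE, is_stop, single_mutants
from .conservation import _pair_counts
from .errors import (
    CodonFrameError,
    GapPhaseError,
    ParameterError,
    StopCodonError,
)
from .seqio import GAP, Alignment, SequenceRecord

logger = logging.getLogger(__name__)

GAP_CODON = GAP * 3

DEFAULT_BOOTSTRAP_SEED = 20230118


class CodonAlignment:
    """An in-frame nucleotide alignment viewed as codon columns.

    Gaps occur only in whole-codon units; no row contains an internal stop.
    """

    def __init__(self, alignment: Alignment, codons: dict[str, list[str]]):
        self.alignment = alignment
        self.codons = codons
        self.n_codons = alignment.n_columns // 3

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.alignment.rows]

    def pairwise_identity(self) -> float:
        """Pooled nucleotide PI (%) over all alignment columns (N is the
        ambiguity character here and matches nothing)."""
        identical = counted = 0
        for col in range(1, self.alignment.n_columns + 1):
            i, c = _pair_counts(self.alignment.column(col), frozenset("N"))
            identical += i
            counted += c
        return 100.0 * identical / counted if counted else float("nan")


def validate_codon_alignment(records: list[SequenceRecord] | Alignment,
                             ) -> CodonAlignment:
    """Check frame, gap phase and internal stops; return a CodonAlignment."""
    alignment = records if isinstance(records, Alignment) else Alignment(records)
    if alignment.n_columns % 3:
        raise CodonFrameError(
            f"alignment length {alignment.n_columns} not divisible by 3"
        )
    codons: dict[str, list[str]] = {}
    n_codons = alignment.n_columns // 3
    for row in alignment.rows:
        row_codons = []
        for i in range(n_codons):
            codon = row.residues[3 * i:3 * i + 3]
            n_gaps = codon.count(GAP)
            if n_gaps == 3:
                row_codons.append(GAP_CODON)
                continue
            if n_gaps:
                raise GapPhaseError(
                    f"row {row.id}: partial-codon gap {codon!r} at codon "
                    f"{i + 1} (gaps must cover whole codons)"
                )
            if is_stop(codon) and i < n_codons - 1:
                raise StopCodonError(
                    f"row {row.id}: internal stop codon {codon} at codon {i + 1}"
                )
            row_codons.append(codon)
        codons[row.id] = row_codons
    return CodonAlignment(alignment, codons)


def ng_site_counts(codon: str, kappa: float = 1.0) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts for one sense codon.

    Enumerates the 9 single-nucleotide mutants; mutants that create stop
    codons are excluded from the mutational target. With weights w (κ for a
    transition, 1 for a transversion):

        syn_sites    = 3 * Σ_syn w    / Σ_counted w
        nonsyn_sites = 3 * Σ_nonsyn w / Σ_counted w

    so syn + nonsyn = 3 for every sense codon regardless of stop-mutant
    exclusions — the codon always offers three mutable positions, normalised
    over the mutations that can actually fix. κ = 1 gives the classic
    unweighted Nei–Gojobori counts.
    """
    if is_stop(codon):
        raise ParameterError(f"{codon} is a stop codon")
    aa = CODON_TABLE[codon]
    syn_w = nonsyn_w = 0.0
    for mutant, _pos, ts in single_mutants(codon):
        if is_stop(mutant):
            continue
        w = kappa if ts else 1.0
        if CODON_TABLE[mutant] == aa:
            syn_w += w
        else:
            nonsyn_w += w
    total = syn_w + nonsyn_w
    return 3.0 * syn_w / total, 3.0 * nonsyn_w / total


# ---------------------------------------------------------------------------
# Fitch parsimony ancestors


def _children(clade: Clade) -> list[Clade]:
    return list(clade.clades)


def fitch_ancestors(tree: Tree, calign: CodonAlignment,
                    ) -> dict[int, list[str | None]]:
    """Per-site ancestral codon states for every clade, keyed by ``id(clade)``.

    Bottom-up pass builds Fitch state sets over the observed codon alphabet
    (generalised to multifurcations: states present in the maximal number of
    child sets). Gap codons are missing data and contribute nothing. The
    top-down pass assigns one state per node: a node inherits its parent's
    state when possible, otherwise picks the candidate minimising
    nonsynonymous change (then lexicographically smallest codon). Ties are
    counted in ``fitch_ancestors.last_ambiguous``.
    """
    leaves = {leaf.name for leaf in tree.get_terminals()}
    ids = set(calign.codons)
    if leaves != ids:
        missing = sorted(leaves ^ ids)
        raise ParameterError(
            "tree leaves and alignment ids differ: " + ", ".join(missing)
        )
    n_sites = calign.n_codons
    state_sets: dict[int, list[frozenset[str] | None]] = {}
    postorder = list(tree.find_clades(order="postorder"))
    for clade in postorder:
        if clade.is_terminal():
            sets = []
            for codon in calign.codons[clade.name]:
                sets.append(None if codon == GAP_CODON else frozenset([codon]))
            state_sets[id(clade)] = sets
            continue
        sets = []
        for s in range(n_sites):
            child_sets = [state_sets[id(c)][s] for c in _children(clade)]
            child_sets = [cs for cs in child_sets if cs is not None]
            if not child_sets:
                sets.append(None)
                continue
            counts: dict[str, int] = {}
            for cs in child_sets:
                for state in cs:
                    counts[state] = counts.get(state, 0) + 1
            best = max(counts.values())
            sets.append(frozenset(s_ for s_, n in counts.items() if n == best))
        state_sets[id(clade)] = sets

    def tie_break(candidates: frozenset[str], clade: Clade, s: int,
                  parent_state: str | None) -> str:
        if parent_state is not None and parent_state in candidates:
            return parent_state
        def score(state):
            cost = 0
            for child in _children(clade):
                cs = state_sets[id(child)][s]
                if cs is None or state in cs:
                    continue
                same_aa = any(CODON_TABLE[c] == CODON_TABLE[state] for c in cs)
                cost += 0 if same_aa else 1
            if parent_state is not None:
                cost += 0 if CODON_TABLE[parent_state] == CODON_TABLE[state] else 1
            return cost
        ranked = sorted(candidates, key=lambda c: (score(c), c))
        return ranked[0]

    assigned: dict[int, list[str | None]] = {}
    ambiguous = 0
    pmap = _parent_map(tree)
    for clade in tree.find_clades(order="preorder"):
        if clade.is_terminal():
            assigned[id(clade)] = [
                None if c == GAP_CODON else c for c in calign.codons[clade.name]
            ]
            continue
        parent = pmap.get(id(clade))
        states: list[str | None] = []
        for s in range(n_sites):
            cands = state_sets[id(clade)][s]
            if cands is None:
                states.append(None)
                continue
            if len(cands) > 1:
                ambiguous += 1
            parent_state = assigned[parent][s] if parent is not None else None
            states.append(tie_break(cands, clade, s, parent_state))
        assigned[id(clade)] = states
    fitch_ancestors.last_ambiguous = ambiguous
    return assigned


def _parent_map(tree: Tree) -> dict[int, int]:
    pmap: dict[int, int] = {}
    for clade in tree.find_clades():
        for child in clade.clades:
            pmap[id(child)] = id(clade)
    return pmap


# ---------------------------------------------------------------------------
# Substitution counting


@dataclass
class SiteCounts:
    """Per-codon-site expected and observed synonymous/nonsynonymous counts."""

    exp_syn: np.ndarray  # ES per site
    exp_nonsyn: np.ndarray  # EN per site
    obs_syn: np.ndarray  # OS per site
    obs_nonsyn: np.ndarray  # ON per site
    kappa: float = 1.0
    # fractional ts/tv tallies of synonymous steps, for kappa estimation
    syn_ts_observed: float = 0.0
    syn_tv_observed: float = 0.0
    syn_ts_opportunity: float = 0.0
    syn_tv_opportunity: float = 0.0

    @property
    def n_sites(self) -> int:
        return len(self.exp_syn)


def _codon_paths(parent: str, child: str):
    """All orderings of single-nucleotide steps from parent to child whose
    intermediates are sense codons. Yields lists of (from, to) steps."""
    diff = [i for i in range(3) if parent[i] != child[i]]
    for order in itertools.permutations(diff):
        current = parent
        steps = []
        ok = True
        for pos in order:
            nxt = current[:pos] + child[pos] + current[pos + 1:]
            if is_stop(nxt):
                ok = False
                break
            steps.append((current, nxt))
            current = nxt
        if ok:
            yield steps


def _classify_steps(parent: str, child: str):
    """(syn, nonsyn, syn_ts, syn_tv) fractional counts for one branch-site
    codon change, averaged over all stop-free single-step orderings.

    If every ordering passes through a stop codon the fallback applies: one
    change classified by the end-state amino-acid comparison (not tallied for
    κ̂ since its ts/tv identity is undefined).
    """
    if parent == child:
        return 0.0, 0.0, 0.0, 0.0
    paths = list(_codon_paths(parent, child))
    if not paths:
        same_aa = CODON_TABLE[parent] == CODON_TABLE[child]
        return (1.0, 0.0, 0.0, 0.0) if same_aa else (0.0, 1.0, 0.0, 0.0)
    syn = nonsyn = syn_ts = syn_tv = 0.0
    for steps in paths:
        for a, b in steps:
            pos = next(i for i in range(3) if a[i] != b[i])
            ts = (a[pos] in "AG") == (b[pos] in "AG")
            if CODON_TABLE[a] == CODON_TABLE[b]:
                syn += 1
                if ts:
                    syn_ts += 1
                else:
                    syn_tv += 1
            else:
                nonsyn += 1
    k = len(paths)
    return syn / k, nonsyn / k, syn_ts / k, syn_tv / k


def _syn_opportunity(codon: str) -> tuple[int, int]:
    """(ts, tv) counts of synonymous single-nucleotide mutants of a codon."""
    aa = CODON_TABLE[codon]
    ts_n = tv_n = 0
    for mutant, _pos, ts in single_mutants(codon):
        if is_stop(mutant) or CODON_TABLE[mutant] != aa:
            continue
        if ts:
            ts_n += 1
        else:
            tv_n += 1
    return ts_n, tv_n


class _BranchTally:
    """Per-branch accumulator: observed syn/nonsyn per site plus branch-level
    totals of observed changes and available (κ-weighted) sites."""

    __slots__ = ("obs_syn", "obs_nonsyn", "syn_sites", "nonsyn_sites")

    def __init__(self, n_sites: int):
        self.obs_syn = np.zeros(n_sites)
        self.obs_nonsyn = np.zeros(n_sites)
        self.syn_sites = 0.0
        self.nonsyn_sites = 0.0


def _saturation_factor(total_changes: float, available_sites: float) -> float:
    """Jukes-Cantor-style multiple-hit inflation for one branch.

    With p observed changes per available site, the expected number of
    events per site is lambda = -3/4 ln(1 - 4p/3); the factor lambda/p >= 1
    scales observed counts up. p is capped at 0.70 to keep the logarithm
    finite on saturated branches.
    """
    if available_sites <= 0 or total_changes <= 0:
        return 1.0
    p = min(total_changes / available_sites, 0.70)
    return float(-0.75 * np.log(1.0 - 4.0 * p / 3.0) / p)


def _aggregate(branches: dict, n: int, exp_syn, exp_nonsyn, branch_n,
               kappa: float, kappa_tallies: tuple[float, float, float, float],
               saturation_correction: bool) -> SiteCounts:
    obs_syn = np.zeros(n)
    obs_nonsyn = np.zeros(n)
    for tally in branches.values():
        if saturation_correction:
            fs = _saturation_factor(tally.obs_syn.sum(), tally.syn_sites)
            fn = _saturation_factor(tally.obs_nonsyn.sum(), tally.nonsyn_sites)
        else:
            fs = fn = 1.0
        obs_syn += tally.obs_syn * fs
        obs_nonsyn += tally.obs_nonsyn * fn
    with np.errstate(invalid="ignore"):
        es = np.where(branch_n > 0, exp_syn / np.maximum(branch_n, 1e-12), 0.0)
        en = np.where(branch_n > 0, exp_nonsyn / np.maximum(branch_n, 1e-12), 0.0)
    o_ts, o_tv, p_ts, p_tv = kappa_tallies
    return SiteCounts(es, en, obs_syn, obs_nonsyn, kappa,
                      o_ts, o_tv, p_ts, p_tv)


def count_substitutions(tree: Tree, calign: CodonAlignment,
                        ancestors: dict[int, list[str | None]] | None = None,
                        kappa: float = 1.0,
                        saturation_correction: bool = False) -> SiteCounts:
    """Tally observed and expected substitutions per site over all branches
    of a single (tie-broken) ancestral reconstruction.

    For each branch and site with parent and child codons present: zero
    differences contribute nothing; one difference is classified by code
    lookup; two or three differences are averaged over all orderings of
    single steps whose intermediates are sense codons (if every ordering
    passes through a stop, the fallback counts one change classified by the
    end-state amino acids). Expected sites are the κ-weighted NG counts of
    the branch **parent** codon, averaged over the branches counted at that
    site. Without the saturation correction, Σ per-site (OS+ON) equals the
    total substitution count of the reconstruction summed over branches.
    """
    if ancestors is None:
        ancestors = fitch_ancestors(tree, calign)
    n = calign.n_codons
    exp_syn = np.zeros(n)
    exp_nonsyn = np.zeros(n)
    branch_n = np.zeros(n)
    o_ts = o_tv = p_ts = p_tv = 0.0
    pmap = _parent_map(tree)
    site_cache: dict[str, tuple[float, float]] = {}
    branches: dict[int, _BranchTally] = {}
    for clade in tree.find_clades():
        parent = pmap.get(id(clade))
        if parent is None:
            continue
        pstates = ancestors[parent]
        cstates = ancestors[id(clade)]
        tally = branches.setdefault(id(clade), _BranchTally(n))
        for s in range(n):
            pc, cc = pstates[s], cstates[s]
            if pc is None or cc is None:
                continue
            if pc not in site_cache:
                site_cache[pc] = ng_site_counts(pc, kappa)
            es, en = site_cache[pc]
            exp_syn[s] += es
            exp_nonsyn[s] += en
            branch_n[s] += 1
            tally.syn_sites += es
            tally.nonsyn_sites += en
            ts_n, tv_n = _syn_opportunity(pc)
            p_ts += ts_n
            p_tv += tv_n
            if pc != cc:
                syn, nonsyn, s_ts, s_tv = _classify_steps(pc, cc)
                tally.obs_syn[s] += syn
                tally.obs_nonsyn[s] += nonsyn
                o_ts += s_ts
                o_tv += s_tv
    return _aggregate(branches, n, exp_syn, exp_nonsyn, branch_n, kappa,
                      (o_ts, o_tv, p_ts, p_tv), saturation_correction)


# ---------------------------------------------------------------------------
# Expectation over maximum-parsimony reconstructions

_INF = 10 ** 9


def _edge_weight(a: str, b: str, omega: float) -> float:
    if a == b:
        return 1.0
    _syn, nonsyn, _ts, _tv = _classify_steps(a, b)
    return max(omega, 1e-6) ** nonsyn


def _site_pair_marginals(tree: Tree, leaf_state: dict[str, str | None],
                         omega: float,
                         ) -> dict[tuple[int, int], dict[tuple[str, str], float]]:
    """Marginal probabilities of (parent codon, child codon) per branch,
    over all maximum-parsimony reconstructions of one site, each weighted
    by omega^(its nonsynonymous changes).

    Unit-cost parsimony over the observed codon states; leaves with missing
    codons (and subtrees without data) are pruned. Validated against
    exhaustive MPR enumeration in the test suite.
    """
    states = sorted({c for c in leaf_state.values() if c is not None})
    if not states:
        return {}
    cost: dict[int, dict[str, float]] = {}
    weight: dict[int, dict[str, float]] = {}
    has_data: dict[int, bool] = {}
    for v in tree.find_clades(order="postorder"):
        if v.is_terminal():
            obs = leaf_state.get(v.name)
            has_data[id(v)] = obs is not None
            if obs is None:
                continue
            cost[id(v)] = {a: (0 if a == obs else _INF) for a in states}
            weight[id(v)] = {a: (1.0 if a == obs else 0.0) for a in states}
            continue
        kids = [c for c in v.clades if has_data[id(c)]]
        has_data[id(v)] = bool(kids)
        if not kids:
            continue
        cv, wv = {}, {}
        for a in states:
            tot_c, tot_w = 0, 1.0
            for c in kids:
                cc = cost[id(c)]
                best = min(cc[b] + (0 if a == b else 1) for b in states)
                tot_c += best
                tot_w *= sum(weight[id(c)][b] * _edge_weight(a, b, omega)
                             for b in states
                             if cc[b] + (0 if a == b else 1) == best)
            cv[a], wv[a] = tot_c, tot_w
        cost[id(v)], weight[id(v)] = cv, wv
    root = tree.root
    if not has_data.get(id(root)):
        return {}
    m = min(cost[id(root)].values())
    z = sum(weight[id(root)][a] for a in states if cost[id(root)][a] == m)
    node_marg = {id(root): {a: (weight[id(root)][a] / z
                                if cost[id(root)][a] == m else 0.0)
                            for a in states}}
    pair: dict[tuple[int, int], dict[tuple[str, str], float]] = {}
    for v in tree.find_clades(order="preorder"):
        if v.is_terminal() or not has_data.get(id(v)):
            continue
        for c in (k for k in v.clades if has_data[id(k)]):
            pm: dict[tuple[str, str], float] = {}
            marg_c = {b: 0.0 for b in states}
            cc = cost[id(c)]
            for a in states:
                pa = node_marg[id(v)].get(a, 0.0)
                if pa <= 0:
                    continue
                best = min(cc[b] + (0 if a == b else 1) for b in states)
                opts = [b for b in states
                        if cc[b] + (0 if a == b else 1) == best]
                wsum = sum(weight[id(c)][b] * _edge_weight(a, b, omega)
                           for b in opts)
                for b in opts:
                    p = pa * weight[id(c)][b] * _edge_weight(a, b, omega) / wsum
                    if p > 0:
                        pm[(a, b)] = pm.get((a, b), 0.0) + p
                        marg_c[b] += p
            pair[(id(v), id(c))] = pm
            node_marg[id(c)] = marg_c
    return pair


def expected_substitution_counts(tree: Tree, calign: CodonAlignment,
                                 omega: float = 1.0, kappa: float = 1.0,
                                 saturation_correction: bool = True,
                                 ) -> SiteCounts:
    """Observed/expected tallies averaged over ω-weighted MPRs.

    Site patterns are deduplicated so the reconstruction DP runs once per
    distinct leaf-codon pattern.
    """
    n = calign.n_codons
    names = list(calign.codons)
    patterns: dict[tuple, list[int]] = {}
    for s in range(n):
        key = tuple(calign.codons[name][s] for name in names)
        patterns.setdefault(key, []).append(s)
    exp_syn = np.zeros(n)
    exp_nonsyn = np.zeros(n)
    branch_n = np.zeros(n)
    o_ts = o_tv = p_ts = p_tv = 0.0
    branches: dict[tuple[int, int], _BranchTally] = {}
    site_cache: dict[str, tuple[float, float]] = {}
    syn_cache: dict[str, tuple[int, int]] = {}
    cls_cache: dict[tuple[str, str], tuple] = {}
    for key, sites in patterns.items():
        leaf_state = {name: (None if c == GAP_CODON else c)
                      for name, c in zip(names, key)}
        pair = _site_pair_marginals(tree, leaf_state, omega)
        for edge, pm in pair.items():
            tally = branches.setdefault(edge, _BranchTally(n))
            for (a, b), p in pm.items():
                if a not in site_cache:
                    site_cache[a] = ng_site_counts(a, kappa)
                es, en = site_cache[a]
                if a not in syn_cache:
                    syn_cache[a] = _syn_opportunity(a)
                ts_n, tv_n = syn_cache[a]
                w = p * len(sites)
                tally.syn_sites += w * es
                tally.nonsyn_sites += w * en
                p_ts += w * ts_n
                p_tv += w * tv_n
                for s in sites:
                    exp_syn[s] += p * es
                    exp_nonsyn[s] += p * en
                    branch_n[s] += p
                if a != b:
                    if (a, b) not in cls_cache:
                        cls_cache[(a, b)] = _classify_steps(a, b)
                    syn, nonsyn, s_ts, s_tv = cls_cache[(a, b)]
                    o_ts += w * s_ts
                    o_tv += w * s_tv
                    for s in sites:
                        tally.obs_syn[s] += p * syn
                        tally.obs_nonsyn[s] += p * nonsyn
    return _aggregate(branches, n, exp_syn, exp_nonsyn, branch_n, kappa,
                      (o_ts, o_tv, p_ts, p_tv), saturation_correction)


def estimate_kappa(counts: SiteCounts) -> float:
    """κ̂ from synonymous substitutions only.

    The rate of synonymous transitions per transition opportunity and of
    synonymous transversions per transversion opportunity (opportunities
    summed over branch parent codons) are each corrected for multiple hits
    with the saturation formula matching their chain — a transition toggles
    a 2-state pair (lambda = -1/2 ln(1-2p)), a transversion moves on a
    3-state set (lambda = -2/3 ln(1-3p/2)) — and κ̂ is their ratio, with 0.5
    pseudocounts guarding empty classes. Estimating on synonymous changes
    keeps κ̂ independent of selection on amino acids.
    """
    if counts.syn_ts_opportunity <= 0 or counts.syn_tv_opportunity <= 0:
        return 1.0
    q_ts = min((counts.syn_ts_observed + 0.5) / counts.syn_ts_opportunity, 0.45)
    q_tv = min((counts.syn_tv_observed + 0.5) / counts.syn_tv_opportunity, 0.60)
    lam_ts = -0.5 * np.log(1.0 - 2.0 * q_ts)
    lam_tv = -(2.0 / 3.0) * np.log(1.0 - 1.5 * q_tv)
    return float(lam_ts / lam_tv)


# ---------------------------------------------------------------------------
# Global estimate and per-site tests


@dataclass
class DndsEstimate:
    """Global dN/dS with a bootstrap 95% CI and per-site selection calls."""

    dn: float
    ds: float
    ratio: float  # NaN when undefined (dS = 0)
    ci_low: float
    ci_high: float
    n_sites: int
    undefined: bool = False
    pss: list[tuple[int, float]] = field(default_factory=list)
    nss: list[tuple[int, float]] = field(default_factory=list)


def global_dnds(counts: SiteCounts, ci_replicates: int = 1000,
                seed: int = DEFAULT_BOOTSTRAP_SEED) -> DndsEstimate:
    """dN = ΣON/ΣEN, dS = ΣOS/ΣES, ratio = dN/dS, with a percentile
    bootstrap CI over codon sites (replicates with dS = 0 are dropped)."""
    sum_es, sum_en = counts.exp_syn.sum(), counts.exp_nonsyn.sum()
    if sum_es <= 0 or sum_en <= 0:
        raise ParameterError("degenerate input: no expected sites")
    dn = counts.obs_nonsyn.sum() / sum_en
    ds = counts.obs_syn.sum() / sum_es
    if ds == 0:
        return DndsEstimate(dn, ds, float("nan"), float("nan"), float("nan"),
                            counts.n_sites, undefined=True)
    ratio = dn / ds
    rng = np.random.default_rng(seed)
    n = counts.n_sites
    idx = rng.integers(0, n, size=(ci_replicates, n))
    es_b = counts.exp_syn[idx].sum(axis=1)
    en_b = counts.exp_nonsyn[idx].sum(axis=1)
    os_b = counts.obs_syn[idx].sum(axis=1)
    on_b = counts.obs_nonsyn[idx].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_b = (on_b / en_b) / (os_b / es_b)
    ratio_b = ratio_b[np.isfinite(ratio_b)]
    if len(ratio_b) < ci_replicates:
        logger.info("dropped %d bootstrap replicates with dS = 0",
                    ci_replicates - len(ratio_b))
    lo, hi = np.percentile(ratio_b, [2.5, 97.5]) if len(ratio_b) else (np.nan,) * 2
    return DndsEstimate(dn, ds, ratio, float(lo), float(hi), counts.n_sites)


def site_selection_test(counts: SiteCounts, alpha: float = 0.05,
                        ) -> tuple[list[tuple[int, float]],
                                   list[tuple[int, float]],
                                   np.ndarray]:
    """Two-tailed binomial test per site; returns (pss, nss, p_values).

    Site s with n = ON_s + OS_s observed changes tests ON_s against
    Binomial(n, EN_s/(EN_s+ES_s)). Fractional multi-hit counts are rounded to
    the nearest integer. Sites with n = 0 carry no information and are
    excluded (p = NaN). No multiple-testing correction is applied, following
    counting-method convention; sites are 1-based in the output lists.
    """
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    pss, nss = [], []
    pvals = np.full(counts.n_sites, np.nan)
    for s in range(counts.n_sites):
        n = int(round(counts.obs_syn[s] + counts.obs_nonsyn[s]))
        if n == 0:
            continue
        tot = counts.exp_syn[s] + counts.exp_nonsyn[s]
        if tot <= 0:
            continue
        p_neutral = counts.exp_nonsyn[s] / tot
        k = int(round(counts.obs_nonsyn[s]))
        k = min(k, n)
        p = stats.binomtest(k, n, p_neutral, alternative="two-sided").pvalue
        pvals[s] = p
        if p <= alpha:
            if k / n > p_neutral:
                pss.append((s + 1, float(p)))
            elif k / n < p_neutral:
                nss.append((s + 1, float(p)))
    return pss, nss, pvals


# ---------------------------------------------------------------------------
# Neighbor-joining fallback tree


def p_distance(a: str, b: str) -> float:
    """Proportion of differing positions among pairs with both bases known."""
    same = diff = 0
    for x, y in zip(a, b):
        if x in (GAP, "N") or y in (GAP, "N"):
            continue
        if x == y:
            same += 1
        else:
            diff += 1
    total = same + diff
    return diff / total if total else 0.0


def nj_tree(calign: CodonAlignment | Alignment) -> Tree:
    """Neighbor-joining on nucleotide p-distances (fallback when no tree is
    supplied). Deterministic given input order; negative branch lengths are
    clamped to zero with a log note."""
    alignment = calign.alignment if isinstance(calign, CodonAlignment) else calign
    names = [r.id for r in alignment.rows]
    if len(names) < 3:
        raise ParameterError("NJ needs at least 3 sequences")
    matrix = []
    for i, ri in enumerate(alignment.rows):
        matrix.append(
            [p_distance(ri.residues, alignment.rows[j].residues)
             for j in range(i)] + [0.0]
        )
    dm = DistanceMatrix(names, matrix)
    tree = DistanceTreeConstructor().nj(dm)
    clamped = 0
    for clade in tree.find_clades():
        if clade.branch_length is not None and clade.branch_length < 0:
            clade.branch_length = 0.0
            clamped += 1
        if not clade.is_terminal():
            clade.name = None  # drop constructor's Inner## labels
    if clamped:
        logger.info("clamped %d negative NJ branch lengths to 0", clamped)
    return tree


# ---------------------------------------------------------------------------
# Model / Results


class DndsModel:
    """Counting-based selection analysis of a codon alignment on a tree.

    Parameters
    ----------
    alignment : CodonAlignment, Alignment or list of SequenceRecord
        In-frame coding alignment (validated on construction).
    tree : Bio.Phylo tree, optional
        Phylogeny whose leaf labels equal the alignment ids. When omitted, a
        neighbor-joining tree on p-distances is built as a fallback.
    """

    def __init__(self, alignment, tree: Tree | None = None):
        self.calign = (alignment if isinstance(alignment, CodonAlignment)
                       else validate_codon_alignment(alignment))
        if self.calign.alignment.n_rows < 3:
            raise ParameterError("tree-based counting needs >= 3 sequences")
        self.tree = tree if tree is not None else nj_tree(self.calign)
        self.tree_source = "user" if tree is not None else "neighbor-joining"

    @classmethod
    def from_files(cls, alignment_path, tree_path=None):
        from . import seqio
        records = seqio.read_fasta(alignment_path, "nucleotide")
        tree = seqio.read_newick(tree_path) if tree_path else None
        return cls(records, tree)

    def fit(self, kappa: float | str = "estimate", ci_replicates: int = 1000,
            seed: int = DEFAULT_BOOTSTRAP_SEED, alpha: float = 0.05,
            reconstruction: str = "expected",
            saturation_correction: bool = True,
            max_iter: int = 8, tol: float = 1e-3) -> "DndsResults":
        """Estimate global and per-site selection.

        Parameters
        ----------
        kappa : "estimate" or float
            Transition/transversion ratio for expected-site weighting;
            "estimate" infers κ̂ from synonymous substitutions.
        reconstruction : {"expected", "single"}
            "expected" averages observed counts over ω̂-weighted
            maximum-parsimony reconstructions, iterating ω̂ from 1 until it
            moves less than ``tol`` (at most ``max_iter`` rounds);
            "single" commits to one Fitch reconstruction with the
            documented tie-break.
        saturation_correction : bool
            Per-branch multiple-hit inflation of observed counts.
        """
        if reconstruction not in ("expected", "single"):
            raise ParameterError(f"unknown reconstruction {reconstruction!r}")
        kappa_used = 1.0 if kappa == "estimate" else float(kappa)
        n_ambiguous = None
        n_iter = 1
        if reconstruction == "single":
            ancestors = fitch_ancestors(self.tree, self.calign)
            n_ambiguous = fitch_ancestors.last_ambiguous
            counts = count_substitutions(self.tree, self.calign, ancestors,
                                         kappa_used, saturation_correction)
            if kappa == "estimate":
                kappa_used = estimate_kappa(counts)
                counts = count_substitutions(self.tree, self.calign, ancestors,
                                             kappa_used, saturation_correction)
        else:
            omega_w = 1.0
            counts = None
            for n_iter in range(1, max_iter + 1):
                counts = expected_substitution_counts(
                    self.tree, self.calign, omega_w, kappa_used,
                    saturation_correction,
                )
                if kappa == "estimate":
                    kappa_used = estimate_kappa(counts)
                sum_os, sum_es = counts.obs_syn.sum(), counts.exp_syn.sum()
                sum_on, sum_en = counts.obs_nonsyn.sum(), counts.exp_nonsyn.sum()
                if sum_os <= 0 or sum_es <= 0 or sum_en <= 0:
                    break  # dS undefined; global_dnds reports the flag
                new_omega = (sum_on / sum_en) / (sum_os / sum_es)
                if abs(new_omega - omega_w) < tol:
                    omega_w = new_omega
                    break
                omega_w = new_omega
        estimate = global_dnds(counts, ci_replicates, seed)
        pss, nss, pvals = site_selection_test(counts, alpha)
        estimate.pss, estimate.nss = pss, nss
        return DndsResults(self, counts, estimate, pvals, kappa_used,
                           alpha, ci_replicates, seed, n_ambiguous,
                           reconstruction, saturation_correction, n_iter)


class DndsResults:
    """Fitted global and per-site selection estimates."""

    def __init__(self, model, counts, estimate, p_values, kappa, alpha,
                 ci_replicates, seed, n_ambiguous_states,
                 reconstruction="expected", saturation_correction=True,
                 n_iterations=1):
        self.model = model
        self.counts = counts
        self.estimate = estimate
        self.p_values = p_values
        self.kappa = kappa
        self.alpha = alpha
        self.ci_replicates = ci_replicates
        self.seed = seed
        self.n_ambiguous_states = n_ambiguous_states
        self.reconstruction = reconstruction
        self.saturation_correction = saturation_correction
        self.n_iterations = n_iterations

    @property
    def ratio(self) -> float:
        return self.estimate.ratio

    @property
    def pairwise_identity(self) -> float:
        return self.model.calign.pairwise_identity()

    @property
    def site_table(self) -> pd.DataFrame:
        c = self.counts
        cls = np.array(["-"] * c.n_sites, dtype=object)
        for s, _ in self.estimate.pss:
            cls[s - 1] = "PSS"
        for s, _ in self.estimate.nss:
            cls[s - 1] = "NSS"
        return pd.DataFrame({
            "site": np.arange(1, c.n_sites + 1),
            "exp_syn": c.exp_syn,
            "exp_nonsyn": c.exp_nonsyn,
            "obs_syn": c.obs_syn,
            "obs_nonsyn": c.obs_nonsyn,
            "p_value": self.p_values,
            "class": cls,
        })

    def summary(self) -> str:
        e = self.estimate
        ratio = "undefined (dS = 0)" if e.undefined else (
            f"{e.ratio:.3f} [{e.ci_low:.3f}-{e.ci_high:.3f}]"
        )
        recon = ("expectation over omega-weighted parsimony reconstructions"
                 f" ({self.n_iterations} iteration(s))"
                 if self.reconstruction == "expected"
                 else "single Fitch reconstruction")
        return "\n".join([
            "Counting-based dN/dS (parsimony-ancestor SLAC-style)",
            f"  sequences: {self.model.calign.alignment.n_rows}   "
            f"codon sites: {self.counts.n_sites}   tree: {self.model.tree_source}",
            f"  ancestors: {recon}; saturation correction: "
            f"{'on' if self.saturation_correction else 'off'}",
            f"  kappa (ts/tv) used for expected sites: {self.kappa:.3f}",
            f"  dN = {e.dn:.4f}   dS = {e.ds:.4f}",
            f"  global dN/dS = {ratio}  "
            f"(95% percentile bootstrap, {self.ci_replicates} replicates, "
            f"seed {self.seed})",
            f"  PSS: {len(e.pss)}   NSS: {len(e.nss)}   "
            f"(binomial test, alpha = {self.alpha}, no multiplicity correction)",
            f"  nucleotide pairwise identity: {self.pairwise_identity:.1f}%",
        ])
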