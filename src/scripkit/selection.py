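"""Counting-based selection analysis (NG86 sites, SLAC-style tests).

The workflow mirrors the standard practice for small secreted-toxin
families: strip the signal peptide (it evolves under different pressures
than the mature toxin), subsample paralogs to one sequence per species in
replicate, mask weakly informative codon columns, reconstruct ancestral
codons by parsimony on a tree, count synonymous (S) and nonsynonymous (N)
changes per site against Nei-Gojobori (1986) expected site counts, test
each site with an exact binomial, and summarise a global
omega = (sum N / sum EN) / (sum S / sum ES).

Conventions: each non-stop single-nucleotide neighbor of a codon
contributes 1/3 of a site (stop neighbors are excluded entirely);
multi-nucleotide codon changes are averaged over all shortest mutational
pathways that avoid stop codons (all pathways are used in the rare case
every one passes through a stop).  The binomial site test rounds the
pathway-averaged counts to the nearest integers; no multiple-testing
correction is applied.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .alignment import CodonAlignment, mask_columns, p_distance_matrix
from .phylo import nj_tree
from .records import CODON_TO_AA, STOP_CODONS, SeqRecord
from .tree import Node, SupportTree

__all__ = [
    "SelectionConfig",
    "SiteRecord",
    "SelectionResult",
    "strip_signal_peptides",
    "subsample_paralogs",
    "ng86_site_counts",
    "pathway_counts",
    "fitch_ancestral_codons",
    "slac_site_test",
    "global_omega",
    "run_selection",
]

_BASES = "ACGT"
_DNA = set(_BASES)


@dataclass
class SelectionConfig:
    n_replicates: int = 3
    seed: int = 0
    site_alpha: float = 0.05
    mask_threshold: float = 0.50
    exclusion_list: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0 < self.site_alpha < 1):
            raise ValueError("site_alpha must be in (0, 1)")
        self.exclusion_list = frozenset(self.exclusion_list)


def strip_signal_peptides(records: Sequence[SeqRecord]) -> list[SeqRecord]:
    """Truncate every record to its mature region (nt and aa).

    Requires ``signal_peptide_end`` on every record; raises listing the
    offending ids otherwise.  Concatenating the removed prefix restores
    the original sequence.
    """
    missing = [r.id for r in records if r.signal_peptide_end is None]
    if missing:
        raise ValueError(f"signal_peptide_end unset for: {sorted(missing)}")
    out = []
    for r in records:
        k = r.signal_peptide_end
        out.append(
            r.with_(
                aa=r.aa[k:],
                nt=r.nt[3 * k :] if r.nt else "",
                signal_peptide_end=None,
            )
        )
    return out


def subsample_paralogs(
    records: Sequence[SeqRecord], config: SelectionConfig
) -> list[list[SeqRecord]]:
    """One randomly chosen record per species, in ``n_replicates``
    replicates (replicate r draws from a stream seeded ``seed + r``).

    The species set of every replicate equals the input species set.
    """
    by_species: dict[str, list[SeqRecord]] = {}
    for r in records:
        by_species.setdefault(r.species, []).append(r)
    species = sorted(by_species)
    replicates = []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng(config.seed + rep)
        chosen = []
        for sp in species:
            group = sorted(by_species[sp], key=lambda r: r.id)
            chosen.append(group[rng.integers(0, len(group))])
        replicates.append(chosen)
    return replicates


# -- NG86 site and substitution counting -----------------------------------

def _neighbors(codon: str) -> list[str]:
    out = []
    for pos in range(3):
        for b in _BASES:
            if b != codon[pos]:
                out.append(codon[:pos] + b + codon[pos + 1 :])
    return out


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Expected (synonymous, nonsynonymous) site counts of a sense codon.

    Each of the 9 single-nucleotide neighbors contributes 1/3 of a site to
    the class of its change; neighbors that are stop codons contribute
    nothing, so ES + EN = (non-stop neighbors)/3.
    """
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon}")
    if codon not in CODON_TO_AA:
        raise ValueError(f"ambiguous or invalid codon {codon!r}")
    syn = nonsyn = 0
    for nb in _neighbors(codon):
        if nb in STOP_CODONS:
            continue
        if CODON_TO_AA[nb] == CODON_TO_AA[codon]:
            syn += 1
        else:
            nonsyn += 1
    return syn / 3.0, nonsyn / 3.0


@lru_cache(maxsize=None)
def pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (nonsynonymous, synonymous) change counts c1->c2.

    Averages over all orderings of the differing positions whose
    intermediate codons avoid stops; falls back to all orderings when
    every path is blocked.
    """
    c1, c2 = c1.upper(), c2.upper()
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked] or [
        steps for _, steps in paths
    ]
    n_tot = s_tot = 0.0
    for steps in usable:
        for a, b in steps:
            aa_a = CODON_TO_AA.get(a, "*")
            aa_b = CODON_TO_AA.get(b, "*")
            if aa_a == aa_b:
                s_tot += 1
            else:
                n_tot += 1
    k = len(usable)
    return n_tot / k, s_tot / k


# -- ancestral reconstruction ----------------------------------------------

def _valid_codon(codon: Optional[str]) -> bool:
    return (
        codon is not None
        and set(codon) <= _DNA
        and codon not in STOP_CODONS
    )


def fitch_ancestral_codons(
    tree: SupportTree, alignment: CodonAlignment, site: int
) -> dict[int, Optional[str]]:
    """Fitch parsimony codon states at one site, keyed by ``id(node)``.

    Leaves with gap/ambiguous/stop codons at the site carry no state and
    are ignored.  Ambiguity at internal nodes resolves toward the state
    observed in the most leaves of the subtree, ties broken
    lexicographically.
    """
    leaf_state: dict[str, Optional[str]] = {}
    for i, sid in enumerate(alignment.ids):
        codon = alignment.codon(i, site)
        leaf_state[sid] = codon if _valid_codon(codon) else None

    sets: dict[int, Optional[frozenset[str]]] = {}
    leaf_counts: dict[int, dict[str, int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            st = leaf_state.get(node.name)
            sets[id(node)] = frozenset({st}) if st else None
            leaf_counts[id(node)] = {st: 1} if st else {}
        else:
            child_sets = [sets[id(c)] for c in node.children if sets[id(c)]]
            counts: dict[str, int] = {}
            for c in node.children:
                for st, k in leaf_counts[id(c)].items():
                    counts[st] = counts.get(st, 0) + k
            leaf_counts[id(node)] = counts
            if not child_sets:
                sets[id(node)] = None
            else:
                inter = frozenset.intersection(*child_sets)
                sets[id(node)] = inter if inter else frozenset.union(*child_sets)

    states: dict[int, Optional[str]] = {}

    def choose(node: Node, candidates: frozenset[str]) -> str:
        counts = leaf_counts[id(node)]
        return min(candidates, key=lambda st: (-counts.get(st, 0), st))

    for node in tree.preorder():
        if node.is_leaf:
            states[id(node)] = leaf_state.get(node.name)
            continue
        s = sets[id(node)]
        if s is None:
            states[id(node)] = None
            continue
        if node.parent is not None:
            pstate = states.get(id(node.parent))
            if pstate in s:
                states[id(node)] = pstate
                continue
        states[id(node)] = choose(node, s)
    return states


# -- per-site test and global omega ----------------------------------------

@dataclass
class SiteRecord:
    site: int  # 1-based masked-column index
    n_changes: float
    s_changes: float
    en: float
    es: float
    dn: Optional[float]
    ds: Optional[float]
    p_value: float
    call: str  # positive | negative | neutral


def _site_counts(
    tree: SupportTree, alignment: CodonAlignment, site: int
) -> Optional[tuple[float, float, float, float]]:
    """(N, S, EN, ES) summed over branches at one masked site."""
    valid_leaves = sum(
        _valid_codon(alignment.codon(i, site)) for i in range(len(alignment.ids))
    )
    if valid_leaves < 2:
        return None
    states = fitch_ancestral_codons(tree, alignment, site)
    N = S = EN = ES = 0.0
    for node in tree.preorder():
        if node.parent is None:
            continue
        child = states[id(node)]
        parent = states[id(node.parent)]
        if child is None or parent is None:
            continue
        n, s = pathway_counts(parent, child)
        N += n
        S += s
        es_c, en_c = ng86_site_counts(parent)
        EN += en_c
        ES += es_c
    return N, S, EN, ES


def slac_site_test(
    tree: SupportTree,
    alignment: CodonAlignment,
    site: int,
    config: Optional[SelectionConfig] = None,
) -> Optional[SiteRecord]:
    """Counting test at one masked codon column.

    Two-sided exact binomial of round(N) successes in round(N+S) trials
    against the expected nonsynonymous proportion EN/(EN+ES); calls
    ``positive``/``negative`` when significant at ``site_alpha`` with the
    observed proportion above/below expectation.  Returns None for sites
    with fewer than two informative leaves.
    """
    config = config or SelectionConfig()
    counts = _site_counts(tree, alignment, site)
    if counts is None:
        return None
    N, S, EN, ES = counts
    dn = N / EN if EN > 0 else None
    ds = S / ES if ES > 0 else None
    trials = int(round(N + S))
    if trials == 0 or EN + ES == 0:
        return SiteRecord(site + 1, N, S, EN, ES, dn, ds, 1.0, "neutral")
    p0 = EN / (EN + ES)
    k = min(int(round(N)), trials)
    p = binomtest(k, trials, p0, alternative="two-sided").pvalue
    call = "neutral"
    if p < config.site_alpha:
        obs = N / (N + S)
        call = "positive" if obs > p0 else "negative"
    return SiteRecord(site + 1, N, S, EN, ES, dn, ds, float(p), call)


def global_omega(tree: SupportTree, alignment: CodonAlignment) -> Optional[float]:
    """(sum N / sum EN) / (sum S / sum ES) over all masked sites and
    branches; None (with a warning) when no synonymous change is seen."""
    N = S = EN = ES = 0.0
    for site_pos in range(len(alignment.column_mask)):
        counts = _site_counts(tree, alignment, site_pos)
        if counts is None:
            continue
        N += counts[0]
        S += counts[1]
        EN += counts[2]
        ES += counts[3]
    if S == 0 or EN == 0 or ES == 0:
        warnings.warn("global omega undefined: no synonymous substitutions observed")
        return None
    return (N / EN) / (S / ES)


@dataclass
class SelectionResult:
    replicate: int
    n_seqs: int
    n_sites: int
    sites: list[SiteRecord]
    global_omega: Optional[float]

    @property
    def n_positive(self) -> int:
        return sum(s.call == "positive" for s in self.sites)

    @property
    def n_negative(self) -> int:
        return sum(s.call == "negative" for s in self.sites)

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "replicate": self.replicate,
                    "site": s.site,
                    "N": s.n_changes,
                    "S": s.s_changes,
                    "EN": s.en,
                    "ES": s.es,
                    "dN": s.dn,
                    "dS": s.ds,
                    "p": s.p_value,
                    "call": s.call,
                }
                for s in self.sites
            ]
        )


def _default_tree_builder(alignment: CodonAlignment) -> SupportTree:
    ids, d = p_distance_matrix(alignment, "nucleotide")
    return nj_tree(ids, d)


def run_selection(
    records: Sequence[SeqRecord],
    config: Optional[SelectionConfig] = None,
    tree_builder: Optional[Callable[[CodonAlignment], SupportTree]] = None,
) -> tuple[list[SelectionResult], pd.DataFrame]:
    """Replicated selection analysis of a pre-aligned, signal-stripped set.

    Per replicate: subsample one paralog per species, mask codon columns
    at the 50% informative threshold, build the tree, run the per-site
    counting test, and estimate global omega.  The summary table carries
    one row per replicate plus a final mean row.
    """
    config = config or SelectionConfig()
    tree_builder = tree_builder or _default_tree_builder
    records = [r for r in records if r.id not in config.exclusion_list]
    if len({len(r.nt) for r in records}) > 1:
        raise ValueError("records must be aligned (equal nt lengths)")
    replicates = subsample_paralogs(records, config)
    results: list[SelectionResult] = []
    for rep_idx, subset in enumerate(replicates):
        aln = CodonAlignment([r.id for r in subset], [r.nt for r in subset])
        aln = mask_columns(aln, config.mask_threshold)
        if len(subset) < 3:
            raise ValueError("a replicate needs >= 3 sequences to build a tree")
        tree = tree_builder(aln)
        sites = [
            rec
            for pos in range(len(aln.column_mask))
            if (rec := slac_site_test(tree, aln, pos, config)) is not None
        ]
        # Global omega from the same per-site sums the tests used.
        N = sum(s.n_changes for s in sites)
        S = sum(s.s_changes for s in sites)
        EN = sum(s.en for s in sites)
        ES = sum(s.es for s in sites)
        omega = (N / EN) / (S / ES) if min(S, EN, ES) > 0 else None
        results.append(
            SelectionResult(
                replicate=rep_idx + 1,
                n_seqs=len(subset),
                n_sites=len(aln.column_mask),
                sites=sites,
                global_omega=omega,
            )
        )
    rows = [
        {
            "replicate": r.replicate,
            "n_seqs": r.n_seqs,
            "n_sites": r.n_sites,
            "n_positive": r.n_positive,
            "n_negative": r.n_negative,
            "global_omega": r.global_omega,
        }
        for r in results
    ]
    omegas = [r.global_omega for r in results if r.global_omega is not None]
    rows.append(
        {
            "replicate": "mean",
            "n_seqs": None,
            "n_sites": None,
            "n_positive": None,
            "n_negative": None,
            "global_omega": float(np.mean(omegas)) if omegas else None,
        }
    )
    return results, pd.DataFrame(rows)
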