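"""Synthetic toxin gene families with planted ground truth.

The generator emulates the structure of a small secreted cysteine-rich
toxin family: a hydrophobic signal peptide (default 22 residues), a mature
region (default 48 residues, matching the 40-48 aa range typical of the
family) realising a fixed eight-cysteine framework, subfamily structure
with controlled within/between nucleotide identity, per-subfamily dN/dS
regimes, and decoy non-toxin ORFs that each violate one screening
criterion.  Every output (records, true tree, alignment, metadata, truth
labels) is deterministic per seed and mutually consistent: the true tree's
clades equal the label groups.

Evolution is simulated by per-branch single-nucleotide codon substitution
sampling with an explicit nonsynonymous acceptance probability
implementing omega (accept nonsynonymous with min(1, omega), synonymous
with min(1, 1/omega)) rather than a full codon rate matrix - a transparent
simplification sufficient for parameter-recovery testing.  Cysteine codons
(and flagged framework prolines) are immutable, substitutions never create
stops, new cysteines, or a proline directly after a cysteine, so every
simulated record keeps the configured framework string.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .alignment import CodonAlignment
from .framework import CysFramework, parse_framework
from .screening import heuristic_signal_peptide, heuristic_tm_count
from .records import CODON_TO_AA, SeqRecord, STOP_CODONS, translate
from .tree import Node, SupportTree

__all__ = [
    "SynthConfig",
    "SynthFamily",
    "realize_framework",
    "generate_family",
    "generate_decoys",
    "simulate_codon_alignment",
    "DEFAULT_FRAMEWORK",
    "DEFAULT_SPECIES_POOL",
]

# The Amil_SCRiP2-style framework: eight cysteines, proline after the
# third, three adjacent cysteines near the C-terminus.
DEFAULT_FRAMEWORK = parse_framework("C(6)C(6)CP(5)C(6)C(6)CCC(2)")

# A plausible mix of stony-coral and sea-anemone sources.
DEFAULT_SPECIES_POOL: tuple[tuple[str, str, str], ...] = (
    ("Acropora millepora", "Acroporidae", "scleractinia_complex"),
    ("Acropora digitifera", "Acroporidae", "scleractinia_complex"),
    ("Montipora capitata", "Acroporidae", "scleractinia_complex"),
    ("Orbicella faveolata", "Merulinidae", "scleractinia_robust"),
    ("Stylophora pistillata", "Pocilloporidae", "scleractinia_robust"),
    ("Desmophyllum pertusum", "Caryophylliidae", "scleractinia_robust"),
    ("Actinia tenebrosa", "Actiniidae", "actiniaria"),
    ("Metridium senile", "Metridiidae", "actiniaria"),
)

_HYDROPHOBIC = "LAVIF"
# Filler excludes C (would change the framework) and P (a proline drifting
# next to a cysteine would change the descriptor).
_FILLER = "ADEGKNQSTVHY"
_HYDROPHILIC = "DDEEKNQSSTGR"

_CODONS_FOR: dict[str, list[str]] = {}
for _codon, _aa in CODON_TO_AA.items():
    _CODONS_FOR.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_FOR:
    _CODONS_FOR[_aa].sort()

_BASES = "ACGT"


@dataclass
class SynthConfig:
    seed: int = 0
    n_subfamilies: int = 4
    members_per_subfamily: Union[int, tuple[int, int]] = 8
    species_pool: Sequence[tuple[str, str, str]] = DEFAULT_SPECIES_POOL
    target_within_identity: float = 75.0
    target_between_identity: float = 45.0
    omega_per_subfamily: Optional[Sequence[float]] = None
    framework: CysFramework = DEFAULT_FRAMEWORK
    signal_len: int = 22
    mature_len: int = 48
    n_decoys: int = 0
    decoy_violations: tuple[str, ...] = (
        "no_signal", "too_long", "too_short", "low_identity", "multi_tm",
    )

    def __post_init__(self) -> None:
        if self.omega_per_subfamily is None:
            # Defaults mirror the observed family regimes: one subfamily
            # under diversifying selection, the rest purifying.
            base = (1.3, 0.65, 0.6, 0.55)
            self.omega_per_subfamily = tuple(
                base[i % len(base)] for i in range(self.n_subfamilies)
            )
        self.omega_per_subfamily = tuple(self.omega_per_subfamily)
        if len(self.omega_per_subfamily) != self.n_subfamilies:
            raise ValueError("omega_per_subfamily length must equal n_subfamilies")
        if not (0 < self.target_between_identity < self.target_within_identity <= 100):
            raise ValueError(
                "need 0 < target_between_identity < target_within_identity <= 100"
            )
        if self.mature_len < self.framework.length:
            raise ValueError(
                f"mature_len {self.mature_len} shorter than framework span "
                f"{self.framework.length}"
            )
        unknown = set(self.decoy_violations) - {
            "no_signal", "too_long", "too_short", "low_identity", "multi_tm"
        }
        if unknown:
            raise ValueError(f"unknown decoy violations: {sorted(unknown)}")
        if self.n_decoys > 0 and not self.decoy_violations:
            raise ValueError("n_decoys > 0 requires a non-empty violation set")


def realize_framework(
    framework: CysFramework,
    filler_distribution: str = _FILLER,
    seed: int = 0,
) -> str:
    """Concrete mature-region protein realising a framework descriptor.

    Cysteines (and flagged prolines) sit at the exact descriptor
    positions; every other residue is drawn from ``filler_distribution``.
    ``derive_framework(realize_framework(F)) == F`` for frameworks whose
    filler excludes C and P.
    """
    rng = np.random.default_rng(seed)

    def filler(k: int) -> str:
        return "".join(rng.choice(list(filler_distribution), size=k))

    parts: list[str] = []
    for i in range(framework.n_cys - 1):
        g = framework.gaps[i]
        if framework.proline_first[i]:
            parts.append("C" + "P" + filler(g - 1))
        else:
            parts.append("C" + filler(g))
    parts.append("C" + filler(framework.tail))
    return "".join(parts)


def _reverse_translate(aa: str, rng: np.random.Generator) -> str:
    return "".join(
        _CODONS_FOR[res][rng.integers(0, len(_CODONS_FOR[res]))] for res in aa
    )


def _mutable_flags(aa: str) -> list[bool]:
    """Codon positions free to mutate: everything except cysteines and
    prolines that immediately follow a cysteine."""
    flags = []
    for i, res in enumerate(aa):
        if res == "C":
            flags.append(False)
        elif res == "P" and i > 0 and aa[i - 1] == "C":
            flags.append(False)
        else:
            flags.append(True)
    return flags


def _evolve(
    nt: str,
    n_subs: int,
    omega: float,
    rng: np.random.Generator,
    protect_framework: bool = True,
) -> str:
    """Apply ``n_subs`` accepted single-nucleotide substitutions.

    Proposals are uniform over mutable codon positions and the three
    alternative bases; stops are never created; with framework protection
    new cysteines and cysteine-adjacent prolines are also forbidden.
    Nonsynonymous proposals are accepted with min(1, omega), synonymous
    with min(1, 1/omega).
    """
    codons = [nt[i : i + 3] for i in range(0, len(nt), 3)]
    aa = [CODON_TO_AA[c] for c in codons]
    if protect_framework:
        mutable = _mutable_flags("".join(aa))
    else:
        mutable = [True] * len(codons)
    mutable_idx = [i for i, m in enumerate(mutable) if m]
    if not mutable_idx:
        raise ValueError("no mutable codons")
    p_nonsyn = min(1.0, omega)
    p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    accepted = 0
    guard = 0
    while accepted < n_subs:
        guard += 1
        if guard > 1000 * max(n_subs, 1) + 10000:
            raise RuntimeError("substitution sampling failed to converge")
        ci = mutable_idx[rng.integers(0, len(mutable_idx))]
        pos = int(rng.integers(0, 3))
        old = codons[ci]
        base = _BASES[rng.integers(0, 4)]
        if base == old[pos]:
            continue
        new = old[:pos] + base + old[pos + 1 :]
        if new in STOP_CODONS:
            continue
        new_aa = CODON_TO_AA[new]
        if protect_framework:
            if new_aa == "C":
                continue
            if new_aa == "P" and ci > 0 and aa[ci - 1] == "C":
                continue
        syn = new_aa == aa[ci]
        p = p_syn if syn else p_nonsyn
        if p < 1.0 and rng.random() >= p:
            continue
        codons[ci] = new
        aa[ci] = new_aa
        accepted += 1
    return "".join(codons)


def _pair_nt_identity(a: str, b: str) -> float:
    return 100.0 * sum(x == y for x, y in zip(a, b)) / len(a)


def _calibrate_separation(
    root_nt: str, target_identity: float, seed: int, n_trials: int = 3
) -> int:
    """Bisect the total substitution separation between two lineages so
    that their realised nucleotide identity hits the target."""

    def realized(total: int) -> float:
        vals = []
        for t in range(n_trials):
            rng = np.random.default_rng((seed, total, t))
            a = _evolve(root_nt, total - total // 2, 1.0, rng)
            b = _evolve(root_nt, total // 2, 1.0, rng)
            vals.append(_pair_nt_identity(a, b))
        return float(np.mean(vals))

    lo, hi = 0, 6 * len(root_nt)
    if realized(hi) > target_identity:
        return hi
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if realized(mid) > target_identity:
            lo = mid
        else:
            hi = mid
    return hi


def _templates(config: SynthConfig) -> tuple[str, str, str, str]:
    """Shared ancestral templates: (signal_aa, mature_aa, signal_nt, mature_nt).

    Drawn from the config seed so that families and decoys generated from
    the same config share a common ancestor (decoys must fail only their
    planted criterion, not homology).
    """
    rng = np.random.default_rng(config.seed)
    lead = config.mature_len - config.framework.length
    mature_aa = "".join(
        rng.choice(list(_FILLER), size=lead)
    ) + realize_framework(config.framework, _FILLER, seed=int(rng.integers(2**31)))
    # The signal must score clearly above the secretion threshold on the
    # package's own hydropathy heuristic; redraw on unlucky A-heavy draws.
    for _ in range(100):
        signal_aa = "M" + "".join(
            rng.choice(list(_HYDROPHOBIC), size=config.signal_len - 1)
        )
        if config.signal_len < 20 or heuristic_signal_peptide(signal_aa)[0] > 0.75:
            break
    else:  # pragma: no cover - probability ~0
        raise RuntimeError("could not draw a hydrophobic signal peptide")
    mature_nt = _reverse_translate(mature_aa, rng)
    signal_nt = _reverse_translate(signal_aa, rng)
    return signal_aa, mature_aa, signal_nt, mature_nt


@dataclass
class SynthFamily:
    records: list[SeqRecord]
    truth: dict[str, str]  # id -> true subfamily label ("sf1", ...)
    tree: SupportTree
    alignment: CodonAlignment  # mature-region CDS, no indels
    metadata: pd.DataFrame

    @property
    def newick(self) -> str:
        return self.tree.to_newick()


def generate_family(config: Optional[SynthConfig] = None) -> SynthFamily:
    """Generate a toxin family with planted subfamily structure.

    One ancestral mature CDS realises the framework; subfamily ancestors
    and members are derived by substitution counts calibrated (by
    bisection) to the within/between identity targets; the emitted
    alignment covers the mature region (the signal peptide is held fixed
    and identical across records).
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed + 1)
    signal_aa, mature_aa, signal_nt, root_mature_nt = _templates(config)

    # Identity targets -> substitution separations (total across a pair).
    sep_within = _calibrate_separation(
        root_mature_nt, config.target_within_identity, seed=config.seed + 101
    )
    sep_between = _calibrate_separation(
        root_mature_nt, config.target_between_identity, seed=config.seed + 202
    )
    if sep_between <= sep_within:
        raise ValueError(
            "infeasible identity targets: between-separation does not exceed "
            "within-separation"
        )
    k_within = max(sep_within // 2, 1)
    k_between = max((sep_between - sep_within) // 2, 1)

    if isinstance(config.members_per_subfamily, int):
        sizes = [config.members_per_subfamily] * config.n_subfamilies
    else:
        lo, hi = config.members_per_subfamily
        sizes = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_subfamilies)]

    records: list[SeqRecord] = []
    truth: dict[str, str] = {}
    aln_ids: list[str] = []
    aln_rows: list[str] = []
    root = Node()
    pool = list(config.species_pool)
    subs_per_site = 1.0 / len(root_mature_nt)

    for j in range(config.n_subfamilies):
        omega = config.omega_per_subfamily[j]
        for attempt in range(50):
            anc_rng = np.random.default_rng((config.seed, 1, j, attempt))
            anc_nt = _evolve(root_mature_nt, k_between, omega, anc_rng)
            if heuristic_tm_count(signal_aa + translate(anc_nt)) <= 1:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw a TM-free subfamily ancestor")
        clade = Node(length=k_between * subs_per_site)
        root.add_child(clade)
        for i in range(sizes[j]):
            # Substitutions can by chance assemble a hydrophobic run in the
            # mature region that reads as a second membrane segment; such
            # draws are rejected so that every emitted record is a clean
            # single-signal secreted peptide.
            for attempt in range(50):
                mem_rng = np.random.default_rng((config.seed, 2, j, i, attempt))
                nt = _evolve(anc_nt, k_within, omega, mem_rng)
                if heuristic_tm_count(signal_aa + translate(nt)) <= 1:
                    break
            else:  # pragma: no cover - vanishingly unlikely
                raise RuntimeError("could not draw a TM-free family member")
            species, fam, lineage = pool[i % len(pool)]
            rid = f"sf{j + 1:02d}m{i + 1:02d}"
            rec = SeqRecord(
                id=rid,
                nt=signal_nt + nt,
                species=species,
                taxon_family=fam,
                lineage=lineage,
                source="transcriptome" if i % 2 else "genome",
                completeness="complete",
                life_stage=("adult", "larva", "gastrula", "egg")[i % 4],
                tissue="tentacle" if lineage == "actiniaria" else "",
                signal_peptide_end=config.signal_len,
                flags={"true_subfamily": f"sf{j + 1}"},
            )
            records.append(rec)
            truth[rid] = f"sf{j + 1}"
            aln_ids.append(rid)
            aln_rows.append(nt)
            clade.add_child(Node(name=rid, length=k_within * subs_per_site))

    tree = SupportTree(root, rooted=True)
    alignment = CodonAlignment(aln_ids, aln_rows)
    metadata = pd.DataFrame(
        [
            {
                "id": r.id,
                "species": r.species,
                "taxon_family": r.taxon_family,
                "lineage": r.lineage,
                "source": r.source,
                "completeness": r.completeness,
                "life_stage": r.life_stage or "",
                "tissue": r.tissue or "",
                "true_subfamily": truth[r.id],
            }
            for r in records
        ]
    )
    return SynthFamily(records, truth, tree, alignment, metadata)


def generate_decoys(config: Optional[SynthConfig] = None) -> list[SeqRecord]:
    """Decoy ORFs, each violating exactly one screening criterion.

    Violations are assigned round-robin from ``config.decoy_violations``
    and recorded in ``record.flags['violation']``; every other screening
    criterion is satisfied by construction.
    """
    config = config or SynthConfig()
    if config.n_decoys < 0:
        raise ValueError("n_decoys must be >= 0")
    if config.n_decoys > 0 and not config.decoy_violations:
        raise ValueError("decoy_violations must be non-empty")
    rng = np.random.default_rng(config.seed + 777)
    lead = config.mature_len - config.framework.length
    signal_aa, base_mature, _, _ = _templates(config)

    decoys: list[SeqRecord] = []
    for d in range(config.n_decoys):
        violation = config.decoy_violations[d % len(config.decoy_violations)]
        if violation == "too_long":
            extra = 101 - (config.signal_len + len(base_mature))
            aa = signal_aa + base_mature + "".join(
                rng.choice(list(_FILLER), size=max(extra, 1) + 4)
            )
        elif violation == "too_short":
            aa = (signal_aa + base_mature)[:55]
        elif violation == "no_signal":
            hydrophilic = "".join(
                rng.choice(list(_HYDROPHILIC), size=config.signal_len)
            )
            aa = hydrophilic + base_mature
        elif violation == "multi_tm":
            # Appended C-terminal hydrophobic segment, well separated from
            # the signal peptide so the hydropathy scan sees two domains.
            tm = "".join(rng.choice(list(_HYDROPHOBIC), size=19))
            aa = signal_aa + base_mature + tm
        else:  # low_identity: unrelated sequence, framework destroyed; its
            # own hydrophobic signal still satisfies the secretion criterion
            own_signal = "M" + "".join(
                rng.choice(list(_HYDROPHOBIC), size=config.signal_len - 1)
            )
            random_mature = "".join(
                rng.choice(list("ADEFGHIKLMNQRSTVWY"), size=len(base_mature))
            )
            aa = own_signal + random_mature
        rec = SeqRecord(
            id=f"decoy{d + 1:02d}_{violation}",
            nt=_reverse_translate(aa, rng),
            species="Decoya synthetica",
            taxon_family="",
            lineage="other",
            source="transcriptome",
            completeness="complete",
            flags={"violation": violation},
        )
        decoys.append(rec)
    return decoys


def simulate_codon_alignment(
    n_taxa: int,
    n_codons: int,
    omega: float,
    subs_per_branch: int,
    seed: int = 0,
) -> tuple[CodonAlignment, SupportTree]:
    """Star-tree codon alignment under a known omega, for estimator tests.

    The ancestral sequence is random sense codons; each tip evolves
    independently by ``subs_per_branch`` accepted substitutions under the
    omega acceptance rule (no framework protection).  Returns the
    alignment and the true star tree.
    """
    rng = np.random.default_rng(seed)
    sense = sorted(CODON_TO_AA)
    anc = "".join(sense[rng.integers(0, len(sense))] for _ in range(n_codons))
    ids, rows = [], []
    root = Node()
    for t in range(n_taxa):
        tip_rng = np.random.default_rng((seed, 3, t))
        nt = _evolve(anc, subs_per_branch, omega, tip_rng, protect_framework=False)
        tid = f"t{t + 1:02d}"
        ids.append(tid)
        rows.append(nt)
        root.add_child(Node(name=tid, length=subs_per_branch / (3 * n_codons)))
    return CodonAlignment(ids, rows), SupportTree(root, rooted=True)
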