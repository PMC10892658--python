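"""Gene-subfamily delimitation on a support-annotated phylogeny.

A subfamily is a maximal monophyletic clade that (i) is well supported at
its subtending node (bootstrap strictly above ``min_support``), (ii) is
cohesive (mean within-clade nucleotide identity strictly above
``min_within_ni``) and (iii) is distinct (mean identity to every
already-accepted subfamily and to every sibling candidate strictly below
``max_between_ni``).  The search is top-down from the ingroup root: a
clade failing any criterion is decomposed into its children; leaves never
captured by an accepted clade are reported as unplaced, never
force-assigned.

Accepted clades are named with Greek letters in the order they are first
encountered in a deterministic pre-order traversal of the ladderized tree
(children by descending subtree size, ties by smallest member id),
mirroring the field convention of lettering subfamilies from the first
major clade of the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .alignment import IdentityMatrix, between_identity, group_identity
from .tree import Node, SupportTree

__all__ = [
    "DelimitConfig",
    "Subfamily",
    "SubfamilyPartition",
    "delimit_subfamilies",
    "assign_names",
    "subfamily_stats",
    "GREEK_NAMES",
    "GREEK_GLYPHS",
]

GREEK_NAMES = (
    "alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta",
    "iota", "kappa", "lambda", "mu", "nu", "xi", "omicron", "pi", "rho",
    "sigma", "tau", "upsilon", "phi", "chi", "psi", "omega",
)
GREEK_GLYPHS = "αβγδεζηθικλμνξοπρστυφχψω"


@dataclass
class DelimitConfig:
    min_support: float = 95.0
    min_within_ni: float = 55.0
    max_between_ni: float = 55.0
    identity_level: str = "nucleotide"

    def __post_init__(self) -> None:
        for v in (self.min_support, self.min_within_ni, self.max_between_ni):
            if not (0 <= v <= 100):
                raise ValueError("thresholds must lie in [0, 100]")
        if self.identity_level not in ("nucleotide", "protein"):
            raise ValueError("identity_level must be 'nucleotide' or 'protein'")


@dataclass
class Subfamily:
    name: str  # machine-readable ("alpha"); glyph available via .glyph
    members: list[str]
    support: Optional[float]
    within_ni: Optional[float] = None
    within_pi: Optional[float] = None

    @property
    def glyph(self) -> str:
        try:
            idx = GREEK_NAMES.index(self.name.rstrip("0123456789"))
        except ValueError:
            return self.name
        suffix = self.name[len(GREEK_NAMES[idx]):]
        return GREEK_GLYPHS[idx] + suffix


@dataclass
class SubfamilyPartition:
    subfamilies: list[Subfamily]
    unplaced: list[str]

    def labels(self) -> dict[str, str]:
        out = {m: sf.name for sf in self.subfamilies for m in sf.members}
        out.update({u: "" for u in self.unplaced})
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"id": m, "subfamily": sf.name, "support": sf.support,
             "within_ni": sf.within_ni, "within_pi": sf.within_pi}
            for sf in self.subfamilies
            for m in sf.members
        ]
        rows += [
            {"id": u, "subfamily": "", "support": None,
             "within_ni": None, "within_pi": None}
            for u in self.unplaced
        ]
        return pd.DataFrame(rows).sort_values("id").reset_index(drop=True)


def _support_of(node: Node) -> Optional[float]:
    return node.support.bootstrap_pct if node.support else None


def _passes(
    node: Node,
    identity: IdentityMatrix,
    config: DelimitConfig,
    accepted: Sequence[frozenset[str]],
    siblings: Sequence[frozenset[str]],
) -> bool:
    members = sorted(node.leaf_names())
    if len(members) < 2:
        return False
    sup = _support_of(node)
    if sup is None or not (sup > config.min_support):
        return False
    within = group_identity(identity, members)
    if within is None or not (within > config.min_within_ni):
        return False
    for other in list(accepted) + [s for s in siblings if s != node.leaf_names()]:
        if between_identity(identity, members, sorted(other)) >= config.max_between_ni:
            return False
    return True


def delimit_subfamilies(
    tree: SupportTree,
    identity: IdentityMatrix,
    config: Optional[DelimitConfig] = None,
) -> SubfamilyPartition:
    """Top-down delimitation; see the module docstring for the criteria."""
    config = config or DelimitConfig()
    if not tree.rooted:
        raise ValueError("delimitation requires a rooted tree")
    missing = tree.leaf_names() - set(identity.ids)
    if missing:
        raise ValueError(f"leaves absent from identity matrix: {sorted(missing)}")

    work = tree.ladderized()
    accepted_nodes: list[Node] = []
    accepted_sets: list[frozenset[str]] = []
    unplaced: list[str] = []

    def visit(node: Node, siblings: Sequence[frozenset[str]]) -> None:
        if node.is_leaf:
            unplaced.append(node.name)
            return
        if _passes(node, identity, config, accepted_sets, siblings):
            accepted_nodes.append(node)
            accepted_sets.append(node.leaf_names())
            return
        child_sets = [c.leaf_names() for c in node.children]
        for i, child in enumerate(node.children):
            visit(child, [s for k, s in enumerate(child_sets) if k != i])

    visit(work.root, [])

    subfamilies = [
        Subfamily(
            name="",
            members=sorted(n.leaf_names()),
            support=_support_of(n),
            within_ni=(
                group_identity(identity, sorted(n.leaf_names()))
                if config.identity_level == "nucleotide"
                else None
            ),
        )
        for n in accepted_nodes
    ]
    partition = SubfamilyPartition(subfamilies, sorted(unplaced))
    return assign_names(partition, tree)


def assign_names(partition: SubfamilyPartition, tree: SupportTree) -> SubfamilyPartition:
    """Greek-letter names in pre-order encounter order on the ladderized
    tree; after 24 subfamilies the cycle continues alpha2, beta2, ..."""
    ladder = tree.ladderized()
    member_sets = {frozenset(sf.members): sf for sf in partition.subfamilies}
    ordered: list[Subfamily] = []
    seen: set[frozenset[str]] = set()
    for node in ladder.preorder():
        key = node.leaf_names()
        if key in member_sets and key not in seen:
            ordered.append(member_sets[key])
            seen.add(key)
    # Clades not locatable on the tree (shouldn't happen) keep input order.
    for sf in partition.subfamilies:
        if frozenset(sf.members) not in seen:
            ordered.append(sf)
    for i, sf in enumerate(ordered):
        cycle, pos = divmod(i, len(GREEK_NAMES))
        sf.name = GREEK_NAMES[pos] + (str(cycle + 1) if cycle else "")
    partition.subfamilies = ordered
    return partition


def subfamily_stats(
    partition: SubfamilyPartition,
    identity_nt: IdentityMatrix,
    identity_aa: Optional[IdentityMatrix] = None,
    metadata: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subfamily summary and taxon-family composition tables.

    Composition percentages are ``100 * count / n`` rounded to 2 decimals.
    """
    rows = []
    comp_rows = []
    fam_of = (
        dict(zip(metadata["id"], metadata["taxon_family"]))
        if metadata is not None
        else {}
    )
    for sf in partition.subfamilies:
        ni = group_identity(identity_nt, sf.members)
        pi = group_identity(identity_aa, sf.members) if identity_aa else None
        sf.within_ni, sf.within_pi = ni, pi
        rows.append(
            {
                "subfamily": sf.name,
                "n": len(sf.members),
                "support": sf.support,
                "within_ni": round(ni, 2) if ni is not None else None,
                "within_pi": round(pi, 2) if pi is not None else None,
            }
        )
        if fam_of:
            counts: dict[str, int] = {}
            for m in sf.members:
                fam = fam_of.get(m, "")
                counts[fam] = counts.get(fam, 0) + 1
            for fam in sorted(counts):
                comp_rows.append(
                    {
                        "subfamily": sf.name,
                        "taxon_family": fam,
                        "count": counts[fam],
                        "pct": round(100.0 * counts[fam] / len(sf.members), 2),
                    }
                )
    stats = pd.DataFrame(
        rows, columns=["subfamily", "n", "support", "within_ni", "within_pi"]
    )
    composition = pd.DataFrame(
        comp_rows, columns=["subfamily", "taxon_family", "count", "pct"]
    )
    return stats, composition
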