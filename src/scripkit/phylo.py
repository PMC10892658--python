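"""Distance-based tree inference with nonparametric bootstrap supports.

Classical Saitou-Nei neighbor joining on p-distance matrices makes the
delimitation layer testable without external maximum-likelihood software;
externally computed trees remain first-class inputs through the Newick
reader, and everything downstream is tree-source-agnostic.

Determinism: ties in the NJ Q-criterion are broken toward the pair whose
(lexicographically smallest, largest) leaf-name pair sorts first, so the
topology is a pure function of the distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alignment import CodonAlignment
from .tree import Node, Support, SupportTree

__all__ = ["BootstrapConfig", "nj_tree", "bootstrap_supports", "root_on_outgroup"]

_DNA_BYTES = frozenset(b"ACGT")


@dataclass
class BootstrapConfig:
    n_replicates: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def nj_tree(ids: Sequence[str], distances: np.ndarray) -> SupportTree:
    """Neighbor joining (Saitou & Nei) on a symmetric distance matrix.

    Returns an unrooted tree (trifurcating root node); negative branch
    length estimates are clamped to zero.  Requires >= 3 taxa.
    """
    ids = list(ids)
    D = np.asarray(distances, dtype=float).copy()
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    if (D < -1e-12).any():
        raise ValueError("distances must be non-negative")

    nodes = [Node(name=i) for i in ids]
    min_names = [i for i in ids]  # representative leaf per active cluster

    while len(nodes) > 3:
        r = len(nodes)
        sums = D.sum(axis=1)
        Q = (r - 2) * D - sums[:, None] - sums[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        i, j = min(
            ((a, b) for a, b in cand if a < b),
            key=lambda ab: tuple(sorted((min_names[ab[0]], min_names[ab[1]]))),
        )
        dij = D[i, j]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = Node()
        a, b = nodes[i], nodes[j]
        a.length, b.length = li, lj
        new.add_child(a)
        new.add_child(b)
        dk = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(r) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dk[keep][None, :]])
        D = np.hstack([D, np.append(dk[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
        min_names = [min_names[k] for k in keep] + [
            min(min_names[i], min_names[j])
        ]

    # Final three clusters joined at an unrooted (trifurcating) root with
    # the closed-form three-point branch lengths.
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = max(0.5 * (dab + dac - dbc), 0.0)
    b.length = max(0.5 * (dab + dbc - dac), 0.0)
    c.length = max(0.5 * (dac + dbc - dab), 0.0)
    root = Node(children=[a, b, c])
    return SupportTree(root, rooted=False)


# -- bootstrap -------------------------------------------------------------

def _column_pair_stats(
    alignment: CodonAlignment, level: str = "nucleotide"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-masked-codon-column match/denominator counts for every row pair.

    Returns ``(M, T)`` of shape (n_columns, n, n): resampling codon columns
    with weights ``w`` gives pairwise identity
    ``100 * (w @ M) / (w @ T)`` under the union denominator.
    """
    ids = alignment.ids
    n = len(ids)
    cols = alignment.column_mask
    A = np.frombuffer(
        "".join(alignment.masked_row(i) for i in range(n)).encode(), dtype="S1"
    ).reshape(n, 3 * len(cols))
    gap = A == b"-"
    valid = np.isin(A, [b"A", b"C", b"G", b"T"])
    C = len(cols)
    M = np.zeros((C, n, n), dtype=np.int32)
    T = np.zeros((C, n, n), dtype=np.int32)
    if level == "nucleotide":
        for i in range(n):
            for j in range(i + 1, n):
                match = (A[i] == A[j]) & valid[i]
                total = ~(gap[i] & gap[j])
                M[:, i, j] = M[:, j, i] = match.reshape(C, 3).sum(axis=1)
                T[:, i, j] = T[:, j, i] = total.reshape(C, 3).sum(axis=1)
    else:  # protein: one unit per codon column
        from .records import translate, STOP_CODONS

        res = np.empty((n, C), dtype="U1")
        for i in range(n):
            row = alignment.masked_row(i)
            for c in range(C):
                codon = row[3 * c : 3 * c + 3]
                if codon == "---":
                    res[i, c] = "-"
                elif codon in STOP_CODONS:
                    res[i, c] = "*"
                elif set(codon) <= set("ACGT"):
                    res[i, c] = translate(codon)
                else:
                    res[i, c] = "X"
        for i in range(n):
            for j in range(i + 1, n):
                both_gap = (res[i] == "-") & (res[j] == "-")
                match = (res[i] == res[j]) & ~np.isin(res[i], ["-", "X", "*"])
                M[:, i, j] = M[:, j, i] = match
                T[:, i, j] = T[:, j, i] = ~both_gap
    return M, T


def _distances_from_stats(M: np.ndarray, T: np.ndarray, w: np.ndarray) -> np.ndarray:
    m = np.tensordot(w, M, axes=1).astype(float)
    t = np.tensordot(w, T, axes=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ident = np.where(t > 0, m / np.maximum(t, 1), 0.0)
    d = 1.0 - ident
    np.fill_diagonal(d, 0.0)
    return d


def bootstrap_supports(
    alignment: CodonAlignment,
    config: Optional[BootstrapConfig] = None,
    level: str = "nucleotide",
) -> SupportTree:
    """NJ tree of the masked alignment with bootstrap supports.

    Codon columns of the mask are resampled with replacement; each
    replicate is rebuilt with NJ and the support of every internal node of
    the original tree is the percentage of replicates whose tree contains
    the same bipartition.  Reproducible given the seed.
    """
    config = config or BootstrapConfig()
    if len(alignment.ids) < 3:
        raise ValueError("bootstrap needs >= 3 rows")
    M, T = _column_pair_stats(alignment, level)
    C = M.shape[0]
    w_full = np.ones(C)
    tree = nj_tree(alignment.ids, _distances_from_stats(M, T, w_full))

    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(config.seed)
    for _ in range(config.n_replicates):
        w = np.bincount(rng.integers(0, C, size=C), minlength=C).astype(float)
        rep = nj_tree(alignment.ids, _distances_from_stats(M, T, w))
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1

    all_leaves = tree.leaf_names()
    anchor = min(all_leaves)
    for node in tree.preorder():
        if node is tree.root or node.is_leaf:
            continue
        side = node.leaf_names()
        if anchor in side:
            side = all_leaves - side
        if side in counts:
            node.support = Support(
                bootstrap_pct=100.0 * counts[side] / config.n_replicates
            )
    return tree


# -- rooting ---------------------------------------------------------------

def _suppress_unary(root: Node) -> None:
    changed = True
    while changed:
        changed = False
        for n in list(root.preorder()):
            if n is root or n.is_leaf or len(n.children) != 1:
                continue
            child = n.children[0]
            parent = n.parent
            idx = parent.children.index(n)
            if n.length is not None or child.length is not None:
                child.length = (n.length or 0.0) + (child.length or 0.0)
            child.parent = parent
            parent.children[idx] = child
            changed = True


def root_on_outgroup(tree: SupportTree, outgroup_ids: Sequence[str]) -> SupportTree:
    """Root on the branch separating a monophyletic outgroup from the rest.

    Raises ``ValueError`` naming the intruding leaves when the outgroup is
    not monophyletic in the unrooted tree.
    """
    og = frozenset(outgroup_ids)
    if not og:
        raise ValueError("empty outgroup")
    t = tree.copy()
    all_leaves = t.leaf_names()
    missing = og - all_leaves
    if missing:
        raise ValueError(f"outgroup ids not in tree: {sorted(missing)}")
    if og == all_leaves:
        raise ValueError("outgroup cannot contain every leaf")

    target = None
    for n in t.root.preorder():
        if n is t.root:
            continue
        ln = n.leaf_names()
        if ln == og or ln == all_leaves - og:
            target = n
            break
    if target is None:
        mrca = t.mrca(og)
        intruders = sorted(mrca.leaf_names() - og)
        raise ValueError(f"outgroup not monophyletic; intruding leaves: {intruders}")

    edge_len = target.length
    edge_support = target.support
    parent = target.parent
    parent.children.remove(target)
    target.parent = None

    # Flip the ancestor chain of `parent` so that it becomes a root-side
    # subtree; each reversed edge keeps its length and support.
    path: list[Node] = []
    n: Optional[Node] = parent
    while n is not None:
        path.append(n)
        n = n.parent
    old_len = [p.length for p in path]
    old_sup = [p.support for p in path]
    for i in range(len(path) - 1):
        path[i + 1].children.remove(path[i])
        path[i + 1].parent = None
    for i in range(len(path) - 1):
        path[i].add_child(path[i + 1])
        path[i + 1].length = old_len[i]
        path[i + 1].support = old_sup[i]

    half = edge_len / 2 if edge_len is not None else None
    target.length = half
    parent.length = half
    parent.parent = None
    # After the flip, `parent` subtends the complement of `target`: both
    # root children describe the same bipartition, the old root edge.
    # Parent's previous support was handed down the flipped chain above.
    parent.support = edge_support
    new_root = Node()
    new_root.add_child(target)
    new_root.add_child(parent)
    _suppress_unary(new_root)
    return SupportTree(new_root, rooted=True)
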