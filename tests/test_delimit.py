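"""Subfamily delimitation: criteria, oracle equivalence, naming."""

import numpy as np
import pytest

from scripkit.alignment import IdentityMatrix, identity_matrix
from scripkit.delimit import (
    DelimitConfig,
    SubfamilyPartition,
    delimit_subfamilies,
    subfamily_stats,
)
from scripkit.phylo import BootstrapConfig, bootstrap_supports, root_on_outgroup
from scripkit.tree import Node, Support, SupportTree


def make_matrix(ids, fill, blocks=None):
    """Identity matrix with a uniform background and optional block values.

    ``blocks`` maps a frozenset of ids to its within-block identity.
    """
    n = len(ids)
    v = np.full((n, n), float(fill))
    if blocks:
        for members, val in blocks.items():
            idx = [ids.index(m) for m in members]
            for a in idx:
                for b in idx:
                    v[a, b] = val
    np.fill_diagonal(v, 100.0)
    return IdentityMatrix(ids, v)


def clade(support, *children):
    node = Node(support=Support(bootstrap_pct=support) if support is not None else None)
    for c in children:
        node.add_child(c if isinstance(c, Node) else Node(name=c))
    return node


# -- independent exhaustive oracle ----------------------------------------

def oracle_delimit(tree, identity, config):
    """Scan every clade in ladderized pre-order; accept a clade when no
    ancestor is accepted and all three criteria hold against previously
    accepted clades and the clade's siblings."""
    from scripkit.alignment import between_identity, group_identity

    work = tree.ladderized()
    accepted = []
    nodes = list(work.preorder())
    accepted_ids = set()

    def has_accepted_ancestor(n):
        p = n.parent
        while p is not None:
            if id(p) in accepted_ids:
                return True
            p = p.parent
        return False

    for n in nodes:
        if n.is_leaf or has_accepted_ancestor(n):
            continue
        sup = n.support.bootstrap_pct if n.support else None
        if sup is None or sup <= config.min_support:
            continue
        members = sorted(n.leaf_names())
        w = group_identity(identity, members)
        if w is None or w <= config.min_within_ni:
            continue
        others = [sorted(a.leaf_names()) for a in accepted]
        if n.parent is not None:
            others += [
                sorted(s.leaf_names()) for s in n.parent.children if s is not n
            ]
        if any(
            between_identity(identity, members, o) >= config.max_between_ni
            for o in others
        ):
            continue
        accepted.append(n)
        accepted_ids.add(id(n))

    placed = set().union(*(a.leaf_names() for a in accepted)) if accepted else set()
    return (
        {frozenset(a.leaf_names()) for a in accepted},
        frozenset(tree.leaf_names() - placed),
    )


def random_tree(rng, n_leaves):
    leaves = [Node(name=f"L{i:02d}") for i in range(n_leaves)]
    nodes = leaves[:]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = Node(
            support=Support(bootstrap_pct=float(rng.choice([30, 60, 90, 96, 100]))),
            children=[a, b],
        )
        nodes.append(parent)
    root = Node(children=nodes)
    return SupportTree(root, rooted=True)


def random_identity(rng, ids):
    v = rng.uniform(20, 100, (len(ids), len(ids)))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 100.0)
    return IdentityMatrix(list(ids), v)


class TestCriteria:
    def test_two_perfect_clades(self):
        ids = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        root = Node(
            children=[
                clade(100, *ids[:4]),
                clade(100, *ids[4:]),
            ]
        )
        tree = SupportTree(root, rooted=True)
        m = make_matrix(
            ids, 30.0,
            blocks={frozenset(ids[:4]): 100.0, frozenset(ids[4:]): 100.0},
        )
        part = delimit_subfamilies(tree, m)
        assert [set(sf.members) for sf in part.subfamilies] == [
            set(ids[:4]), set(ids[4:])
        ]
        assert part.unplaced == []

    def test_low_support_leaves_everything_unplaced(self):
        ids = ["a", "b", "c", "d"]
        tree = SupportTree(
            Node(children=[clade(50, "a", "b"), clade(50, "c", "d")]), rooted=True
        )
        m = make_matrix(ids, 90.0)
        part = delimit_subfamilies(tree, m)
        assert not part.subfamilies
        assert part.unplaced == ids

    def test_support_threshold_is_strict(self):
        ids = ["a", "b", "c", "d"]
        tree = SupportTree(
            Node(children=[clade(95, "a", "b"), clade(96, "c", "d")]), rooted=True
        )
        m = make_matrix(
            ids, 30.0,
            blocks={frozenset({"a", "b"}): 90.0, frozenset({"c", "d"}): 90.0},
        )
        part = delimit_subfamilies(tree, m, DelimitConfig(min_support=95))
        assert [set(sf.members) for sf in part.subfamilies] == [{"c", "d"}]

    def test_unrooted_tree_rejected(self, family):
        m = identity_matrix(family.alignment)
        t = bootstrap_supports(family.alignment, BootstrapConfig(10, 0))
        with pytest.raises(ValueError, match="rooted"):
            delimit_subfamilies(t, m)

    def test_raising_min_support_shrinks_leaf_coverage(self):
        # The subfamily COUNT is not monotone in the support threshold (a
        # clade failing a raised threshold may split into two accepted
        # children), but with the between-group criterion inactive the set
        # of leaves placed in any subfamily can only shrink.
        rng = np.random.default_rng(12)
        for trial in range(5):
            tree = random_tree(rng, 12)
            ids = sorted(tree.leaf_names())
            v = rng.uniform(20, 95, (len(ids), len(ids)))
            v = (v + v.T) / 2
            np.fill_diagonal(v, 100.0)
            m = IdentityMatrix(ids, v)
            prev = None
            for min_sup in (20, 50, 80, 95):
                part = delimit_subfamilies(
                    tree, m, DelimitConfig(min_support=min_sup, min_within_ni=40,
                                           max_between_ni=100)
                )
                placed = {x for sf in part.subfamilies for x in sf.members}
                if prev is not None:
                    assert placed <= prev
                prev = placed


class TestOracleEquivalence:
    def test_matches_exhaustive_enumeration_on_random_trees(self):
        rng = np.random.default_rng(99)
        for trial in range(30):
            n = int(rng.integers(4, 33))
            tree = random_tree(rng, n)
            m = random_identity(rng, sorted(tree.leaf_names()))
            cfg = DelimitConfig(
                min_support=float(rng.choice([50, 80, 95])),
                min_within_ni=float(rng.choice([40, 55, 65])),
                max_between_ni=float(rng.choice([55, 65, 80])),
            )
            part = delimit_subfamilies(tree, m, cfg)
            got = ({frozenset(sf.members) for sf in part.subfamilies},
                   frozenset(part.unplaced))
            assert got == oracle_delimit(tree, m, cfg), f"trial {trial}"


class TestPlantedRecovery:
    def test_planted_subfamilies_recovered_exactly(self, family):
        sklearn = pytest.importorskip("sklearn")
        from sklearn.metrics import adjusted_rand_score

        aln = family.alignment
        t = bootstrap_supports(aln, BootstrapConfig(n_replicates=100, seed=5))
        out_clade = [rid for rid, sf in family.truth.items() if sf == "sf1"]
        rooted = root_on_outgroup(t, out_clade)
        m = identity_matrix(aln)
        part = delimit_subfamilies(rooted, m)
        labels = part.labels()
        ids = sorted(family.truth)
        ari = adjusted_rand_score(
            [family.truth[i] for i in ids], [labels[i] for i in ids]
        )
        assert ari == 1.0
        assert len(part.subfamilies) == 4


class TestNaming:
    def test_larger_clade_encountered_first_is_alpha(self):
        ids = ["a", "b", "c", "d", "e"]
        tree = SupportTree(
            Node(children=[clade(100, "a", "b"), clade(100, "c", "d", "e")]),
            rooted=True,
        )
        m = make_matrix(
            ids, 30.0,
            blocks={frozenset({"a", "b"}): 90.0, frozenset({"c", "d", "e"}): 90.0},
        )
        part = delimit_subfamilies(tree, m, DelimitConfig(min_support=90))
        by_name = {sf.name: set(sf.members) for sf in part.subfamilies}
        assert by_name["alpha"] == {"c", "d", "e"}
        assert by_name["beta"] == {"a", "b"}
        assert part.subfamilies[0].glyph == "α"

    def test_naming_stable_under_leaf_permutation(self, family):
        aln = family.alignment
        cfg = BootstrapConfig(n_replicates=60, seed=3)
        out_clade = [rid for rid, sf in family.truth.items() if sf == "sf1"]
        m = identity_matrix(aln)

        def names(a):
            t = root_on_outgroup(bootstrap_supports(a, cfg), out_clade)
            part = delimit_subfamilies(t, m)
            return {sf.name: frozenset(sf.members) for sf in part.subfamilies}

        perm = np.random.default_rng(1).permutation(len(aln.ids))
        from scripkit.alignment import CodonAlignment

        shuffled = CodonAlignment(
            [aln.ids[i] for i in perm], [aln.rows[i] for i in perm]
        )
        assert names(aln) == names(shuffled)


class TestStats:
    def test_composition_percentages(self, family):
        import pandas as pd

        part = SubfamilyPartition(
            subfamilies=[], unplaced=[]
        )
        # Hand-built partitions exercising the printed-percentage arithmetic.
        from scripkit.delimit import Subfamily

        ids31 = [f"m{i:02d}" for i in range(31)]
        ids45 = [f"n{i:02d}" for i in range(45)]
        part = SubfamilyPartition(
            subfamilies=[
                Subfamily("delta", ids31, 91.0),
                Subfamily("beta", ids45, 70.0),
            ],
            unplaced=[],
        )
        all_ids = ids31 + ids45
        m = make_matrix(all_ids, 50.0)
        meta = pd.DataFrame(
            {
                "id": all_ids,
                "taxon_family": ["Actiniidae"] * 19 + ["Acroporidae"] * 12
                + ["Merulinidae"] * 23 + ["Pocilloporidae"] * 22,
            }
        )
        stats, comp = subfamily_stats(part, m, None, meta)
        comp = comp.set_index(["subfamily", "taxon_family"])
        assert comp.loc[("delta", "Actiniidae"), "pct"] == 61.29
        assert comp.loc[("beta", "Merulinidae"), "pct"] == 51.11

    def test_empty_partition_gives_empty_tables(self):
        part = SubfamilyPartition([], [])
        m = make_matrix(["a", "b"], 50.0)
        stats, comp = subfamily_stats(part, m)
        assert stats.empty and comp.empty
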