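"""NG86 site counts, pathway counting, parsimony ancestors, site tests,
global omega."""

import itertools

import numpy as np
import pytest
from scipy.stats import binomtest

from scripkit.alignment import CodonAlignment
from scripkit.records import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, SeqRecord
from scripkit.selection import (
    SelectionConfig,
    fitch_ancestral_codons,
    global_omega,
    ng86_site_counts,
    pathway_counts,
    run_selection,
    slac_site_test,
    strip_signal_peptides,
    subsample_paralogs,
)
from scripkit.simulate import simulate_codon_alignment
from scripkit.tree import Node, SupportTree, parse_newick


def enumerate_neighbors(codon):
    """Independent enumeration oracle over the nine single-nt neighbors."""
    syn = nonsyn = stops = 0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            nb = codon[:pos] + b + codon[pos + 1 :]
            if nb in STOP_CODONS:
                stops += 1
            elif CODON_TO_AA[nb] == CODON_TO_AA[codon]:
                syn += 1
            else:
                nonsyn += 1
    return syn, nonsyn, stops


class TestNG86Sites:
    def test_phenylalanine_codon(self):
        es, en = ng86_site_counts("TTT")
        assert es == pytest.approx(1 / 3)
        assert en == pytest.approx(8 / 3)

    def test_tryptophan_excludes_stop_neighbors(self):
        es, en = ng86_site_counts("TGG")
        syn, nonsyn, stops = enumerate_neighbors("TGG")
        assert stops == 2
        assert es == pytest.approx(syn / 3) == 0.0
        assert en == pytest.approx(nonsyn / 3) == pytest.approx(7 / 3)

    def test_fourfold_site_contributes_full_synonymous_site(self):
        # GGG position 3: all three alternatives are glycine.
        es, en = ng86_site_counts("GGG")
        syn, nonsyn, _ = enumerate_neighbors("GGG")
        assert syn >= 3  # the third position alone provides three
        assert es == pytest.approx(syn / 3)

    def test_conservation_over_all_sense_codons(self):
        for codon in SENSE_CODONS:
            es, en = ng86_site_counts(codon)
            syn, nonsyn, stops = enumerate_neighbors(codon)
            assert es + en == pytest.approx(3 - stops / 3 * 1.0)
            assert es + en == pytest.approx((9 - stops) / 3)

    def test_stop_and_ambiguous_codons_rejected(self):
        with pytest.raises(ValueError):
            ng86_site_counts("TAA")
        with pytest.raises(ValueError):
            ng86_site_counts("TNT")


class TestPathwayCounts:
    def test_identical_codons(self):
        assert pathway_counts("AAA", "AAA") == (0.0, 0.0)

    def test_single_difference(self):
        # TTT -> TTC synonymous
        assert pathway_counts("TTT", "TTC") == (0.0, 1.0)
        # TTT -> TTA nonsynonymous (Phe -> Leu)
        assert pathway_counts("TTT", "TTA") == (1.0, 0.0)

    def test_two_step_average_matches_manual_enumeration(self):
        # TTT (Phe) -> GTA (Val): paths via GTT (Val) or TTA (Leu).
        # via GTT: TTT->GTT nonsyn, GTT->GTA syn  => (1 N, 1 S)
        # via TTA: TTT->TTA nonsyn, TTA->GTA nonsyn => (2 N, 0 S)
        n, s = pathway_counts("TTT", "GTA")
        assert n == pytest.approx(1.5)
        assert s == pytest.approx(0.5)

    def test_paths_through_stops_are_skipped(self):
        # TGT (Cys) -> TAG would not occur (target is a stop) but
        # TGT -> AGA (Arg): via AGT (Ser) or TGA (stop; skipped).
        n, s = pathway_counts("TGT", "AGA")
        assert n + s == 2.0
        assert n == 2.0  # only the AGT path survives: both steps nonsyn

    def test_symmetric_totals_for_reversed_direction(self):
        n1, s1 = pathway_counts("TTT", "GTA")
        n2, s2 = pathway_counts("GTA", "TTT")
        assert n1 + s1 == n2 + s2


class TestFitch:
    def tree4(self):
        return parse_newick("((a,b),(c,d));")

    def test_invariant_site_has_single_state_everywhere(self):
        aln = CodonAlignment(["a", "b", "c", "d"], ["TTT"] * 4)
        t = self.tree4()
        states = fitch_ancestral_codons(t, aln, 0)
        assert set(states.values()) == {"TTT"}

    def test_single_derived_codon_yields_one_change(self):
        aln = CodonAlignment(["a", "b", "c", "d"], ["TTT", "TTT", "TTT", "TTC"])
        t = self.tree4()
        states = fitch_ancestral_codons(t, aln, 0)
        changes = 0
        for node in t.preorder():
            if node.parent is None:
                continue
            if states[id(node)] != states[id(node.parent)]:
                changes += 1
        assert changes == 1

    def test_minimum_changes_match_brute_force(self):
        # Brute force: try every assignment of codon states to the three
        # internal nodes and count the minimum number of changed edges.
        aln = CodonAlignment(
            ["a", "b", "c", "d"], ["TTT", "TTC", "CTC", "CTT"]
        )
        t = self.tree4()
        leaf_state = dict(zip(["a", "b", "c", "d"], ["TTT", "TTC", "CTC", "CTT"]))
        internals = [n for n in t.preorder() if not n.is_leaf]
        observed = set(leaf_state.values())
        best = None
        for combo in itertools.product(observed, repeat=len(internals)):
            assign = {id(n): c for n, c in zip(internals, combo)}
            assign.update(
                {id(n): leaf_state[n.name] for n in t.preorder() if n.is_leaf}
            )
            changes = sum(
                assign[id(n)] != assign[id(n.parent)]
                for n in t.preorder()
                if n.parent is not None
            )
            best = changes if best is None else min(best, changes)
        states = fitch_ancestral_codons(t, aln, 0)
        fitch_changes = sum(
            states[id(n)] != states[id(n.parent)]
            for n in t.preorder()
            if n.parent is not None
        )
        assert fitch_changes == best

    def test_gap_leaves_carry_no_state(self):
        aln = CodonAlignment(["a", "b", "c", "d"], ["TTT", "---", "TTT", "TTT"])
        t = self.tree4()
        states = fitch_ancestral_codons(t, aln, 0)
        leaf_b = next(n for n in t.preorder() if n.name == "b")
        assert states[id(leaf_b)] is None


class TestSiteTest:
    def test_invariant_site_is_neutral(self):
        aln = CodonAlignment(["a", "b", "c"], ["TTT"] * 3)
        t = parse_newick("(a,(b,c));")
        rec = slac_site_test(t, aln, 0)
        assert rec.call == "neutral"
        assert rec.n_changes == rec.s_changes == 0

    def test_purifying_site_called_negative(self):
        # Star tree, six leaves: five synonymous changes, zero nonsyn.
        codons = ["TTT", "TTC", "TTT", "TTC", "TTT", "TTC"]
        ids = [f"s{i}" for i in range(6)]
        aln = CodonAlignment(ids, codons)
        root = Node(children=[Node(name=i) for i in ids])
        t = SupportTree(root, rooted=True)
        rec = slac_site_test(t, aln, 0, SelectionConfig(site_alpha=0.05))
        assert rec.n_changes == 0 and rec.s_changes >= 2
        # independent check of the binomial tail the test should have used
        trials = int(round(rec.n_changes + rec.s_changes))
        p0 = rec.en / (rec.en + rec.es)
        expected_p = binomtest(0, trials, p0).pvalue
        assert rec.p_value == pytest.approx(expected_p)
        if expected_p < 0.05:
            assert rec.call == "negative"

    def test_all_gap_site_absent(self):
        aln = CodonAlignment(["a", "b", "c"], ["---TTT", "---TTC", "---TTT"])
        t = parse_newick("(a,(b,c));")
        assert slac_site_test(t, aln, 0) is None
        assert slac_site_test(t, aln, 1) is not None


class TestGlobalOmega:
    def test_identical_sequences_undefined(self):
        aln = CodonAlignment(["a", "b", "c"], ["TTTAAA"] * 3)
        t = parse_newick("(a,(b,c));")
        with pytest.warns(UserWarning, match="undefined"):
            assert global_omega(t, aln) is None

    def test_star_toy_hand_computation(self):
        # Majority root state TTT on a 4-leaf star: one synonymous change
        # (TTC) and one nonsynonymous change (TTA) on the tip branches.
        ids = ["a1", "a2", "b", "c"]
        aln = CodonAlignment(ids, ["TTT", "TTT", "TTC", "TTA"])
        root = Node(children=[Node(name=i) for i in ids])
        t = SupportTree(root, rooted=True)
        om = global_omega(t, aln)
        # Four branches with parent codon TTT: ES_tot = 4/3, EN_tot = 32/3;
        # N = S = 1 -> omega = (1/EN_tot)/(1/ES_tot) = ES_tot/EN_tot = 1/8.
        assert om == pytest.approx(1 / 8)

    def test_invariant_to_sequence_input_order(self):
        aln, t = simulate_codon_alignment(8, 60, 0.8, 20, seed=4)
        om1 = global_omega(t, aln)
        perm = list(reversed(range(len(aln.ids))))
        aln2 = CodonAlignment([aln.ids[i] for i in perm], [aln.rows[i] for i in perm])
        om2 = global_omega(t, aln2)
        assert om1 == pytest.approx(om2)

    @pytest.mark.parametrize("omega_true", [0.3, 2.0])
    def test_recovery_separates_purifying_from_diversifying(self, omega_true):
        ests = []
        for s in range(5):
            aln, t = simulate_codon_alignment(12, 150, omega_true, 40, seed=50 + s)
            ests.append(global_omega(t, aln))
        med = float(np.median(ests))
        assert (med < 1) == (omega_true < 1)
        assert abs(med - omega_true) / omega_true < 0.30


class TestPreprocessing:
    def records(self):
        out = []
        for i, sp in enumerate(["A sp", "A sp", "B sp", "B sp", "C sp"]):
            nt = "ATGCTG" + ["TTT", "TTC", "CTT", "CTC", "ATT"][i] * 3
            out.append(
                SeqRecord(id=f"r{i}", nt=nt, species=sp,
                          signal_peptide_end=2)
            )
        return out

    def test_strip_round_trip(self):
        recs = self.records()
        mature = strip_signal_peptides(recs)
        for before, after in zip(recs, mature):
            assert before.nt == before.nt[:6] + after.nt
            assert len(after.nt) == 3 * len(after.aa)

    def test_strip_requires_signal_end(self):
        r = SeqRecord(id="x", nt="ATGTTTAAA"[:6])
        with pytest.raises(ValueError, match="x"):
            strip_signal_peptides([r])

    def test_subsample_keeps_one_per_species(self):
        recs = self.records()
        reps = subsample_paralogs(recs, SelectionConfig(n_replicates=3, seed=1))
        for rep in reps:
            assert len(rep) == 3
            assert {r.species for r in rep} == {"A sp", "B sp", "C sp"}

    def test_subsample_deterministic(self):
        recs = self.records()
        a = subsample_paralogs(recs, SelectionConfig(n_replicates=3, seed=5))
        b = subsample_paralogs(recs, SelectionConfig(n_replicates=3, seed=5))
        assert [[r.id for r in rep] for rep in a] == [[r.id for r in rep] for rep in b]

    def test_single_record_per_species_means_identical_replicates(self):
        recs = [r for i, r in enumerate(self.records()) if i in (0, 2, 4)]
        reps = subsample_paralogs(recs, SelectionConfig(n_replicates=3, seed=2))
        assert all([r.id for r in rep] == [r.id for r in reps[0]] for rep in reps)


class TestRunSelection:
    def test_replicates_and_summary_mean(self):
        rng = np.random.default_rng(0)
        aln, _ = simulate_codon_alignment(9, 60, 0.5, 25, seed=9)
        recs = [
            SeqRecord(id=sid, nt=row, species=f"sp{i % 3}")
            for i, (sid, row) in enumerate(zip(aln.ids, aln.rows))
        ]
        cfg = SelectionConfig(n_replicates=3, seed=7)
        results, summary = run_selection(recs, cfg)
        assert len(results) == 3
        omegas = [r.global_omega for r in results]
        assert summary.iloc[-1]["global_omega"] == pytest.approx(
            float(np.mean(omegas))
        )

    def test_exclusion_list_respected(self):
        aln, _ = simulate_codon_alignment(9, 60, 0.5, 25, seed=9)
        recs = [
            SeqRecord(id=sid, nt=row, species=f"sp{i}")
            for i, (sid, row) in enumerate(zip(aln.ids, aln.rows))
        ]
        cfg = SelectionConfig(
            n_replicates=2, seed=7, exclusion_list=frozenset({"t01"})
        )
        results, _ = run_selection(recs, cfg)
        for r in results:
            assert r.n_seqs == 8

    def test_deterministic_end_to_end(self):
        aln, _ = simulate_codon_alignment(9, 60, 0.5, 25, seed=9)
        recs = [
            SeqRecord(id=sid, nt=row, species=f"sp{i % 3}")
            for i, (sid, row) in enumerate(zip(aln.ids, aln.rows))
        ]
        cfg = SelectionConfig(n_replicates=2, seed=3)
        _, s1 = run_selection(recs, cfg)
        _, s2 = run_selection(recs, cfg)
        assert s1.equals(s2)
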