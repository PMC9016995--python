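"""InDel calling, branch assignment on a chronogram, occurrence rates."""

import numpy as np
import pytest

import plastcomp as pc
from plastcomp.errors import DoubleGapColumn, UnknownTaxon
from plastcomp.indels import Chronogram, _fitch_gains

SIX_LEAF = ("((AN1:4,(AN2:2,AN3:2)AN23:2)AN:8,"
            "(SA1:4,(SA2:2,SA3:2)SA23:2)SA:8)root:6;")


class TestCallIndels:
    def test_deletion_in_sample(self):
        evs = pc.call_indels("ACGTACGT", "AC--ACGT")
        assert [(e.ref_pos, e.etype, e.length) for e in evs] == \
            [(2, "deletion", 2)]

    def test_insertion_in_sample(self):
        evs = pc.call_indels("AC--GT", "ACTTGT")
        assert [(e.ref_pos, e.etype, e.length) for e in evs] == \
            [(2, "insertion", 2)]

    def test_adjacent_runs_of_same_type_separated_by_match(self):
        evs = pc.call_indels("AAAAAAA", "A--A--A")
        assert len(evs) == 2
        assert {e.ref_pos for e in evs} == {1, 4}

    def test_double_gap_column_raises(self):
        with pytest.raises(DoubleGapColumn):
            pc.call_indels("A-G", "A-G")

    def test_planted_events_recalled_from_truth_alignment(self, default_truth):
        """Every leaf's called event bp equals the net truth for its path."""
        for leaf in sorted(default_truth.leaf_entries):
            ref, smp = default_truth.pairwise_alignment(leaf)
            evs = pc.call_indels(ref, smp, taxon=leaf)
            called_ins = sum(e.length for e in evs if e.etype == "insertion")
            called_del = sum(e.length for e in evs if e.etype == "deletion")
            assert called_ins - called_del == \
                len(smp.replace("-", "")) - len(ref.replace("-", ""))


class TestMergeEvents:
    def test_identical_events_merge_carriers(self):
        per_taxon = {
            "a": [pc.IndelEvent(10, "deletion", 3, frozenset(["a"]))],
            "b": [pc.IndelEvent(10, "deletion", 3, frozenset(["b"]))],
            "c": [pc.IndelEvent(10, "deletion", 4, frozenset(["c"]))],
        }
        merged = pc.merge_events(per_taxon)
        assert len(merged) == 2
        big = [e for e in merged if e.length == 3][0]
        assert big.carriers == frozenset(["a", "b"])

    def test_slop_window_clusters_jittered_positions(self):
        per_taxon = {
            "a": [pc.IndelEvent(10, "deletion", 3, frozenset(["a"]))],
            "b": [pc.IndelEvent(12, "deletion", 3, frozenset(["b"]))],
        }
        assert len(pc.merge_events(per_taxon, slop=0)) == 2
        merged = pc.merge_events(per_taxon, slop=2)
        assert len(merged) == 1 and merged[0].carriers == frozenset(["a", "b"])


class TestChronogram:
    def test_ages_and_durations(self):
        tree = Chronogram.from_newick(SIX_LEAF)
        durs = tree.branch_durations()
        assert durs["root"] == 6 and durs["AN"] == 8 and durs["AN2"] == 2
        root = tree.tree.seed_node
        assert root.pc_age == pytest.approx(12.0)

    def test_clade_branch_ids_include_stem(self):
        tree = Chronogram.from_newick(SIX_LEAF)
        ids = set(tree.clade_branch_ids(frozenset(["AN1", "AN2", "AN3"])))
        assert ids == {"AN", "AN1", "AN23", "AN2", "AN3"}


class TestAssignEvents:
    def test_monophyletic_carriers_go_to_stem(self):
        tree = Chronogram.from_newick(SIX_LEAF)
        ev = pc.IndelEvent(5, "deletion", 10, frozenset(["AN1", "AN2", "AN3"]))
        rec = pc.assign_events_to_branches([ev], tree)[0]
        assert rec["branches"] == [("AN", 1.0)]
        assert not rec["homoplastic"]

    def test_single_leaf_gets_terminal_branch(self):
        tree = Chronogram.from_newick(SIX_LEAF)
        ev = pc.IndelEvent(5, "insertion", 4, frozenset(["SA2"]))
        rec = pc.assign_events_to_branches([ev], tree)[0]
        assert rec["branches"] == [("SA2", 1.0)]

    def test_cross_clade_pair_split_fifty_fifty(self):
        tree = Chronogram.from_newick(SIX_LEAF)
        ev = pc.IndelEvent(5, "deletion", 8, frozenset(["AN1", "SA1"]))
        rec = pc.assign_events_to_branches([ev], tree)[0]
        assert rec["homoplastic"]
        assert sorted(b for b, _ in rec["branches"]) == ["AN1", "SA1"]
        assert all(w == pytest.approx(0.5) for _, w in rec["branches"])

    def test_fitch_gain_count_never_exceeds_exhaustive_minimum(self):
        """The number of gain branches is bounded by the true parsimony
        minimum of state changes, found by exhaustive assignment of internal
        states on the 6-leaf tree (gains are a subset of all changes)."""
        import itertools
        tree = Chronogram.from_newick(SIX_LEAF)
        internals = [nd for nd in tree.tree.preorder_node_iter()
                     if not nd.is_leaf()]
        leaves = [nd.pc_id for nd in tree.tree.leaf_node_iter()]
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(20):
            carriers = {l for l in leaves if rng.random() < 0.4}
            if not carriers:
                continue
            best = min(_changes(tree, dict(zip(internals, assign)), carriers)
                       for assign in itertools.product([0, 1],
                                                       repeat=len(internals)))
            gains = _fitch_gains(tree, carriers)
            assert len(gains) <= best
            checked += 1
        assert checked >= 10

    def test_unknown_taxon_raises(self):
        tree = Chronogram.from_newick(SIX_LEAF)
        ev = pc.IndelEvent(0, "deletion", 1, frozenset(["nope"]))
        with pytest.raises(UnknownTaxon):
            pc.assign_events_to_branches([ev], tree)


def _changes(tree, internal_states, carriers):
    """State changes for one full assignment; presence at the root counts
    as a change from the ancestral (reference) absence state."""
    states = {id(nd): st for nd, st in internal_states.items()}
    for nd in tree.tree.leaf_node_iter():
        states[id(nd)] = 1 if nd.pc_id in carriers else 0
    cost = states[id(tree.tree.seed_node)]
    for nd in tree.tree.preorder_node_iter():
        if nd.parent_node is not None:
            cost += int(states[id(nd)] != states[id(nd.parent_node)])
    return cost


class TestOccurrenceRates:
    def _assignments(self, tree, events):
        return pc.assign_events_to_branches(events, tree)

    def test_branch_rate_is_bp_over_duration(self):
        tree = Chronogram.from_newick(SIX_LEAF)
        evs = [pc.IndelEvent(1, "insertion", 500,
                             frozenset(["AN1", "AN2", "AN3"]))]
        branch_df, _ = pc.occurrence_rates(self._assignments(tree, evs), tree)
        row = branch_df[branch_df.branch == "AN"].iloc[0]
        assert row.ins_rate == pytest.approx(500 / 8.0)

    def test_branch_without_events_has_zero_rate(self):
        tree = Chronogram.from_newick(SIX_LEAF)
        branch_df, _ = pc.occurrence_rates([], tree)
        assert (branch_df.ins_rate == 0).all()

    def test_length_conservation_with_homoplasy(self):
        tree = Chronogram.from_newick(SIX_LEAF)
        rng = np.random.default_rng(7)
        leaves = ["AN1", "AN2", "AN3", "SA1", "SA2", "SA3"]
        events = []
        for i in range(40):
            carriers = frozenset(l for l in leaves if rng.random() < 0.5)
            if not carriers:
                continue
            events.append(pc.IndelEvent(i, "deletion",
                                        int(rng.integers(1, 30)), carriers))
        assigns = self._assignments(tree, events)
        branch_df, _ = pc.occurrence_rates(assigns, tree)
        assert branch_df.del_bp.sum() == pytest.approx(
            sum(e.length for e in events))

    def test_clade_rate_pools_branches(self):
        tree = Chronogram.from_newick(SIX_LEAF)
        evs = [pc.IndelEvent(1, "deletion", 180,
                             frozenset(["AN1", "AN2", "AN3"]))]
        _, clade_df = pc.occurrence_rates(
            self._assignments(tree, evs), tree,
            {"AN": frozenset(["AN1", "AN2", "AN3"])})
        row = clade_df.iloc[0]
        assert row.duration_myr == pytest.approx(8 + 4 + 2 + 2 + 2)
        assert row.del_rate == pytest.approx(180 / 18.0)


class TestIndelRegionDensity:
    def test_deletion_density_in_ssc(self, default_ancestor):
        part = default_ancestor.partition
        ev = pc.IndelEvent(part.ssc.start + 100, "deletion", 100, frozenset(["x"]))
        dens = pc.indel_region_density([ev], part)
        ssc = [d for d in dens["deletion"] if d.region == "SSC"][0]
        assert ssc.density == pytest.approx(100 / (part.ssc.length / 1000))

    def test_no_events_all_zero(self, default_ancestor):
        dens = pc.indel_region_density([], default_ancestor.partition)
        assert all(d.density == 0 for et in dens.values() for d in et)

    def test_junction_spanning_deletion_prorated(self, default_ancestor):
        part = default_ancestor.partition
        ev = pc.IndelEvent(part.irb.start - 20, "deletion", 50, frozenset(["x"]))
        dens = {d.region: d.density for d in
                pc.indel_region_density([ev], part)["deletion"]}
        assert dens["LSC"] * part.lsc.length / 1000 == pytest.approx(20)
        assert dens["IR"] * 2 * part.irb.length / 1000 == pytest.approx(30)

    def test_region_bias_recovered_in_simulation(self):
        """SSC InDel densities exceed LSC in nearly all seeded replicates
        when the planted SSC rate is three times the LSC rate."""
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            truth = pc.simulate(pc.SimulationConfig(
                seed=100 + seed, indel_rate=8e-4))
            per_taxon = {}
            for leaf in sorted(truth.leaf_entries):
                ref, smp = truth.pairwise_alignment(leaf)
                per_taxon[leaf] = pc.call_indels(ref, smp, taxon=leaf)
            merged = pc.merge_events(per_taxon)
            dens = pc.indel_region_density(merged, truth.ancestor.partition)
            tot = {r.region: 0.0 for r in dens["deletion"]}
            for et in dens.values():
                for rd in et:
                    tot[rd.region] += rd.density
            if tot["SSC"] > tot["LSC"]:
                wins += 1
        assert wins >= int(0.95 * n_rep)
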