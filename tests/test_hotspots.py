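"""Non-coding locus extraction, site counting and the SV statistic."""

import pytest
from hypothesis import given, settings, strategies as stst

import plastcomp as pc
from plastcomp.errors import EmptyAfterTrim, UndefinedSV
from plastcomp.hotspots import LocusVariability, locus_variability


class TestExtractNoncodingLoci:
    def test_adjacent_genes_give_spacer(self):
        feats = [
            pc.GeneFeature("g1", "CDS", "+", (pc.Interval(100, 200),)),
            pc.GeneFeature("g2", "CDS", "+", (pc.Interval(300, 400),)),
        ]
        rec = pc.PlastomeRecord("r", "A" * 500, feats)
        loci, skipped = pc.extract_noncoding_loci(rec)
        names = dict(loci)
        assert "g1-g2" in names and len(names["g1-g2"]) == 100
        assert not skipped

    def test_compound_gene_gives_intron(self):
        feats = [pc.GeneFeature("g", "CDS", "+",
                                (pc.Interval(10, 40), pc.Interval(70, 100)))]
        rec = pc.PlastomeRecord("r", "A" * 200, feats)
        loci, _ = pc.extract_noncoding_loci(rec)
        assert ("g-intron", "A" * 30) in loci

    def test_overlapping_genes_skipped(self):
        feats = [
            pc.GeneFeature("g1", "CDS", "+", (pc.Interval(100, 250),)),
            pc.GeneFeature("g2", "CDS", "+", (pc.Interval(200, 400),)),
        ]
        rec = pc.PlastomeRecord("r", "A" * 500, feats)
        loci, skipped = pc.extract_noncoding_loci(rec)
        assert skipped == ["g1-g2"]

    def test_ndhf_loss_merges_ycf1_rpl32(self):
        cfg = pc.SimulationConfig(seed=4, jsb_scenario="C", ndhf_absent=True)
        anc = pc.build_ancestor(cfg)
        loci, _ = pc.extract_noncoding_loci(anc.record)
        names = [n for n, _ in loci]
        assert "ycf1-rpl32" in names
        assert not any("ndhF" in n for n in names)

    def test_ndhf_present_separates_loci(self):
        cfg = pc.SimulationConfig(seed=4, jsb_scenario="C")
        anc = pc.build_ancestor(cfg)
        names = [n for n, _ in pc.extract_noncoding_loci(anc.record)[0]]
        assert "ndhF-rpl32" in names
        assert "ycf1-rpl32" not in names


class TestTrimTerminalGaps:
    def test_spec_example(self):
        out = pc.trim_terminal_gaps({"a": "-AC-", "b": "TAC-"})
        assert out == {"a": "AC", "b": "AC"}

    def test_gapless_unchanged(self):
        aln = {"a": "ACGT", "b": "AGGT"}
        assert pc.trim_terminal_gaps(aln) == aln

    def test_all_columns_gapped_raises(self):
        with pytest.raises(EmptyAfterTrim):
            pc.trim_terminal_gaps({"a": "--A", "b": "A--"})


class TestCountSites:
    def test_identical_alignment(self):
        aln = {"a": "A" * 100, "b": "A" * 100}
        assert pc.count_sites(aln) == (0, 0, 100)

    def test_hand_enumerated_mixture(self):
        """2 SNP columns + one 3-column gap run + 95 conserved columns."""
        a = list("A" * 100)
        b = list("A" * 100)
        b[10] = "G"
        b[50] = "T"
        for i in (70, 71, 72):
            b[i] = "-"
        aln = {"a": "".join(a), "b": "".join(b)}
        assert pc.count_sites(aln) == (2, 1, 95)

    def test_fully_distinct_rows(self):
        assert pc.count_sites({"a": "ACGTACGTAC", "b": "CGTACGTACG"}) == (10, 0, 0)

    def test_two_indel_events_separated_by_match(self):
        aln = {"a": "AAAAAAA", "b": "A--A--A"}
        assert pc.count_sites(aln) == (0, 2, 3)

    def test_different_gap_subsets_are_different_events(self):
        aln = {"a": "A-AA", "b": "AA-A", "c": "AAAA"}
        snps, indels, conserved = pc.count_sites(aln)
        assert indels == 2

    def test_column_unit_switch(self):
        aln = {"a": "AAAAA", "b": "A---A"}
        assert pc.count_sites(aln, indel_unit="event") == (0, 1, 2)
        assert pc.count_sites(aln, indel_unit="column") == (0, 3, 2)

    @given(stst.lists(stst.sampled_from("ACGT-"), min_size=20, max_size=60),
           stst.permutations(["a", "b", "c"]))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_column_conservation_and_row_order_invariance(self, chars, order):
        ncol = len(chars) // 2
        rows = {"a": "".join(chars[:ncol]), "b": "".join(chars[ncol:2 * ncol]),
                "c": "A" * ncol}
        if any(set(c) == {"-"} for c in zip(*rows.values())):
            return  # all-gap columns are undefined input for site counting
        snps, indels, conserved = pc.count_sites(rows)
        # columns split exactly into SNP, conserved, and indel-run columns
        gap_cols = sum(1 for col in zip(*rows.values()) if "-" in col)
        assert snps + conserved + gap_cols == ncol
        shuffled = {k: rows[k] for k in order}
        assert pc.count_sites(shuffled) == (snps, indels, conserved)


class TestSequenceVariability:
    @pytest.mark.parametrize("counts,expected", [
        ((0, 0, 100), 0.0),
        ((2, 1, 95), 3.0612),  # 3/98 x 100
        ((10, 0, 0), 100.0),
    ])
    def test_formula(self, counts, expected):
        assert pc.sequence_variability(counts) == pytest.approx(expected, abs=1e-4)

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedSV):
            pc.sequence_variability((0, 0, 0))

    def test_monotonicity(self):
        """Extra SNPs never lower SV; extra conserved sites never raise it."""
        base = pc.sequence_variability((5, 2, 93))
        assert pc.sequence_variability((6, 2, 93)) >= base
        assert pc.sequence_variability((5, 2, 94)) <= base


class TestRankHotspots:
    def _lv(self, name, snps, conserved):
        return LocusVariability(name, snps, 0, conserved)

    def test_low_conserved_locus_excluded(self):
        lvs = [self._lv("keep", 10, 100), self._lv("drop", 90, 99)]
        table = pc.rank_hotspots(lvs)
        assert not table[table.locus == "drop"].kept.iloc[0]
        assert table[table.locus == "keep"].hotspot.iloc[0]

    def test_top_ten_of_twelve_exact(self):
        lvs = [self._lv(f"L{i:02d}", i, 100) for i in range(1, 13)]
        table = pc.rank_hotspots(lvs, k=10)
        flagged = table[table.hotspot].sort_values("rank")
        assert flagged.locus.tolist() == [f"L{i:02d}" for i in range(12, 2, -1)]

    def test_shared_hotspots_between_two_rankings(self):
        a = pc.rank_hotspots([self._lv(f"A{i}", i, 100) for i in range(1, 11)]
                             + [self._lv("common1", 50, 100),
                                self._lv("common2", 60, 100)], k=10)
        b = pc.rank_hotspots([self._lv(f"B{i}", i, 100) for i in range(1, 11)]
                             + [self._lv("common1", 40, 100),
                                self._lv("common2", 70, 100)], k=10)
        assert pc.shared_hotspots(a, b) == ["common1", "common2"]

    def test_tie_broken_by_name(self):
        lvs = [self._lv("zeta", 10, 100), self._lv("alpha", 10, 100)]
        table = pc.rank_hotspots(lvs)
        assert table.sort_values("rank").locus.tolist() == ["alpha", "zeta"]


class TestInducedAlignments:
    def test_locus_variability_from_truth_alignment(self, default_truth):
        spans, _ = pc.noncoding_spans(default_truth.ancestor.record)
        n = default_truth.ancestor.record.length
        usable = [(name, a, b) for name, a, b in spans if b <= n and b - a > 120]
        assert usable
        name, a, b = usable[0]
        msa = default_truth.induced_msa(span=(a, b))
        lv = locus_variability(name, msa)
        assert lv.snps + lv.indels + lv.conserved > 0
        assert 0 <= lv.sv_percent <= 100
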