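"""SSR and dispersed-repeat detectors against brute-force oracles."""

import numpy as np
import pytest

import plastcomp as pc
from plastcomp.errors import ZeroVariance
from plastcomp.repeats import DEFAULT_SSR_THRESHOLDS

from conftest import random_dna
from oracles import oracle_dispersed, oracle_ssrs, rc, comp


def _plant(seq, pos, insert):
    return seq[:pos] + insert + seq[pos + len(insert):]


class TestFindSSRs:
    def test_mononucleotide_threshold_boundary(self, rng):
        base = random_dna(rng, 200)
        s8 = _plant("C" + base + "C", 79, "C" + "A" * 8 + "C")
        s7 = _plant("C" + base + "C", 79, "C" + "A" * 7 + "C")
        hits8 = [s for s in pc.find_ssrs(s8, circular=False) if s.motif == "A"]
        hits7 = [s for s in pc.find_ssrs(s7, circular=False) if s.motif == "A"]
        assert any(s.copies >= 8 for s in hits8)
        assert not hits7

    def test_non_primitive_motifs_suppressed(self):
        seq = "C" * 10 + "AT" * 6 + "G" * 10
        hits = pc.find_ssrs(seq, circular=False)
        motifs = {(s.motif, s.unit_len, s.copies) for s in hits}
        assert ("AT", 2, 6) in motifs
        assert not any(s.unit_len == 4 for s in hits)  # no ATAT x 3 duplicate

    def test_wraps_origin_in_circular_mode(self):
        seq = "AAAA" + "GCGT" * 30 + "AAAAA"  # A x 9 across the origin
        hits = [s for s in pc.find_ssrs(seq, circular=True) if s.motif == "A"]
        assert len(hits) == 1
        assert hits[0].wraps and hits[0].copies == 9

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_on_planted_sequences(self, seed):
        rng = np.random.default_rng(1000 + seed)
        seq = random_dna(rng, 500)
        for pos, motif, copies in ((40, "A", 9), (120, "AG", 6), (300, "ACT", 5)):
            seq = _plant(seq, pos, motif * copies)
        got = {(s.start, s.motif, s.copies)
               for s in pc.find_ssrs(seq, circular=False)}
        assert got == oracle_ssrs(seq, DEFAULT_SSR_THRESHOLDS)

    def test_maximality_of_reported_runs(self, rng):
        seq = random_dna(rng, 400)
        seq = _plant(seq, 100, "A" * 10)
        for s in pc.find_ssrs(seq, circular=False):
            left = seq[s.start - 1] if s.start else None
            if left is not None:
                assert left != seq[s.start + s.unit_len - 1]


class TestFindDispersedRepeats:
    def test_forward_pair_exact(self, rng):
        unit = random_dna(rng, 30)
        seq = "A" + random_dna(rng, 200) + "A" + unit + "A" \
            + random_dna(rng, 200) + "A" + unit + "A" + random_dna(rng, 100)
        got = pc.find_dispersed_repeats(seq, circular=False, max_hamming=0)
        fw = [r for r in got if r.rtype == "forward" and r.hamming == 0]
        assert any(r.rlen >= 30 for r in fw)

    def test_palindromic_pair_found(self, rng):
        unit = random_dna(rng, 30)
        seq = "A" + random_dna(rng, 150) + "A" + unit + "A" \
            + random_dna(rng, 150) + "A" + rc(unit) + "A" + random_dna(rng, 80)
        got = pc.find_dispersed_repeats(seq, circular=False, max_hamming=0)
        assert any(r.rtype == "palindromic" and r.rlen >= 30 for r in got)

    def test_four_mismatches_excluded(self, rng):
        unit = random_dna(rng, 40)
        mutated = list(unit)
        for i in (5, 15, 25, 35):
            mutated[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[i]]
        seq = random_dna(rng, 100) + unit + random_dna(rng, 100) \
            + "".join(mutated) + random_dna(rng, 100)
        got = pc.find_dispersed_repeats(seq, circular=False)
        # any window covering both copies would carry 4 mismatches
        assert all(r.hamming <= 3 for r in got)
        assert all((r.rlen - r.hamming) / r.rlen >= 0.90 for r in got)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_with_planted_repeats(self, seed):
        rng = np.random.default_rng(2000 + seed)
        n = int(rng.integers(300, 1200))
        seq = random_dna(rng, n)
        # plant one pair of each type, some with mismatches
        unit = random_dna(rng, 34)
        variants = {
            "forward": unit,
            "reverse": unit[::-1],
            "complement": comp(unit),
            "palindromic": rc(unit),
        }
        pos = 10
        seq = _plant(seq, pos, unit)
        for i, (rtype, copy2) in enumerate(sorted(variants.items())):
            p2 = 60 + i * 60
            mutated = list(copy2)
            if i % 2:
                j = 17
                mutated[j] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[j]]
            seq = _plant(seq, p2, "".join(mutated))
        got = {(r.rtype, r.pos1, r.pos2, r.rlen, r.hamming)
               for r in pc.find_dispersed_repeats(seq, circular=False)}
        assert got == oracle_dispersed(seq)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_pure_random(self, seed):
        rng = np.random.default_rng(3000 + seed)
        seq = random_dna(rng, int(rng.integers(500, 2000)))
        got = {(r.rtype, r.pos1, r.pos2, r.rlen, r.hamming)
               for r in pc.find_dispersed_repeats(seq, circular=False)}
        assert got == oracle_dispersed(seq)

    def test_circular_wrap_hit_flagged(self, rng):
        unit = random_dna(rng, 36)
        # copy 2 crosses the origin: last 18 bases + first 18 bases
        seq = unit[18:] + "A" + random_dna(rng, 300) + "A" + unit + "A" \
            + random_dna(rng, 200) + "A" + unit[:18]
        got = pc.find_dispersed_repeats(seq, circular=True, max_hamming=0)
        assert any(r.wraps and r.rlen >= 30 for r in got)


class TestDensities:
    def test_single_repeat_density_value(self, default_ancestor):
        part = default_ancestor.partition
        rep = pc.DispersedRepeat("forward", part.ssc.start + 10,
                                 part.ssc.start + 100, 30, 0)
        dens = {d.region: d.density for d in pc.repeat_density([rep], part)}
        assert dens["SSC"] == pytest.approx(60 / (part.ssc.length / 1000))
        assert dens["LSC"] == 0.0

    def test_no_repeats_all_zero(self, default_ancestor):
        dens = pc.repeat_density([], default_ancestor.partition)
        assert all(d.density == 0 for d in dens)

    def test_density_conservation_with_planted_truth(self, default_ancestor):
        """sum(density x region_kb) equals total repeat bases counted."""
        part = default_ancestor.partition
        reps = pc.find_dispersed_repeats(default_ancestor.record, max_hamming=0)
        assert {(r.rtype, r.pos1, r.pos2, r.rlen) for r in reps} == \
            {(r.rtype, r.pos1, r.pos2, r.rlen)
             for r in default_ancestor.planted_repeats}
        dens = pc.repeat_density(reps, part)
        kb = {"LSC": part.lsc.length, "SSC": part.ssc.length,
              "IR": part.irb.length + part.ira.length}
        total = sum(d.density * kb[d.region] / 1000 for d in dens)
        assert total == pytest.approx(sum(2 * r.rlen for r in reps))

    def test_junction_spanning_repeat_prorated(self, default_ancestor):
        part = default_ancestor.partition
        j = part.irb.start  # 10 bp in LSC, 20 bp in IRb
        rep = pc.DispersedRepeat("forward", j - 10, part.ssc.start + 200, 30, 0)
        dens = {d.region: d.density for d in pc.repeat_density([rep], part)}
        assert dens["LSC"] * part.lsc.length / 1000 == pytest.approx(10)
        assert dens["IR"] * (2 * part.irb.length) / 1000 == pytest.approx(20)


class TestDensityGCCorrelation:
    def test_exact_negative_linear_relation(self):
        r, p = pc.density_gc_correlation([1, 2, 3, 4], [8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_constant_vector_raises(self):
        with pytest.raises(ZeroVariance):
            pc.density_gc_correlation([1, 2, 3], [5, 5, 5])

    def test_known_correlation_recovered(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = 0.8 * x + np.sqrt(1 - 0.8 ** 2) * rng.normal(size=n)
        r, _ = pc.density_gc_correlation(x, y)
        assert abs(r - 0.8) < 0.1
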