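"""Quadripartite structure detection and regional GC statistics.

A plastome tiles into LSC + IRb + SSC + IRa, where IRa is the reverse
complement of IRb up to a small number of mismatches. The detector finds the
maximal-length inverted-repeat pair by k-mer seeding between the doubled
sequence and its reverse complement, extending seeds along anti-diagonals
under a mismatch budget, and trimming unsupported window ends. The genome is
then canonically rotated so the LSC starts at position 0, and oriented so
that ycf1 (when annotated) lies on the SSC/IRa side.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import (Interval, PlastomeRecord, flip_record, gc_percent,
                   revcomp, rotate_record)
from .errors import AmbiguousPartition, DegenerateGroups, NoIRFound

REGIONS = ("LSC", "IRb", "SSC", "IRa")


@dataclass(frozen=True)
class QuadripartitePartition:
    """Coordinates of LSC/IRb/SSC/IRa on the canonically rotated sequence.

    ``rotation`` and ``flipped`` record how to transform the input record
    into canonical form: reverse-complement first when ``flipped``, then
    rotate so old position ``rotation`` becomes 0.
    """

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    mismatches: int
    rotation: int = 0
    flipped: bool = False

    @property
    def length(self) -> int:
        return self.ira.end

    def lengths(self) -> tuple[int, int, int, int]:
        return (self.lsc.length, self.irb.length, self.ssc.length, self.ira.length)

    def region_interval(self, region: str) -> Interval:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}[region]

    def validate(self) -> None:
        n = self.length
        assert self.lsc.start == 0
        assert self.lsc.end == self.irb.start
        assert self.irb.end == self.ssc.start
        assert self.ssc.end == self.ira.start
        assert sum(self.lengths()) == n
        assert self.irb.length == self.ira.length
        assert self.ssc.length <= self.lsc.length

    def region_of(self, pos: int) -> str:
        for name in REGIONS:
            if self.region_interval(name).contains(pos):
                return name
        raise ValueError(f"position {pos} outside genome of length {self.length}")


def canonicalize(record: PlastomeRecord, partition: QuadripartitePartition) -> PlastomeRecord:
    """Apply the partition's flip/rotation so the LSC starts at position 0."""
    rec = flip_record(record) if partition.flipped else record
    return rotate_record(rec, partition.rotation)


# ---------------------------------------------------------------------------
# inverted-repeat pair search


def _mismatch_windows(mis: np.ndarray, lo: int, hi: int, k: int) -> list[tuple[int, int]]:
    """Maximal windows within [lo, hi) containing at most k mismatches.

    ``mis`` holds sorted mismatch positions inside [lo, hi). Each window is
    bounded on each side by the (k+1)-th mismatch or the range boundary.
    """
    m = len(mis)
    if m <= k:
        return [(lo, hi)]
    bounds = np.concatenate(([lo - 1], mis, [hi]))
    out = []
    for j in range(m - k + 1):
        out.append((int(bounds[j]) + 1, int(bounds[j + k + 1])))
    return out


def _extend_core(j: int, bounds: np.ndarray, frac: float, min_terminal: int
                 ) -> tuple[int, int, int]:
    """Grow exact run j outward, absorbing isolated mismatches.

    ``bounds`` is [lo-1, mismatch positions..., hi]; run j spans
    (bounds[j]+1, bounds[j+1]). A mismatch is absorbed only when the exact
    run beyond it has at least ``min_terminal`` matches (so the window never
    drifts into unrelated sequence) and the running mismatch fraction stays
    within ``frac``. Returns (start, end, mismatches).
    """
    wa = int(bounds[j]) + 1
    wb = int(bounds[j + 1])
    mm = 0
    right = j + 1
    while right < len(bounds) - 1:
        nxt = int(bounds[right + 1]) - int(bounds[right]) - 1
        if nxt < min_terminal or (mm + 1) > frac * (int(bounds[right + 1]) - wa):
            break
        mm += 1
        wb = int(bounds[right + 1])
        right += 1
    left = j
    while left > 0:
        prv = int(bounds[left]) - int(bounds[left - 1]) - 1
        if prv < min_terminal or (mm + 1) > frac * (wb - int(bounds[left - 1]) - 1):
            break
        mm += 1
        wa = int(bounds[left - 1]) + 1
        left -= 1
    return wa, wb, mm


def _circular_disjoint(p: int, q: int, length: int, n: int) -> bool:
    """True when [p, p+length) and [q, q+length) do not overlap mod n."""
    if 2 * length > n:
        return False
    gap1 = (q - (p + length)) % n
    gap2 = (p - (q + length)) % n
    return gap1 + gap2 + 2 * length == n


def _find_ir_candidates(seq: str, min_len: int, max_mismatch_frac: float,
                        seed_k: int, min_terminal: int) -> dict[tuple, tuple]:
    n = len(seq)
    s2 = seq + seq
    z2 = revcomp(s2)  # z2[x + e] pairs with s2 position 2n-1-x-e
    index: dict[str, list[int]] = defaultdict(list)
    for pos in range(len(z2) - seed_k + 1):
        index[z2[pos:pos + seed_k]].append(pos)
    diagonals: set[int] = set()
    for x in range(len(s2) - seed_k + 1):
        kmer = s2[x:x + seed_k]
        for zpos in index.get(kmer, ()):
            diagonals.add(zpos - x)

    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    b2 = np.frombuffer(z2.encode(), dtype=np.uint8)
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    valid_a = np.isin(a2, acgt)
    valid_b = np.isin(b2, acgt)
    core_min = max(seed_k, min_terminal)

    candidates: dict[tuple, tuple] = {}
    for e in sorted(diagonals):
        lo = max(0, -e)
        hi = min(len(s2), len(s2) - e)
        if hi - lo < min_len:
            continue
        mism = (a2[lo:hi] != b2[lo + e:hi + e]) | ~valid_a[lo:hi] | ~valid_b[lo + e:hi + e]
        mis = np.flatnonzero(mism) + lo
        bounds = np.concatenate(([lo - 1], mis, [hi]))
        run_lens = np.diff(bounds) - 1
        seen: set[tuple[int, int]] = set()
        for j in np.flatnonzero(run_lens >= core_min):
            wa, wb, mm = _extend_core(int(j), bounds, max_mismatch_frac,
                                      min_terminal)
            if (wa, wb) in seen:
                continue
            seen.add((wa, wb))
            length = wb - wa
            if length < min_len or mm > max_mismatch_frac * length:
                continue
            p1 = wa % n
            q = (2 * n - e - wb) % n
            if not _circular_disjoint(p1, q, length, n):
                continue
            key = (frozenset({p1, q}), length)
            if key not in candidates or mm < candidates[key][3]:
                candidates[key] = (p1, q, length, mm)
    return candidates


def _derive_regions(p1: int, q: int, length: int, n: int):
    """Order the two copies and the two single-copy gaps on the circle.

    Returns (lsc_start, lsc_len, irb_start, ssc_start, ssc_len, ira_start),
    all in the current (unrotated) coordinate frame, or None lengths when
    the two gaps tie (caller breaks the tie).
    """
    gap_a = (q - (p1 + length)) % n  # after copy at p1
    gap_b = (p1 - (q + length)) % n  # after copy at q
    if gap_a >= gap_b:
        # gap after p1-copy is the LSC; the copy at q follows it -> IRb
        return ((p1 + length) % n, gap_a, q, (q + length) % n, gap_b, p1)
    return ((q + length) % n, gap_b, p1, (p1 + length) % n, gap_a, q)


def detect_partition(genome: PlastomeRecord, min_ir_len: int = 1000,
                     max_mismatch_frac: float = 0.02, *, seed_k: int = 21,
                     min_terminal_matches: int = 10) -> QuadripartitePartition:
    """Detect the IR pair and partition the circular genome.

    Returns coordinates on the canonically rotated (and possibly
    reverse-complemented) sequence; apply :func:`canonicalize` to obtain
    that sequence. Raises :class:`NoIRFound` when no inverted duplication of
    at least ``min_ir_len`` qualifies and :class:`AmbiguousPartition` when
    two non-equivalent maximal pairs tie.
    """
    n = genome.length
    if n < 4 * min_ir_len:
        raise ValueError(f"genome length {n} < 4 x min_ir_len {min_ir_len}")
    seq = genome.sequence
    if not any(b in "ACGT" for b in seq):
        raise ValueError("sequence has no unambiguous bases")

    candidates = _find_ir_candidates(seq, min_ir_len, max_mismatch_frac,
                                     seed_k, min_terminal_matches)
    if not candidates:
        raise NoIRFound(f"no inverted repeat pair of >= {min_ir_len} bp "
                        f"at mismatch fraction <= {max_mismatch_frac}")
    best_len = max(key[1] for key in candidates)
    finalists = {k: v for k, v in candidates.items() if k[1] == best_len}
    if len(finalists) > 1:
        raise AmbiguousPartition(
            f"{len(finalists)} non-equivalent maximal IR pairs of {best_len} bp",
            candidates=[(v[0], v[1], v[2]) for v in finalists.values()])
    (p1, q, ir_len, mism) = next(iter(finalists.values()))

    lsc_start, lsc_len, irb_start, ssc_start, ssc_len, ira_start = \
        _derive_regions(p1, q, ir_len, n)
    if lsc_len == ssc_len:
        gc_a = gc_percent(genome.fragment(lsc_start, lsc_start + lsc_len))
        gc_b = gc_percent(genome.fragment(ssc_start, ssc_start + ssc_len))
        if gc_a == gc_b:
            raise AmbiguousPartition("single-copy regions tie in length and GC",
                                     candidates=[(p1, q, ir_len)])
        if gc_a < gc_b:  # lower-GC segment is taken as the SSC
            lsc_start, ssc_start = ssc_start, lsc_start
            irb_start, ira_start = ira_start, irb_start

    flipped = _needs_flip(genome, ssc_start, ssc_len, ira_start, ir_len)
    if flipped:
        # map coordinates onto the reverse complement: pos -> n-1-pos
        def fl(start, length):
            return (n - (start + length)) % n
        p1f, qf = fl(irb_start, ir_len), fl(ira_start, ir_len)
        lsc_start, lsc_len, irb_start, ssc_start, ssc_len, ira_start = \
            _derive_regions(p1f, qf, ir_len, n)

    rotation = lsc_start
    part = QuadripartitePartition(
        lsc=Interval(0, lsc_len),
        irb=Interval(lsc_len, lsc_len + ir_len),
        ssc=Interval(lsc_len + ir_len, lsc_len + ir_len + ssc_len),
        ira=Interval(lsc_len + ir_len + ssc_len, n),
        mismatches=mism, rotation=rotation, flipped=flipped)
    part.validate()
    return part


def _needs_flip(genome: PlastomeRecord, ssc_start: int, ssc_len: int,
                ira_start: int, ir_len: int) -> bool:
    """Orientation rule: ycf1 on the SSC/IRa side; else lexicographic SSC."""
    n = genome.length
    ycf1 = genome.feature_by_name("ycf1")
    if ycf1:
        for feat in ycf1:
            for iv in feat.intervals:
                for target_start, target_len in ((ssc_start, ssc_len),
                                                 (ira_start, ir_len)):
                    if _circular_overlap(iv.start, iv.end, target_start,
                                         target_start + target_len, n):
                        return False
        return True
    ssc_seq = genome.fragment(ssc_start, ssc_start + ssc_len)
    return revcomp(ssc_seq) < ssc_seq


def _circular_overlap(s1, e1, s2, e2, n) -> bool:
    def pieces(s, e):
        s %= n
        span = e - s
        return [(s, min(s + span, n))] + ([(0, (s + span) - n)] if s + span > n else [])
    for a1, b1 in pieces(s1, e1):
        for a2, b2 in pieces(s2, e2):
            if min(b1, b2) > max(a1, a2):
                return True
    return False


# ---------------------------------------------------------------------------
# regional GC


@dataclass(frozen=True)
class RegionGC:
    region: str  # total | LSC | SSC | IR
    gc_percent: float


def region_gc(genome: PlastomeRecord, partition: QuadripartitePartition) -> list[RegionGC]:
    """GC% for total / LSC / IR (both copies pooled) / SSC, 2-dp rounded."""
    rec = genome
    if partition.rotation != 0 or partition.flipped:
        rec = canonicalize(genome, partition)
    seq = rec.sequence
    lsc = seq[partition.lsc.start:partition.lsc.end]
    irb = seq[partition.irb.start:partition.irb.end]
    ssc = seq[partition.ssc.start:partition.ssc.end]
    ira = seq[partition.ira.start:partition.ira.end]
    return [
        RegionGC("total", round(gc_percent(seq), 2)),
        RegionGC("LSC", round(gc_percent(lsc), 2)),
        RegionGC("IR", round(gc_percent(irb + ira), 2)),
        RegionGC("SSC", round(gc_percent(ssc), 2)),
    ]


def region_gc_table(entries: dict[str, list[RegionGC]]) -> pd.DataFrame:
    """Stack per-genome RegionGC lists into a genomes x regions table."""
    rows = {gid: {rg.region: rg.gc_percent for rg in lst}
            for gid, lst in entries.items()}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "genome"
    return df[["total", "LSC", "IR", "SSC"]]


def weighted_total_gc(lsc_bp: int, ir_bp: int, ssc_bp: int,
                      gc_lsc: float, gc_ir: float, gc_ssc: float) -> float:
    """Length-weighted mean of regional GC values (IR counted twice)."""
    total = lsc_bp + 2 * ir_bp + ssc_bp
    return round((gc_lsc * lsc_bp + gc_ir * 2 * ir_bp + gc_ssc * ssc_bp) / total, 2)


def load_feature_table() -> pd.DataFrame:
    """Published genome-feature table for 19 Asian + 8 South American
    Bulbophyllum plastomes: per-genome region lengths (bp) and GC (%)."""
    import importlib.resources as ir
    with ir.files("plastcomp").joinpath("data/bulbophyllum_cp_features.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def validate_feature_table(df: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic consistency of a feature table row set.

    Adds columns: ``length_check`` (LSC + 2xIR + SSC == total) and
    ``gc_weighted`` (length-weighted total GC from the regional values).
    """
    out = df.copy()
    out["length_check"] = (out.lsc_bp + 2 * out.ir_bp + out.ssc_bp) == out.length_bp
    out["gc_weighted"] = [
        weighted_total_gc(r.lsc_bp, r.ir_bp, r.ssc_bp, r.gc_lsc, r.gc_ir, r.gc_ssc)
        for r in out.itertuples()]
    return out


def clade_gc_compare(gc_table: pd.DataFrame, clade_labels: dict[str, str]) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per region between two clades.

    ``gc_table`` is the output of :func:`region_gc_table`; ``clade_labels``
    maps genome id to one of exactly two clade names. Returns one row per
    region with U, p and the direction of the median shift.
    """
    clades = sorted(set(clade_labels.values()))
    if len(clades) != 2:
        raise DegenerateGroups(f"need exactly 2 clades, got {clades}")
    a_name, b_name = clades
    rows = []
    for region in gc_table.columns:
        a = gc_table.loc[[g for g in gc_table.index if clade_labels.get(g) == a_name], region]
        b = gc_table.loc[[g for g in gc_table.index if clade_labels.get(g) == b_name], region]
        if len(a) < 2 or len(b) < 2:
            raise DegenerateGroups(f"clade with <2 members for region {region}")
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        if a.median() == b.median():
            direction = "tie"
        else:
            direction = f"{a_name}>{b_name}" if a.median() > b.median() else f"{b_name}>{a_name}"
        rows.append({"region": region, "U": float(u), "p": float(p),
                     "direction": direction, f"n_{a_name}": len(a), f"n_{b_name}": len(b)})
    return pd.DataFrame(rows)
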