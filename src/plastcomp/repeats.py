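"""SSR and long-dispersed-repeat detection, densities, GC correlation.

SSRs are perfect tandem repeats of 1-6 nt motifs at MISA-style minimum copy
numbers (8 for mononucleotide motifs, 5 for all longer motifs). Dispersed
repeats follow the REPuter definition: maximal repeat pairs of four
orientations (forward, reverse, complement, palindromic) of at least 30 bp,
at most 3 mismatches and at least 90% identity. Both detectors scan the
circular genome across the origin; origin-spanning hits are flagged.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import PlastomeRecord, complement, revcomp
from .errors import EmptyRegion, ZeroVariance
from .structure import QuadripartitePartition

#: minimum copy number per motif length (mono 8, poly 5)
DEFAULT_SSR_THRESHOLDS = {1: 8, 2: 5, 3: 5, 4: 5, 5: 5, 6: 5}

REPEAT_TYPES = ("forward", "reverse", "complement", "palindromic")


@dataclass(frozen=True)
class SSRLocus:
    start: int
    motif: str
    unit_len: int
    copies: int
    span: int
    wraps: bool = False

    def intervals(self, n: int) -> list[tuple[int, int]]:
        if self.start + self.span <= n:
            return [(self.start, self.start + self.span)]
        return [(self.start, n), (0, self.start + self.span - n)]


@dataclass(frozen=True)
class DispersedRepeat:
    rtype: str
    pos1: int
    pos2: int
    rlen: int
    hamming: int
    wraps: bool = False

    @property
    def identity(self) -> float:
        return (self.rlen - self.hamming) / self.rlen

    def intervals(self, n: int) -> list[tuple[int, int]]:
        out = []
        for pos in (self.pos1, self.pos2):
            if pos + self.rlen <= n:
                out.append((pos, pos + self.rlen))
            else:
                out.append((pos, n))
                out.append((0, pos + self.rlen - n))
        return out


def _is_primitive(motif: str) -> bool:
    u = len(motif)
    for d in range(1, u):
        if u % d == 0 and motif == motif[:d] * (u // d):
            return False
    return True


def _circular_true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a circular boolean array as (start, length)."""
    n = len(mask)
    if mask.all():
        return [(0, n)]
    gaps = np.flatnonzero(~mask)
    runs = []
    for j in range(len(gaps)):
        a = (int(gaps[j]) + 1) % n
        nxt = int(gaps[(j + 1) % len(gaps)])
        length = (nxt - int(gaps[j]) - 1) % n
        if length > 0:
            runs.append((a, length))
    return runs


def find_ssrs(genome: PlastomeRecord | str, thresholds: dict[int, int] | None = None,
              circular: bool = True) -> list[SSRLocus]:
    """All maximal perfect tandem repeats meeting the copy-number thresholds.

    Non-primitive motifs are suppressed so a run is reported once, at its
    shortest period. In circular mode the scan wraps the origin and hits
    crossing it carry ``wraps=True``.
    """
    seq = genome.sequence if isinstance(genome, PlastomeRecord) else str(genome).upper()
    thresholds = dict(DEFAULT_SSR_THRESHOLDS if thresholds is None else thresholds)
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    found = []
    for u, min_copies in sorted(thresholds.items()):
        if n <= u:
            continue
        if circular:
            eq = arr == np.roll(arr, u)
            runs = _circular_true_runs(eq)
        else:
            eq = arr[u:] == arr[:-u]
            runs = [(int(a) + u, int(l)) for a, l in _linear_true_runs(eq)]
        for i, m in runs:
            run_len = min(m + u, n)
            copies = run_len // u
            if copies < min_copies:
                continue
            start = (i - u) % n if circular else i - u
            motif = (seq + seq)[start:start + u]
            if not _is_primitive(motif):
                continue
            span = copies * u
            found.append(SSRLocus(start=start, motif=motif, unit_len=u,
                                  copies=copies, span=span,
                                  wraps=circular and start + span > n))
    return sorted(found, key=lambda s: (s.start, s.unit_len))


def _linear_true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(a), int(b - a)) for a, b in zip(starts, ends)]


# ---------------------------------------------------------------------------
# dispersed repeats


def _seed_hits(x: str, z: str, k: int, skip_nonpositive: bool) -> dict[int, list[int]]:
    """x positions of exact k-mer matches, grouped by diagonal e = zpos - xpos."""
    index: dict[str, list[int]] = defaultdict(list)
    for pos in range(len(x) - k + 1):
        index[x[pos:pos + k]].append(pos)
    hits: dict[int, list[int]] = defaultdict(list)
    for zpos in range(len(z) - k + 1):
        for xpos in index.get(z[zpos:zpos + k], ()):
            e = zpos - xpos
            if skip_nonpositive and e <= 0:
                continue
            hits[e].append(xpos)
    return hits


def _windows_around_seeds(x: str, z: str, e: int, xs: list[int], k: int,
                          max_hamming: int, min_len: int):
    """Maximal <=max_hamming windows on diagonal z = x + e containing a seed.

    Every window of length >= min_len with <= max_hamming mismatches holds
    an exact run of >= (min_len - max_hamming)/(max_hamming + 1) matches,
    so extending outward from each seeded exact run enumerates exactly the
    qualifying maximal windows. Yields (start, end, hamming), end exclusive.
    """
    lo = max(0, -e)
    hi = min(len(x), len(z) - e)
    if hi - lo < min_len:
        return
    xs = sorted(set(xs))
    covered_until = lo - 1
    seen: set[tuple[int, int]] = set()
    h = max_hamming
    for xpos in xs:
        if xpos < covered_until:  # inside an already-expanded run
            continue
        # expand the seed into its full exact run [a, b)
        a = xpos
        while a - 1 >= lo and x[a - 1] == z[a - 1 + e]:
            a -= 1
        b = xpos + k
        while b < hi and x[b] == z[b + e]:
            b += 1
        covered_until = b
        # h+1 nearest mismatches on each side (sentinel at the range wall)
        lb: list[int] = []
        i = a - 1
        while len(lb) <= h and i >= lo:
            lb.append(i)
            i -= 1
            while i >= lo and x[i] == z[i + e]:
                i -= 1
        left_wall = len(lb) <= h
        if left_wall:
            lb.append(lo - 1)
        rb: list[int] = []
        i = b
        while len(rb) <= h and i < hi:
            rb.append(i)
            i += 1
            while i < hi and x[i] == z[i + e]:
                i += 1
        right_wall = len(rb) <= h
        if right_wall:
            rb.append(hi)
        for t in range(h + 1):
            jl = min(t, len(lb) - 1)
            jr = min(h - t, len(rb) - 1)
            wa = lb[jl] + 1
            wb = rb[jr]
            if (wa, wb) in seen:
                continue
            seen.add((wa, wb))
            if wb - wa < min_len:
                continue
            # absorbed mismatches are the jl (left) + jr (right) entries
            # strictly inside the window; a bounding sentinel is a wall
            yield wa, wb, jl + jr


def find_dispersed_repeats(genome: PlastomeRecord | str, min_len: int = 30,
                           max_hamming: int = 3, min_identity: float = 0.90,
                           circular: bool = True,
                           rtypes: Sequence[str] = REPEAT_TYPES) -> list[DispersedRepeat]:
    """Maximal dispersed repeat pairs of the four orientations.

    A pair is maximal when extending it by one base on either side would
    exceed ``max_hamming``; pairs additionally need length >= ``min_len``
    and identity >= ``min_identity``. The trivial forward self-match is
    excluded, and each unordered pair is reported once.
    """
    seq = genome.sequence if isinstance(genome, PlastomeRecord) else str(genome).upper()
    n = len(seq)
    if n < min_len:
        return []
    scan = seq + seq if circular else seq
    m = len(scan)
    k_seed = max(4, math.ceil((min_len - max_hamming) / (max_hamming + 1)))
    results: dict[tuple, DispersedRepeat] = {}
    for rtype in rtypes:
        if rtype == "forward":
            zstr = scan
        elif rtype == "complement":
            zstr = complement(scan)
        elif rtype == "reverse":
            zstr = scan[::-1]
        elif rtype == "palindromic":
            zstr = revcomp(scan)
        else:
            raise ValueError(f"unknown repeat type {rtype!r}")
        hits = _seed_hits(scan, zstr, k_seed,
                          skip_nonpositive=rtype in ("forward", "complement"))
        if circular and rtype == "forward":
            hits.pop(n, None)  # self-identity diagonal of the doubled sequence
        for e in sorted(hits):
            lo = max(0, -e)
            hi = min(m, m - e)
            for wa, wb, mm in _windows_around_seeds(scan, zstr, e, hits[e],
                                                    k_seed, max_hamming, min_len):
                length = wb - wa
                if (length - mm) / length < min_identity:
                    continue
                if circular:
                    # boundary-clipped duplicates of wrapped windows
                    if wa == lo or wb == hi:
                        continue
                    if length > n:
                        continue
                if rtype in ("forward", "complement"):
                    p1, p2 = wa, wa + e
                else:
                    p1, p2 = wa, m - wb - e
                if circular:
                    p1, p2 = p1 % n, p2 % n
                if p2 < p1:
                    p1, p2 = p2, p1
                key = (rtype, p1, p2, length)
                if key not in results:
                    wraps = circular and (p1 + length > n or p2 + length > n)
                    results[key] = DispersedRepeat(rtype, p1, p2, length, mm, wraps)
    return sorted(results.values(),
                  key=lambda r: (r.pos1, r.pos2, r.rlen, r.rtype))


# ---------------------------------------------------------------------------
# densities and correlation


@dataclass(frozen=True)
class RegionDensity:
    region: str  # LSC | IR | SSC
    density: float  # bp / kbp


def repeat_density(repeats: Iterable[SSRLocus | DispersedRepeat],
                   partition: QuadripartitePartition) -> list[RegionDensity]:
    """Repeat bases per region, in bp/kbp; junction-spanning hits pro-rated.

    Both copies of a dispersed repeat contribute; IRb and IRa are pooled.
    Bases are counted with multiplicity, so the conservation identity
    sum(density x region_kb) == total repeat bases holds exactly.
    """
    n = partition.length
    region_ivs = {
        "LSC": [partition.lsc.as_tuple()],
        "IR": [partition.irb.as_tuple(), partition.ira.as_tuple()],
        "SSC": [partition.ssc.as_tuple()],
    }
    bases = {name: 0 for name in region_ivs}
    for rep in repeats:
        for (a, b) in rep.intervals(n):
            for name, ivs in region_ivs.items():
                for (ra, rb) in ivs:
                    bases[name] += max(0, min(b, rb) - max(a, ra))
    out = []
    for name, ivs in region_ivs.items():
        rlen = sum(b - a for a, b in ivs)
        if rlen == 0:
            raise EmptyRegion(f"region {name} has zero length")
        out.append(RegionDensity(name, bases[name] / (rlen / 1000.0)))
    return out


def density_gc_correlation(densities: Sequence[float], gcs: Sequence[float]) -> tuple[float, float]:
    """Pearson r and two-sided p between paired density and GC values."""
    x = np.asarray(densities, dtype=float)
    y = np.asarray(gcs, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVariance("constant vector in correlation")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
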