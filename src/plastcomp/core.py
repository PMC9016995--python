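"""Core containers for circular plastome records and gene annotations.

Coordinates are 0-based half-open throughout the library; GFF3 I/O performs
the conversion to 1-based closed coordinates at the boundary. The plastome
sequence is circular: indexing helpers wrap modulo the genome length, and a
feature interval list may contain a split interval pair produced by
normalising a span that crosses the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

_COMP = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                      "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def complement(seq: str) -> str:
    """Complement of a IUPAC nucleotide string (case preserved)."""
    return seq.translate(_COMP)


def revcomp(seq: str) -> str:
    """Reverse complement of a IUPAC nucleotide string."""
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Interval:
    """Half-open interval [start, end) on a linearised circular sequence."""

    start: int
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"interval end {self.end} < start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap(self, other: "Interval") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def as_tuple(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class GeneFeature:
    """A gene annotation: one or more ordered spans on the genome.

    ``intervals`` is compound for intron-containing genes; spans are kept in
    genome order regardless of strand. ``frame_offset`` is the GFF3 phase of
    the first coding span.
    """

    name: str
    kind: str  # CDS | tRNA | rRNA
    strand: str  # '+' | '-'
    intervals: tuple[Interval, ...]
    frame_offset: int = 0

    def __post_init__(self):
        if self.kind not in {"CDS", "tRNA", "rRNA"}:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.intervals:
            raise ValueError("feature needs at least one interval")
        if not 0 <= self.frame_offset <= 2:
            raise ValueError("frame_offset must be 0..2")

    @property
    def start(self) -> int:
        return min(iv.start for iv in self.intervals)

    @property
    def end(self) -> int:
        return max(iv.end for iv in self.intervals)

    @property
    def span_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def covers(self, pos: int) -> bool:
        return any(iv.contains(pos) for iv in self.intervals)


@dataclass
class PlastomeRecord:
    """A circular plastome: id, uppercase sequence and its annotations."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, pos: int) -> str:
        return self.sequence[pos % self.length]

    def fragment(self, start: int, end: int) -> str:
        """Subsequence [start, end) with circular wrap; end may exceed length."""
        n = self.length
        start %= n
        span = end - start if end >= start else end % n + n - start
        doubled = self.sequence + self.sequence
        return doubled[start:start + span]

    def feature_by_name(self, name: str) -> list[GeneFeature]:
        return [f for f in self.features if f.name == name]


def shift_interval(iv: Interval, offset: int, n: int) -> list[Interval]:
    """Shift an interval left by ``offset`` on a circle of size n.

    Returns one interval, or a split pair when the shifted span crosses the
    origin (first the piece ending at n, then the wrapped piece from 0).
    """
    ns = (iv.start - offset) % n
    ne = ns + iv.length
    if ne <= n:
        return [Interval(ns, ne)]
    return [Interval(ns, n), Interval(0, ne - n)]


def rotate_record(record: PlastomeRecord, offset: int) -> PlastomeRecord:
    """Rotate so that old position ``offset`` becomes position 0."""
    n = record.length
    offset %= n
    seq = record.sequence[offset:] + record.sequence[:offset]
    feats = []
    for f in record.features:
        ivs: list[Interval] = []
        for iv in f.intervals:
            ivs.extend(shift_interval(iv, offset, n))
        feats.append(replace(f, intervals=tuple(ivs)))
    return PlastomeRecord(record.id, seq, feats)


def flip_record(record: PlastomeRecord) -> PlastomeRecord:
    """Reverse-complement the record; intervals are remapped, strands swap."""
    n = record.length
    seq = revcomp(record.sequence)
    feats = []
    for f in record.features:
        ivs = tuple(sorted((Interval(n - iv.end, n - iv.start)
                            for iv in f.intervals), key=lambda v: v.start))
        strand = "-" if f.strand == "+" else "+"
        feats.append(replace(f, intervals=ivs, strand=strand))
    return PlastomeRecord(record.id, seq, feats)


def sorted_features(features: Iterable[GeneFeature]) -> list[GeneFeature]:
    return sorted(features, key=lambda f: (f.start, f.end, f.name))


def gc_percent(seq: str) -> float:
    """GC% over unambiguous bases only; ambiguity codes are excluded."""
    g = seq.count("G")
    c = seq.count("C")
    a = seq.count("A")
    t = seq.count("T")
    denom = a + c + g + t
    if denom == 0:
        from .errors import EmptyRegion
        raise EmptyRegion("no unambiguous bases in region")
    return 100.0 * (g + c) / denom
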