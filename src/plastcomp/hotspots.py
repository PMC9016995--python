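"""Mutational-hotspot screening of non-coding plastome loci.

For every intergenic spacer and intron, aligned across taxa, the sequence
variability statistic is

    SV = 100 x (SNPs + InDel events) / (SNPs + InDel events + conserved sites)

where a conserved site is a gap-free column with a single residue state, a
SNP is a gap-free column with two or more states, and an InDel event is a
maximal run of columns in which the same non-empty subset of rows is gapped
(DnaSP-style event counting). Columns inside InDel runs contribute to
neither SNPs nor conserved sites. Loci with fewer than 100 conserved sites
are removed before ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import PlastomeRecord, sorted_features
from .errors import EmptyAfterTrim, UndefinedSV

DEFAULT_MIN_CONSERVED = 100


@dataclass(frozen=True)
class NoncodingLocus:
    """A named non-coding locus: spacer ("geneA-geneB") or intron
    ("geneX-intron"), optionally aligned (equal-length gapped rows)."""

    name: str
    taxa: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self):
        if len(self.taxa) != len(self.seqs):
            raise ValueError("taxa/seqs length mismatch")


@dataclass(frozen=True)
class LocusVariability:
    name: str
    snps: int
    indels: int
    conserved: int

    @property
    def sv_percent(self) -> float:
        return sequence_variability((self.snps, self.indels, self.conserved))


def noncoding_spans(genome: PlastomeRecord) -> tuple[list[tuple[str, int, int]], list[str]]:
    """Coordinates of every intergenic spacer and intron in genome order.

    Returns ``(spans, skipped)``: each span is ``(name, start, end)``; the
    wrap-around spacer between the last and first gene is encoded with
    ``end > genome.length``. Spacers flanked by overlapping genes are
    undefined and reported in ``skipped``.
    """
    feats = sorted_features(genome.features)
    spans: list[tuple[str, int, int]] = []
    skipped: list[str] = []
    # introns: gaps between consecutive intervals of a compound gene
    for f in feats:
        ivs = sorted(f.intervals, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start > a.end:
                spans.append((f"{f.name}-intron", a.end, b.start))
    # spacers between consecutive genes (by overall span)
    for f1, f2 in zip(feats, feats[1:]):
        name = f"{f1.name}-{f2.name}"
        if f2.start < f1.end:
            skipped.append(name)
            continue
        if f2.start > f1.end:
            spans.append((name, f1.end, f2.start))
    # wrap-around spacer between the last and first gene
    if len(feats) >= 2:
        last, first = feats[-1], feats[0]
        if last.end + first.start > 0 and last.end <= genome.length:
            spans.append((f"{last.name}-{first.name}", last.end,
                          genome.length + first.start))
    return spans, skipped


def extract_noncoding_loci(genome: PlastomeRecord) -> tuple[list[tuple[str, str]], list[str]]:
    """All intergenic spacers and introns in genome order, as sequences.

    Returns ``(loci, skipped)`` where each locus is ``(name, sequence)``.
    Spacers flanked by overlapping genes are skipped and reported in
    ``skipped``. When ndhF is absent and ycf1/rpl32 become neighbours their
    spacer appears as the single "ycf1-rpl32" fragment, which falls out of
    plain adjacency.
    """
    spans, skipped = noncoding_spans(genome)
    doubled = genome.sequence + genome.sequence
    loci = [(name, doubled[a:b]) for name, a, b in spans if b > a]
    return loci, skipped


def trim_terminal_gaps(alignment: dict[str, str]) -> dict[str, str]:
    """Remove leading/trailing columns that contain any gap."""
    rows = list(alignment.values())
    if len({len(r) for r in rows}) != 1:
        raise ValueError("rows have unequal aligned lengths")
    ncol = len(rows[0])
    first = 0
    while first < ncol and any(r[first] == "-" for r in rows):
        first += 1
    last = ncol
    while last > first and any(r[last - 1] == "-" for r in rows):
        last -= 1
    if last <= first:
        raise EmptyAfterTrim("every column carries a terminal gap")
    return {k: v[first:last] for k, v in alignment.items()}


def count_sites(alignment: dict[str, str], indel_unit: str = "event") -> tuple[int, int, int]:
    """(snps, indels, conserved) for a trimmed alignment of >= 2 rows.

    ``indel_unit='event'`` counts a maximal run of columns gapped in the
    same row subset as one InDel; ``'column'`` counts each gapped column.
    """
    rows = list(alignment.values())
    if len(rows) < 2:
        raise ValueError("need >= 2 rows")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("rows have unequal aligned lengths")
    snps = conserved = indels = 0
    prev_gapset: frozenset[int] | None = None
    for col in range(len(rows[0])):
        column = [r[col] for r in rows]
        gapset = frozenset(i for i, b in enumerate(column) if b == "-")
        if gapset:
            if indel_unit == "column" or gapset != prev_gapset:
                indels += 1
        else:
            states = set(column)
            if len(states) == 1:
                conserved += 1
            else:
                snps += 1
        prev_gapset = gapset or None
    return snps, indels, conserved


def sequence_variability(counts: tuple[int, int, int]) -> float:
    """SV% = 100 x (SNPs + InDels) / (SNPs + InDels + conserved)."""
    snps, indels, conserved = counts
    denom = snps + indels + conserved
    if denom == 0:
        raise UndefinedSV("no informative sites")
    return round(100.0 * (snps + indels) / denom, 4)


def locus_variability(name: str, alignment: dict[str, str],
                      indel_unit: str = "event") -> LocusVariability:
    trimmed = trim_terminal_gaps(alignment)
    snps, indels, conserved = count_sites(trimmed, indel_unit=indel_unit)
    return LocusVariability(name, snps, indels, conserved)


def rank_hotspots(variabilities: list[LocusVariability],
                  min_conserved: int = DEFAULT_MIN_CONSERVED,
                  k: int = 10) -> pd.DataFrame:
    """Filter, sort and flag the top-k mutational hotspots.

    Loci with fewer than ``min_conserved`` conserved sites are dropped
    (kept=False, no rank). Remaining loci are sorted by SV descending, ties
    broken by locus name; the first k are flagged as hotspots.
    """
    rows = []
    for lv in variabilities:
        try:
            sv = lv.sv_percent
        except UndefinedSV:
            sv = float("nan")
        rows.append({"locus": lv.name, "snps": lv.snps, "indels": lv.indels,
                     "conserved": lv.conserved, "sv_percent": sv,
                     "kept": lv.conserved >= min_conserved})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(rank=pd.Series(dtype="Int64"), hotspot=pd.Series(dtype=bool))
    kept = df[df.kept].sort_values(["sv_percent", "locus"],
                                   ascending=[False, True], kind="mergesort")
    df["rank"] = pd.Series(dtype="Int64")
    df.loc[kept.index, "rank"] = range(1, len(kept) + 1)
    df["hotspot"] = df["rank"].notna() & (df["rank"] <= k)
    return df.sort_values(["kept", "rank"], ascending=[False, True]).reset_index(drop=True)


def shared_hotspots(rank_a: pd.DataFrame, rank_b: pd.DataFrame, k: int = 10) -> list[str]:
    """Loci flagged in the top-k of both clade rankings, sorted by name."""
    a = set(rank_a[rank_a.hotspot].locus)
    b = set(rank_b[rank_b.hotspot].locus)
    return sorted(a & b)
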