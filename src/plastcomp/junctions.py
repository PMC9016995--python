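"""IR/SC junction profiling and J_SB expansion-contraction typing.

The four junctions of a canonical plastome are J_LB (LSC|IRb), J_SB
(IRb|SSC), J_SA (SSC|IRa) and J_LA (IRa|LSC, at the origin). A gene that
spans a junction into an IR copy leaves a pseudogene fragment of the same
length at the opposite IR copy; fragment lengths are measured from the
annotation and partition geometry. J_SB falls into three types:

* A - long psi-ycf1 fragment together with a psi-ndhF,
* B - short psi-ycf1 fragment together with a psi-ndhF,
* C - no psi-ndhF.

The observed psi-ycf1 ranges (796-1434 bp for A, 156-360 bp for B) leave
361-795 bp unassigned; the midpoint 578 bp is the default A/B threshold and
is exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import GeneFeature, PlastomeRecord
from .errors import MissingAnchorGene
from .structure import QuadripartitePartition

JUNCTIONS = ("J_LB", "J_SB", "J_SA", "J_LA")
ANCHOR_GENES = ("ycf1", "rpl22", "ndhF", "psbA")

#: midpoint between the longest type-B (360) and shortest type-A (796) fragment
DEFAULT_AB_THRESHOLD = 578


@dataclass
class JunctionProfile:
    genome_id: str
    #: per junction: (gene name or None, signed bases). Positive values are
    #: bases the gene extends past the junction into the downstream region;
    #: negative values are the distance from the nearest gene to the junction.
    junction_genes: dict[str, tuple[str | None, int]] = field(default_factory=dict)
    psi_ycf1_len: int = 0
    psi_rpl22_len: int = 0
    psi_ndhF_present: bool = False
    psi_ndhF_len: int = 0
    ndhF_distance: int | None = None


@dataclass(frozen=True)
class JsbType:
    label: str  # A | B | C


def _circ_dist(a: int, b: int, n: int) -> int:
    d = abs(a - b)
    return min(d, n - d)


def _gene_at_junction(features: list[GeneFeature], pos: int, n: int,
                      window: int) -> tuple[str | None, int]:
    """Spanning gene (largest overlap past the junction) or nearest in window."""
    best_span: tuple[int, str] | None = None
    for f in features:
        for iv in f.intervals:
            if iv.start < pos < iv.end:
                over = iv.end - pos  # bases past the junction, downstream
                if best_span is None or over > best_span[0]:
                    best_span = (over, f.name)
    if best_span:
        return best_span[1], best_span[0]
    best_near: tuple[int, str] | None = None
    for f in features:
        for iv in f.intervals:
            d = min(_circ_dist(iv.start, pos, n), _circ_dist(iv.end, pos, n))
            if d <= window and (best_near is None or d < best_near[0]):
                best_near = (d, f.name)
    if best_near:
        return best_near[1], -best_near[0]
    return None, 0


def profile_junctions(genome: PlastomeRecord, partition: QuadripartitePartition,
                      window: int = 1000) -> JunctionProfile:
    """Measure junction-flanking genes and pseudogene fragment lengths.

    The genome must be on the partition's canonical rotation. Raises
    :class:`MissingAnchorGene` when none of ycf1/rpl22/ndhF/psbA is
    annotated.
    """
    feats = genome.features
    names = {f.name for f in feats}
    if not names & set(ANCHOR_GENES):
        raise MissingAnchorGene(f"annotation lacks all of {ANCHOR_GENES}")
    n = partition.length
    positions = {"J_LB": partition.irb.start, "J_SB": partition.ssc.start,
                 "J_SA": partition.ira.start}
    prof = JunctionProfile(genome_id=genome.id)
    for j in ("J_LB", "J_SB", "J_SA"):
        prof.junction_genes[j] = _gene_at_junction(feats, positions[j], n, window)
    prof.junction_genes["J_LA"] = _gene_at_origin(feats, n, window)

    # psi-ycf1: portion of the J_SA-spanning ycf1 copy that lies inside IRa,
    # hence duplicated (reverse-complemented) into IRb next to J_SB.
    for f in genome.feature_by_name("ycf1"):
        for iv in f.intervals:
            if iv.start < partition.ira.start < iv.end:
                prof.psi_ycf1_len = min(iv.end, partition.ira.end) - partition.ira.start
    # psi-rpl22: portion of the J_LB-spanning rpl22 inside IRb, duplicated at J_LA.
    for f in genome.feature_by_name("rpl22"):
        for iv in f.intervals:
            if iv.start < partition.irb.start < iv.end:
                prof.psi_rpl22_len = min(iv.end, partition.irb.end) - partition.irb.start
    # psi-ndhF: IRb has expanded across J_SB into ndhF when ndhF overlaps IRb.
    ndhf = genome.feature_by_name("ndhF")
    if ndhf:
        jsb = partition.ssc.start
        best = 0
        dist = None
        for f in ndhf:
            for iv in f.intervals:
                over = min(iv.end, jsb) - max(iv.start, partition.irb.start)
                if over > 0:
                    best = max(best, over)
                else:
                    d = iv.start - jsb if iv.start >= jsb else jsb - iv.end
                    dist = d if dist is None else min(dist, d)
        prof.psi_ndhF_present = best > 0
        prof.psi_ndhF_len = max(best, 0)
        prof.ndhF_distance = None if best > 0 else dist
    return prof


def _gene_at_origin(features: list[GeneFeature], n: int, window: int):
    """J_LA sits at the origin; nearest gene with circular distance to 0."""
    best_near = None
    for f in features:
        for iv in f.intervals:
            d = min(iv.start % n, (n - iv.end) % n)
            if d <= window and (best_near is None or d < best_near[0]):
                best_near = (d, f.name)
    if best_near:
        return best_near[1], -best_near[0]
    return None, 0


def classify_jsb(profile: JunctionProfile,
                 ab_threshold: int = DEFAULT_AB_THRESHOLD) -> JsbType:
    """Type C without a psi-ndhF; else A when psi-ycf1 >= threshold, else B."""
    if not profile.psi_ndhF_present:
        return JsbType("C")
    return JsbType("A" if profile.psi_ycf1_len >= ab_threshold else "B")


def junction_map_table(profiles: list[JunctionProfile],
                       ab_threshold: int = DEFAULT_AB_THRESHOLD) -> pd.DataFrame:
    """One row per genome: junction genes, fragment lengths and J_SB type."""
    rows = []
    for p in profiles:
        row = {"genome": p.genome_id}
        for j in JUNCTIONS:
            gene, dist = p.junction_genes.get(j, (None, 0))
            row[f"{j}_gene"] = gene
            row[f"{j}_offset"] = dist
        row.update({
            "psi_ycf1_len": p.psi_ycf1_len,
            "psi_rpl22_len": p.psi_rpl22_len,
            "psi_ndhF_present": p.psi_ndhF_present,
            "psi_ndhF_len": p.psi_ndhF_len,
            "ndhF_distance": p.ndhF_distance,
            "jsb_type": classify_jsb(p, ab_threshold).label,
        })
        rows.append(row)
    cols = (["genome"] + [f"{j}_{k}" for j in JUNCTIONS for k in ("gene", "offset")]
            + ["psi_ycf1_len", "psi_rpl22_len", "psi_ndhF_present", "psi_ndhF_len",
               "ndhF_distance", "jsb_type"])
    return pd.DataFrame(rows, columns=cols)


def jsb_type_counts(table: pd.DataFrame,
                    clade_labels: dict[str, str] | None = None) -> dict:
    """Overall and optional per-clade counts of J_SB types A/B/C."""
    out: dict = {"all": table.jsb_type.value_counts().to_dict()}
    if clade_labels:
        for clade in sorted(set(clade_labels.values())):
            members = [g for g, c in clade_labels.items() if c == clade]
            sub = table[table.genome.isin(members)]
            out[clade] = sub.jsb_type.value_counts().to_dict()
    return out
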