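"""Synthetic plastome generator with clade-structured evolution.

Builds a toy circular plastome with the canonical quadripartite layout
(LSC + IRb + SSC + IRa, IRa the exact reverse complement of IRb), a ~12
gene annotation including the three junction-diagnostic genes (rpl22
spanning J_LB, ndhF at/near J_SB, ycf1 spanning J_SA), planted SSRs and
dispersed repeats, and then evolves it along a time-calibrated tree with
per-branch Poisson substitution and InDel processes plus a codon-level
process with per-gene selection intensity (omega).

The generator defines the study conditions for the whole package; every
planted element and every evolutionary event is logged in a TruthTable so
downstream detectors can be scored against exact ground truth:

* IR substitutions are applied symmetrically to both copies (gene
  conversion keeps real plastome IRs near-identical), so the IR pair stays
  an exact reverse-complement pair in every descendant.
* InDels are restricted to single-copy non-coding zones, which keeps gene
  coordinates liftable and the quadripartite truth well defined per leaf.
* The two bases flanking each IR boundary are held fixed so that the
  maximal inverted repeat remains exactly the planted one.

Replaying a leaf's logged events from the ancestor reproduces its sequence
byte for byte.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .core import (GeneFeature, Interval, PlastomeRecord, complement, revcomp)
from .errors import ExtinctSequence, LayoutConflict
from .indels import Chronogram
from .repeats import DispersedRepeat, SSRLocus
from .structure import QuadripartitePartition

#: two clades of three leaves, stems of 8 myr, whole-tree stem of 6 myr
DEFAULT_TREE = ("((AN1:4,(AN2:2,AN3:2)AN23:2)AN:8,"
                "(SA1:4,(SA2:2,SA3:2)SA23:2)SA:8)root:6;")

#: scenario -> default ycf1 overlap into IRa (bp); observed psi-ycf1
#: fragments span 796-1434 bp for type A and 156-360 bp for type B
SCENARIO_YCF1_OVERLAP = {"A": 1000, "B": 250, "C": 500}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated panel.

    Rates are per site per myr. Region multipliers reflect the observed
    variability ordering SSC > LSC >> IR; the IR InDel multiplier is zero
    because plastome IRs are homogenised by copy correction.
    """

    lsc_len: int = 8000
    ir_len: int = 2500
    ssc_len: int = 1500
    jsb_scenario: str = "A"  # A | B | C
    ycf1_overlap: int | None = None  # default per scenario
    rpl22_overlap: int = 62
    ndhf_overlap: int = 60  # bp of ndhF inside IRb (scenarios A/B)
    ndhf_distance: int = 200  # bp from J_SB (scenario C)
    ndhf_absent: bool = False
    tree_newick: str = DEFAULT_TREE
    subst_rate: float = 2e-3
    indel_rate: float = 2e-4
    indel_len_geom_p: float = 0.25
    ins_fraction: float = 0.5
    region_rate_multipliers: dict = field(default_factory=lambda: {
        "LSC": 1.0, "SSC": 3.0, "IR": 0.3})
    indel_region_multipliers: dict = field(default_factory=lambda: {
        "LSC": 1.0, "SSC": 3.0, "IR": 0.0})
    branch_indel_multipliers: dict = field(default_factory=dict)
    codon_subst_rate: float = 1.5e-3
    gene_omega: dict = field(default_factory=lambda: {
        "psbA": 0.2, "atpA": 0.2, "rbcL": 0.2, "matK": 0.3, "psbZ": 0.2})
    seed: int = 0

    def resolved_ycf1_overlap(self) -> int:
        if self.ycf1_overlap is not None:
            return self.ycf1_overlap
        return SCENARIO_YCF1_OVERLAP[self.jsb_scenario]

    def validate(self) -> None:
        if self.jsb_scenario not in "ABC":
            raise LayoutConflict(f"unknown scenario {self.jsb_scenario!r}")
        if not 0 < self.indel_len_geom_p <= 1:
            raise LayoutConflict("indel_len_geom_p must be in (0, 1]")
        ov = self.resolved_ycf1_overlap()
        if ov > self.ir_len - 1400 or self.rpl22_overlap >= 200:
            raise LayoutConflict("junction-gene overlap collides with IR genes")
        if self.lsc_len < 7800 or self.ssc_len < 1400 or self.ir_len < 2000:
            raise LayoutConflict("regions too small for the built-in gene layout")


# ---------------------------------------------------------------------------
# ancestor construction


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(rng.choice(list("ACGT"), size=n))


def _random_cds(rng: np.random.Generator, n_codons: int, table_id: int = 1) -> str:
    """In-frame CDS without internal stops (start/stop codons not modelled)."""
    from .selection import _code
    _, stops = _code(table_id)
    out = []
    while len(out) < n_codons:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in stops:
            out.append(c)
    return "".join(out)


@dataclass
class AncestorTruth:
    record: PlastomeRecord
    partition: QuadripartitePartition
    planted_ssrs: list[SSRLocus]
    planted_repeats: list[DispersedRepeat]
    #: gene -> (start, end, omega) for genes evolved under the codon process
    cds_genes: dict[str, tuple[int, int, float]]
    #: ancestor positions immune to substitution and deletion (IR-boundary
    #: anchors keeping the planted maximal IR exact)
    anchor_positions: frozenset[int]


def build_ancestor(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> AncestorTruth:
    """Construct the ancestral plastome, annotation and planted truth."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L, R, S = config.lsc_len, config.ir_len, config.ssc_len
    ov = config.resolved_ycf1_overlap()
    lsc = _random_seq(rng, L)
    irb = _random_seq(rng, R)
    ssc = _random_seq(rng, S)

    features: list[GeneFeature] = []
    cds_genes: dict[str, tuple[int, int, float]] = {}

    def place_cds(name: str, start: int, n_codons: int, region: list, offset: int):
        seq = _random_cds(rng, n_codons)
        region[start:start + len(seq)] = list(seq)
        a, b = offset + start, offset + start + len(seq)
        features.append(GeneFeature(name, "CDS", "+", (Interval(a, b),)))
        omega = config.gene_omega.get(name)
        if omega is not None:
            cds_genes[name] = (a, b, float(omega))

    # --- LSC genes (content-bearing CDSs evolved under the codon process)
    place_cds("psbA", 100, 400, lsc, 0)
    place_cds("atpA", 1600, 500, lsc, 0)
    place_cds("rbcL", 3400, 478, lsc, 0)
    place_cds("matK", 5100, 500, lsc, 0)
    place_cds("psbZ", 6800, 63, lsc, 0)
    # rpl22 spans J_LB into IRb; its IRb portion lives in the IR copy
    rpl22_len = 400 + config.rpl22_overlap
    rpl22_len += (-rpl22_len) % 3
    features.append(GeneFeature("rpl22", "CDS", "+",
                                (Interval(L - 400, L - 400 + rpl22_len),)))

    # --- IRb genes
    features.append(GeneFeature("rrn16", "rRNA", "+",
                                (Interval(L + 200, L + 1400),)))
    # psi-ycf1 fragment adjacent to J_SB (sequence arrives via the IR mirror)
    features.append(GeneFeature("ycf1", "CDS", "-",
                                (Interval(L + R - ov, L + R),),
                                frame_offset=(3 - ov % 3) % 3))

    # --- SSC genes
    jsb = L + R
    if not config.ndhf_absent:
        ndhf_len = 702
        if config.jsb_scenario in "AB":
            nd_start = jsb - config.ndhf_overlap
        else:
            nd_start = jsb + config.ndhf_distance
        features.append(GeneFeature("ndhF", "CDS", "-",
                                    (Interval(nd_start, nd_start + ndhf_len),)))
    features.append(GeneFeature("rpl32", "CDS", "-",
                                (Interval(jsb + 950, jsb + 1130),)))
    # ycf1 spans J_SA into IRa
    tail = 300 + (-(300 + ov)) % 3
    jsa = L + R + S
    features.append(GeneFeature("ycf1", "CDS", "-",
                                (Interval(jsa - tail, jsa + ov),)))

    # --- planted SSRs and dispersed repeats (coordinates are absolute)
    ssr_specs = [(3150, "A", 9), (3250, "AT", 6), (jsb + 910, "AAT", 5)]
    repeat_specs = [("forward", 4850, 6620, 35), ("palindromic", 7050, 7200, 35)]
    planted_ssrs = []
    planted_repeats = []

    def write(pos: int, bases: str):
        for i, b in enumerate(bases):
            p = pos + i
            if p < L:
                lsc[p] = b
            elif p < L + R:
                irb[p - L] = b
            else:
                ssc[p - L - R] = b

    def read(pos: int) -> str:
        if pos < L:
            return lsc[pos]
        if pos < L + R:
            return irb[pos - L]
        return ssc[pos - L - R]

    for pos, motif, copies in ssr_specs:
        u = len(motif)
        write(pos, motif * copies)
        # break maximality on both flanks
        if read(pos - 1) == motif[-1]:
            write(pos - 1, _other_base(rng, motif[-1]))
        end = pos + u * copies
        if read(end) == read(end - u):
            write(end, _other_base(rng, read(end - u)))
        planted_ssrs.append(SSRLocus(pos, motif, u, copies, u * copies))

    for rtype, p1, p2, rlen in repeat_specs:
        unit = "".join(_random_seq(rng, rlen))
        write(p1, unit)
        write(p2, unit if rtype == "forward" else revcomp(unit))
        if rtype == "forward":
            if read(p1 - 1) == read(p2 - 1):
                write(p1 - 1, _other_base(rng, read(p2 - 1)))
            if read(p1 + rlen) == read(p2 + rlen):
                write(p1 + rlen, _other_base(rng, read(p2 + rlen)))
        else:  # palindromic: extension pairs p1-1 with p2+rlen, p1+rlen with p2-1
            if read(p1 - 1) == complement(read(p2 + rlen)):
                write(p1 - 1, _other_base(rng, complement(read(p2 + rlen))))
            if read(p1 + rlen) == complement(read(p2 - 1)):
                write(p1 + rlen, _other_base(rng, complement(read(p2 - 1))))
        planted_repeats.append(DispersedRepeat(rtype, p1, p2, rlen, 0))

    _check_layout(features, planted_ssrs, planted_repeats, L, R, S)

    # --- assemble: IRa is the exact reverse complement of IRb
    n = L + 2 * R + S
    # IR-boundary anchors: the base on each single-copy side of each IR end
    # must not complement-pair with its circular partner, otherwise the
    # maximal inverted repeat would extend past the planted boundary.
    if lsc[-1] == complement(lsc[0]):
        lsc[-1] = _other_base(rng, complement(lsc[0]))
    if ssc[0] == complement(ssc[-1]):
        ssc[0] = _other_base(rng, complement(ssc[-1]))
    sequence = "".join(lsc) + "".join(irb) + "".join(ssc) + revcomp("".join(irb))
    anchors = frozenset({L - 1, 0, L + R, L + R + S - 1})

    partition = QuadripartitePartition(
        lsc=Interval(0, L), irb=Interval(L, L + R),
        ssc=Interval(L + R, L + R + S), ira=Interval(L + R + S, n),
        mismatches=0)
    partition.validate()
    # the IR pair itself is the largest planted (palindromic) repeat
    planted_repeats.append(DispersedRepeat("palindromic", L, L + R + S, R, 0))
    record = PlastomeRecord("ancestor", sequence, features)
    return AncestorTruth(record, partition, planted_ssrs, planted_repeats,
                         cds_genes, anchors)


def _other_base(rng: np.random.Generator, base: str) -> str:
    return str(rng.choice([b for b in "ACGT" if b != base]))


def _check_layout(features, ssrs, repeats, L, R, S):
    """Planted SSRs/repeats must not collide with genes or each other."""
    gene_ivs = [(iv.start, iv.end) for f in features for iv in f.intervals]
    plant_ivs = []
    for s in ssrs:
        plant_ivs.append((s.start, s.start + s.span))
    for r in repeats:
        plant_ivs.append((r.pos1, r.pos1 + r.rlen))
        plant_ivs.append((r.pos2, r.pos2 + r.rlen))
    for i, (a1, b1) in enumerate(plant_ivs):
        for a2, b2 in gene_ivs:
            if min(b1, b2) > max(a1, a2):
                raise LayoutConflict(f"planted element [{a1},{b1}) overlaps a gene")
        for a2, b2 in plant_ivs[i + 1:]:
            if min(b1, b2) > max(a1, a2):
                raise LayoutConflict(f"planted elements [{a1},{b1}) and "
                                     f"[{a2},{b2}) overlap")
    if any(b > L + 2 * R + S for _, b in plant_ivs):
        raise LayoutConflict("planted element outside genome")


# ---------------------------------------------------------------------------
# evolution along the chronogram


class _Entry:
    """One base of a lineage: unique id, ancestor anchor (None for inserted
    bases), current base, region tag and InDel eligibility."""

    __slots__ = ("eid", "anc", "base", "region", "sub_ok", "indel_ok")

    def __init__(self, eid, anc, base, region, sub_ok, indel_ok):
        self.eid = eid
        self.anc = anc
        self.base = base
        self.region = region
        self.sub_ok = sub_ok
        self.indel_ok = indel_ok

    def clone(self) -> "_Entry":
        return _Entry(self.eid, self.anc, self.base, self.region,
                      self.sub_ok, self.indel_ok)


@dataclass
class TruthTable:
    """Everything the generator did: ancestor, planted elements, per-branch
    event logs and the final per-leaf states."""

    config: SimulationConfig
    ancestor: AncestorTruth
    chronogram: Chronogram
    branch_logs: dict[str, list[dict]]
    leaf_entries: dict[str, list[_Entry]]

    # -- leaf views -------------------------------------------------------

    def leaf_sequence(self, leaf: str) -> str:
        return "".join(e.base for e in self.leaf_entries[leaf])

    def leaf_record(self, leaf: str) -> PlastomeRecord:
        entries = self.leaf_entries[leaf]
        anc_to_leaf = {e.anc: i for i, e in enumerate(entries) if e.anc is not None}
        feats = []
        for f in self.ancestor.record.features:
            ivs = tuple(Interval(anc_to_leaf[iv.start], anc_to_leaf[iv.end - 1] + 1)
                        for iv in f.intervals)
            feats.append(GeneFeature(f.name, f.kind, f.strand, ivs, f.frame_offset))
        return PlastomeRecord(leaf, self.leaf_sequence(leaf), feats)

    def leaf_partition(self, leaf: str) -> QuadripartitePartition:
        counts = {"LSC": 0, "IRb": 0, "SSC": 0, "IRa": 0}
        for e in self.leaf_entries[leaf]:
            counts[e.region] += 1
        l, r1 = counts["LSC"], counts["IRb"]
        s, r2 = counts["SSC"], counts["IRa"]
        part = QuadripartitePartition(
            lsc=Interval(0, l), irb=Interval(l, l + r1),
            ssc=Interval(l + r1, l + r1 + s),
            ira=Interval(l + r1 + s, l + r1 + s + r2), mismatches=0)
        part.validate()
        return part

    def pairwise_alignment(self, leaf: str) -> tuple[str, str]:
        """(reference row, leaf row) of the ancestor-vs-leaf alignment."""
        anc_seq = self.ancestor.record.sequence
        ref, smp = [], []
        nxt = 0
        for e in self.leaf_entries[leaf]:
            if e.anc is None:
                ref.append("-")
                smp.append(e.base)
            else:
                while nxt < e.anc:  # deleted ancestor bases
                    ref.append(anc_seq[nxt])
                    smp.append("-")
                    nxt += 1
                ref.append(anc_seq[e.anc])
                smp.append(e.base)
                nxt = e.anc + 1
        while nxt < len(anc_seq):
            ref.append(anc_seq[nxt])
            smp.append("-")
            nxt += 1
        return "".join(ref), "".join(smp)

    def leaf_cds(self, leaf: str, gene: str) -> str:
        start, end, _ = self.ancestor.cds_genes[gene]
        entries = self.leaf_entries[leaf]
        anc_to_leaf = {e.anc: e.base for e in entries if e.anc is not None}
        return "".join(anc_to_leaf[p] for p in range(start, end))

    def induced_msa(self, span: tuple[int, int] | None = None,
                    include_reference: bool = False) -> dict[str, str]:
        """Exact multiple alignment induced by shared event history.

        Columns are ancestor positions plus insertion columns keyed by the
        inserted entries' ids, so an insertion inherited from an internal
        branch occupies the same columns in every descendant. Insertions
        anchored before the span's first position are excluded.
        """
        a, b = span if span else (0, self.ancestor.record.length)
        leaves = sorted(self.leaf_entries)
        per_leaf: dict[str, dict] = {}
        for leaf in leaves:
            anchored: dict[int, str] = {}
            ins_after: dict[int, list[tuple[int, str]]] = {}
            last_anc = -1
            for e in self.leaf_entries[leaf]:
                if e.anc is None:
                    ins_after.setdefault(last_anc, []).append((e.eid, e.base))
                else:
                    anchored[e.anc] = e.base
                    last_anc = e.anc
            per_leaf[leaf] = {"anchored": anchored, "ins": ins_after}
        rows = {leaf: [] for leaf in leaves}
        ref_row: list[str] = []
        anc_seq = self.ancestor.record.sequence
        for p in range(a, b):
            for leaf in leaves:
                rows[leaf].append(per_leaf[leaf]["anchored"].get(p, "-"))
            ref_row.append(anc_seq[p])
            # merged insertion columns at this anchor, ordered by first use
            col_ids: list[int] = []
            seen = set()
            for leaf in leaves:
                for eid, _ in per_leaf[leaf]["ins"].get(p, []):
                    if eid not in seen:
                        seen.add(eid)
                        col_ids.append(eid)
            for eid in col_ids:
                for leaf in leaves:
                    here = dict(per_leaf[leaf]["ins"].get(p, []))
                    rows[leaf].append(here.get(eid, "-"))
                ref_row.append("-")
        out = {leaf: "".join(chars) for leaf, chars in rows.items()}
        if include_reference:
            out = {"ancestor": "".join(ref_row), **out}
        return out

    # -- branch-level truth ----------------------------------------------

    def branch_indel_bp(self) -> dict[str, tuple[int, int]]:
        """Branch id -> (inserted bp, deleted bp) actually generated."""
        out = {}
        for branch, ops in self.branch_logs.items():
            ins = sum(len(op["entries"]) for op in ops if op["op"] == "ins")
            dele = sum(len(op["eids"]) for op in ops if op["op"] == "del")
            out[branch] = (ins, dele)
        return out

    def replay_leaf(self, leaf: str) -> str:
        """Re-apply the logged events from the ancestor; must equal the leaf."""
        node = self.chronogram.node_by_id(leaf)
        path = []
        while node is not None:
            if node.edge.length is not None:
                path.append(node.pc_id)
            node = node.parent_node
        entries = [e.clone() for e in _ancestor_entries(self.config, self.ancestor)]
        for branch in reversed(path):
            index = {e.eid: i for i, e in enumerate(entries)}
            for op in self.branch_logs.get(branch, []):
                if op["op"] == "sub":
                    entries[index[op["eid"]]].base = op["base"]
                elif op["op"] == "ins":
                    at = index[op["after"]]
                    tmpl = entries[at]
                    new = [_Entry(eid, None, b, tmpl.region, True, True)
                           for eid, b in op["entries"]]
                    entries[at + 1:at + 1] = new
                    index = {e.eid: i for i, e in enumerate(entries)}
                elif op["op"] == "del":
                    doomed = set(op["eids"])
                    entries = [e for e in entries if e.eid not in doomed]
                    index = {e.eid: i for i, e in enumerate(entries)}
        return "".join(e.base for e in entries)


def _ancestor_entries(config: SimulationConfig, anc: AncestorTruth) -> list[_Entry]:
    part = anc.partition
    seq = anc.record.sequence
    gene_pos = set()
    for f in anc.record.features:
        for iv in f.intervals:
            gene_pos.update(range(iv.start, iv.end))
    plant_pos = set()
    for s in anc.planted_ssrs:
        plant_pos.update(range(s.start, s.start + s.span))
    for r in anc.planted_repeats:
        plant_pos.update(range(r.pos1, r.pos1 + r.rlen))
        plant_pos.update(range(r.pos2, r.pos2 + r.rlen))
    cds_pos = set()
    for (a, b, _w) in anc.cds_genes.values():
        cds_pos.update(range(a, b))
    entries = []
    for p in range(len(seq)):
        region = part.region_of(p)
        in_ir = region in ("IRb", "IRa")
        sub_ok = (p not in anc.anchor_positions and p not in cds_pos
                  and region != "IRa")
        indel_ok = (not in_ir and p not in gene_pos and p not in plant_pos
                    and p not in anc.anchor_positions)
        entries.append(_Entry(p, p, seq[p], region, sub_ok, indel_ok))
    return entries


def evolve_along_tree(ancestor: AncestorTruth, config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> TruthTable:
    """Evolve the ancestor along the chronogram, logging every event."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    tree = Chronogram.from_newick(config.tree_newick)
    part = ancestor.partition
    L, R = part.lsc.length, part.irb.length
    S = part.ssc.length
    irb_span = (L, L + R)
    ira_start = L + R + S
    next_eid = [len(ancestor.record.sequence)]
    branch_logs: dict[str, list[dict]] = {}
    leaf_entries: dict[str, list[_Entry]] = {}

    from .selection import _code
    fwd_code, stops = _code(1)

    def mirror_anc(p: int) -> int:
        # IRa[t] = comp(IRb[R-1-t]); ancestor coordinates are stable in IRs
        return ira_start + (R - 1 - (p - L))

    def evolve_branch(entries: list[_Entry], branch: str, dur: float):
        log: list[dict] = []
        anc_index = {e.anc: i for i, e in enumerate(entries) if e.anc is not None}

        # 1. neutral substitutions, region-weighted; IR hits are mirrored
        pools: dict[str, list[int]] = {"LSC": [], "SSC": [], "IR": []}
        for i, e in enumerate(entries):
            if e.sub_ok:
                pools["IR" if e.region in ("IRb", "IRa") else e.region].append(i)
        for region, pool in pools.items():
            mult = config.region_rate_multipliers.get(region, 1.0)
            lam = config.subst_rate * mult * dur * len(pool)
            for _ in range(rng.poisson(lam)):
                i = pool[int(rng.integers(len(pool)))]
                e = entries[i]
                new = _other_base(rng, e.base)
                e.base = new
                log.append({"op": "sub", "eid": e.eid, "base": new})
                if e.anc is not None and irb_span[0] <= e.anc < irb_span[1]:
                    j = anc_index[mirror_anc(e.anc)]
                    entries[j].base = complement(new)
                    log.append({"op": "sub", "eid": entries[j].eid,
                                "base": entries[j].base})

        # 2. codon process inside omega genes
        for gene, (ga, gb, omega) in ancestor.cds_genes.items():
            lam = config.codon_subst_rate * dur * (gb - ga)
            for _ in range(rng.poisson(lam)):
                pos = ga + int(rng.integers(gb - ga))
                off = (pos - ga) % 3
                cstart = pos - off
                idxs = [anc_index[cstart + k] for k in range(3)]
                codon = "".join(entries[i].base for i in idxs)
                new_base = _other_base(rng, codon[off])
                new_codon = codon[:off] + new_base + codon[off + 1:]
                if new_codon in stops:
                    continue
                syn = fwd_code[new_codon] == fwd_code[codon]
                accept = 1.0 if syn else min(omega, 1.0)
                if omega > 1.0:
                    accept = (1.0 / omega) if syn else 1.0
                if rng.random() >= accept:
                    continue
                e = entries[idxs[off]]
                e.base = new_base
                log.append({"op": "sub", "eid": e.eid, "base": new_base})

        # 3. InDels in single-copy non-coding zones
        bmult = config.branch_indel_multipliers.get(branch, 1.0)
        pools = {"LSC": [], "SSC": [], "IR": []}
        for i, e in enumerate(entries):
            if e.indel_ok:
                pools["IR" if e.region in ("IRb", "IRa") else e.region].append(i)
        dirty = False
        for region in ("LSC", "SSC", "IR"):
            mult = config.indel_region_multipliers.get(region, 0.0) * bmult
            lam = config.indel_rate * mult * dur * len(pools[region])
            for _ in range(rng.poisson(lam)):
                if dirty:  # indices shifted by a previous event
                    pools2 = [i for i, e in enumerate(entries)
                              if e.indel_ok and
                              ("IR" if e.region in ("IRb", "IRa") else e.region) == region]
                else:
                    pools2 = pools[region]
                if not pools2:
                    raise ExtinctSequence(f"region {region} exhausted")
                i = pools2[int(rng.integers(len(pools2)))]
                length = int(rng.geometric(config.indel_len_geom_p))
                if rng.random() < config.ins_fraction:
                    tmpl = entries[i]
                    new = []
                    for b in rng.choice(list("ACGT"), size=length):
                        next_eid[0] += 1
                        new.append(_Entry(next_eid[0], None, str(b),
                                          tmpl.region, True, True))
                    entries[i + 1:i + 1] = new
                    log.append({"op": "ins", "after": tmpl.eid,
                                "entries": [(e.eid, e.base) for e in new]})
                else:
                    j = i
                    doomed = []
                    while (j < len(entries) and len(doomed) < length
                           and entries[j].indel_ok and entries[j].region
                           == entries[i].region):
                        doomed.append(entries[j])
                        j += 1
                    remaining = sum(1 for e in entries
                                    if e.region == entries[i].region) - len(doomed)
                    if remaining <= 0:
                        raise ExtinctSequence(f"region {entries[i].region} exhausted")
                    ids = {e.eid for e in doomed}
                    entries[:] = [e for e in entries if e.eid not in ids]
                    log.append({"op": "del", "eids": [e.eid for e in doomed]})
                dirty = True
        branch_logs[branch] = log

    def recurse(node, entries):
        if node.edge.length is not None:
            evolve_branch(entries, node.pc_id, float(node.edge.length))
        if node.is_leaf():
            leaf_entries[node.pc_id] = entries
            return
        children = node.child_nodes()
        for k, child in enumerate(children):
            child_entries = entries if k == len(children) - 1 \
                else [e.clone() for e in entries]
            recurse(child, child_entries)

    root_entries = [e.clone() for e in _ancestor_entries(config, ancestor)]
    recurse(tree.tree.seed_node, root_entries)
    return TruthTable(config, ancestor, tree, branch_logs, leaf_entries)


def simulate(config: SimulationConfig) -> TruthTable:
    """Build the ancestor and evolve it: one shared RNG stream, seeded once.

    Draw order is documented and fixed: ancestor construction first, then a
    preorder traversal of the chronogram with substitutions, codon events
    and InDels in that order per branch.
    """
    rng = np.random.default_rng(config.seed)
    anc = build_ancestor(config, rng)
    return evolve_along_tree(anc, config, rng)


def build_panel(n_a: int, n_b: int, n_c: int, seed: int = 0,
                base_config: SimulationConfig | None = None
                ) -> list[tuple[str, AncestorTruth]]:
    """Independent genomes with planted J_SB scenarios A/B/C, in that order.

    Mirrors a mixed panel of junction types; each genome gets a sub-seed
    derived from ``seed``.
    """
    out = []
    idx = 0
    for scenario, count in (("A", n_a), ("B", n_b), ("C", n_c)):
        for _ in range(count):
            cfg = copy.deepcopy(base_config) if base_config else SimulationConfig()
            cfg.jsb_scenario = scenario
            cfg.ycf1_overlap = None
            cfg.seed = (seed * 1009 + idx * 7919) % (2 ** 31)
            rng = np.random.default_rng(cfg.seed)
            anc = build_ancestor(cfg, rng)
            anc.record.id = f"g{idx:02d}_{scenario}"
            out.append((scenario, anc))
            idx += 1
    return out
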