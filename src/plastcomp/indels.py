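"""Reference-anchored InDel calling and occurrence-rate dating.

InDels are called per taxon against a reference from pairwise (or
reference-anchored multiple) alignments, merged across taxa when their
(reference position, type, length) coincide, placed on the branches of a
time-calibrated tree, and converted into occurrence rates in bp/myr.

Branch placement: an event whose carrier set is exactly the leaf set of a
clade goes on that clade's stem branch. Otherwise presence/absence is
reconstructed by Fitch parsimony (absence preferred at an ambiguous root,
i.e. the reference state is ancestral) and the event is assigned to the
gain branches; multi-gain events are flagged homoplastic and their length
is split evenly across the gains, which conserves total event length.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import dendropy
import pandas as pd

from .errors import DoubleGapColumn, UnknownTaxon, ZeroDuration
from .structure import QuadripartitePartition
from .repeats import RegionDensity


@dataclass(frozen=True)
class IndelEvent:
    ref_pos: int  # 0-based reference coordinate of the event start
    etype: str  # insertion | deletion
    length: int
    carriers: frozenset[str] = frozenset()

    def key(self) -> tuple[int, str, int]:
        return (self.ref_pos, self.etype, self.length)


def call_indels(ref_row: str, sample_row: str, taxon: str | None = None) -> list[IndelEvent]:
    """Maximal gap runs of a two-row alignment, anchored on the reference.

    A gap run in the reference row is an insertion in the sample; a gap run
    in the sample row is a deletion. ``ref_pos`` counts reference bases
    before the event. Columns gapped in both rows raise
    :class:`DoubleGapColumn`.
    """
    if len(ref_row) != len(sample_row):
        raise ValueError("alignment rows differ in length")
    carriers = frozenset([taxon]) if taxon else frozenset()
    events = []
    ref_pos = 0
    run_type: str | None = None
    run_len = 0
    run_start = 0
    for col, (r, s) in enumerate(zip(ref_row, sample_row)):
        if r == "-" and s == "-":
            raise DoubleGapColumn(f"column {col} gapped in both rows")
        state = "insertion" if r == "-" else ("deletion" if s == "-" else None)
        if state != run_type:
            if run_type is not None:
                events.append(IndelEvent(run_start, run_type, run_len, carriers))
            run_type = state
            run_len = 0
            run_start = ref_pos
        if state is not None:
            run_len += 1
        if r != "-":
            ref_pos += 1
    if run_type is not None:
        events.append(IndelEvent(run_start, run_type, run_len, carriers))
    return events


def merge_events(per_taxon: dict[str, list[IndelEvent]], slop: int = 0) -> list[IndelEvent]:
    """Merge per-taxon events sharing (ref_pos, type, length) into one event.

    ``slop`` allows reference positions to differ by up to that many bases
    (alignment jitter); clustering is greedy on sorted positions.
    """
    buckets: dict[tuple[str, int], list[tuple[int, str]]] = defaultdict(list)
    for taxon, events in per_taxon.items():
        for ev in events:
            buckets[(ev.etype, ev.length)].append((ev.ref_pos, taxon))
    merged: list[IndelEvent] = []
    for (etype, length), entries in sorted(buckets.items()):
        entries.sort()
        cluster_pos: int | None = None
        carriers: set[str] = set()
        for pos, taxon in entries:
            if cluster_pos is None or pos - cluster_pos > slop:
                if cluster_pos is not None:
                    merged.append(IndelEvent(cluster_pos, etype, length,
                                             frozenset(carriers)))
                cluster_pos = pos
                carriers = set()
            carriers.add(taxon)
        if cluster_pos is not None:
            merged.append(IndelEvent(cluster_pos, etype, length, frozenset(carriers)))
    return sorted(merged, key=lambda e: (e.ref_pos, e.etype, e.length))


def indel_region_density(events: list[IndelEvent],
                         partition: QuadripartitePartition) -> dict[str, list[RegionDensity]]:
    """Event bp per region and kbp, separately for insertions and deletions.

    Insertions have no reference extent; their full length is attributed to
    the region of the insertion point. Deletions spanning a junction are
    pro-rated base-by-base. IRb and IRa are pooled.
    """
    region_ivs = {
        "LSC": [partition.lsc.as_tuple()],
        "IR": [partition.irb.as_tuple(), partition.ira.as_tuple()],
        "SSC": [partition.ssc.as_tuple()],
    }
    out: dict[str, list[RegionDensity]] = {}
    for etype in ("insertion", "deletion"):
        bases = {name: 0.0 for name in region_ivs}
        for ev in events:
            if ev.etype != etype:
                continue
            if etype == "insertion":
                bases[partition.region_of(min(ev.ref_pos, partition.length - 1))
                      .replace("IRb", "IR").replace("IRa", "IR")] += ev.length
            else:
                a, b = ev.ref_pos, ev.ref_pos + ev.length
                for name, ivs in region_ivs.items():
                    for ra, rb in ivs:
                        bases[name] += max(0, min(b, rb) - max(a, ra))
        out[etype] = [RegionDensity(name, bases[name] / (sum(b - a for a, b in ivs) / 1000.0))
                      for name, ivs in region_ivs.items()]
    return out


# ---------------------------------------------------------------------------
# chronogram


class Chronogram:
    """A rooted ultrametric tree with branch durations in myr.

    Wraps a dendropy tree; every node gets a stable id (leaf label for
    leaves, ``N<i>`` in preorder for internal nodes) and an age (leaves at
    0). The root's own edge length, when present in the Newick, is kept as
    the stem duration of the whole tree.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._label_nodes()
        self._compute_ages()

    @classmethod
    def from_newick(cls, newick: str) -> "Chronogram":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 suppress_internal_node_taxa=True)
        return cls(tree)

    def _label_nodes(self):
        i = 0
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                node.pc_id = node.taxon.label.replace(" ", "_")
            else:
                i += 1
                node.pc_id = node.label or f"N{i}"

    def _compute_ages(self):
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node.pc_age = 0.0
            else:
                ages = [c.pc_age + (c.edge.length or 0.0)
                        for c in node.child_nodes()]
                node.pc_age = max(ages)

    @property
    def leaves(self) -> list[str]:
        return [l.pc_id for l in self.tree.leaf_node_iter()]

    def node_by_id(self, node_id: str):
        for node in self.tree.preorder_node_iter():
            if node.pc_id == node_id:
                return node
        raise KeyError(node_id)

    def branch_durations(self) -> dict[str, float]:
        """Child-node id -> stem branch duration (myr)."""
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.edge.length is not None:
                out[node.pc_id] = float(node.edge.length)
        return out

    def leafset(self, node) -> frozenset[str]:
        return frozenset(l.pc_id for l in node.leaf_iter())

    def mrca(self, taxa: frozenset[str]):
        labels = {t.replace(" ", "_") for t in taxa}
        # dendropy's label-based mrca munges underscores; walk postorder instead
        best = None
        for nd in self.tree.postorder_node_iter():
            ls = self.leafset(nd)
            if labels <= ls and (best is None or len(ls) < len(best[1])):
                best = (nd, ls)
        if best is None:
            raise UnknownTaxon(f"taxa {sorted(labels)} not all in tree")
        return best[0]

    def clade_branch_ids(self, taxa: frozenset[str], include_stem: bool = True) -> list[str]:
        """Ids of all branches inside the clade spanned by ``taxa``."""
        top = self.mrca(taxa)
        ids = []
        for nd in top.preorder_iter():
            if nd is top and not include_stem:
                continue
            if nd.edge.length is not None:
                ids.append(nd.pc_id)
        return ids


def assign_events_to_branches(events: list[IndelEvent], tree: Chronogram
                              ) -> list[dict]:
    """Map each merged event to gain branch(es) of the chronogram.

    Returns one record per event: ``{event, branches: [(id, weight)],
    homoplastic: bool}`` with weights summing to 1.
    """
    leaves = set(tree.leaves)
    out = []
    for ev in events:
        carriers = {c.replace(" ", "_") for c in ev.carriers}
        unknown = carriers - leaves
        if unknown:
            raise UnknownTaxon(f"carriers {sorted(unknown)} not in tree")
        if not carriers:
            continue
        if carriers == tree.leafset(tree.mrca(frozenset(carriers))):
            branches = [(tree.mrca(frozenset(carriers)).pc_id, 1.0)]
            homoplastic = False
        else:
            gains = _fitch_gains(tree, carriers)
            w = 1.0 / len(gains)
            branches = [(g, w) for g in gains]
            homoplastic = len(gains) > 1
        out.append({"event": ev, "branches": branches, "homoplastic": homoplastic})
    return out


def _fitch_gains(tree: Chronogram, carriers: set[str]) -> list[str]:
    """Gain branches of one most-parsimonious reconstruction.

    Fitch down-pass, then an up-pass resolving ambiguity toward the parent
    state; the root prefers absence (the reference state is ancestral).
    """
    sets: dict = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            sets[node] = {1} if node.pc_id in carriers else {0}
        else:
            children = [sets[c] for c in node.child_nodes()]
            inter = set.intersection(*children)
            sets[node] = inter if inter else set.union(*children)
    state: dict = {}
    gains = []
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            state[node] = 0 if 0 in sets[node] else 1
            if state[node] == 1:
                gains.append(node.pc_id)  # gained on the root stem
        else:
            p = state[node.parent_node]
            state[node] = p if p in sets[node] else next(iter(sets[node]))
            if state[node] == 1 and p == 0:
                gains.append(node.pc_id)
    return gains


@dataclass(frozen=True)
class BranchRate:
    branch: str
    ins_bp: float
    del_bp: float
    duration: float

    @property
    def ins_rate(self) -> float:
        return self.ins_bp / self.duration

    @property
    def del_rate(self) -> float:
        return self.del_bp / self.duration


def occurrence_rates(assignments: list[dict], tree: Chronogram,
                     clades: dict[str, frozenset[str]] | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-branch and per-clade InDel occurrence rates in bp/myr.

    A branch rate is assigned event bp over the branch duration; a clade
    rate pools bp and durations over every branch inside the clade, stem
    included.
    """
    durations = tree.branch_durations()
    bp: dict[str, dict[str, float]] = defaultdict(lambda: {"insertion": 0.0,
                                                           "deletion": 0.0})
    for rec in assignments:
        ev = rec["event"]
        for branch, w in rec["branches"]:
            if branch not in durations:
                raise ZeroDuration(f"branch {branch} has no duration")
            bp[branch][ev.etype] += w * ev.length
    branch_rows = []
    for branch, dur in sorted(durations.items()):
        if dur <= 0:
            raise ZeroDuration(f"branch {branch} duration {dur}")
        rate = BranchRate(branch, bp[branch]["insertion"], bp[branch]["deletion"], dur)
        branch_rows.append({"branch": branch, "duration_myr": dur,
                            "ins_bp": rate.ins_bp, "del_bp": rate.del_bp,
                            "ins_rate": rate.ins_rate, "del_rate": rate.del_rate})
    branch_df = pd.DataFrame(branch_rows)
    clade_rows = []
    for name, taxa in (clades or {}).items():
        ids = tree.clade_branch_ids(frozenset(t.replace(" ", "_") for t in taxa))
        tot_dur = sum(durations[i] for i in ids)
        ins = sum(bp[i]["insertion"] for i in ids)
        dele = sum(bp[i]["deletion"] for i in ids)
        if tot_dur <= 0:
            raise ZeroDuration(f"clade {name} has zero total duration")
        clade_rows.append({"clade": name, "duration_myr": tot_dur,
                           "ins_bp": ins, "del_bp": dele,
                           "ins_rate": ins / tot_dur, "del_rate": dele / tot_dur})
    return branch_df, pd.DataFrame(clade_rows)
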