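"""Nei-Gojobori (1986) counting estimates of dN, dS and omega per gene.

Synonymous and nonsynonymous site counts use the fractional-site method: at
each codon position the synonymous fraction is the number of synonymous
single-base changes over three; changes creating stop codons count toward
the nonsynonymous fraction, so N + S equals the nucleotide length exactly.
Differences between codons are averaged over all shortest substitution
pathways, excluding pathways that pass through stop codons (when every
pathway is blocked, all are used with stop steps counted nonsynonymous).
The Jukes-Cantor correction d = -(3/4) ln(1 - (4/3)p) is applied to pN and
pS separately. omega = dN/dS is reported as NA (None) when dS = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .errors import FrameError, InsufficientData, SaturationError

BASES = "ACGT"


@lru_cache(maxsize=4)
def _code(table_id: int = 1) -> tuple[dict[str, str], frozenset[str]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), frozenset(table.stop_codons)


@lru_cache(maxsize=None)
def syn_site_fraction(codon: str, table_id: int = 1) -> float:
    """Number of synonymous sites (0..3) of one codon."""
    fwd, stops = _code(table_id)
    if codon in stops:
        raise FrameError(f"stop codon {codon} in frame")
    aa = fwd[codon]
    s = 0.0
    for i in range(3):
        syn = 0
        for b in BASES:
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1:]
            if alt not in stops and fwd[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


@lru_cache(maxsize=None)
def codon_pair_differences(c1: str, c2: str, table_id: int = 1) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over all orderings of the differing positions; pathways through
    stop codons are excluded from the average. Implemented as a first-step
    recursion (the test suite holds an independent pathway enumerator).
    """
    sd, nd, paths = _pair_recurse(c1, c2, table_id, skip_stops=True)
    if paths == 0:
        sd, nd, paths = _pair_recurse(c1, c2, table_id, skip_stops=False)
    return sd / paths, nd / paths


def _pair_recurse(c1: str, c2: str, table_id: int, skip_stops: bool):
    fwd, stops = _code(table_id)
    if c1 == c2:
        return 0.0, 0.0, 1
    total_paths = 0
    sd = nd = 0.0
    for i in range(3):
        if c1[i] == c2[i]:
            continue
        step = c1[:i] + c2[i] + c1[i + 1:]
        if skip_stops and step in stops:
            continue
        syn_step = (step not in stops and c1 not in stops
                    and fwd.get(step) == fwd.get(c1))
        sub_sd, sub_nd, sub_paths = _pair_recurse(step, c2, table_id, skip_stops)
        if sub_paths == 0:
            continue
        total_paths += sub_paths
        sd += sub_sd + (1.0 if syn_step else 0.0) * sub_paths
        nd += sub_nd + (0.0 if syn_step else 1.0) * sub_paths
    return sd, nd, total_paths


def jukes_cantor(p: float) -> float:
    """d = -(3/4) ln(1 - (4/3) p); saturates at p >= 3/4."""
    if p == 0:
        return 0.0
    if p * 4.0 / 3.0 >= 1.0:
        raise SaturationError(f"p = {p:.4f} too large for Jukes-Cantor")
    return -0.75 * math.log(1.0 - p * 4.0 / 3.0)


@dataclass(frozen=True)
class DnDsResult:
    gene: str
    taxon: str
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    dn: float
    ds: float

    @property
    def omega(self) -> float | None:
        if self.ds == 0:
            return None
        return self.dn / self.ds


def _check_codon_seq(seq: str, table_id: int) -> list[str]:
    seq = seq.upper()
    if len(seq) % 3:
        raise FrameError(f"length {len(seq)} not divisible by 3")
    if set(seq) - set(BASES):
        raise FrameError(f"ambiguous bases {sorted(set(seq) - set(BASES))}")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    _, stops = _code(table_id)
    for i, c in enumerate(codons):
        if c in stops:
            raise FrameError(f"internal stop {c} at codon {i}")
    return codons


def ng86_dnds(seq_a: str, seq_b: str, gene: str = "", taxon: str = "",
              table_id: int = 1) -> DnDsResult:
    """NG86 pairwise dN/dS between two in-frame, stop-free codon sequences."""
    ca = _check_codon_seq(seq_a, table_id)
    cb = _check_codon_seq(seq_b, table_id)
    if len(ca) != len(cb):
        raise FrameError("sequences differ in codon length")
    s_a = sum(syn_site_fraction(c, table_id) for c in ca)
    s_b = sum(syn_site_fraction(c, table_id) for c in cb)
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * len(ca) - s_sites
    sd = nd = 0.0
    for x, y in zip(ca, cb):
        if x != y:
            dsd, dnd = codon_pair_differences(x, y, table_id)
            sd += dsd
            nd += dnd
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    return DnDsResult(gene=gene, taxon=taxon, n_sites=n_sites, s_sites=s_sites,
                      nd=nd, sd=sd, dn=jukes_cantor(pn), ds=jukes_cantor(ps))


def gene_dnds_table(gene_seqs: dict[str, dict[str, str]], reference: str,
                    table_id: int = 1) -> pd.DataFrame:
    """Pairwise NG86 of every taxon against the reference, per gene.

    ``gene_seqs`` maps gene -> {taxon: codon sequence}; the reference taxon
    must be present for each gene.
    """
    rows = []
    for gene, taxa in sorted(gene_seqs.items()):
        ref_seq = taxa[reference]
        for taxon, seq in sorted(taxa.items()):
            if taxon == reference:
                continue
            res = ng86_dnds(ref_seq, seq, gene=gene, taxon=taxon, table_id=table_id)
            rows.append({"gene": gene, "taxon": taxon, "n_sites": res.n_sites,
                         "s_sites": res.s_sites, "Nd": res.nd, "Sd": res.sd,
                         "dN": res.dn, "dS": res.ds, "omega": res.omega})
    return pd.DataFrame(rows)


def clade_omega_screen(dnds: pd.DataFrame, clade_labels: dict[str, str],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene Welch t-test of omega between two clades.

    Taxa with undefined omega (dS = 0) are excluded and counted; genes with
    fewer than two defined omegas in either clade are reported as skipped.
    """
    clades = sorted(set(clade_labels.values()))
    if len(clades) != 2:
        raise InsufficientData(f"need exactly 2 clades, got {clades}")
    a_name, b_name = clades
    rows = []
    for gene, sub in dnds.groupby("gene"):
        defined = sub[sub.omega.notna()]
        excluded = len(sub) - len(defined)
        a = defined[defined.taxon.map(clade_labels) == a_name].omega.astype(float)
        b = defined[defined.taxon.map(clade_labels) == b_name].omega.astype(float)
        row = {"gene": gene, f"n_{a_name}": len(a), f"n_{b_name}": len(b),
               "n_undefined": excluded}
        if len(a) < 2 or len(b) < 2:
            row.update({"t": np.nan, "p": np.nan, "flagged": False,
                        "direction": "insufficient_data"})
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            direction = f"{a_name}>{b_name}" if a.mean() > b.mean() else f"{b_name}>{a_name}"
            row.update({"t": float(t), "p": float(p),
                        "flagged": bool(p < alpha), "direction": direction})
        rows.append(row)
    return pd.DataFrame(rows)


def positive_selection_flags(dnds: pd.DataFrame,
                             groups: dict[str, list[str]]) -> pd.DataFrame:
    """Genes whose mean pairwise omega exceeds 1 within each taxon group.

    ``groups`` maps a group name (e.g. a clade or 'all') to its taxa. Taxa
    with undefined omega are excluded from the mean.
    """
    rows = []
    for group, taxa in groups.items():
        sub = dnds[dnds.taxon.isin(taxa) & dnds.omega.notna()]
        for gene, gsub in sub.groupby("gene"):
            mean_omega = float(gsub.omega.astype(float).mean())
            rows.append({"group": group, "gene": gene, "mean_omega": mean_omega,
                         "n": len(gsub), "positive": mean_omega > 1.0})
    return pd.DataFrame(rows)
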