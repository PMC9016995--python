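"""File-format boundary: FASTA, GFF3, Newick and small TSV tables.

Internally everything is 0-based half-open; GFF3 rows are converted from/to
1-based closed coordinates here and nowhere else.
"""

from __future__ import annotations

from collections import defaultdict
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GeneFeature, Interval, PlastomeRecord

_FEATURE_KINDS = {"CDS", "tRNA", "rRNA"}


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: uppercase sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(recs, str(path), "fasta")


def read_plastome(fasta_path, gff3_path=None, record_id=None) -> PlastomeRecord:
    """Load a single circular plastome, optionally with its GFF3 annotation."""
    seqs = read_fasta(fasta_path)
    if record_id is None:
        if len(seqs) != 1:
            raise ValueError(f"{fasta_path} holds {len(seqs)} sequences; pass record_id")
        record_id, seq = next(iter(seqs.items()))
    else:
        seq = seqs[record_id]
    features = []
    if gff3_path is not None:
        features = read_gff3(gff3_path).get(record_id, [])
    return PlastomeRecord(record_id, seq, features)


def read_gff3(path) -> dict[str, list[GeneFeature]]:
    """Parse GFF3 into per-seqid GeneFeature lists.

    Rows of type CDS/tRNA/rRNA sharing an ``ID`` attribute are merged into a
    single compound feature (intron-containing genes). Phase of the first
    span becomes ``frame_offset``.
    """
    # keyed by (seqid, feature id): list of (start0, end0, strand, kind, phase)
    groups: dict[tuple[str, str], list[tuple]] = defaultdict(list)
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                continue
            seqid, _src, ftype, start, end, _score, strand, phase, attrs = cols
            if ftype not in _FEATURE_KINDS:
                continue
            attr = _parse_attributes(attrs)
            name = attr.get("gene") or attr.get("Name") or attr.get("ID")
            fid = attr.get("ID", name)
            key = (seqid, fid)
            if key not in groups:
                order.append(key)
            groups[key].append((int(start) - 1, int(end), strand, ftype,
                                0 if phase in {".", ""} else int(phase), name))
    out: dict[str, list[GeneFeature]] = defaultdict(list)
    for key in order:
        rows = sorted(groups[key])
        seqid = key[0]
        ivs = tuple(Interval(r[0], r[1]) for r in rows)
        out[seqid].append(GeneFeature(name=rows[0][5], kind=rows[0][3],
                                      strand=rows[0][2], intervals=ivs,
                                      frame_offset=rows[0][4]))
    return dict(out)


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.split(";"):
        part = part.strip()
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def write_gff3(path, record: PlastomeRecord) -> None:
    """Write a record's features as GFF3 (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record.id} 1 {record.length}\n")
        counts: dict[str, int] = defaultdict(int)
        for feat in record.features:
            counts[feat.name] += 1
            fid = feat.name if counts[feat.name] == 1 else f"{feat.name}.{counts[feat.name]}"
            phase_left = feat.frame_offset
            for i, iv in enumerate(feat.intervals):
                phase = str(phase_left) if feat.kind == "CDS" else "."
                if feat.kind == "CDS":
                    phase_left = (3 - ((iv.length - phase_left) % 3)) % 3
                fh.write("\t".join([
                    record.id, "plastcomp", feat.kind,
                    str(iv.start + 1), str(iv.end), ".", feat.strand, phase,
                    f"ID={fid};gene={feat.name}",
                ]) + "\n")


def read_clade_labels(path) -> dict[str, str]:
    """TSV ``taxon<TAB>clade`` -> mapping (header line optional)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0].lower() in {"taxon", "id", "species"}:
                continue
            out[cols[0]] = cols[1]
    return out


def read_alignment_fasta(path) -> dict[str, str]:
    """Aligned FASTA: equal-length gapped rows."""
    rows = read_fasta(path)
    lengths = {len(s) for s in rows.values()}
    if len(lengths) > 1:
        raise ValueError(f"{path}: rows have unequal aligned lengths {sorted(lengths)}")
    return rows


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
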