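"""Readers and writers for the file formats the toolkit exchanges.

FASTA goes through Bio.SeqIO. GFF3 (1-based closed), BED (0-based
half-open), Bismark-style CX reports and PAF/BLAST tabular alignment files
are read and written by small format-scoped routines limited to the fields
this toolkit defines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, GenomeSet, SDRecord, TEAnnotation

# ---------------------------------------------------------------- FASTA


def write_fasta(genome, path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_fasta(path) -> GenomeSet:
    return GenomeSet.from_sequences(
        {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    )


# ---------------------------------------------------------------- GFF3


def write_gff3(genes, path) -> None:
    """gene/mRNA/CDS features, 1-based closed coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            base = f"{g.chrom}\tt2tdup\t"
            fh.write(
                f"{base}gene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{base}mRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(sorted(g.cds_parts)):
                fh.write(
                    f"{base}CDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}.t1\n"
                )


def _attrs(field: str) -> dict:
    out = {}
    for part in field.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path) -> list:
    """Parse gene/mRNA/CDS GFF3 back into GeneModel records."""
    genes: dict[str, GeneModel] = {}
    mrna_to_gene: dict[str, str] = {}
    cds: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _, ftype, start, end, _, strand, _, attrs = f[:9]
            a = _attrs(attrs)
            start, end = int(start) - 1, int(end)
            if ftype == "gene":
                genes[a["ID"]] = GeneModel(a["ID"], chrom, start, end, strand, [])
            elif ftype == "mRNA":
                mrna_to_gene[a["ID"]] = a["Parent"]
            elif ftype == "CDS":
                cds.setdefault(a["Parent"], []).append((start, end))
    for mrna_id, parts in cds.items():
        gid = mrna_to_gene.get(mrna_id, mrna_id)
        if gid in genes:
            genes[gid].cds_parts = sorted(parts)
    for g in genes.values():
        if not g.cds_parts:
            g.cds_parts = [(g.start, g.end)]
    return list(genes.values())


# ---------------------------------------------------------------- BED


def write_bed(records, path) -> None:
    """records: iterable of (chrom, start, end, name) tuples."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join(str(x) for x in rec) + "\n")


def write_te_bed(tes, path) -> None:
    write_bed([(t.chrom, t.start, t.end, t.family) for t in tes], path)


def read_te_bed(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, family = line.split("\t")[:4]
            out.append(TEAnnotation(chrom, int(start), int(end), family.strip()))
    return out


# ---------------------------------------------------------------- CX report


CX_COLUMNS = [
    "chrom",
    "position",
    "strand",
    "count_methylated",
    "count_unmethylated",
    "context",
    "trinucleotide",
]


def write_cx_report(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=CX_COLUMNS)


def read_cx_report(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=CX_COLUMNS)
    return df


# ---------------------------------------------------------------- counts


def write_counts(counts: pd.DataFrame, path) -> None:
    """genes x sample.rep columns, TSV with index label 'gene_id'."""
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


# ---------------------------------------------------------------- PAF / BLAST


def write_paf(sds, path) -> None:
    """SD candidates as PAF lines (query = interval_a, target = interval_b).

    Gap-compressed identity goes in a ``gi:f:`` tag and the alignment path,
    when present, in ``cg:Z:`` so a round-trip preserves filtering behavior.
    """
    with open(path, "w") as fh:
        for sd in sds:
            matches = int(round(sd.identity * sd.length))
            fields = [
                sd.chrom_a, 10 ** 9, sd.start_a, sd.end_a, sd.strand,
                sd.chrom_b, 10 ** 9, sd.start_b, sd.end_b,
                matches, max(sd.length, 1), 255,
                f"gi:f:{sd.identity:.6f}",
            ]
            fh.write("\t".join(str(x) for x in fields) + "\n")


def read_paf(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            ident = None
            for tag in f[12:]:
                if tag.startswith("gi:f:"):
                    ident = float(tag[5:])
            blocklen = int(f[10])
            if ident is None:
                ident = int(f[9]) / blocklen if blocklen else 0.0
            out.append(
                SDRecord(
                    chrom_a=f[0], start_a=int(f[2]), end_a=int(f[3]),
                    chrom_b=f[5], start_b=int(f[7]), end_b=int(f[8]),
                    identity=ident, length=blocklen, strand=f[4],
                )
            )
    return out


def read_blast_tabular(path) -> list:
    """BLAST outfmt-6 (1-based closed; converted to 0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            qstart, qend = int(f[6]), int(f[7])
            sstart, send = int(f[8]), int(f[9])
            strand = "+"
            if sstart > send:
                sstart, send = send, sstart
                strand = "-"
            out.append(
                SDRecord(
                    chrom_a=f[0], start_a=qstart - 1, end_a=qend,
                    chrom_b=f[1], start_b=sstart - 1, end_b=send,
                    identity=float(f[2]) / 100.0, length=int(f[3]),
                    strand=strand,
                )
            )
    return out


# ---------------------------------------------------------------- JSON


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n"
    )


def read_json(path):
    return json.loads(Path(path).read_text())
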