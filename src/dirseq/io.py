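"""Readers and writers for annotations, coverage, junctions and tables.

GFF3/GTF are 1-based inclusive and converted to the package's 0-based
half-open convention on read; BED and bedGraph are already 0-based
half-open. All tabular outputs are tab-separated with a header line and
may carry ``#``-prefixed comment lines (config hash, seed) at the top.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd

from .genes import AnnotationError, GeneModel, TranscriptModel

JUNCTION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "read_count",
    "motif",
    "annotated_flag",
]


# ---------------------------------------------------------------------------
# annotation (GFF3 / GTF)
# ---------------------------------------------------------------------------

def _validate_feature_lines(path: str) -> None:
    """Cheap structural check so malformed lines fail with a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise AnnotationError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start < 1 or end < start:
                raise AnnotationError(
                    f"{path}: line {lineno}: invalid interval {start}-{end}"
                )


def _detect_dialect(path: str) -> str:
    if path.endswith((".gtf", ".gtf.gz")):
        return "gtf"
    if path.endswith((".gff", ".gff3", ".gff.gz", ".gff3.gz")):
        return "gff3"
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            attrs = line.rstrip("\n").split("\t")[-1]
            return "gtf" if 'gene_id "' in attrs else "gff3"
    return "gff3"


def read_annotation(path: str) -> list[GeneModel]:
    """Read a GFF3 or GTF annotation into GeneModels (0-based half-open).

    Genes are ordered deterministically by (chrom, start, gene_id);
    transcripts by transcript_id.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    _validate_feature_lines(path)
    dialect = _detect_dialect(path)
    if dialect == "gtf":
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=False,
            disable_infer_transcripts=False,
        )
    else:
        db = gffutils.create_db(
            path, ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts = []
        for tx in db.children(gene, level=1):
            if tx.featuretype not in ("mRNA", "transcript"):
                continue
            exons = sorted(
                (e.start - 1, e.end)
                for e in db.children(tx, featuretype="exon")
            )
            if not exons:
                continue
            transcripts.append(
                TranscriptModel(
                    transcript_id=tx.id, exons=tuple(exons), strand=gene.strand
                )
            )
        if not transcripts:
            # gene with exons directly attached (minimal GTF)
            exons = sorted(
                (e.start - 1, e.end)
                for e in db.children(gene, featuretype="exon")
            )
            if exons:
                transcripts.append(
                    TranscriptModel(
                        transcript_id=f"{gene.id}.t1",
                        exons=tuple(exons),
                        strand=gene.strand,
                    )
                )
        if not transcripts:
            continue
        transcripts.sort(key=lambda t: t.transcript_id)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                transcripts=tuple(transcripts),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str) -> None:
    """Write GeneModels as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id)):
            s, e = g.span
            fh.write(
                f"{g.chrom}\tdirseq\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{g.chrom}\tdirseq\tmRNA\t{t.start + 1}\t{t.end}\t.\t"
                    f"{g.strand}\t.\tID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for i, (xs, xe) in enumerate(t.exons, start=1):
                    fh.write(
                        f"{g.chrom}\tdirseq\texon\t{xs + 1}\t{xe}\t.\t"
                        f"{g.strand}\t.\tID={t.transcript_id}.exon{i};"
                        f"Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# BED12 transcript models
# ---------------------------------------------------------------------------

def read_bed12(path: str) -> list[tuple[str, TranscriptModel]]:
    """Read BED12 transcript alignments as (chrom, TranscriptModel) pairs."""
    out: list[tuple[str, TranscriptModel]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}: line {lineno}: expected 12 BED fields")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}: line {lineno}: block count mismatch")
            exons = tuple(
                (chrom_start + off, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            )
            out.append(
                (chrom, TranscriptModel(transcript_id=name, exons=exons, strand=strand))
            )
    return out


def write_bed12(
    records: Iterable[tuple[str, TranscriptModel]], path: str,
    header_comment: str | None = None,
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"#{header_comment}\n")
        for chrom, t in records:
            sizes = ",".join(str(e - s) for s, e in t.exons)
            starts = ",".join(str(s - t.start) for s, _ in t.exons)
            fh.write(
                f"{chrom}\t{t.start}\t{t.end}\t{t.transcript_id}\t0\t{t.strand}\t"
                f"{t.start}\t{t.end}\t0\t{len(t.exons)}\t{sizes},\t{starts},\n"
            )


# ---------------------------------------------------------------------------
# bedGraph coverage
# ---------------------------------------------------------------------------

def write_bedgraph(depth: dict[str, np.ndarray], path: str,
                   header_comment: str | None = None) -> None:
    """Write per-chrom depth arrays as run-length-encoded bedGraph."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"#{header_comment}\n")
        for chrom in sorted(depth):
            arr = np.asarray(depth[chrom])
            if arr.size == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{int(v)}\n")


def read_bedgraph(path: str, chrom_sizes: dict[str, int]) -> dict[str, np.ndarray]:
    """Read bedGraph into dense per-chrom integer depth arrays."""
    depth = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")
            if chrom in depth:
                depth[chrom][int(s):int(e)] = int(float(v))
    return depth


# ---------------------------------------------------------------------------
# junction and generic tables
# ---------------------------------------------------------------------------

def read_junction_tsv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in JUNCTION_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing junction columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str,
                header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"#{header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ---------------------------------------------------------------------------
# FASTA (linear scan, in-memory dict)
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(seqs):
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")
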