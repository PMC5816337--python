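"""Splice-junction extraction, motif classification, filtering, novelty.

Junction coordinates are intron coordinates (first and one-past-last
intronic base), 0-based half-open, matching BED-style junction files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .genes import GeneModel, enumerate_introns
from .io import JUNCTION_COLUMNS, read_junction_tsv

log = logging.getLogger(__name__)

CANONICAL_MOTIFS = ("GT/AG", "GC/AG", "AT/AC")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class JunctionRecord:
    chrom: str
    start: int
    end: int
    strand: str  # '+', '-' or '.'
    read_count: int
    motif_class: str = "other"
    annotated: bool = False
    max_overhang: int = 0

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("junction read_count must be >= 1")
        if self.end <= self.start:
            raise ValueError(f"empty junction interval ({self.start},{self.end})")

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.start, self.end, self.strand)


@dataclass(frozen=True)
class FilterConfig:
    """Rule-based stand-in for a trained junction classifier."""

    motifs: tuple[str, ...] = CANONICAL_MOTIFS
    min_read_count: int = 2
    min_overhang: int = 8


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def _junctions_from_bam(path: str, min_overhang: int) -> list[JunctionRecord]:
    import pysam

    acc: dict[tuple[str, int, int, str], list[int]] = {}
    last_pos: dict[str, int] = {}
    with pysam.AlignmentFile(path, "rb") as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.has_tag("NH") and read.get_tag("NH") > 1:
                continue  # only uniquely aligned reads
            if read.reference_start < last_pos.get(read.reference_name, -1):
                raise ValueError(f"{path}: alignments not coordinate-sorted")
            last_pos[read.reference_name] = read.reference_start
            strand = read.get_tag("XS") if read.has_tag("XS") else "."
            pos = read.reference_start
            left = 0
            cig = read.cigartuples or []
            for i, (op, length) in enumerate(cig):
                if op in (0, 7, 8, 2):  # M, =, X, D consume reference
                    left += length
                    pos += length
                elif op == 3:  # N: splice junction
                    right = sum(
                        l for o, l in cig[i + 1:] if o in (0, 7, 8)
                    )
                    overhang = min(left, right)
                    key = (read.reference_name, pos, pos + length, strand)
                    acc.setdefault(key, []).append(overhang)
                    pos += length
                    left = 0  # overhang resets past the junction
    records = [
        JunctionRecord(
            chrom=c, start=s, end=e, strand=st,
            read_count=len(ovh), max_overhang=max(ovh),
        )
        for (c, s, e, st), ovh in acc.items()
    ]
    records = [r for r in records if r.max_overhang >= min_overhang]
    records.sort(key=lambda r: r.key)
    return records


def _junctions_from_tsv(path: str) -> list[JunctionRecord]:
    df = read_junction_tsv(path)
    acc: dict[tuple[str, int, int, str], dict] = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.start), int(row.end), str(row.strand))
        slot = acc.setdefault(key, {"count": 0, "overhang": 0})
        slot["count"] += int(row.read_count)
        slot["overhang"] = max(
            slot["overhang"], int(getattr(row, "max_overhang", 0))
        )
    records = [
        JunctionRecord(
            chrom=c, start=s, end=e, strand=st,
            read_count=v["count"], max_overhang=v["overhang"],
        )
        for (c, s, e, st), v in acc.items()
    ]
    records.sort(key=lambda r: r.key)
    return records


def extract_junctions(path: str, min_overhang: int = 0) -> list[JunctionRecord]:
    """Extract distinct junctions from a sorted BAM or a junction TSV.

    One record per distinct (chrom, start, end, strand) with summed read
    count and the maximum observed anchor overhang; multi-mapping reads
    (NH > 1) are excluded on the BAM path.
    """
    if path.endswith((".bam", ".sam", ".cram")):
        records = _junctions_from_bam(path, min_overhang)
    else:
        records = _junctions_from_tsv(path)
        if min_overhang:
            records = [r for r in records if r.max_overhang >= min_overhang]
    if not records:
        log.warning("no junctions extracted from %s", path)
    return records


# ---------------------------------------------------------------------------
# motif classification
# ---------------------------------------------------------------------------

def _motif_of(donor2: str, acceptor2: str) -> str:
    pair = f"{donor2}/{acceptor2}"
    return pair if pair in CANONICAL_MOTIFS else "other"


def classify_motif(junction: JunctionRecord, genome: dict[str, str]) -> str:
    """Terminal-dinucleotide class of a junction: GT/AG, GC/AG, AT/AC, other.

    The donor is the first two intronic bases and the acceptor the last two,
    read in transcript orientation (reverse-complemented on the minus
    strand). Unstranded junctions try both orientations and keep the one
    yielding a whitelisted motif; ties stay 'other'.
    """
    if junction.chrom not in genome:
        raise KeyError(f"chrom {junction.chrom} not in genome")
    seq = genome[junction.chrom]
    if junction.end > len(seq) or junction.start < 0:
        raise IndexError(
            f"junction {junction.chrom}:{junction.start}-{junction.end} "
            "outside genome bounds"
        )
    left2 = seq[junction.start:junction.start + 2].upper()
    right2 = seq[junction.end - 2:junction.end].upper()
    fwd = _motif_of(left2, right2)
    rev = _motif_of(reverse_complement(right2), reverse_complement(left2))
    if junction.strand == "+":
        return fwd
    if junction.strand == "-":
        return rev
    if fwd in CANONICAL_MOTIFS and rev not in CANONICAL_MOTIFS:
        return fwd
    if rev in CANONICAL_MOTIFS and fwd not in CANONICAL_MOTIFS:
        return rev
    return "other"


def classify_motifs(
    records: Sequence[JunctionRecord], genome: dict[str, str]
) -> list[JunctionRecord]:
    out = []
    for r in records:
        motif = classify_motif(r, genome)
        strand = r.strand
        if strand == ".":
            # adopt the orientation that produced a whitelisted motif
            if motif in CANONICAL_MOTIFS:
                seq = genome[r.chrom]
                fwd = _motif_of(
                    seq[r.start:r.start + 2].upper(), seq[r.end - 2:r.end].upper()
                )
                strand = "+" if fwd == motif else "-"
        out.append(replace(r, motif_class=motif, strand=strand))
    return out


# ---------------------------------------------------------------------------
# filtering and novelty
# ---------------------------------------------------------------------------

def filter_junctions(
    records: Sequence[JunctionRecord], rules: FilterConfig | None = None
) -> tuple[list[JunctionRecord], list[JunctionRecord]]:
    """Partition junctions into (kept, discarded) by the rule set."""
    rules = rules or FilterConfig()
    kept, discarded = [], []
    for r in records:
        ok = (
            r.motif_class in rules.motifs
            and r.read_count >= rules.min_read_count
            and r.max_overhang >= rules.min_overhang
        )
        (kept if ok else discarded).append(r)
    return kept, discarded


def annotate_novelty(
    records: Sequence[JunctionRecord], genes: Iterable[GeneModel]
) -> list[JunctionRecord]:
    """Flag junctions exactly matching an annotated intron as annotated."""
    known = {
        (i.chrom, i.start, i.end)
        for g in genes
        for i in enumerate_introns(g)
    }
    return [
        replace(r, annotated=(r.chrom, r.start, r.end) in known) for r in records
    ]


def junctions_to_frame(records: Sequence[JunctionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.chrom, r.start, r.end, r.strand, r.read_count, r.motif_class,
             int(r.annotated))
            for r in records
        ],
        columns=JUNCTION_COLUMNS,
    )
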