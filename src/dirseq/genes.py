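"""Gene and transcript models and intron enumeration.

All coordinates are 0-based half-open throughout the package; 1-based
inclusive conventions (GFF3/GTF) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

#: Gaps shorter than this are treated as alignment artifacts, not introns.
DEFAULT_MIN_INTRON_LENGTH = 20


class AnnotationError(ValueError):
    """Raised for structurally invalid gene/transcript models."""


@dataclass(frozen=True)
class TranscriptModel:
    """An exon chain on one strand, exons sorted and non-overlapping."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        exons = tuple(tuple(e) for e in self.exons)
        object.__setattr__(self, "exons", exons)
        for start, end in exons:
            if end <= start:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: empty exon ({start}, {end})"
                )
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"({s0},{e0}) and ({s1},{e1})"
                )
            if s1 == e0:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: zero-length gap between "
                    f"({s0},{e0}) and ({s1},{e1})"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def junctions(self) -> list[tuple[int, int]]:
        """Intron intervals (exon_end, next_exon_start), left to right."""
        return [(e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])]


@dataclass(frozen=True)
class GeneModel:
    """A gene: one or more transcripts on the same chrom and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id}: no transcripts")
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        for t in self.transcripts:
            if t.strand != self.strand:
                raise AnnotationError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} strand mismatch"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.start for t in self.transcripts),
            max(t.end for t in self.transcripts),
        )


@dataclass(frozen=True)
class IntronRecord:
    """One distinct intron of a gene.

    ``ordinal`` counts introns in transcript (5'->3') orientation: ordinal 1
    of a minus-strand gene is the rightmost gap on the chromosome.
    """

    intron_id: str
    chrom: str
    start: int
    end: int
    strand: str
    parent_gene: str
    ordinal: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def donor(self) -> int:
        """Genomic position of the donor (5') boundary, strand-oriented."""
        return self.start if self.strand == "+" else self.end

    @property
    def acceptor(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def enumerate_introns(
    gene: GeneModel, min_length: int = DEFAULT_MIN_INTRON_LENGTH
) -> list[IntronRecord]:
    """Distinct introns of ``gene`` across all its transcripts.

    Introns are keyed by (start, end); an intron shared by several isoforms
    is reported once. Gaps shorter than ``min_length`` are skipped. Ordinals
    run 5'->3' in transcript orientation.
    """
    gaps: set[tuple[int, int]] = set()
    for t in gene.transcripts:
        gaps.update(j for j in t.junctions() if j[1] - j[0] >= min_length)
    ordered = sorted(gaps, reverse=(gene.strand == "-"))
    return [
        IntronRecord(
            intron_id=f"{gene.gene_id}.i{i}",
            chrom=gene.chrom,
            start=start,
            end=end,
            strand=gene.strand,
            parent_gene=gene.gene_id,
            ordinal=i,
        )
        for i, (start, end) in enumerate(ordered, start=1)
    ]


def enumerate_all_introns(
    genes: Iterable[GeneModel], min_length: int = DEFAULT_MIN_INTRON_LENGTH
) -> list[IntronRecord]:
    out: list[IntronRecord] = []
    for g in genes:
        out.extend(enumerate_introns(g, min_length=min_length))
    return out
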