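"""Long-read isoform collapsing and alternative-splicing event classification.

Observed isoforms (e.g. aligned long-read transcript models) are collapsed
by shared junction chain and compared against the reference annotation.
Four event classes are called — intron retention (IR), alternative donor
(Alt5), alternative acceptor (Alt3) and exon skipping (ES) — with mutually
exclusive exons (MXE) reported as a subcategory that summaries fold into ES.
Donor and acceptor are defined in transcript orientation, so an Alt5 event
on the minus strand alters the right-hand junction coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .genes import GeneModel, TranscriptModel, enumerate_introns

EVENT_CLASSES = ("IR", "Alt3", "Alt5", "ES")  # summary order


@dataclass(frozen=True)
class Isoform:
    isoform_id: str
    chrom: str
    model: TranscriptModel
    support: int = 1
    source_gene: str | None = None

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("isoform support must be >= 1")


@dataclass(frozen=True)
class ASEvent:
    event_type: str  # IR, Alt5, Alt3, ES, MXE
    gene_id: str
    isoform_id: str
    coordinates: tuple[tuple[int, int], ...]
    reference_transcript: str

    def __post_init__(self) -> None:
        if self.event_type == "MXE" and len(self.coordinates) != 2:
            raise ValueError("MXE events carry exactly two exon intervals")


@dataclass(frozen=True)
class NovelRegion:
    region_id: str
    chrom: str
    start: int
    end: int
    strand: str
    isoforms: tuple[Isoform, ...]
    has_AS: bool
    coding_capacity: str  # 'coding' | 'noncoding'


# ---------------------------------------------------------------------------
# collapsing
# ---------------------------------------------------------------------------

def collapse_isoforms(
    models: Sequence[tuple[str, TranscriptModel]], strand_aware: bool = True
) -> list[Isoform]:
    """Merge aligned transcript models into unique isoforms.

    Multi-exon models with an identical (chrom, strand, junction chain) are
    merged into one isoform whose terminal exons take the outermost observed
    ends; single-exon models merge when they overlap on the same strand.
    Support counts the merged models. Idempotent.
    """
    multi: dict[tuple, list[TranscriptModel]] = {}
    single: dict[tuple[str, str], list[TranscriptModel]] = {}
    chroms: dict[tuple, str] = {}
    for chrom, t in models:
        strand = t.strand if strand_aware else "+"
        if len(t.exons) > 1:
            key = (chrom, strand, tuple(t.junctions()))
            multi.setdefault(key, []).append(t)
            chroms[key] = chrom
        else:
            single.setdefault((chrom, strand), []).append(t)

    out: list[Isoform] = []
    for key in sorted(multi, key=lambda k: (k[0], k[2][0][0], k[1])):
        chrom, strand, chain = key
        members = multi[key]
        start = min(t.start for t in members)
        end = max(t.end for t in members)
        bounds = [start] + [c for j in chain for c in j] + [end]
        exons = tuple(zip(bounds[::2], bounds[1::2]))
        support = len(members)
        out.append(
            Isoform(
                isoform_id=sorted(t.transcript_id for t in members)[0],
                chrom=chrom,
                model=TranscriptModel(
                    transcript_id=sorted(t.transcript_id for t in members)[0],
                    exons=exons,
                    strand=members[0].strand,
                ),
                support=support,
            )
        )
    # single-exon: sweep-line overlap merge per (chrom, strand)
    for (chrom, strand), members in sorted(single.items()):
        members.sort(key=lambda t: (t.start, t.end))
        cluster: list[TranscriptModel] = []
        cur_end = -1
        def _flush(cluster: list[TranscriptModel]) -> None:
            if not cluster:
                return
            s = min(t.start for t in cluster)
            e = max(t.end for t in cluster)
            name = sorted(t.transcript_id for t in cluster)[0]
            out.append(
                Isoform(
                    isoform_id=name,
                    chrom=chrom,
                    model=TranscriptModel(
                        transcript_id=name, exons=((s, e),),
                        strand=cluster[0].strand,
                    ),
                    support=len(cluster),
                )
            )
        for t in members:
            if cluster and t.start >= cur_end:
                _flush(cluster)
                cluster = []
            cluster.append(t)
            cur_end = max(cur_end, t.end)
        _flush(cluster)
    out.sort(key=lambda i: (i.chrom, i.model.start, i.isoform_id))
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _oriented(junction: tuple[int, int], strand: str) -> tuple[int, int]:
    """(donor, acceptor) genomic coordinates in transcript orientation."""
    s, e = junction
    return (s, e) if strand == "+" else (e, s)


def pick_reference_transcript(
    isoform: Isoform, gene: GeneModel
) -> TranscriptModel:
    """Reference = transcript sharing the most junctions with the isoform;
    ties broken by longest exonic length, then lexicographic id."""
    iso_j = set(isoform.model.junctions())

    def rank(t: TranscriptModel):
        shared = len(iso_j & set(t.junctions()))
        return (-shared, -t.exonic_length, t.transcript_id)

    return min(gene.transcripts, key=rank)


def classify_events(isoform: Isoform, gene: GeneModel) -> list[ASEvent]:
    """Classify splicing differences of one isoform against its gene.

    Each local difference yields one event; terminal-exon differences are
    not events. An ES junction skipping exactly one reference exon is
    upgraded to MXE when the isoform retains an adjacent reference exon and
    another annotated transcript shows the complementary inclusion pattern.
    """
    if isoform.chrom != gene.chrom or isoform.model.strand != gene.strand:
        raise ValueError(
            f"isoform {isoform.isoform_id} does not overlap gene "
            f"{gene.gene_id} on the same strand"
        )
    ref = pick_reference_transcript(isoform, gene)
    strand = gene.strand
    ref_junctions = set(ref.junctions())
    ref_donors = {_oriented(j, strand)[0]: j for j in ref_junctions}
    ref_acceptors = {_oriented(j, strand)[1]: j for j in ref_junctions}
    iso_exons = isoform.model.exons
    iso_span = (isoform.model.start, isoform.model.end)

    events: list[ASEvent] = []

    # IR: a reference intron fully inside one isoform exon
    for intron in ref.junctions():
        s, e = intron
        if any(xs <= s and e <= xe for xs, xe in iso_exons):
            events.append(
                ASEvent("IR", gene.gene_id, isoform.isoform_id,
                        ((s, e),), ref.transcript_id)
            )

    internal_ref_exons = ref.exons[1:-1]
    iso_exon_set = set(iso_exons)
    for j in isoform.model.junctions():
        if j in ref_junctions:
            continue
        js, je = j
        skipped = [x for x in internal_ref_exons if js <= x[0] and x[1] <= je]
        if skipped:
            ev_type = "ES"
            coords: tuple[tuple[int, int], ...] = tuple(skipped)
            if len(skipped) == 1:
                mxe = _mutually_exclusive_partner(
                    skipped[0], ref, gene, iso_exon_set
                )
                if mxe is not None:
                    ev_type, coords = "MXE", (skipped[0], mxe)
            events.append(
                ASEvent(ev_type, gene.gene_id, isoform.isoform_id,
                        coords, ref.transcript_id)
            )
            continue
        donor, acceptor = _oriented(j, strand)
        if acceptor in ref_acceptors and donor not in ref_donors:
            events.append(
                ASEvent("Alt5", gene.gene_id, isoform.isoform_id,
                        ((js, je),), ref.transcript_id)
            )
        elif donor in ref_donors and acceptor not in ref_acceptors:
            events.append(
                ASEvent("Alt3", gene.gene_id, isoform.isoform_id,
                        ((js, je),), ref.transcript_id)
            )
        elif donor in ref_donors and acceptor in ref_acceptors:
            # both boundaries known but pairing novel and no exon skipped:
            # treat as a novel combination, not one of the four classes
            continue
    events.sort(key=lambda e: (e.coordinates[0][0], e.event_type))
    return events


def _mutually_exclusive_partner(
    skipped: tuple[int, int],
    ref: TranscriptModel,
    gene: GeneModel,
    iso_exons: set[tuple[int, int]],
) -> tuple[int, int] | None:
    """Adjacent reference exon making (skipped, partner) mutually exclusive."""
    idx = ref.exons.index(skipped)
    for nb in (idx - 1, idx + 1):
        if nb < 0 or nb >= len(ref.exons):
            continue
        partner = ref.exons[nb]
        if partner not in iso_exons:
            continue
        for other in gene.transcripts:
            if other.transcript_id == ref.transcript_id:
                continue
            ox = set(other.exons)
            if skipped in ox and partner not in ox:
                return partner
    return None


def classify_all(
    isoforms: Sequence[Isoform], genes: Sequence[GeneModel]
) -> list[ASEvent]:
    """Assign each isoform to the overlapping same-strand gene and classify."""
    events: list[ASEvent] = []
    for iso in isoforms:
        gene = _assign_gene(iso, genes)
        if gene is None:
            continue
        events.extend(classify_events(iso, gene))
    return events


def _assign_gene(iso: Isoform, genes: Sequence[GeneModel]) -> GeneModel | None:
    best, best_ov = None, 0
    for g in genes:
        if g.chrom != iso.chrom or g.strand != iso.model.strand:
            continue
        ov = min(g.span[1], iso.model.end) - max(g.span[0], iso.model.start)
        if ov > best_ov:
            best, best_ov = g, ov
    return best


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_event_distribution(
    counts_or_events: dict[str, int] | Sequence[ASEvent],
) -> pd.DataFrame:
    """Per-class counts and percentages, MXE folded into ES.

    Accepts either pre-tallied per-class counts or a list of events (in
    which case both the event tally and an isoform-level tally, counting
    each isoform once per class it exhibits, are derivable by the caller).
    Percentages are 100 * count / total to one decimal; NA when empty.
    """
    if isinstance(counts_or_events, dict):
        counts = {k: int(v) for k, v in counts_or_events.items()}
    else:
        counts = {}
        for ev in counts_or_events:
            cls = "ES" if ev.event_type == "MXE" else ev.event_type
            counts[cls] = counts.get(cls, 0) + 1
    counts["ES"] = counts.pop("MXE", 0) + counts.pop("ES", 0)
    total = sum(counts.values())
    rows = []
    for cls in EVENT_CLASSES:
        n = counts.get(cls, 0)
        pct = round(100.0 * n / total, 1) if total else float("nan")
        rows.append((cls, n, pct))
    return pd.DataFrame(rows, columns=["event_class", "count", "percent"])


def isoform_class_counts(events: Sequence[ASEvent]) -> dict[str, int]:
    """Isoform-level tally: each isoform counted once per class it shows."""
    seen: set[tuple[str, str]] = set()
    for ev in events:
        cls = "ES" if ev.event_type == "MXE" else ev.event_type
        seen.add((ev.isoform_id, cls))
    counts: dict[str, int] = {c: 0 for c in EVENT_CLASSES}
    for _, cls in seen:
        counts[cls] += 1
    return counts


# ---------------------------------------------------------------------------
# novel transcribed regions
# ---------------------------------------------------------------------------

_STOPS = ("TAA", "TAG", "TGA")
_START = "ATG"


def longest_orf_codons(seq: str) -> int:
    """Length in codons of the longest ATG..stop ORF on the given strand."""
    best = 0
    n = len(seq)
    for frame in range(3):
        start = None
        for i in range(frame, n - 2, 3):
            codon = seq[i:i + 3]
            if start is None and codon == _START:
                start = i
            elif start is not None and codon in _STOPS:
                best = max(best, (i - start) // 3 + 1)
                start = None
    return best


def detect_novel_regions(
    isoforms: Sequence[Isoform],
    genes: Sequence[GeneModel],
    genome: dict[str, str] | None = None,
    min_orf_codons: int = 100,
) -> list[NovelRegion]:
    """Group intergenic isoforms into strand-aware overlap clusters.

    A region has AS when >= 2 member isoforms differ in junction chain;
    coding capacity requires a spliced-transcript ORF of at least
    ``min_orf_codons`` codons (noncoding when no genome is supplied).
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        spans.setdefault(g.chrom, []).append(g.span)

    def intergenic(iso: Isoform) -> bool:
        for s, e in spans.get(iso.chrom, ()):
            if iso.model.start < e and s < iso.model.end:
                return False
        return True

    candidates = sorted(
        (i for i in isoforms if intergenic(i)),
        key=lambda i: (i.chrom, i.model.strand, i.model.start, i.isoform_id),
    )
    regions: list[NovelRegion] = []
    cluster: list[Isoform] = []
    ckey: tuple[str, str] | None = None
    cend = -1

    def _close() -> None:
        if not cluster:
            return
        s = min(i.model.start for i in cluster)
        e = max(i.model.end for i in cluster)
        chains = {tuple(i.model.junctions()) for i in cluster}
        has_as = len(cluster) >= 2 and len(chains) >= 2
        coding = "noncoding"
        if genome is not None:
            from .junctions import reverse_complement

            for iso in cluster:
                seq = "".join(
                    genome[iso.chrom][xs:xe] for xs, xe in iso.model.exons
                )
                if iso.model.strand == "-":
                    seq = reverse_complement(seq)
                if longest_orf_codons(seq) >= min_orf_codons:
                    coding = "coding"
                    break
        regions.append(
            NovelRegion(
                region_id=f"NR{len(regions) + 1:05d}",
                chrom=cluster[0].chrom,
                start=s,
                end=e,
                strand=cluster[0].model.strand,
                isoforms=tuple(cluster),
                has_AS=has_as,
                coding_capacity=coding,
            )
        )

    for iso in candidates:
        key = (iso.chrom, iso.model.strand)
        if cluster and (key != ckey or iso.model.start >= cend):
            _close()
            cluster, cend = [], -1
        cluster.append(iso)
        ckey = key
        cend = max(cend, iso.model.end)
    _close()
    return regions
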