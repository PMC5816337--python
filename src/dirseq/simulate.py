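"""Synthetic ground-truth data with the statistical structure the
analysis assumes.

The generator emits, deterministically under a seed: a random genome with
multi-exon gene models whose introns carry configurable splice-site
motifs; per-condition, per-replicate coverage in which exonic depth is
negative-binomial around the gene's expression level and each intron
splits reads into retained (inclusion level psi) versus spliced (junction
counts); long-read isoform models carrying seeded AS events of all five
classes; and ddPCR droplet counts from a Poisson partition model. A
TruthManifest records every generative choice so each pipeline stage can
be checked against an independent oracle.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .ddpcr import DdpcrWell
from .dircall import CONTROL_LABEL, CoverageBundle
from .genes import GeneModel, IntronRecord, TranscriptModel, enumerate_introns
from .junctions import reverse_complement

DEFAULT_MOTIF_FRACTIONS = {"GT/AG": 0.90, "GC/AG": 0.08, "AT/AC": 0.02}
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Generative settings; defaults mirror the study design at toy scale:
    3 tissues x 4 stresses x 2 phases x 3 replicates plus per-tissue
    controls, 20 genes."""

    n_genes: int = 20
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (60, 200)
    intergenic_gap: tuple[int, int] = (200, 500)
    base_depth: float = 50.0
    nb_dispersion: float = 0.1
    psi_control: float = 0.1
    delta_psi: float = 0.3
    dir_fraction: float = 0.2
    expression_changed_fraction: float = 0.0
    expression_changed_fold: float = 8.0
    n_replicates: int = 3
    tissues: tuple[str, ...] = ("leaf", "root", "xylem")
    stresses: tuple[str, ...] = ("cold", "drought", "heat", "salt")
    phases: tuple[str, ...] = ("short", "prolonged")
    motif_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_FRACTIONS)
    )
    min_intron_length: int = 20
    seed: int = 0

    def treatment_conditions(self) -> list[tuple[str, str, str]]:
        return [
            (t, s, p)
            for t in self.tissues
            for s in self.stresses
            for p in self.phases
        ]

    def condition_labels(self) -> list[str]:
        return [f"{t}|{s}|{p}" for t, s, p in self.treatment_conditions()]


@dataclass
class SeededIsoform:
    isoform_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    events: tuple[dict, ...]  # {'type': ..., 'coordinates': [...]}


@dataclass
class TruthManifest:
    """Everything needed to predict each pipeline stage's output."""

    config: SimulationConfig
    chrom_sizes: dict[str, int]
    genes: list[GeneModel]
    introns: list[IntronRecord]
    intron_motifs: dict[str, str]  # intron_id -> motif class
    psi: dict[str, dict[str, float]]  # intron_id -> condition label -> psi
    true_dirs: dict[str, dict]  # intron_id -> {'stresses': [...], 'direction'}
    expression: dict[str, dict[str, float]]  # gene -> condition -> fold
    isoforms: list[SeededIsoform]
    junction_set: set

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, (GeneModel, TranscriptModel, IntronRecord)):
                return asdict(o)
            if isinstance(o, SeededIsoform):
                return asdict(o)
            if isinstance(o, SimulationConfig):
                return asdict(o)
            if isinstance(o, set):
                return sorted(o)
            if isinstance(o, tuple):
                return list(o)
            raise TypeError(type(o))

        return json.dumps(asdict(self), default=_default, indent=1, sort_keys=True)


def _rng_for(seed: int, *names) -> np.random.Generator:
    """Independent, reproducible stream keyed by seed and string/int tags."""
    keys = [seed & 0x7FFFFFFF]
    for n in names:
        keys.append(zlib.crc32(str(n).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(keys)


# ---------------------------------------------------------------------------
# genome and annotation
# ---------------------------------------------------------------------------

def make_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel], TruthManifest]:
    """Random genome, annotation and the manifest that explains them."""
    if config.exon_length[0] < 10 or config.intron_length[0] < config.min_intron_length:
        raise ValueError("infeasible exon/intron length constraints")
    rng = _rng_for(config.seed, "genome")
    chrom = "chr1"
    cursor = int(rng.integers(*config.intergenic_gap))
    genes: list[GeneModel] = []
    boundary_motifs: list[tuple[int, int, str, str]] = []  # start,end,strand,motif
    motif_names = list(config.motif_fractions)
    motif_p = np.array([config.motif_fractions[m] for m in motif_names], float)
    motif_p = motif_p / motif_p.sum()

    for gi in range(config.n_genes):
        gene_id = f"G{gi + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        exons = []
        pos = cursor
        for xi in range(n_exons):
            xlen = int(rng.integers(*config.exon_length))
            exons.append((pos, pos + xlen))
            pos += xlen
            if xi < n_exons - 1:
                pos += int(rng.integers(*config.intron_length))
        tx = TranscriptModel(f"{gene_id}.1", tuple(exons), strand)
        gene = GeneModel(gene_id, chrom, strand, (tx,))
        genes.append(gene)
        for s, e in tx.junctions():
            motif = str(rng.choice(motif_names, p=motif_p))
            boundary_motifs.append((s, e, strand, motif))
        cursor = pos + int(rng.integers(*config.intergenic_gap))

    size = cursor + 200
    seq = rng.choice(_BASES, size=size)
    for s, e, strand, motif in boundary_motifs:
        donor, acceptor = motif.split("/")
        if strand == "+":
            seq[s:s + 2] = list(donor)
            seq[e - 2:e] = list(acceptor)
        else:
            seq[e - 2:e] = list(reverse_complement(donor))
            seq[s:s + 2] = list(reverse_complement(acceptor))
    sequences = {chrom: "".join(seq)}

    introns: list[IntronRecord] = []
    intron_motifs: dict[str, str] = {}
    motif_by_interval = {(s, e): m for s, e, _, m in boundary_motifs}
    for g in genes:
        for rec in enumerate_introns(g, min_length=config.min_intron_length):
            introns.append(rec)
            intron_motifs[rec.intron_id] = motif_by_interval[(rec.start, rec.end)]

    psi, true_dirs = _assign_psi(config, introns)
    expression = _assign_expression(config, genes)
    isoforms = _seed_isoforms(config, genes)
    # MXE seeding adds a second annotated transcript to its gene
    genes = _augment_mxe_references(genes, isoforms)
    junction_set = {
        (i.chrom, i.start, i.end, i.strand) for i in introns
    }
    manifest = TruthManifest(
        config=config,
        chrom_sizes={chrom: size},
        genes=genes,
        introns=introns,
        intron_motifs=intron_motifs,
        psi=psi,
        true_dirs=true_dirs,
        expression=expression,
        isoforms=isoforms,
        junction_set=junction_set,
    )
    return sequences, genes, manifest


def _assign_psi(config: SimulationConfig, introns: list[IntronRecord]):
    rng = _rng_for(config.seed, "psi")
    labels = config.condition_labels()
    psi: dict[str, dict[str, float]] = {}
    true_dirs: dict[str, dict] = {}
    for rec in introns:
        base = config.psi_control
        per = {f"{t}|{CONTROL_LABEL}": base for t in config.tissues}
        per.update({lab: base for lab in labels})
        if rng.random() < config.dir_fraction:
            direction = 1 if rng.random() < 0.5 else -1
            delta = config.delta_psi * direction
            k = int(rng.integers(1, len(config.stresses) + 1))
            hit = sorted(
                rng.choice(config.stresses, size=k, replace=False).tolist()
            )
            for t, s, p in config.treatment_conditions():
                if s in hit:
                    per[f"{t}|{s}|{p}"] = float(
                        np.clip(base + delta, 0.0, 0.95)
                    )
            true_dirs[rec.intron_id] = {
                "stresses": hit,
                "direction": "increased IR" if direction > 0 else "decreased IR",
                "delta_psi": delta,
                "chrom": rec.chrom,
                "start": rec.start,
                "end": rec.end,
                "gene_id": rec.parent_gene,
            }
        psi[rec.intron_id] = per
    return psi, true_dirs


def _assign_expression(config: SimulationConfig, genes: list[GeneModel]):
    rng = _rng_for(config.seed, "expression")
    labels = config.condition_labels()
    out: dict[str, dict[str, float]] = {}
    for g in genes:
        per = {f"{t}|{CONTROL_LABEL}": 1.0 for t in config.tissues}
        changed = rng.random() < config.expression_changed_fraction
        for lab in labels:
            if changed:
                fold = (
                    config.expression_changed_fold
                    if rng.random() < 0.5
                    else 1.0 / config.expression_changed_fold
                )
            else:
                fold = 1.0
            per[lab] = fold
        out[g.gene_id] = per
    return out


# ---------------------------------------------------------------------------
# seeded AS isoforms
# ---------------------------------------------------------------------------

_EVENT_CYCLE = ("IR", "Alt5", "Alt3", "ES", "MXE")


def _seed_isoforms(
    config: SimulationConfig, genes: list[GeneModel]
) -> list[SeededIsoform]:
    """One observed isoform with one seeded AS event per eligible gene."""
    rng = _rng_for(config.seed, "isoforms")
    out: list[SeededIsoform] = []
    cycle = 0
    for g in genes:
        tx = g.transcripts[0]
        if len(tx.exons) < 4:
            continue  # need internal exons for ES/MXE seeding
        ev = _EVENT_CYCLE[cycle % len(_EVENT_CYCLE)]
        cycle += 1
        iso = _build_event_isoform(g, tx, ev, rng, config.min_intron_length)
        if iso is not None:
            out.append(iso)
    return out


def _build_event_isoform(
    gene: GeneModel,
    tx: TranscriptModel,
    event: str,
    rng: np.random.Generator,
    min_intron: int,
) -> SeededIsoform | None:
    exons = list(tx.exons)
    introns = tx.junctions()
    iid = f"{gene.gene_id}.obs.{event}"
    strand = gene.strand
    if event == "IR":
        k = int(rng.integers(0, len(introns)))
        merged = exons[:k] + [(exons[k][0], exons[k + 1][1])] + exons[k + 2:]
        coords = (tuple(introns[k]),)
        return SeededIsoform(iid, gene.gene_id, gene.chrom, strand,
                             tuple(merged), ({"type": "IR",
                                              "coordinates": coords},))
    if event in ("Alt5", "Alt3"):
        k = int(rng.integers(0, len(introns)))
        s, e = introns[k]
        shift = 6
        if (e - s) - shift < min_intron:
            return None
        # Alt5 moves the donor, Alt3 the acceptor (transcript orientation)
        move_left = (event == "Alt5") == (strand == "+")
        if move_left:
            new_s, new_e = s + shift, e
            exons[k] = (exons[k][0], exons[k][1] + shift)
        else:
            new_s, new_e = s, e - shift
            exons[k + 1] = (exons[k + 1][0] - shift, exons[k + 1][1])
        coords = ((new_s, new_e),)
        return SeededIsoform(iid, gene.gene_id, gene.chrom, strand,
                             tuple(exons), ({"type": event,
                                             "coordinates": coords},))
    if event == "ES":
        k = int(rng.integers(1, len(exons) - 1))
        skipped = exons[k]
        rest = exons[:k] + exons[k + 1:]
        return SeededIsoform(iid, gene.gene_id, gene.chrom, strand,
                             tuple(rest), ({"type": "ES",
                                            "coordinates": (tuple(skipped),)},))
    if event == "MXE":
        if len(exons) < 4:
            return None
        k = int(rng.integers(1, len(exons) - 2))  # skip exon k+1, keep exon k
        kept, skipped = exons[k], exons[k + 1]
        rest = exons[:k + 1] + exons[k + 2:]
        return SeededIsoform(
            iid, gene.gene_id, gene.chrom, strand, tuple(rest),
            ({"type": "MXE", "coordinates": (tuple(skipped), tuple(kept))},),
        )
    raise ValueError(event)


def _augment_mxe_references(
    genes: list[GeneModel], isoforms: list[SeededIsoform]
) -> list[GeneModel]:
    """Give each MXE gene a second annotated transcript with the
    complementary exon choice (includes the skipped exon, excludes the
    kept neighbour)."""
    mxe = {
        iso.gene_id: iso
        for iso in isoforms
        if any(e["type"] == "MXE" for e in iso.events)
    }
    out = []
    for g in genes:
        iso = mxe.get(g.gene_id)
        if iso is None:
            out.append(g)
            continue
        ev = next(e for e in iso.events if e["type"] == "MXE")
        skipped, kept = (tuple(c) for c in ev["coordinates"])
        main = g.transcripts[0]
        alt_exons = tuple(x for x in main.exons if x != kept)
        alt = TranscriptModel(f"{g.gene_id}.2", alt_exons, g.strand)
        out.append(
            GeneModel(g.gene_id, g.chrom, g.strand, (main, alt))
        )
    return out


def simulate_isoseq(
    manifest: TruthManifest,
    reads_per_isoform: int = 5,
    max_truncation: int = 60,
    seed: int | None = None,
) -> list[tuple[str, TranscriptModel]]:
    """Long-read transcript models: per seeded isoform, ``reads_per_isoform``
    reads with uniform 5' truncation (read 0 full length) that never
    removes an internal junction."""
    seed = manifest.config.seed if seed is None else seed
    rng = _rng_for(seed, "isoseq")
    reads: list[tuple[str, TranscriptModel]] = []
    for iso in manifest.isoforms:
        exons = [tuple(e) for e in iso.exons]
        first_len = exons[0][1] - exons[0][0]
        last_len = exons[-1][1] - exons[-1][0]
        for ri in range(reads_per_isoform):
            ex = [list(e) for e in exons]
            if ri > 0:
                if iso.strand == "+":
                    t = int(rng.integers(0, max(1, min(max_truncation,
                                                       first_len - 10))))
                    ex[0][0] += t
                else:
                    t = int(rng.integers(0, max(1, min(max_truncation,
                                                       last_len - 10))))
                    ex[-1][1] -= t
            reads.append(
                (
                    iso.chrom,
                    TranscriptModel(
                        f"{iso.isoform_id}.r{ri}",
                        tuple(tuple(e) for e in ex),
                        iso.strand,
                    ),
                )
            )
    return reads


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

def _nb_sample(rng, mean: float, dispersion: float, size: int) -> np.ndarray:
    """NB with variance mu + mu^2 * dispersion (gamma-Poisson mixture)."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion, size=size)
    return rng.poisson(lam)


def simulate_coverage(
    manifest: TruthManifest,
    condition: str,
    replicate: int,
) -> CoverageBundle:
    """One replicate library for one condition label.

    Exonic positions draw NB depth around expression x base depth; each
    intron's positions draw NB depth around psi x that mean (exact zeros
    when psi = 0), and its junction count is Binomial over the spliced
    fraction of a Poisson read total.
    """
    cfg = manifest.config
    rng = _rng_for(cfg.seed, "coverage", condition, replicate)
    depth = {c: np.zeros(n, dtype=np.int64)
             for c, n in manifest.chrom_sizes.items()}
    junction_counts: dict[tuple[str, int, int], int] = {}
    introns_by_gene: dict[str, list[IntronRecord]] = {}
    for rec in manifest.introns:
        introns_by_gene.setdefault(rec.parent_gene, []).append(rec)
    for gene in manifest.genes:
        fold = manifest.expression[gene.gene_id].get(condition, 1.0)
        mean = fold * cfg.base_depth
        arr = depth[gene.chrom]
        exonic = np.zeros(arr.size, dtype=bool)
        for t in gene.transcripts:
            for s, e in t.exons:
                exonic[s:e] = True
        span = gene.span
        idx = np.flatnonzero(exonic[span[0]:span[1]]) + span[0]
        arr[idx] = _nb_sample(rng, mean, cfg.nb_dispersion, idx.size)
        for rec in introns_by_gene.get(gene.gene_id, []):
            p = manifest.psi[rec.intron_id][condition]
            body = np.arange(rec.start, rec.end)
            body = body[~exonic[rec.start:rec.end]]
            if p > 0 and body.size:
                arr[body] = _nb_sample(rng, p * mean, cfg.nb_dispersion,
                                       body.size)
            n_reads = rng.poisson(mean)
            junction_counts[(rec.chrom, rec.start, rec.end)] = int(
                rng.binomial(n_reads, 1.0 - p) if n_reads > 0 else 0
            )
    parts = condition.split("|")
    tissue = parts[0]
    stress = parts[1]
    phase = parts[2] if len(parts) > 2 else ""
    return CoverageBundle(
        sample_id=f"{condition.replace('|', '_')}_rep{replicate}",
        tissue=tissue,
        stress=stress,
        phase=phase,
        replicate=replicate,
        depth=depth,
        junction_counts=junction_counts,
    )


def simulate_all_coverage(manifest: TruthManifest) -> list[CoverageBundle]:
    """Replicate bundles for every condition including per-tissue controls."""
    cfg = manifest.config
    bundles = []
    labels = [f"{t}|{CONTROL_LABEL}" for t in cfg.tissues]
    labels += cfg.condition_labels()
    for lab in labels:
        for rep in range(1, cfg.n_replicates + 1):
            bundles.append(simulate_coverage(manifest, lab, rep))
    return bundles


def junction_tsv_rows(bundle: CoverageBundle) -> list[tuple]:
    """Bundle's junction evidence in the 7-column junction-table layout."""
    rows = []
    for (chrom, s, e), n in sorted(bundle.junction_counts.items()):
        if n > 0:
            rows.append((chrom, s, e, ".", n, "other", 0))
    return rows


# ---------------------------------------------------------------------------
# ddPCR
# ---------------------------------------------------------------------------

def simulate_ddpcr(
    true_lambda: dict[tuple[str, str], float],
    droplets_total: int = 20000,
    seed: int = 0,
) -> list[DdpcrWell]:
    """Wells with droplets_positive ~ Binomial(total, 1 - exp(-lambda))."""
    rng = _rng_for(seed, "ddpcr")
    wells = []
    for i, ((condition, target), lam) in enumerate(sorted(true_lambda.items())):
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        p = 1.0 - np.exp(-lam)
        positive = int(rng.binomial(droplets_total, p)) if p > 0 else 0
        wells.append(
            DdpcrWell(
                well_id=f"W{i + 1:03d}",
                target=target,
                condition=condition,
                droplets_total=droplets_total,
                droplets_positive=positive,
            )
        )
    return wells
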