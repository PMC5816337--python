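"""Junction extraction, motif classes, rule filtering, novelty flags."""

import pytest

from dirseq.genes import GeneModel, TranscriptModel
from dirseq.junctions import (
    FilterConfig,
    JunctionRecord,
    annotate_novelty,
    classify_motif,
    classify_motifs,
    extract_junctions,
    filter_junctions,
    reverse_complement,
)


def _jr(start, end, strand="+", count=5, motif="GT/AG", overhang=20):
    return JunctionRecord("chr1", start, end, strand, count,
                          motif_class=motif, max_overhang=overhang)


class TestExtraction:
    def test_tsv_reads_summed_per_distinct_junction(self, tmp_path):
        p = tmp_path / "j.tsv"
        p.write_text(
            "chrom\tstart\tend\tstrand\tread_count\tmotif\tannotated_flag\n"
            "chr1\t100\t200\t+\t2\tGT/AG\t0\n"
            "chr1\t100\t200\t+\t3\tGT/AG\t0\n"
            "chr1\t300\t400\t+\t1\tGT/AG\t0\n"
        )
        records = extract_junctions(str(p))
        assert [(r.start, r.end, r.read_count) for r in records] == [
            (100, 200, 5),
            (300, 400, 1),
        ]

    def test_sam_path_matches_counts_and_overhangs(self, tmp_path):
        sam = tmp_path / "reads.sam"
        lines = ["@HD\tVN:1.6\tSO:coordinate", "@SQ\tSN:chr1\tLN:1000"]
        # two reads over the same 100-200 gap, overhangs 30 and 4
        lines.append("r2\t0\tchr1\t71\t60\t30M100N30M\t*\t0\t0\t" + "A" * 60 + "\t*\tNH:i:1")
        lines.append("r1\t0\tchr1\t97\t60\t4M100N10M\t*\t0\t0\t" + "A" * 14 + "\t*\tNH:i:1")
        # a multi-mapper to be excluded
        lines.append("r3\t0\tchr1\t97\t60\t4M100N4M\t*\t0\t0\t" + "A" * 8 + "\t*\tNH:i:2")
        sam.write_text("\n".join(lines) + "\n")
        records = extract_junctions(str(sam))
        assert len(records) == 1
        rec = records[0]
        assert (rec.start, rec.end) == (100, 200)
        assert rec.read_count == 2
        assert rec.max_overhang == 30

    def test_unsorted_sam_rejected(self, tmp_path):
        sam = tmp_path / "u.sam"
        sam.write_text(
            "@SQ\tSN:chr1\tLN:1000\n"
            "r1\t0\tchr1\t500\t60\t5M50N5M\t*\t0\t0\t" + "A" * 10 + "\t*\n"
            "r2\t0\tchr1\t100\t60\t5M50N5M\t*\t0\t0\t" + "A" * 10 + "\t*\n"
        )
        with pytest.raises(ValueError, match="sorted"):
            extract_junctions(str(sam))

    def test_synthetic_bundle_round_trip_matches_manifest(self, tmp_path, toy_world):
        from dirseq.simulate import simulate_coverage

        _, _, manifest = toy_world
        bundle = simulate_coverage(manifest, "leaf|control", 1)
        p = tmp_path / "j.tsv"
        rows = [
            f"{c}\t{s}\t{e}\t.\t{n}\tother\t0"
            for (c, s, e), n in sorted(bundle.junction_counts.items())
            if n > 0
        ]
        p.write_text(
            "chrom\tstart\tend\tstrand\tread_count\tmotif\tannotated_flag\n"
            + "\n".join(rows) + "\n"
        )
        extracted = {(r.chrom, r.start, r.end) for r in extract_junctions(str(p))}
        truth = {
            (c, s, e) for (c, s, e), n in bundle.junction_counts.items() if n > 0
        }
        assert extracted == truth


class TestMotifs:
    def test_plus_strand_canonical(self):
        genome = {"chr1": "AAAA" + "GT" + "C" * 20 + "AG" + "AAAA"}
        jr = _jr(4, 28)
        assert classify_motif(jr, genome) == "GT/AG"

    def test_minus_strand_forward_ct_ac_is_canonical(self):
        genome = {"chr1": "AAAA" + "CT" + "C" * 20 + "AC" + "AAAA"}
        assert classify_motif(_jr(4, 28, strand="-"), genome) == "GT/AG"

    @pytest.mark.parametrize(
        "donor,acceptor,expected",
        [("AT", "AC", "AT/AC"), ("GC", "AG", "GC/AG"), ("CA", "GG", "other")],
    )
    def test_motif_definitions(self, donor, acceptor, expected):
        genome = {"chr1": "AAAA" + donor + "C" * 20 + acceptor + "AAAA"}
        assert classify_motif(_jr(4, 28), genome) == expected

    def test_strand_symmetry_under_reverse_complement(self, toy_world):
        sequences, _, manifest = toy_world
        for rec in manifest.introns[:40]:
            jr = JunctionRecord(rec.chrom, rec.start, rec.end, rec.strand, 1)
            assert classify_motif(jr, sequences) == manifest.intron_motifs[rec.intron_id]

    def test_unstranded_junction_adopts_motif_strand(self, toy_world):
        sequences, _, manifest = toy_world
        unstranded = [
            JunctionRecord(r.chrom, r.start, r.end, ".", 3)
            for r in manifest.introns
        ]
        classified = classify_motifs(unstranded, sequences)
        for c, r in zip(classified, manifest.introns):
            assert c.strand == r.strand
            assert c.motif_class == manifest.intron_motifs[r.intron_id]

    def test_out_of_bounds_errors(self):
        with pytest.raises(IndexError):
            classify_motif(_jr(4, 9999), {"chr1": "ACGT" * 10})

    def test_reverse_complement(self):
        assert reverse_complement("GTAC") == "GTAC"
        assert reverse_complement("AAGT") == "ACTT"


class TestFilterAndNovelty:
    def test_other_motif_discarded_regardless_of_count(self):
        kept, discarded = filter_junctions([_jr(0, 50, motif="other", count=10)])
        assert kept == [] and len(discarded) == 1

    def test_low_count_discarded_under_default(self):
        kept, _ = filter_junctions([_jr(0, 50, count=1)])
        assert kept == []

    def test_partition_is_exhaustive_and_disjoint_with_seeded_violations(self):
        records = []
        for i in range(100):
            if i < 10:
                records.append(_jr(i * 100, i * 100 + 50, motif="other"))
            elif i < 17:
                records.append(_jr(i * 100, i * 100 + 50, count=1))
            else:
                records.append(_jr(i * 100, i * 100 + 50))
        kept, discarded = filter_junctions(records)
        assert len(kept) == 83
        assert len(kept) + len(discarded) == 100
        assert set(map(id, kept)).isdisjoint(map(id, discarded))

    def test_novelty_requires_exact_intron_match(self):
        tx = TranscriptModel("t", ((0, 100), (200, 300)), "+")
        gene = GeneModel("g", "chr1", "+", (tx,))
        exact = _jr(100, 200)
        shifted = _jr(101, 200)
        out = annotate_novelty([exact, shifted], [gene])
        assert [r.annotated for r in out] == [True, False]

    def test_seeded_perturbations_counted_novel(self, toy_world):
        _, genes, manifest = toy_world
        records = [
            JunctionRecord(r.chrom, r.start, r.end, r.strand, 2)
            for r in manifest.introns[:10]
        ]
        perturbed = [
            JunctionRecord(r.chrom, r.start + 1, r.end, r.strand, 2)
            for r in manifest.introns[10:13]
        ]
        out = annotate_novelty(records + perturbed, genes)
        assert sum(not r.annotated for r in out) == 3
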