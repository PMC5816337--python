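"""Isoform collapsing, AS-event classification, summaries, novel regions."""

import pytest

from dirseq.asevents import (
    Isoform,
    classify_events,
    collapse_isoforms,
    detect_novel_regions,
    isoform_class_counts,
    summarize_event_distribution,
)
from dirseq.genes import GeneModel, TranscriptModel
from dirseq.simulate import SimulationConfig, make_genome, simulate_isoseq


def _tx(name, exons, strand="+"):
    return TranscriptModel(name, tuple(exons), strand)


def _iso(exons, strand="+", name="iso1"):
    return Isoform(name, "chr1", _tx(name, exons, strand))


REF_EXONS = ((0, 100), (200, 300), (400, 500), (600, 700))


def _ref_gene(transcripts=None):
    transcripts = transcripts or (_tx("ref.1", REF_EXONS),)
    return GeneModel("g", "chr1", "+", tuple(transcripts))


class TestCollapse:
    def test_shared_junctions_merge_keeping_outermost_ends(self):
        a = _tx("a", ((0, 100), (200, 300)))
        b = _tx("b", ((50, 100), (200, 320)))
        (iso,) = collapse_isoforms([("chr1", a), ("chr1", b)])
        assert iso.support == 2
        assert iso.model.exons == ((0, 100), (200, 320))

    def test_acceptor_shift_keeps_isoforms_apart(self):
        a = _tx("a", ((0, 100), (200, 300)))
        b = _tx("b", ((0, 100), (203, 300)))
        out = collapse_isoforms([("chr1", a), ("chr1", b)])
        assert len(out) == 2

    def test_single_exon_overlap_merges_same_strand_only(self):
        a = _tx("a", ((0, 500),), "+")
        b = _tx("b", ((400, 900),), "+")
        c = _tx("c", ((450, 800),), "-")
        out = collapse_isoforms([("chr1", a), ("chr1", b), ("chr1", c)])
        assert sorted((i.model.strand, i.support) for i in out) == [("+", 2), ("-", 1)]

    def test_collapse_is_idempotent(self, toy_world):
        _, _, manifest = toy_world
        reads = simulate_isoseq(manifest)
        once = collapse_isoforms(reads)
        twice = collapse_isoforms([(i.chrom, i.model) for i in once])
        assert [i.model.exons for i in twice] == [i.model.exons for i in once]

    def test_manifest_isoform_count_and_supports_recovered(self, toy_world):
        _, _, manifest = toy_world
        reads = simulate_isoseq(manifest, reads_per_isoform=7)
        collapsed = collapse_isoforms(reads)
        assert len(collapsed) == len(manifest.isoforms)
        assert all(i.support == 7 for i in collapsed)
        truth = {iso.isoform_id: tuple(tuple(e) for e in iso.exons)
                 for iso in manifest.isoforms}
        for iso in collapsed:
            key = iso.isoform_id.rsplit(".r", 1)[0]
            assert iso.model.exons == truth[key]


class TestClassification:
    def test_identical_isoform_yields_no_events(self):
        gene = _ref_gene()
        assert classify_events(_iso(REF_EXONS), gene) == []

    def test_intron_retention_inside_one_exon(self):
        gene = _ref_gene()
        iso = _iso(((0, 100), (200, 500), (600, 700)))  # spans exons 2-3
        events = classify_events(iso, gene)
        assert [(e.event_type, e.coordinates) for e in events] == [
            ("IR", ((300, 400),))
        ]

    def test_alt_donor_and_acceptor_in_transcript_orientation(self):
        gene = _ref_gene()
        alt_donor = _iso(((0, 106), (200, 300), (400, 500), (600, 700)))
        assert [e.event_type for e in classify_events(alt_donor, gene)] == ["Alt5"]
        alt_acc = _iso(((0, 100), (194, 300), (400, 500), (600, 700)))
        assert [e.event_type for e in classify_events(alt_acc, gene)] == ["Alt3"]

    def test_minus_strand_swaps_donor_acceptor_roles(self):
        ref = _tx("ref.1", REF_EXONS, "-")
        gene = GeneModel("g", "chr1", "-", (ref,))
        # changing the left (acceptor-side) coordinate of a minus-strand
        # junction is an Alt3 (alternative acceptor) event
        iso = Isoform("i", "chr1", _tx("i", ((0, 106), (200, 300), (400, 500), (600, 700)), "-"))
        assert [e.event_type for e in classify_events(iso, gene)] == ["Alt3"]

    def test_exon_skip_reports_skipped_exon(self):
        gene = _ref_gene()
        iso = _iso(((0, 100), (400, 500), (600, 700)))
        events = classify_events(iso, gene)
        assert [(e.event_type, e.coordinates) for e in events] == [
            ("ES", ((200, 300),))
        ]

    def test_mutually_exclusive_exons_need_complementary_reference(self):
        main = _tx("ref.1", REF_EXONS)
        alt = _tx("ref.2", ((0, 100), (400, 500), (600, 700)))  # skips exon 2
        gene = _ref_gene((main, alt))
        iso = _iso(((0, 100), (200, 300), (600, 700)))  # skips exon 3, keeps 2
        events = classify_events(iso, gene)
        assert [e.event_type for e in events] == ["MXE"]
        assert set(events[0].coordinates) == {(400, 500), (200, 300)}

    def test_strand_mismatch_signals_misassignment(self):
        gene = _ref_gene()
        iso = Isoform("i", "chr1", _tx("i", REF_EXONS, "-"))
        with pytest.raises(ValueError):
            classify_events(iso, gene)

    def test_seeded_events_recovered_exactly(self, toy_world):
        _, genes, manifest = toy_world
        by_gene = {g.gene_id: g for g in genes}
        for seeded in manifest.isoforms:
            iso = Isoform(
                seeded.isoform_id, seeded.chrom,
                _tx(seeded.isoform_id,
                    tuple(tuple(e) for e in seeded.exons), seeded.strand),
            )
            events = classify_events(iso, by_gene[seeded.gene_id])
            assert [e.event_type for e in events] == [
                ev["type"] for ev in seeded.events
            ], seeded.isoform_id

    def test_input_order_never_changes_calls(self, toy_world):
        _, genes, manifest = toy_world
        from dirseq.asevents import classify_all

        reads = simulate_isoseq(manifest)
        fwd = classify_all(collapse_isoforms(reads), genes)
        rev = classify_all(collapse_isoforms(reads[::-1]), genes)
        assert sorted((e.isoform_id, e.event_type, e.coordinates) for e in fwd) == \
            sorted((e.isoform_id, e.event_type, e.coordinates) for e in rev)


class TestSummary:
    def test_reported_class_proportions(self):
        counts = {"IR": 20504, "Alt3": 12658, "Alt5": 9378, "ES": 3288}
        df = summarize_event_distribution(counts).set_index("event_class")
        assert df.loc["IR", "percent"] == 44.7
        assert df.loc["Alt3", "percent"] == 27.6
        assert df.loc["Alt5", "percent"] == 20.5
        assert df.loc["ES", "percent"] == 7.2
        assert abs(df["percent"].sum() - 100.0) <= 0.2

    def test_uniform_counts_split_evenly(self):
        df = summarize_event_distribution(
            {"IR": 1, "Alt3": 1, "Alt5": 1, "ES": 1}
        )
        assert (df["percent"] == 25.0).all()

    def test_mxe_folds_into_es(self):
        df = summarize_event_distribution({"ES": 2, "MXE": 3}).set_index("event_class")
        assert df.loc["ES", "count"] == 5

    def test_empty_input_gives_na_percentages(self):
        df = summarize_event_distribution({})
        assert df["count"].sum() == 0
        assert df["percent"].isna().all()

    def test_seeded_composition_recovered(self, toy_world):
        _, genes, manifest = toy_world
        from dirseq.asevents import classify_all

        isoforms = collapse_isoforms(simulate_isoseq(manifest))
        events = classify_all(isoforms, genes)
        truth = {}
        for iso in manifest.isoforms:
            for ev in iso.events:
                cls = "ES" if ev["type"] == "MXE" else ev["type"]
                truth[cls] = truth.get(cls, 0) + 1
        df = summarize_event_distribution(events).set_index("event_class")
        for cls, n in truth.items():
            assert df.loc[cls, "count"] == n
        # isoform-level tally: one seeded event per isoform, so identical here
        assert isoform_class_counts(events) == {
            c: truth.get(c, 0) for c in ("IR", "Alt3", "Alt5", "ES")
        }


class TestNovelRegions:
    def test_isolated_intergenic_isoform_is_one_region_without_as(self):
        gene = _ref_gene()
        iso = _iso(((10000, 10500), (10700, 11000)), name="far")
        (region,) = detect_novel_regions([iso], [gene])
        assert not region.has_AS
        assert (region.start, region.end) == (10000, 11000)

    def test_two_overlapping_isoforms_with_different_donor_have_as(self):
        gene = _ref_gene()
        a = _iso(((10000, 10500), (10700, 11000)), name="a")
        b = _iso(((10000, 10508), (10700, 11000)), name="b")
        (region,) = detect_novel_regions([a, b], [gene])
        assert region.has_AS

    def test_gene_overlapping_isoform_excluded(self):
        gene = _ref_gene()
        iso = _iso(((50, 150), (400, 450)), name="inside")
        assert detect_novel_regions([iso], [gene]) == []

    def test_seeded_intergenic_loci_counted(self):
        gene = _ref_gene()
        isoforms = []
        n_as = 0
        for k in range(5):
            base = 10000 + k * 5000
            isoforms.append(_iso(((base, base + 400), (base + 600, base + 900)),
                                 name=f"L{k}a"))
            if k < 2:
                isoforms.append(
                    _iso(((base, base + 407), (base + 600, base + 900)),
                         name=f"L{k}b")
                )
                n_as += 1
        regions = detect_novel_regions(isoforms, [gene])
        assert len(regions) == 5
        assert sum(r.has_AS for r in regions) == n_as

    def test_coding_capacity_by_orf_rule(self):
        gene = _ref_gene()
        iso = _iso(((10000, 10400),), name="orf")
        seq = ["A"] * 20000
        start = 10010
        seq[start:start + 3] = list("ATG")
        for i in range(start + 3, start + 3 + 100 * 3, 3):
            seq[i:i + 3] = list("GGG")
        stop = start + 3 + 100 * 3
        seq[stop:stop + 3] = list("TAA")
        genome = {"chr1": "".join(seq)}
        (coding,) = detect_novel_regions([iso], [gene], genome, min_orf_codons=100)
        assert coding.coding_capacity == "coding"
        (noncoding,) = detect_novel_regions([iso], [gene], genome,
                                            min_orf_codons=200)
        assert noncoding.coding_capacity == "noncoding"
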