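"""Intron retention measurement, the adjusted-LFC statistic, DIR calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dirseq.dircall import (
    CoverageBundle,
    adjusted_lfc,
    call_dirs,
    dir_gene_sets,
    dir_test,
    expression_filter,
    measure_intron,
    set_intersections,
    splicing_ratio_difference,
    summarize_dir_calls,
)
from dirseq.genes import GeneModel, IntronRecord, TranscriptModel
from dirseq.simulate import SimulationConfig, make_genome, simulate_all_coverage


def _bundle(depth, junctions, sample_id="s1", stress="control"):
    return CoverageBundle(
        sample_id=sample_id, tissue="leaf", stress=stress, phase="short",
        replicate=1, depth={"chr1": np.asarray(depth)},
        junction_counts=junctions,
    )


INTRON = IntronRecord("g.i1", "chr1", 10, 30, "+", "g", 1)


class TestMeasure:
    def test_uniform_depth_over_junction_reads(self):
        b = _bundle([0] * 10 + [10] * 20 + [0] * 10, {("chr1", 10, 30): 20})
        m = measure_intron(b, INTRON)
        assert m.mean_depth == 10.0
        assert m.ir_ratio == 0.5

    def test_zero_depth_gives_zero_ratio(self):
        b = _bundle([0] * 40, {("chr1", 10, 30): 7})
        assert measure_intron(b, INTRON).ir_ratio == 0.0

    def test_no_junction_support_flagged_with_pseudo_denominator(self):
        b = _bundle([0] * 10 + [4] * 20 + [0] * 10, {})
        m = measure_intron(b, INTRON)
        assert m.no_splice_support
        assert m.ir_ratio == 4.0

    def test_unscored_when_no_evidence_at_all(self):
        b = _bundle([0] * 40, {})
        assert measure_intron(b, INTRON).ir_ratio is None

    def test_missing_chrom_names_intron(self):
        b = CoverageBundle("s", "leaf", "control", "", 1, {}, {})
        with pytest.raises(KeyError, match="g.i1"):
            measure_intron(b, INTRON)

    @given(st.integers(min_value=1, max_value=50))
    @settings(deadline=None, max_examples=20)
    def test_ratio_scale_invariant(self, k):
        base = _bundle([0] * 10 + [6] * 20 + [0] * 10, {("chr1", 10, 30): 12})
        scaled = _bundle(
            [0] * 10 + [6 * k] * 20 + [0] * 10, {("chr1", 10, 30): 12 * k}
        )
        assert measure_intron(base, INTRON).ir_ratio == pytest.approx(
            measure_intron(scaled, INTRON).ir_ratio
        )

    def test_ratio_difference_antisymmetric(self):
        assert splicing_ratio_difference(0.5, 0.5) == 0.0
        assert splicing_ratio_difference(0.8, 0.2) == pytest.approx(0.6)
        assert splicing_ratio_difference(0.2, 0.8) == pytest.approx(-0.6)

    def test_inclusion_odds_identity_on_simulated_intron(self):
        from dirseq.simulate import SimulationConfig, make_genome, simulate_coverage
        from dirseq.genes import enumerate_introns

        cfg = SimulationConfig(
            n_genes=4, seed=9, tissues=("leaf",), stresses=("salt",),
            phases=("short",), psi_control=0.3, base_depth=100.0,
            dir_fraction=0.0,
        )
        _, genes, manifest = make_genome(cfg)
        intron = enumerate_introns(genes[0])[0]
        ratios = []
        for rep in range(1, 51):
            b = simulate_coverage(manifest, "leaf|control", rep)
            m = measure_intron(b, intron)
            ratios.append(m.ir_ratio)
        odds = 0.3 / 0.7
        assert np.mean(ratios) == pytest.approx(odds, rel=0.1)


class TestAdjustedLFC:
    def test_equal_replicates_give_zero_for_every_pseudocount(self):
        alfc, c = adjusted_lfc([10, 10, 10], [10, 10, 10])
        assert alfc == 0.0

    def test_pseudo_count_shrinks_raw_lfc_magnitude(self):
        grid = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
        a, b = 40.0, 10.0
        raw = [abs(math.log2((a + c) / (b + c))) for c in grid]
        assert all(x <= raw[0] + 1e-12 for x in raw)  # non-increasing map
        _, selected = adjusted_lfc([a], [b], grid)
        assert selected in grid

    def test_seeded_fold_increase_has_positive_sign(self):
        rng = np.random.default_rng(1)
        signs = []
        for _ in range(500):
            lam_c = rng.gamma(10, 10, 3)  # NB dispersion 0.1 around 100
            lam_t = rng.gamma(10, 40, 3)  # 4-fold up
            c = rng.poisson(lam_c)
            t = rng.poisson(lam_t)
            alfc, _ = adjusted_lfc(t, c)
            signs.append(alfc > 0)
        assert np.mean(signs) >= 0.99

    def test_empty_replicates_error(self):
        with pytest.raises(ValueError):
            adjusted_lfc([], [1.0])


class TestDirTest:
    def test_identical_values_give_p_one(self):
        assert dir_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_label_swap_symmetry(self):
        x = [0.1, 0.4, 0.3]
        y = [0.9, 1.3, 1.1]
        assert dir_test(x, y) == pytest.approx(dir_test(y, x))

    def test_permutation_path_with_single_replicate_side(self):
        p = dir_test([0.1, 0.2, 0.15, 0.12, 0.18], [5.0])
        assert p is not None and 0 < p <= 1

    def test_insufficient_replicates_return_none(self):
        assert dir_test([1.0], [2.0]) is None

    def test_null_type_one_error_near_nominal(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n = 2000
        for _ in range(n):
            x = rng.normal(size=3)
            y = rng.normal(size=3)
            rejections += dir_test(x, y) < 0.05
        assert 0.02 <= rejections / n <= 0.07


class TestExpressionFilter:
    @pytest.mark.parametrize(
        "fc,expected", [(4.9, True), (5.1, False), (0.19, False), (0.21, True)]
    )
    def test_fivefold_threshold_both_directions(self, fc, expected):
        assert expression_filter(1.0, fc) is expected

    def test_nonpositive_expression_errors(self):
        with pytest.raises(ValueError):
            expression_filter(0.0, 1.0)

    def test_seeded_expression_changes_excluded_from_calls(self):
        # modest changed fraction: with CPM library scaling, a large share of
        # strongly shifted genes moves the library total itself and compresses
        # every measured fold, so exact exclusion needs the total stable
        cfg = SimulationConfig(
            n_genes=30, seed=21, tissues=("leaf",), stresses=("salt",),
            phases=("short",), expression_changed_fraction=0.1,
            expression_changed_fold=8.0, dir_fraction=0.0,
        )
        _, genes, manifest = make_genome(cfg)
        bundles = simulate_all_coverage(manifest)
        results = call_dirs(bundles, genes)
        changed = {
            g for g, per in manifest.expression.items()
            if any(f != 1.0 for f in per.values())
        }
        by_gene = results.groupby("gene_id")["passed_expression_filter"].any()
        for gene_id, passed in by_gene.items():
            assert passed == (gene_id not in changed)


@pytest.fixture(scope="module")
def calls():
    cfg = SimulationConfig(
        n_genes=40, seed=13, tissues=("leaf",), stresses=("cold", "salt"),
        phases=("short",), base_depth=100.0, dir_fraction=0.25,
    )
    _, genes, manifest = make_genome(cfg)
    bundles = simulate_all_coverage(manifest)
    return manifest, call_dirs(bundles, genes)


class TestCallDirsBookkeeping:
    def test_summary_matches_brute_force_set_arithmetic(self, calls):
        _, results = calls
        summary = summarize_dir_calls(results).set_index("condition")
        sig = results[results["significant"]]
        for cond, grp in sig.groupby("condition"):
            pairs = set(zip(grp["gene_id"], grp["intron_id"]))
            genes = {g for g, _ in pairs}
            multi = {
                g for g in genes
                if sum(1 for gg, _ in pairs if gg == g) >= 2
            }
            assert summary.loc[cond, "dir_events"] == len(pairs)
            assert summary.loc[cond, "unique_loci"] == len(genes)
            assert summary.loc[cond, "multi_dir_loci"] == len(multi)
        all_pairs = set(zip(sig["gene_id"], sig["intron_id"]))
        assert summary.loc["ALL", "dir_events"] == len(all_pairs)

    def test_bh_adjustment_monotone_in_p_rank(self, calls):
        _, results = calls
        for _, grp in results.dropna(subset=["p_adj"]).groupby("condition"):
            g = grp.sort_values("p_value")
            assert (g["p_adj"].to_numpy() >= g["p_value"].to_numpy() - 1e-12).all()
            assert (np.diff(g["p_adj"].to_numpy()) >= -1e-12).all()

    def test_direction_consistent_with_alfc_sign(self, calls):
        _, results = calls
        up = results["direction"] == "increased IR"
        assert ((results["alfc"] > 0) == up).all()

    def test_shared_seeded_loci_appear_in_intersection_report(self, calls):
        manifest, results = calls
        sets = dir_gene_sets(results, by="stress")
        report = set_intersections(sets).set_index("combination")
        both_truth = {
            d["gene_id"] for d in manifest.true_dirs.values()
            if set(d["stresses"]) == {"cold", "salt"}
        }
        shared = sets.get("cold", set()) & sets.get("salt", set())
        assert report.loc["cold&salt", "shared_genes"] == len(shared)
        # every seeded both-stress locus that was called at all in both shows up
        assert both_truth & sets.get("cold", set()) & sets.get("salt", set()) <= shared
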