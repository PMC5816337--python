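"""Self-validation experiments on synthetic ground truth.

Each function runs one calibration or recovery experiment end to end —
generate data from the truth manifest, run the corresponding pipeline
stage, score against the manifest — and returns plain numbers. They back
both the package's acceptance checks and reproducibility reports.

Problem sizes are desk-scale by design: a few hundred genes, hundreds to
a thousand introns, tens of seeds; large enough for stable Monte-Carlo
estimates of rates while keeping a full run in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .asevents import Isoform, classify_events, summarize_event_distribution
from .coreg import coreg_significance
from .ddpcr import poisson_lambda
from .dircall import call_dirs, measure_intron, summarize_dir_calls
from .genes import TranscriptModel, enumerate_introns
from .simulate import (
    SimulationConfig,
    make_genome,
    simulate_all_coverage,
    simulate_coverage,
    simulate_ddpcr,
)


def as_class_percentages(counts: dict[str, int]) -> dict[str, float]:
    """Per-class AS percentages from per-class isoform counts."""
    df = summarize_event_distribution(counts).set_index("event_class")
    return {cls: float(df.loc[cls, "percent"]) for cls in df.index}


def classifier_accuracy(n_isoforms: int = 500, seed: int = 0) -> dict:
    """Precision/recall of event classification on seeded single-event
    isoforms spanning all five event classes (MXE kept distinct here)."""
    n_genes = n_isoforms + max(10, n_isoforms // 10)
    cfg = SimulationConfig(
        n_genes=n_genes, seed=seed, exons_per_gene=(4, 8)
    )
    _, genes, manifest = make_genome(cfg)
    by_gene = {g.gene_id: g for g in genes}
    seeded = manifest.isoforms[:n_isoforms]
    tp = fp = fn = 0
    for iso in seeded:
        model = TranscriptModel(
            iso.isoform_id, tuple(tuple(e) for e in iso.exons), iso.strand
        )
        events = classify_events(
            Isoform(iso.isoform_id, iso.chrom, model), by_gene[iso.gene_id]
        )
        called = [e.event_type for e in events]
        wanted = [e["type"] for e in iso.events]
        for w in wanted:
            if w in called:
                tp += 1
                called.remove(w)
            else:
                fn += 1
        fp += len(called)
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {"precision": precision, "recall": recall, "n": len(seeded)}


def _single_comparison_config(seed: int, n_genes: int, **kw) -> SimulationConfig:
    return SimulationConfig(
        n_genes=n_genes, seed=seed, tissues=("leaf",), stresses=("salt",),
        phases=("short",), base_depth=100.0, **kw,
    )


def dir_null_calibration(
    n_seeds: int = 20, n_genes: int = 230, seed: int = 0
) -> dict:
    """Type-I error of the DIR pipeline on equal-inclusion simulations.

    3 vs 3 replicates; reports the raw p < 0.05 rejection fraction pooled
    over all introns and seeds, and the empirical FDR after BH (mean over
    seeds of V / max(R, 1); every discovery is false under the null).
    """
    rejections = total = 0
    fdr_terms = []
    for k in range(n_seeds):
        cfg = _single_comparison_config(seed + 1000 + k, n_genes,
                                        dir_fraction=0.0)
        _, genes, manifest = make_genome(cfg)
        bundles = simulate_all_coverage(manifest)
        res = call_dirs(bundles, genes)
        p = res["p_value"].dropna()
        rejections += int((p < 0.05).sum())
        total += len(p)
        n_called = int(res["significant"].sum())
        fdr_terms.append(1.0 if n_called > 0 else 0.0)
    return {
        "raw_rejection_rate": rejections / total,
        "empirical_fdr": float(np.mean(fdr_terms)),
        "n_tests": total,
        "n_seeds": n_seeds,
    }


def dir_power(
    seed: int = 0, n_genes: int = 120, delta_psi: float = 0.3
) -> dict:
    """Recovery of seeded DIRs (delta psi 0.3, depth 100, 3 vs 3)."""
    cfg = _single_comparison_config(seed + 5000, n_genes,
                                    dir_fraction=0.25, delta_psi=delta_psi)
    _, genes, manifest = make_genome(cfg)
    bundles = simulate_all_coverage(manifest)
    res = call_dirs(bundles, genes)
    res = res.assign(key=list(zip(res["start"], res["end"])))
    truth = {
        (d["start"], d["end"]): d["direction"]
        for d in manifest.true_dirs.values()
    }
    sig = res[res["significant"]]
    tp = sig[sig["key"].isin(truth)]
    recall = len(tp) / len(truth) if truth else float("nan")
    direction_acc = (
        float(np.mean([truth[k] == d for k, d in zip(tp["key"], tp["direction"])]))
        if len(tp)
        else float("nan")
    )
    return {
        "recall": recall,
        "direction_accuracy": direction_acc,
        "n_true": len(truth),
        "n_called": int(len(sig)),
    }


def ir_ratio_identity(
    seed: int = 0, psi: float = 0.3, depth: float = 500.0, n_reps: int = 100
) -> dict:
    """Convergence of the empirical IR ratio to the odds psi/(1 - psi)."""
    cfg = SimulationConfig(
        n_genes=3, seed=seed + 7000, tissues=("leaf",), stresses=("salt",),
        phases=("short",), psi_control=psi, base_depth=depth,
        dir_fraction=0.0,
    )
    _, genes, manifest = make_genome(cfg)
    intron = enumerate_introns(genes[0])[0]
    ratios = [
        measure_intron(simulate_coverage(manifest, "leaf|control", r),
                       intron).ir_ratio
        for r in range(1, n_reps + 1)
    ]
    odds = psi / (1.0 - psi)
    rel_error = abs(float(np.mean(ratios)) - odds) / odds
    return {"relative_error": rel_error, "odds": odds, "n": n_reps}


def bookkeeping_consistency(seed: int = 0, n_genes: int = 60) -> dict:
    """Pipeline Table-1-style tallies versus brute-force set arithmetic."""
    cfg = SimulationConfig(
        n_genes=n_genes, seed=seed + 9000, tissues=("leaf", "root"),
        stresses=("cold", "salt"), phases=("short",), base_depth=100.0,
        dir_fraction=0.25,
    )
    _, genes, manifest = make_genome(cfg)
    bundles = simulate_all_coverage(manifest)
    res = call_dirs(bundles, genes)
    summary = summarize_dir_calls(res).set_index("condition")
    sig = res[res["significant"]]
    mismatches = 0
    checks = 0
    for cond, grp in sig.groupby("condition"):
        pairs = set(zip(grp["gene_id"], grp["intron_id"]))
        loci = {g for g, _ in pairs}
        multi = {g for g in loci if sum(1 for gg, _ in pairs if gg == g) >= 2}
        expected = (len(pairs), len(loci), len(multi))
        got = (
            int(summary.loc[cond, "dir_events"]),
            int(summary.loc[cond, "unique_loci"]),
            int(summary.loc[cond, "multi_dir_loci"]),
        )
        checks += 3
        mismatches += sum(a != b for a, b in zip(expected, got))
    return {"mismatches": mismatches, "checks": checks,
            "n_events": int(summary.loc["ALL", "dir_events"])}


def cluster_null_calibration(
    n_clusters: int = 200, n_permutations: int = 200, seed: int = 0
) -> dict:
    """Rejection rate of the coherence permutation test on random rows."""
    rng = np.random.default_rng(seed + 11000)
    rejections = 0
    for _ in range(n_clusters):
        mat = pd.DataFrame(rng.normal(size=(4, 12)))
        p = coreg_significance(mat, n_permutations=n_permutations, rng=rng)
        rejections += p < 0.05
    return {"rejection_rate": rejections / n_clusters, "n": n_clusters}


def cluster_power(
    n_seeds: int = 20, n_permutations: int = 400, seed: int = 0
) -> dict:
    """Detection of seeded coherent clusters (pairwise r ~ 0.9, 6 members,
    12 conditions) at p < 0.05."""
    rng = np.random.default_rng(seed + 13000)
    detected = 0
    for _ in range(n_seeds):
        archetype = rng.normal(size=12)
        rows = [archetype + rng.normal(size=12) * 0.33 for _ in range(6)]
        mat = pd.DataFrame(rows)
        p = coreg_significance(mat, n_permutations=n_permutations, rng=rng)
        detected += p < 0.05
    return {"detection_rate": detected / n_seeds, "n": n_seeds}


def ddpcr_roundtrip(
    true_lambda: float = 0.4, droplets: int = 20000, n_seeds: int = 100,
    seed: int = 0,
) -> dict:
    """Mean recovered occupancy over simulated wells, plus the closed-form
    half-positive check (lambda = ln 2)."""
    estimates = []
    for k in range(n_seeds):
        (well,) = simulate_ddpcr(
            {("c", "t"): true_lambda}, droplets, seed=seed + 15000 + k
        )
        estimates.append(poisson_lambda(well.droplets_positive, droplets))
    mean = float(np.mean(estimates))
    half_lambda = poisson_lambda(10000, 20000)
    return {
        "relative_error": abs(mean - true_lambda) / true_lambda,
        "mean_lambda": mean,
        "true_lambda": true_lambda,
        "half_positive_lambda": half_lambda,
        "n": n_seeds,
    }
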