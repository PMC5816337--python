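"""Differential intron retention (DIR) statistics.

The retention of an intron in one sample is summarised by its relative IR
score r = (mean per-base read depth over the intron) / (reads supporting
the intron's spliced junction) — a retention:splicing odds. A DIR call
between a treatment and its control combines:

* an adjusted log-fold change aLFC(c) = log2((m_t + c) / (m_c + c)) / SE,
  where m are replicate-mean normalized intron depths, c a pseudo-count
  chosen from a grid to minimise |aLFC|, and SE the pooled standard error
  of replicate log2(depth + c) values floored at a small epsilon;
* a two-sided Welch t-test on replicate log2((intron depth + 1) /
  (gene expression + 1)), normalising retention change for expression
  change, with Benjamini-Hochberg adjustment within each comparison;
* a fivefold expression filter excluding genes whose overall expression
  moves more than ``max_fold`` between the conditions;
* the splicing-ratio difference dr = r_control - r_treatment.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genes import GeneModel, IntronRecord, enumerate_introns

log = logging.getLogger(__name__)

DEFAULT_PSEUDO_GRID = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
SE_FLOOR = 0.05
CONTROL_LABEL = "control"


@dataclass
class CoverageBundle:
    """Per-base depth and junction counts for one sequencing library."""

    sample_id: str
    tissue: str
    stress: str  # CONTROL_LABEL marks the untreated reference
    phase: str
    replicate: int
    depth: dict[str, np.ndarray]
    junction_counts: dict[tuple[str, int, int], int]

    @property
    def is_control(self) -> bool:
        return self.stress == CONTROL_LABEL

    @property
    def condition(self) -> str:
        if self.is_control:
            return f"{self.tissue}|{CONTROL_LABEL}"
        return f"{self.tissue}|{self.stress}|{self.phase}"

    def total_aligned_bases(self) -> float:
        return float(sum(int(a.sum()) for a in self.depth.values()))

    def scale(self) -> float:
        """Counts-per-million-aligned-bases library scaling factor."""
        total = self.total_aligned_bases()
        return 1e6 / total if total > 0 else 1.0


@dataclass(frozen=True)
class IntronMeasure:
    intron_id: str
    sample_id: str
    mean_depth: float
    junction_reads: int
    ir_ratio: float | None
    no_splice_support: bool = False


@dataclass(frozen=True)
class DIRResult:
    intron_id: str
    gene_id: str
    condition: str
    alfc: float
    pseudo_count: float
    p_value: float | None
    p_adj: float | None
    direction: str  # 'increased IR' | 'decreased IR'
    ratio_difference: float
    passed_expression_filter: bool

    @property
    def significant(self) -> bool:
        return (
            self.passed_expression_filter
            and self.p_adj is not None
            and self.p_adj < 0.05
        )


# ---------------------------------------------------------------------------
# per-sample measurement
# ---------------------------------------------------------------------------

def measure_intron(
    bundle: CoverageBundle, intron: IntronRecord, scale: float = 1.0
) -> IntronMeasure:
    """Mean depth, junction support and IR ratio of one intron in one sample.

    When the spliced junction has no supporting reads but the intron has
    coverage, the ratio uses a pseudo-denominator of 1 and is flagged; with
    neither coverage nor junction reads the intron is unscored (ratio None).
    """
    if intron.chrom not in bundle.depth:
        raise KeyError(
            f"intron {intron.intron_id}: chrom {intron.chrom} absent from "
            f"bundle {bundle.sample_id}"
        )
    arr = bundle.depth[intron.chrom]
    if intron.end > arr.size:
        raise KeyError(
            f"intron {intron.intron_id} extends past coverage of "
            f"bundle {bundle.sample_id}"
        )
    mean_depth = float(arr[intron.start:intron.end].mean()) * scale
    jr = int(bundle.junction_counts.get(
        (intron.chrom, intron.start, intron.end), 0
    ))
    if jr > 0:
        ratio: float | None = mean_depth / (jr * scale)
        flag = False
    elif mean_depth > 0:
        ratio = mean_depth / (1.0 * scale)
        flag = True
    else:
        ratio = None
        flag = False
    return IntronMeasure(
        intron_id=intron.intron_id,
        sample_id=bundle.sample_id,
        mean_depth=mean_depth,
        junction_reads=jr,
        ir_ratio=ratio,
        no_splice_support=flag,
    )


def splicing_ratio_difference(r_control: float, r_treatment: float) -> float:
    """dr = r_control - r_treatment (antisymmetric under swap)."""
    return float(r_control) - float(r_treatment)


# ---------------------------------------------------------------------------
# the adjusted log-fold-change statistic
# ---------------------------------------------------------------------------

def adjusted_lfc(
    depth_treatment: Sequence[float],
    depth_control: Sequence[float],
    pseudo_grid: Sequence[float] = DEFAULT_PSEUDO_GRID,
    se_floor: float = SE_FLOOR,
) -> tuple[float, float]:
    """Pseudo-count-adjusted log-fold change of intron coverage.

    For each candidate pseudo-count c, aLFC(c) = log2((m_t + c)/(m_c + c))
    divided by the pooled standard error of replicate log2(depth + c)
    values (floored at ``se_floor``); the (aLFC, c) pair of minimal |aLFC|
    over the grid is returned — a conservative effect size.
    """
    t = np.asarray(depth_treatment, dtype=float)
    c_ = np.asarray(depth_control, dtype=float)
    if t.size == 0 or c_.size == 0:
        raise ValueError("adjusted_lfc requires >=1 replicate per side")
    if not len(pseudo_grid):
        raise ValueError("pseudo-count grid is empty")
    best: tuple[float, float] | None = None
    for c in pseudo_grid:
        if c <= 0:
            raise ValueError("pseudo-counts must be > 0")
        lfc = math.log2((t.mean() + c) / (c_.mean() + c))
        se = _pooled_se(np.log2(t + c), np.log2(c_ + c), se_floor)
        alfc = lfc / se
        if best is None or abs(alfc) < abs(best[0]):
            best = (alfc, float(c))
    assert best is not None
    return best


def _pooled_se(a: np.ndarray, b: np.ndarray, floor: float) -> float:
    va = a.var(ddof=1) / a.size if a.size > 1 else 0.0
    vb = b.var(ddof=1) / b.size if b.size > 1 else 0.0
    return max(math.sqrt(va + vb), floor)


# ---------------------------------------------------------------------------
# hypothesis test
# ---------------------------------------------------------------------------

def dir_test(
    values_control: Sequence[float], values_treatment: Sequence[float]
) -> float | None:
    """Two-sided p-value for equal expression-normalized intron retention.

    Welch t-test on the replicate-level statistics when both sides have
    >= 2 replicates; exact permutation of condition labels (difference of
    means) when one side has a single replicate but >= 6 exchangeable units
    exist; otherwise None with a warning.
    """
    x = np.asarray(values_control, dtype=float)
    y = np.asarray(values_treatment, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("dir_test requires >=1 replicate per side")
    pooled = np.concatenate([x, y])
    if np.allclose(pooled, pooled[0]):
        return 1.0  # exchangeable by construction
    if x.size >= 2 and y.size >= 2:
        t, p = stats.ttest_ind(y, x, equal_var=False)
        if math.isnan(p):  # zero variance on both sides, unequal means
            return 0.0 if not np.allclose(x.mean(), y.mean()) else 1.0
        return float(p)
    if pooled.size >= 6:
        return _permutation_p(x, y)
    log.warning("dir_test: insufficient replicates (%d vs %d)", x.size, y.size)
    return None


def _permutation_p(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    n = pooled.size
    obs = abs(y.mean() - x.mean())
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), x.size):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        d = abs(pooled[~mask].mean() - pooled[mask].mean())
        if d >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def expression_filter(
    expr_control: float, expr_treatment: float, max_fold: float = 5.0
) -> bool:
    """True iff expression changes at most ``max_fold`` in either direction."""
    if expr_control <= 0 or expr_treatment <= 0:
        raise ValueError("expression values must be > 0")
    fc = expr_treatment / expr_control
    return max(fc, 1.0 / fc) <= max_fold


# ---------------------------------------------------------------------------
# full DIR calling
# ---------------------------------------------------------------------------

def gene_expression(bundle: CoverageBundle, gene: GeneModel,
                    scale: float | None = None) -> float:
    """Normalized gene expression: mean depth over the exonic union."""
    if scale is None:
        scale = bundle.scale()
    arr = bundle.depth[gene.chrom]
    mask = np.zeros(arr.size, dtype=bool)
    for t in gene.transcripts:
        for s, e in t.exons:
            mask[s:e] = True
    total = int(mask.sum())
    return float(arr[mask].mean()) * scale if total else 0.0


def call_dirs(
    bundles: Sequence[CoverageBundle],
    genes: Sequence[GeneModel],
    alpha: float = 0.05,
    max_fold: float = 5.0,
    pseudo_grid: Sequence[float] = DEFAULT_PSEUDO_GRID,
    min_intron_length: int = 20,
) -> pd.DataFrame:
    """Call DIRs for every treatment condition against its tissue control.

    Returns one row per intron per comparison with aLFC, pseudo-count,
    p-value, BH-adjusted p-value (within comparison), direction, splicing
    ratio difference and the expression-filter flag. Introns unscored in
    every replicate of a side are dropped from that comparison.
    """
    controls: dict[str, list[CoverageBundle]] = {}
    treatments: dict[tuple[str, str, str], list[CoverageBundle]] = {}
    for b in bundles:
        if b.is_control:
            controls.setdefault(b.tissue, []).append(b)
        else:
            treatments.setdefault((b.tissue, b.stress, b.phase), []).append(b)

    intron_index: list[tuple[GeneModel, IntronRecord]] = [
        (g, i)
        for g in genes
        for i in enumerate_introns(g, min_length=min_intron_length)
    ]

    # gene expression once per (bundle, gene), exon masks once per gene
    scale_of = {b.sample_id: b.scale() for b in bundles}
    expr: dict[str, dict[str, float]] = {b.sample_id: {} for b in bundles}
    for g in genes:
        idx_cache: dict[str, np.ndarray] = {}
        for b in bundles:
            if g.chrom not in idx_cache:
                mask = np.zeros(b.depth[g.chrom].size, dtype=bool)
                for t in g.transcripts:
                    for s, e in t.exons:
                        mask[s:e] = True
                idx_cache[g.chrom] = np.flatnonzero(mask)
            idx = idx_cache[g.chrom]
            mean = float(b.depth[g.chrom][idx].mean()) if idx.size else 0.0
            expr[b.sample_id][g.gene_id] = mean * scale_of[b.sample_id]

    rows: list[dict] = []
    for key in sorted(treatments):
        tissue, stress, phase = key
        ctrl = controls.get(tissue)
        if not ctrl:
            raise ValueError(f"no control bundles for tissue {tissue}")
        trt = treatments[key]
        condition = f"{tissue}|{stress}|{phase}"
        scales_c = [scale_of[b.sample_id] for b in ctrl]
        scales_t = [scale_of[b.sample_id] for b in trt]
        n_shared = 0
        for gene, intron in intron_index:
            m_c = [measure_intron(b, intron, s) for b, s in zip(ctrl, scales_c)]
            m_t = [measure_intron(b, intron, s) for b, s in zip(trt, scales_t)]
            if all(m.ir_ratio is None for m in m_c) and all(
                m.ir_ratio is None for m in m_t
            ):
                continue
            n_shared += 1
            e_c = [expr[b.sample_id][gene.gene_id] for b in ctrl]
            e_t = [expr[b.sample_id][gene.gene_id] for b in trt]
            mean_ec, mean_et = float(np.mean(e_c)), float(np.mean(e_t))
            try:
                passed = expression_filter(mean_ec, mean_et, max_fold)
            except ValueError:
                passed = False
            d_c = [m.mean_depth for m in m_c]
            d_t = [m.mean_depth for m in m_t]
            alfc, c_sel = adjusted_lfc(d_t, d_c, pseudo_grid)
            x_c = [
                math.log2((d + 1.0) / (e + 1.0)) for d, e in zip(d_c, e_c)
            ]
            x_t = [
                math.log2((d + 1.0) / (e + 1.0)) for d, e in zip(d_t, e_t)
            ]
            p = dir_test(x_c, x_t)
            r_c = [m.ir_ratio for m in m_c if m.ir_ratio is not None]
            r_t = [m.ir_ratio for m in m_t if m.ir_ratio is not None]
            dr = (
                splicing_ratio_difference(float(np.mean(r_c)), float(np.mean(r_t)))
                if r_c and r_t
                else float("nan")
            )
            rows.append(
                {
                    "intron_id": intron.intron_id,
                    "gene_id": gene.gene_id,
                    "chrom": intron.chrom,
                    "start": intron.start,
                    "end": intron.end,
                    "tissue": tissue,
                    "stress": stress,
                    "phase": phase,
                    "condition": condition,
                    "alfc": alfc,
                    "pseudo_count": c_sel,
                    "p_value": p,
                    "direction": "increased IR" if alfc > 0 else "decreased IR",
                    "ratio_difference": dr,
                    "passed_expression_filter": passed,
                }
            )
        if n_shared == 0:
            raise ValueError(f"comparison {condition}: no shared introns")

    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df["p_adj"] = np.nan
    for cond, grp in df.groupby("condition"):
        testable = grp["passed_expression_filter"] & grp["p_value"].notna()
        idx = grp.index[testable]
        if len(idx):
            df.loc[idx, "p_adj"] = multipletests(
                df.loc[idx, "p_value"], method="fdr_bh"
            )[1]
    df["significant"] = (
        df["passed_expression_filter"] & (df["p_adj"] < alpha)
    ).fillna(False)
    return df


# ---------------------------------------------------------------------------
# bookkeeping summaries (per-treatment tallies and set intersections)
# ---------------------------------------------------------------------------

def summarize_dir_calls(results: pd.DataFrame) -> pd.DataFrame:
    """Per-comparison tallies: events, unique loci, loci with >= 2 DIRs."""
    rows = []
    for cond, grp in results[results["significant"]].groupby("condition"):
        per_gene = grp.groupby("gene_id")["intron_id"].nunique()
        rows.append(
            {
                "condition": cond,
                "dir_events": int(grp["intron_id"].nunique()),
                "unique_loci": int(per_gene.size),
                "multi_dir_loci": int((per_gene >= 2).sum()),
            }
        )
    sig = results[results["significant"]]
    per_gene_all = sig.groupby("gene_id")["intron_id"].nunique()
    rows.append(
        {
            "condition": "ALL",
            "dir_events": int(
                sig[["gene_id", "intron_id"]].drop_duplicates().shape[0]
            ),
            "unique_loci": int(per_gene_all.size),
            "multi_dir_loci": int((per_gene_all >= 2).sum()),
        }
    )
    return pd.DataFrame(rows)


def dir_gene_sets(results: pd.DataFrame, by: str = "stress") -> dict[str, set]:
    """Significant-DIR gene sets keyed by a grouping column (e.g. stress)."""
    sig = results[results["significant"]]
    return {
        str(k): set(grp["gene_id"]) for k, grp in sig.groupby(by)
    }


def set_intersections(sets: Mapping[str, set]) -> pd.DataFrame:
    """Exclusive Venn-region sizes for every non-empty label combination."""
    labels = sorted(sets)
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(
                *(sets[l] for l in labels if l not in combo), set()
            )
            exclusive = inside - outside
            rows.append(
                {
                    "combination": "&".join(combo),
                    "degree": r,
                    "shared_genes": len(inside),
                    "exclusive_genes": len(exclusive),
                }
            )
    return pd.DataFrame(rows)
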