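"""Co-regulated DIR profiles: ratio matrices, clustering, permutation tests.

Rows are introns, columns condition labels (tissue x stress x phase),
values the splicing-ratio difference dr. Rows are z-scored and clustered
hierarchically under correlation distance (1 - Pearson) with average
linkage; the tree is cut at a configured distance and singletons dropped.
Cluster coherence (mean pairwise Pearson correlation of member rows) is
tested by independently permuting each member row's condition labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

DEFAULT_CUT = 0.3


@dataclass(frozen=True)
class DIRCluster:
    cluster_id: str
    members: tuple[str, ...]
    centroid: np.ndarray
    coherence: float
    p_value: float | None = None

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("clusters need >= 2 members")


def build_ratio_matrix(
    dir_results: pd.DataFrame,
    value: str = "ratio_difference",
    min_fraction_present: float = 0.5,
    significant_only: bool = True,
) -> pd.DataFrame:
    """Assemble the intron x condition dr matrix from DIR results.

    Rows observed in fewer than ``min_fraction_present`` of the conditions
    are dropped (logged). Conflicting duplicate (intron, condition) values
    raise; exact duplicates collapse silently.
    """
    df = dir_results
    if significant_only and "significant" in df.columns:
        keep_introns = set(df.loc[df["significant"], "intron_id"])
        df = df[df["intron_id"].isin(keep_introns)]
    dup = df.groupby(["intron_id", "condition"])[value].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index[0]
        raise ValueError(f"conflicting {value} for {bad[0]} in {bad[1]}")
    mat = (
        df.drop_duplicates(["intron_id", "condition"])
        .pivot(index="intron_id", columns="condition", values=value)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    frac = mat.notna().mean(axis=1)
    dropped = mat.index[frac < min_fraction_present]
    if len(dropped):
        log.info("dropping %d sparse rows from ratio matrix", len(dropped))
    return mat.loc[frac >= min_fraction_present]


def _zscore_rows(mat: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Row z-scores; returns (z, excluded_constant_rows)."""
    values = mat.to_numpy(dtype=float)
    mean = np.nanmean(values, axis=1, keepdims=True)
    sd = np.nanstd(values, axis=1, ddof=0, keepdims=True)
    constant = mat.index[(sd.ravel() == 0) | ~np.isfinite(sd.ravel())]
    z = (values - mean) / np.where(sd == 0, 1.0, sd)
    z = np.nan_to_num(z, nan=0.0)  # missing -> row mean after z-scoring
    zdf = pd.DataFrame(z, index=mat.index, columns=mat.columns)
    return zdf.drop(index=constant), constant


def cluster_profiles(
    matrix: pd.DataFrame,
    cut: float = DEFAULT_CUT,
    n_permutations: int = 0,
    seed: int | None = None,
) -> list[DIRCluster]:
    """Hierarchically cluster dr profiles; singletons are discarded.

    With ``n_permutations`` > 0 each cluster also gets a permutation
    p-value (see :func:`coreg_significance`).
    """
    if matrix.shape[0] < 2:
        raise ValueError("clustering requires >= 2 rows")
    z, constant = _zscore_rows(matrix)
    if len(constant):
        log.warning("excluded %d constant rows from clustering", len(constant))
    if z.shape[0] < 2:
        return []
    dist = pdist(z.to_numpy(), metric="correlation")
    dist = np.clip(dist, 0.0, None)  # guard tiny negative rounding
    tree = linkage(dist, method="average")
    labels = fcluster(tree, t=cut, criterion="distance")
    clusters: list[DIRCluster] = []
    for lab in sorted(set(labels)):
        members = z.index[labels == lab]
        if len(members) < 2:
            continue
        sub = matrix.loc[members]
        coh = coherence_statistic(sub)
        clusters.append(
            DIRCluster(
                cluster_id=f"C{len(clusters) + 1:03d}",
                members=tuple(members),
                centroid=z.loc[members].to_numpy().mean(axis=0),
                coherence=coh,
            )
        )
    if n_permutations:
        rng = np.random.default_rng(seed)
        clusters = [
            DIRCluster(
                cluster_id=c.cluster_id,
                members=c.members,
                centroid=c.centroid,
                coherence=c.coherence,
                p_value=coreg_significance(
                    matrix.loc[list(c.members)], n_permutations, rng
                ),
            )
            for c in clusters
        ]
    return clusters


def coherence_statistic(rows: pd.DataFrame) -> float:
    """Mean pairwise Pearson correlation of member rows (in [-1, 1])."""
    values = np.nan_to_num(rows.to_numpy(dtype=float))
    n = values.shape[0]
    if n < 2:
        raise ValueError("coherence needs >= 2 rows")
    corr = np.corrcoef(values)
    iu = np.triu_indices(n, k=1)
    return float(np.nanmean(corr[iu]))


def coreg_significance(
    member_rows: pd.DataFrame,
    n_permutations: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Permutation p-value for cluster coherence.

    The null permutes each member row's condition labels independently;
    p = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    if member_rows.shape[0] < 2:
        raise ValueError("cluster of size < 2")
    if n_permutations < 200:
        raise ValueError("need >= 200 permutations")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    obs = coherence_statistic(member_rows)
    values = np.nan_to_num(member_rows.to_numpy(dtype=float))
    n_rows, n_cols = values.shape
    count = 0
    for _ in range(n_permutations):
        perm = np.empty_like(values)
        for i in range(n_rows):
            perm[i] = values[i, rng.permutation(n_cols)]
        if _coherence_array(perm) >= obs - 1e-12:
            count += 1
    return (1 + count) / (1 + n_permutations)


def _coherence_array(values: np.ndarray) -> float:
    corr = np.corrcoef(values)
    iu = np.triu_indices(values.shape[0], k=1)
    return float(np.nanmean(corr[iu]))


def clusters_to_frame(clusters: list[DIRCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "n_members": len(c.members),
                "members": ",".join(c.members),
                "coherence": c.coherence,
                "p_value": c.p_value,
            }
            for c in clusters
        ]
    )
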