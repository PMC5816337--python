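"""Droplet digital PCR quantification.

Each droplet partitions the template at random, so the count of template
molecules per droplet is Poisson. From the fraction of positive droplets
p = positive/total the mean occupancy is lambda = -ln(1 - p) copies per
droplet, and the sample concentration follows from the droplet volume and
dilution. Relative isoform abundance is the percentage of the
intron-retaining isoform's absolute copy number over the fully spliced
mRNA, and a "ratio switch" flags conditions where the spliced copy number
and the relative ratio move to opposite sides of their baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

DEFAULT_DROPLET_VOLUME_NL = 0.85
SPLICED = "spliced"


class SaturationError(ValueError):
    """All droplets positive: occupancy not estimable."""


@dataclass(frozen=True)
class DdpcrWell:
    well_id: str
    target: str  # 'spliced' or an intron-retention label such as 'I4R'
    condition: str
    droplets_total: int
    droplets_positive: int
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.droplets_total <= 0:
            raise ValueError("droplets_total must be > 0")
        if not 0 <= self.droplets_positive <= self.droplets_total:
            raise ValueError("droplets_positive out of range")
        if self.droplet_volume_nl <= 0 or self.dilution_factor <= 0:
            raise ValueError("volume and dilution must be > 0")


def poisson_lambda(positive: int, total: int) -> float:
    """Mean copies per droplet from the positive-droplet fraction."""
    if total <= 0:
        raise ValueError("droplets_total must be > 0")
    if positive >= total:
        raise SaturationError("all droplets positive; sample too concentrated")
    return -math.log((total - positive) / total)


def poisson_concentration(well: DdpcrWell) -> float:
    """Absolute concentration (copies per microlitre of sample)."""
    lam = poisson_lambda(well.droplets_positive, well.droplets_total)
    volume_ul = well.droplet_volume_nl * 1e-3
    return lam / volume_ul * well.dilution_factor


def lambda_confidence_interval(
    positive: int, total: int, level: float = 0.95
) -> tuple[float, float]:
    """Normal-approximation CI for lambda on the log scale (reported only)."""
    from scipy import stats

    lam = poisson_lambda(positive, total)
    if positive == 0:
        return (0.0, 0.0)
    p = positive / total
    # delta method: var(lambda-hat) = p / ((1-p) * total)
    se = math.sqrt(p / ((1 - p) * total))
    z = stats.norm.ppf(0.5 + level / 2)
    log_se = se / lam
    return (lam * math.exp(-z * log_se), lam * math.exp(z * log_se))


def pool_wells(wells: list[DdpcrWell]) -> DdpcrWell:
    """Combine replicate wells of one target/condition by pooling droplets.

    Pooling droplet counts before the Poisson correction preserves the
    Poisson likelihood (unlike averaging concentrations).
    """
    if not wells:
        raise ValueError("no wells to pool")
    first = wells[0]
    if any(
        (w.target, w.condition, w.droplet_volume_nl, w.dilution_factor)
        != (first.target, first.condition, first.droplet_volume_nl,
            first.dilution_factor)
        for w in wells
    ):
        raise ValueError("can only pool replicate wells of one target/condition")
    return DdpcrWell(
        well_id="+".join(w.well_id for w in wells),
        target=first.target,
        condition=first.condition,
        droplets_total=sum(w.droplets_total for w in wells),
        droplets_positive=sum(w.droplets_positive for w in wells),
        droplet_volume_nl=first.droplet_volume_nl,
        dilution_factor=first.dilution_factor,
    )


def isoform_ratio(spliced: float, retained: float) -> float | None:
    """Percent abundance of the retained isoform relative to spliced."""
    if spliced < 0 or retained < 0:
        raise ValueError("concentrations must be >= 0")
    if spliced == 0:
        return None
    return 100.0 * retained / spliced


def quantify(wells: list[DdpcrWell]) -> pd.DataFrame:
    """Concentrations and relative ratios per condition and target.

    Replicate wells are pooled per (condition, target); each non-spliced
    target gets relative_ratio_percent against the spliced target of the
    same condition (NA when spliced is absent or zero).
    """
    groups: dict[tuple[str, str], list[DdpcrWell]] = {}
    for w in wells:
        groups.setdefault((w.condition, w.target), []).append(w)
    conc: dict[tuple[str, str], float] = {
        key: poisson_concentration(pool_wells(ws)) for key, ws in groups.items()
    }
    rows = []
    for (condition, target), c in sorted(conc.items()):
        ratio = None
        if target != SPLICED:
            spliced = conc.get((condition, SPLICED))
            if spliced is not None:
                ratio = isoform_ratio(spliced, c)
        rows.append(
            {
                "condition": condition,
                "target": target,
                "copies_per_ul": c,
                "relative_ratio_percent": ratio,
            }
        )
    return pd.DataFrame(rows)


def ratio_switch(quantified: pd.DataFrame, baseline: str) -> pd.DataFrame:
    """Per target and condition: fold changes vs baseline and a switch flag.

    switch = True when the spliced copy-number fold change and the relative
    ratio fold change lie on opposite sides of 1 — the signature of a
    splicing-efficiency shift accompanying an expression change.
    """
    base = quantified[quantified["condition"] == baseline]
    if base.empty:
        raise ValueError(f"baseline condition {baseline!r} absent")
    base_spliced = base.loc[base["target"] == SPLICED, "copies_per_ul"]
    if base_spliced.empty:
        raise ValueError("baseline lacks a spliced target")
    base_spliced = float(base_spliced.iloc[0])
    base_ratio = {
        row["target"]: row["relative_ratio_percent"]
        for _, row in base.iterrows()
        if row["target"] != SPLICED
    }
    rows = []
    for condition, grp in quantified.groupby("condition"):
        if condition == baseline:
            continue
        spliced = grp.loc[grp["target"] == SPLICED, "copies_per_ul"]
        if spliced.empty:
            continue
        spliced_fold = float(spliced.iloc[0]) / base_spliced
        for _, row in grp[grp["target"] != SPLICED].iterrows():
            b = base_ratio.get(row["target"])
            r = row["relative_ratio_percent"]
            ratio_fold = (r / b) if (b and r is not None) else None
            switch = (
                ratio_fold is not None
                and (spliced_fold - 1.0) * (ratio_fold - 1.0) < 0
            )
            rows.append(
                {
                    "condition": condition,
                    "target": row["target"],
                    "spliced_fold_change": spliced_fold,
                    "ratio_fold_change": ratio_fold,
                    "switch": switch,
                }
            )
    return pd.DataFrame(rows)


def read_wells_tsv(path: str) -> list[DdpcrWell]:
    df = pd.read_csv(path, sep="\t", comment="#")
    wells = []
    for row in df.itertuples(index=False):
        wells.append(
            DdpcrWell(
                well_id=str(row.well_id),
                target=str(row.target),
                condition=str(row.condition),
                droplets_total=int(row.droplets_total),
                droplets_positive=int(row.droplets_positive),
                droplet_volume_nl=float(
                    getattr(row, "droplet_volume_nl", DEFAULT_DROPLET_VOLUME_NL)
                ),
                dilution_factor=float(getattr(row, "dilution_factor", 1.0)),
            )
        )
    return wells
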