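"""Distant-eQTL hotspot detection on the genetic map.

Distant eQTL outside common hyper-divergent regions are assigned to
half-open 0.5 cM bins per chromosome (anchored at each chromosome's minimum
map position, zero-count bins included). Under uniform placement the
per-bin counts are Poisson; bins whose count strictly exceeds the 99th
percentile of a Poisson with the maximum-likelihood rate (the mean count)
are hotspots, and runs of adjacent qualifying bins merge into one hotspot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genorel import positions_in_intervals
from .ioformats import GeneticMap

BIN_CM = 0.5

BIN_COLUMNS = ["chrom", "cm_start", "cm_end", "count", "members"]
HOTSPOT_COLUMNS = ["chrom", "cm_start", "cm_end", "count", "n_bins", "members"]


@dataclass
class HotspotModel:
    """Binned distant-eQTL counts with the fitted Poisson threshold."""

    bin_cM: float
    lambda_hat: float
    q99: int
    bins: pd.DataFrame
    hotspots: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=HOTSPOT_COLUMNS)
    )


def bin_distant_eqtl(
    eqtls: pd.DataFrame,
    gmap: GeneticMap,
    common_divergent: pd.DataFrame | None = None,
    bin_cM: float = BIN_CM,
) -> pd.DataFrame:
    """Count distant eQTL per 0.5 cM bin.

    ``eqtls`` needs columns trait, chrom, peak_bp, classification. Distant
    eQTL with peaks inside common hyper-divergent regions or on chromosomes
    absent from the genetic map (e.g. mitochondrial) are excluded. Bins with
    zero counts across each chromosome's covered cM range are included.
    """
    distant = eqtls[eqtls["classification"] == "distant"].copy()
    rows = []
    for chrom in gmap.chroms:
        sub = distant[distant["chrom"] == chrom]
        if len(sub) and common_divergent is not None and len(common_divergent):
            hit = positions_in_intervals(
                common_divergent, chrom, sub["peak_bp"].to_numpy()
            )
            sub = sub[~hit]
        cm_min, cm_max = gmap.cm_range(chrom)
        n_bins = max(int(np.ceil((cm_max - cm_min) / bin_cM)), 1)
        counts = np.zeros(n_bins, dtype=int)
        members: list[list] = [[] for _ in range(n_bins)]
        if len(sub):
            cm = gmap.interp(chrom, sub["peak_bp"].to_numpy())
            idx = np.minimum(
                ((cm - cm_min) // bin_cM).astype(int), n_bins - 1
            )
            for i, trait in zip(idx, sub["trait"]):
                counts[i] += 1
                members[i].append(trait)
        for b in range(n_bins):
            rows.append(
                (
                    chrom,
                    cm_min + b * bin_cM,
                    cm_min + (b + 1) * bin_cM,
                    int(counts[b]),
                    ";".join(map(str, members[b])),
                )
            )
    return pd.DataFrame(rows, columns=BIN_COLUMNS)


def poisson_q99(lam: float, q: float = 0.99) -> int:
    """Smallest integer k with Poisson CDF(k; lam) >= q."""
    if lam <= 0:
        return 0
    k = int(stats.poisson.ppf(q, lam))
    while stats.poisson.cdf(k, lam) < q:  # guard against ppf edge cases
        k += 1
    while k > 0 and stats.poisson.cdf(k - 1, lam) >= q:
        k -= 1
    return k


def detect_hotspots(
    bins: pd.DataFrame,
    bin_cM: float = BIN_CM,
    lambda_bins: str = "all",
    q: float = 0.99,
) -> HotspotModel:
    """Poisson-threshold hotspot calls with adjacent-bin merging.

    ``lambda_bins`` selects the rate denominator: 'all' bins genome-wide
    (default) or 'nonempty' bins only. A bin qualifies iff its count
    strictly exceeds the q-quantile of Poisson(lambda_hat).
    """
    if bins.empty:
        return HotspotModel(bin_cM, 0.0, 0, bins)
    counts = bins["count"].to_numpy()
    if lambda_bins == "nonempty":
        used = counts[counts > 0]
        lam = float(used.mean()) if used.size else 0.0
    elif lambda_bins == "all":
        lam = float(counts.mean())
    else:
        raise ValueError("lambda_bins must be 'all' or 'nonempty'")
    q99 = poisson_q99(lam, q)
    qual = counts > q99
    hotspots = []
    bins = bins.reset_index(drop=True)
    i = 0
    while i < len(bins):
        if qual[i]:
            j = i
            while (
                j + 1 < len(bins)
                and qual[j + 1]
                and bins["chrom"][j + 1] == bins["chrom"][i]
                and np.isclose(bins["cm_start"][j + 1], bins["cm_end"][j])
            ):
                j += 1
            run = bins.iloc[i : j + 1]
            member_lists = [m for m in run["members"] if m]
            hotspots.append(
                (
                    bins["chrom"][i],
                    float(run["cm_start"].iloc[0]),
                    float(run["cm_end"].iloc[-1]),
                    int(run["count"].sum()),
                    int(j - i + 1),
                    ";".join(member_lists),
                )
            )
            i = j + 1
        else:
            i += 1
    return HotspotModel(
        bin_cM,
        lam,
        q99,
        bins,
        pd.DataFrame(hotspots, columns=HOTSPOT_COLUMNS),
    )
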