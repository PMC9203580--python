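"""Genotype filtering, LD pruning, kinship, distances, and NJ trees.

These stages prepare the marker set used for association mapping: markers
with any missing call or minor-allele frequency below 5% are removed, the
remainder is pruned to weak pairwise LD (windowed r^2 < 0.8, mirroring
PLINK's ``--indep-pairwise 50 10 0.8``), and a kinship matrix is built from
the pruned dosages. Distance matrices and neighbor-joining trees summarize
genetic and expression relatedness across the strain panel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateInputError, EmptyInputError, FormatError
from .ioformats import DivergentMaskSet, GenotypeMatrix


@dataclass
class KinshipMatrix:
    """Symmetric strains x strains genetic covariance matrix."""

    strains: np.ndarray
    K: np.ndarray

    def __post_init__(self):
        self.strains = np.asarray(self.strains, dtype=object)
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.strains)
        if self.K.shape != (n, n):
            raise FormatError("kinship shape does not match strain count")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise FormatError("kinship matrix not symmetric")

    def align(self, strain_ids) -> "KinshipMatrix":
        pos = {s: i for i, s in enumerate(self.strains)}
        idx = np.array([pos[s] for s in strain_ids])
        return KinshipMatrix(self.strains[idx], self.K[np.ix_(idx, idx)])


def filter_markers(G: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Drop markers with any missing call or MAF strictly below ``maf_min``."""
    complete = ~np.isnan(G.dosage).any(axis=0)
    maf = G.maf()
    with np.errstate(invalid="ignore"):
        keep = complete & (maf >= maf_min)
    if not keep.any():
        raise EmptyInputError("no markers survive missingness/MAF filtering")
    return G.subset(marker_idx=np.flatnonzero(keep))


def _r2_matrix(X: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between columns of X (no missing values)."""
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = np.nan
    C = (Xc.T @ Xc) / X.shape[0]
    r = C / np.outer(sd, sd)
    return np.clip(r**2, 0.0, 1.0)


def ld_prune(
    G: GenotypeMatrix, window: int = 50, step: int = 10, r2_max: float = 0.8
) -> GenotypeMatrix:
    """Greedy windowed LD pruning per chromosome.

    Within each ``window``-marker window (slid by ``step``), while any pair of
    surviving markers has r^2 > ``r2_max``, one member of the worst pair is
    removed: the one with lower MAF, or the later in map order on a tie.
    """
    maf = G.maf()
    keep = np.ones(G.n_markers, dtype=bool)
    chrom = G.markers["chrom"].to_numpy()
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while start < len(idx):
            win = idx[start : start + window]
            alive = win[keep[win]]
            while len(alive) > 1:
                r2 = _r2_matrix(G.dosage[:, alive])
                np.fill_diagonal(r2, 0.0)
                i, j = np.unravel_index(np.nanargmax(r2), r2.shape)
                if not (r2[i, j] > r2_max):
                    break
                a, b = alive[i], alive[j]
                if maf[a] < maf[b]:
                    drop = a
                elif maf[b] < maf[a]:
                    drop = b
                else:
                    drop = max(a, b)  # tie: later in map order
                keep[drop] = False
                alive = win[keep[win]]
            if start + window >= len(idx):
                break
            start += step
    return G.subset(marker_idx=np.flatnonzero(keep))


def kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """Realized-relationship kinship from centered dosages.

    K = M M' / sum_j p_j (1 - p_j) with M the column-centered dosage matrix
    and p_j the mean dosage (allele frequency) of marker j. Requires a
    complete (no missing call) dosage matrix.
    """
    D = G.dosage
    if np.isnan(D).any():
        raise FormatError("kinship requires a complete dosage matrix")
    p = D.mean(axis=0)
    denom = float(np.sum(p * (1.0 - p)))
    if denom <= 0:
        raise DegenerateInputError("all markers monomorphic; kinship undefined")
    M = D - p
    K = (M @ M.T) / denom
    K = 0.5 * (K + K.T)  # kill rounding asymmetry
    return KinshipMatrix(G.strains, K)


def distance_matrix(X: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Pairwise distances between rows of X (strains x features)."""
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise FormatError("distance_matrix requires complete features")
    return squareform(pdist(X, metric=metric))


def nj_tree(D: np.ndarray, labels) -> str:
    """Unrooted neighbor-joining (Saitou-Nei) tree as a newick string.

    Negative branch lengths arising from non-additive distances are clipped
    at zero. Requires at least three taxa.
    """
    import skbio

    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise EmptyInputError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T, atol=1e-8) or not np.allclose(np.diag(D), 0.0):
        raise FormatError("distance matrix must be symmetric with zero diagonal")
    dm = skbio.DistanceMatrix(D, ids=[str(x) for x in labels])
    tree = skbio.tree.nj(dm)
    return str(tree).strip()


def consolidate_common_divergent(
    masks: DivergentMaskSet,
    n_strains: int | None = None,
    bin_bp: int = 1000,
    frac: float = 0.05,
    chrom_lengths: dict | None = None,
) -> pd.DataFrame:
    """Consolidate per-strain divergent masks into common-divergent intervals.

    The genome is split into ``bin_bp`` bins; a bin is common-divergent iff
    the fraction of strains whose mask overlaps it by >= 1 bp is at least
    ``frac``. Adjacent qualifying bins are merged. ``n_strains`` defaults to
    the number of strains present in the mask set.

    Returns a DataFrame (chrom, start, end), 0-based half-open.
    """
    empty = pd.DataFrame(columns=["chrom", "start", "end"])
    if masks.is_empty():
        return empty
    if n_strains is None:
        n_strains = len(masks.strains)
    t = masks.table
    out = []
    chroms = (
        list(chrom_lengths) if chrom_lengths is not None else list(pd.unique(t["chrom"]))
    )
    for chrom in chroms:
        sub = t[t["chrom"] == chrom]
        if sub.empty:
            continue
        length = (
            chrom_lengths[chrom] if chrom_lengths is not None else int(sub["end"].max())
        )
        n_bins = int(np.ceil(length / bin_bp))
        counts = np.zeros(n_bins, dtype=int)
        for strain, ssub in sub.groupby("strain"):
            covered = np.zeros(n_bins, dtype=bool)
            for s, e in ssub[["start", "end"]].to_numpy():
                if e <= s:
                    continue
                lo = int(s // bin_bp)
                hi = int(np.ceil(e / bin_bp))
                covered[lo : min(hi, n_bins)] = True
            counts += covered
        common = counts / n_strains >= frac
        # merge runs of qualifying bins
        i = 0
        while i < n_bins:
            if common[i]:
                j = i
                while j + 1 < n_bins and common[j + 1]:
                    j += 1
                out.append((chrom, i * bin_bp, (j + 1) * bin_bp))
                i = j + 1
            else:
                i += 1
    return pd.DataFrame(out, columns=["chrom", "start", "end"]) if out else empty


def positions_in_intervals(
    intervals: pd.DataFrame, chrom, bp_1based: np.ndarray
) -> np.ndarray:
    """Boolean mask: 1-based positions falling in 0-based half-open intervals."""
    bp0 = np.asarray(bp_1based) - 1
    hit = np.zeros(len(bp0), dtype=bool)
    if intervals is None or len(intervals) == 0:
        return hit
    sub = intervals[intervals["chrom"] == chrom]
    for s, e in sub[["start", "end"]].to_numpy():
        hit |= (bp0 >= s) & (bp0 < e)
    return hit
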