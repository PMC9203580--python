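"""Per-trait QTL calling, permutation FDR, classification, LD, fine mapping.

A QTL is called wherever at least one marker exceeds the applied -log10(p)
threshold. Significant markers on a chromosome are grouped into one QTL
when separated by at most ``gap_markers`` marker indices; the peak is the
most significant marker (leftmost on ties), the confidence interval extends
100 marker indices beyond the outermost significant markers (clamped to the
chromosome), and variance explained is the squared Pearson correlation
between the peak dosage and the trait.

The 5% permutation FDR cutoff is the 95th percentile of peak significances
of all QTL detected on permuted traits (traits permuted, genotypes and
kinship fixed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .genorel import positions_in_intervals
from .ioformats import GenotypeMatrix
from .mixedmodel import (
    KinshipDecomposition,
    KinshipLMM,
    ScanResult,
    ThresholdSpec,
)

log = logging.getLogger(__name__)

QTL_COLUMNS = [
    "trait",
    "chrom",
    "peak_marker",
    "peak_bp",
    "neglog10p",
    "interval_left_bp",
    "interval_right_bp",
    "variance_explained",
    "classification",
    "divergent_flag",
]


@dataclass
class QTLRecord:
    """One mapped peak with significance, interval, VE, and class."""

    trait: str
    chrom: str
    peak_marker: str
    peak_bp: int
    neglog10p: float
    interval_left_bp: int
    interval_right_bp: int
    variance_explained: float
    classification: str = "unclassified"
    divergent_flag: bool = False


def qtl_frame(records) -> pd.DataFrame:
    """QTLRecord list -> DataFrame with a stable column order."""
    if not records:
        return pd.DataFrame(columns=QTL_COLUMNS)
    return pd.DataFrame([asdict(r) for r in records])[QTL_COLUMNS]


def _restrict(y, G: GenotypeMatrix, K):
    """Drop strains with missing trait values; rebuild the decomposition."""
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if ok.all():
        kd = K if isinstance(K, KinshipDecomposition) else KinshipDecomposition(K)
        return y, G, kd
    idx = np.flatnonzero(ok)
    Ksub = (K.K if hasattr(K, "K") else np.asarray(K))
    if isinstance(K, KinshipDecomposition):
        raise ValueError("pass the kinship matrix itself when traits have NaN")
    Ksub = Ksub[np.ix_(idx, idx)]
    return y[idx], G.subset(strain_idx=idx), KinshipDecomposition(Ksub)


def call_qtl(
    trait_id: str,
    scan: ScanResult,
    markers: pd.DataFrame,
    dosage: np.ndarray,
    y: np.ndarray,
    threshold: float,
    gap_markers: int = 1000,
    flank_snvs: int = 100,
) -> list[QTLRecord]:
    """Group significant markers of one scan into QTL records."""
    sig = scan.neglog10p >= threshold
    records: list[QTLRecord] = []
    chrom_arr = markers["chrom"].to_numpy()
    bp_arr = markers["bp"].to_numpy()
    id_arr = markers["marker"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        cidx = np.flatnonzero(chrom_arr == chrom)
        hits = cidx[sig[cidx]]
        if hits.size == 0:
            continue
        local = np.searchsorted(cidx, hits)  # positions within the chromosome
        splits = np.flatnonzero(np.diff(local) > gap_markers)
        groups = np.split(np.arange(len(local)), splits + 1)
        for grp in groups:
            members = hits[grp]
            peak = members[np.argmax(scan.neglog10p[members])]  # argmax -> leftmost tie
            lo = cidx[max(local[grp[0]] - flank_snvs, 0)]
            hi = cidx[min(local[grp[-1]] + flank_snvs, len(cidx) - 1)]
            x = dosage[:, peak]
            vx, vy = x.var(), y.var()
            ve = 0.0
            if vx > 0 and vy > 0:
                r = np.corrcoef(x, y)[0, 1]
                ve = float(r * r)
            records.append(
                QTLRecord(
                    trait=trait_id,
                    chrom=chrom,
                    peak_marker=id_arr[peak],
                    peak_bp=int(bp_arr[peak]),
                    neglog10p=float(scan.neglog10p[peak]),
                    interval_left_bp=int(bp_arr[lo]),
                    interval_right_bp=int(bp_arr[hi]),
                    variance_explained=ve,
                )
            )
    return records


def map_trait(
    y,
    G: GenotypeMatrix,
    K,
    threshold: float,
    trait_id: str = "trait",
    gap_markers: int = 1000,
    flank_snvs: int = 100,
    rotated: np.ndarray | None = None,
) -> list[QTLRecord]:
    """Scan one strain-level trait and call QTL above ``threshold``.

    ``y`` is aligned with ``G.strains``; NaN entries restrict the strain set
    (and the kinship) before fitting. An empty list (no significant marker)
    is a normal outcome, not an error.
    """
    y2, G2, kd = _restrict(y, G, K)
    model = KinshipLMM(y2, kd, trait=trait_id)
    scan = model.fit().scan(G2.dosage, rotated=rotated if G2 is G else None)
    return call_qtl(
        trait_id, scan, G2.markers, G2.dosage, y2, threshold, gap_markers, flank_snvs
    )


def permutation_fdr(
    trait_matrix: pd.DataFrame,
    G: GenotypeMatrix,
    K,
    threshold_spec: ThresholdSpec,
    mode: str = "eigen",
    n_traits: int = 200,
    n_perm: int = 200,
    seed: int = 0,
    gap_markers: int = 1000,
) -> float:
    """Permutation-calibrated 5% FDR cutoff on the -log10(p) scale.

    Samples ``n_traits`` traits (rows of the transcripts x strains matrix)
    without replacement, permutes each across strains ``n_perm`` times, maps
    every permuted trait against the raw EIGEN or Bonferroni threshold, and
    returns the 95th percentile (linear interpolation) of the pooled peak
    significances of all detected QTL. Falls back to the raw threshold when
    no permuted QTL is found.
    """
    if len(trait_matrix) < n_traits:
        raise EmptyInputError(
            f"need >= {n_traits} traits for FDR calibration, have {len(trait_matrix)}"
        )
    raw = threshold_spec.threshold(mode)
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(trait_matrix), size=n_traits, replace=False)
    strain_order = list(G.strains)
    peaks: list[float] = []
    for row in pick:
        y_full = trait_matrix.iloc[row].reindex(strain_order).to_numpy(dtype=float)
        ok = np.isfinite(y_full)
        idx = np.flatnonzero(ok)
        if idx.size < 30 or np.var(y_full[idx]) == 0:
            continue
        Gs = G.subset(strain_idx=idx)
        Ks = (K.K if hasattr(K, "K") else np.asarray(K))[np.ix_(idx, idx)]
        kd = KinshipDecomposition(Ks)
        Gr = kd.rotate(Gs.dosage)
        base = y_full[idx]
        for _ in range(n_perm):
            yp = rng.permutation(base)
            model = KinshipLMM(yp, kd, trait=f"perm{row}")
            scan = model.fit().scan(Gs.dosage, rotated=Gr)
            for rec in call_qtl(
                "perm", scan, Gs.markers, Gs.dosage, yp, raw, gap_markers
            ):
                peaks.append(rec.neglog10p)
    if not peaks:
        log.warning("permutation FDR: no QTL detected; falling back to raw threshold")
        return raw
    return float(np.percentile(peaks, 95))


def classify_eqtl(qtl: QTLRecord, annotation: pd.DataFrame, window_bp: int = 1_000_000) -> str:
    """'local' iff the peak is on the transcript's chromosome within the TSS
    window (|peak - TSS| <= window_bp), else 'distant'; 'unclassified' when
    the transcript is not annotated."""
    hit = annotation[annotation["transcript"] == qtl.trait]
    if hit.empty:
        warnings.warn(
            f"transcript {qtl.trait!r} missing from annotation", RuntimeWarning,
            stacklevel=2,
        )
        return "unclassified"
    row = hit.iloc[0]
    if row["chrom"] == qtl.chrom and abs(qtl.peak_bp - int(row["tss"])) <= window_bp:
        return "local"
    return "distant"


def classify_all(records, annotation, window_bp: int = 1_000_000) -> None:
    for rec in records:
        rec.classification = classify_eqtl(rec, annotation, window_bp)


def flag_divergent(records, common_divergent: pd.DataFrame) -> None:
    """Set ``divergent_flag`` for peaks inside common hyper-divergent regions."""
    for rec in records:
        hit = positions_in_intervals(
            common_divergent, rec.chrom, np.array([rec.peak_bp])
        )
        rec.divergent_flag = bool(hit[0])


def qtl_ld(records, G: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise r^2 between peak dosages of one trait's QTL."""
    rows = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            xi = G.dosage_of(records[i].peak_marker)
            xj = G.dosage_of(records[j].peak_marker)
            if xi.std() == 0 or xj.std() == 0:
                r2 = np.nan
            else:
                r2 = float(np.corrcoef(xi, xj)[0, 1] ** 2)
            rows.append((records[i].peak_marker, records[j].peak_marker, r2))
    return pd.DataFrame(rows, columns=["marker_a", "marker_b", "r2"])


def finemap(
    y,
    roi: GenotypeMatrix,
    K,
    common_divergent: pd.DataFrame | None = None,
    variant_annotation: pd.DataFrame | None = None,
    top_frac: float = 0.05,
) -> pd.DataFrame:
    """Candidate causal variants within a QTL region of interest.

    The ROI markers are tested unpruned with the same mixed-model machinery;
    candidates must rank in the top ``top_frac`` by significance, fall
    outside common hyper-divergent regions, and carry a negative BLOSUM
    score in the variant annotation.
    """
    y2, roi2, kd = _restrict(y, roi, K)
    scan = KinshipLMM(y2, kd, trait="finemap").fit().scan(roi2.dosage)
    df = roi2.markers.copy()
    df["neglog10p"] = scan.neglog10p
    k = max(int(np.ceil(top_frac * len(df))), 1)
    order = np.argsort(-df["neglog10p"].to_numpy(), kind="stable")
    top = df.iloc[order[:k]].copy()
    if common_divergent is not None and len(common_divergent):
        keep = []
        for _, row in top.iterrows():
            hit = positions_in_intervals(
                common_divergent, row["chrom"], np.array([row["bp"]])
            )
            keep.append(not hit[0])
        top = top[np.array(keep, dtype=bool)]
    if variant_annotation is None or variant_annotation.empty:
        warnings.warn("finemap: empty variant annotation", RuntimeWarning, stacklevel=2)
        return top.iloc[0:0].assign(blosum=pd.Series(dtype=float))
    blos = variant_annotation.groupby("marker")["blosum"].min()
    top = top.assign(blosum=top["marker"].map(blos))
    top = top[np.isfinite(top["blosum"]) & (top["blosum"] < 0)]
    return top.reset_index(drop=True)
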