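"""Expression normalization, filtering, masking, and sample QC.

Stages, in pipeline order:

1. :func:`select_samples` — iterative outlier-replicate removal by
   comparing intra-strain to inter-strain sample distances.
2. :func:`norm_factors` — median-of-ratios per-sample factors over a set of
   reference transcripts, applied to raw TPM.
3. :func:`filter_reliable` — keep transcripts with >= ``min_count``
   normalized counts in all replicates of >= ``min_strains`` strains.
4. :func:`apply_divergent_mask` — blank (transcript, strain) entries whose
   TSS falls in that strain's hyper-divergent intervals; drop transcripts
   retained in too few strains.
5. :func:`log_transform` / :func:`strain_means` — log2(x + 0.5) and
   replicate averaging to the strain-level trait matrix used for mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ConvergenceError, MetadataError, NormalizationError
from .ioformats import DivergentMaskSet, ExpressionMatrix


@dataclass
class QCReport:
    """Outcome of sample/transcript QC; kept and dropped partition the input."""

    kept_samples: list = field(default_factory=list)
    dropped_samples: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample", "reason"])
    )
    kept_transcripts: list = field(default_factory=list)
    dropped_transcripts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["transcript", "reason"])
    )
    iterations_to_converge: int = 1


def norm_factors(tpm: ExpressionMatrix, reference_transcripts) -> np.ndarray:
    """Median-of-ratios normalization factors per sample.

    Over reference transcripts with strictly positive, unmasked values in
    every sample: factor_s = median_t( TPM_ts / geomean_t(TPM) ). Normalized
    expression is TPM / factor.
    """
    ref = set(reference_transcripts)
    idx = np.array([i for i, t in enumerate(tpm.transcripts) if t in ref])
    if idx.size == 0:
        raise NormalizationError("no reference transcripts present in the matrix")
    V = tpm.masked_values()[idx]
    usable = np.all(np.isfinite(V) & (V > 0), axis=1)
    if not usable.any():
        raise NormalizationError("no reference transcript positive in all samples")
    V = V[usable]
    log_geomean = np.mean(np.log(V), axis=1)
    ratios = np.exp(np.log(V) - log_geomean[:, None])
    return np.median(ratios, axis=0)


def apply_factors(expr: ExpressionMatrix, factors: np.ndarray) -> ExpressionMatrix:
    """Divide each sample column by its normalization factor."""
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (expr.n_samples,):
        raise MetadataError("one factor per sample required")
    return ExpressionMatrix(
        expr.transcripts,
        expr.samples,
        expr.values / factors,
        expr.mask.copy(),
        expr.log_scale,
    )


def filter_reliable(
    norm_counts: ExpressionMatrix, min_count: float = 5, min_strains: int = 10
) -> list:
    """Transcripts with >= min_count normalized counts in all replicates of
    at least min_strains strains. Masked/NaN replicate values fail the
    per-strain "all replicates" requirement."""
    V = norm_counts.masked_values()
    ok = np.isfinite(V) & (V >= min_count)
    strains = norm_counts.samples["strain"].to_numpy()
    n_good = np.zeros(norm_counts.n_transcripts, dtype=int)
    for s in pd.unique(strains):
        cols = strains == s
        n_good += ok[:, cols].all(axis=1)
    return [t for t, n in zip(norm_counts.transcripts, n_good) if n >= min_strains]


def apply_divergent_mask(
    expr: ExpressionMatrix,
    masks: DivergentMaskSet,
    annotation: pd.DataFrame,
    min_strains_retained: int = 100,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Mask per-strain expression of transcripts whose TSS is hyper-divergent.

    A transcript is masked for a strain iff its TSS (1-based) lies inside
    one of that strain's divergent intervals; transcripts retained in fewer
    than ``min_strains_retained`` strains are dropped entirely.

    Returns (masked matrix, dropped-transcript table with reason).
    """
    ann = annotation.set_index("transcript")
    missing = [t for t in expr.transcripts if t not in ann.index]
    if missing:
        raise MetadataError(f"transcript {missing[0]!r} absent from annotation")
    mask = expr.mask.copy()
    strains = expr.samples["strain"].to_numpy()
    if not masks.is_empty():
        strain_cols = {s: np.flatnonzero(strains == s) for s in pd.unique(strains)}
        by_strain_chrom = {
            key: sub[["start", "end"]].to_numpy()
            for key, sub in masks.table.groupby(["strain", "chrom"])
        }
        chrom_arr = ann.loc[list(expr.transcripts), "chrom"].to_numpy()
        tss_arr = ann.loc[list(expr.transcripts), "tss"].to_numpy()
        for s, cols in strain_cols.items():
            for chrom in pd.unique(chrom_arr):
                iv = by_strain_chrom.get((s, chrom))
                if iv is None:
                    continue
                rows = np.flatnonzero(chrom_arr == chrom)
                pos0 = tss_arr[rows] - 1
                hit = np.zeros(len(rows), dtype=bool)
                for a, b in iv:
                    hit |= (pos0 >= a) & (pos0 < b)
                if hit.any():
                    mask[np.ix_(rows[hit], cols)] = True
    # strains with at least one unmasked replicate count as retained
    n_strains_total = len(pd.unique(strains))
    retained = np.zeros(expr.n_transcripts, dtype=int)
    for s in pd.unique(strains):
        cols = strains == s
        retained += (~mask[:, cols]).any(axis=1)
    keep = retained >= min(min_strains_retained, n_strains_total)
    dropped = pd.DataFrame(
        {
            "transcript": expr.transcripts[~keep],
            "reason": "too_few_strains",
        }
    )
    out = ExpressionMatrix(
        expr.transcripts, expr.samples, expr.values, mask, expr.log_scale
    ).subset(transcript_idx=np.flatnonzero(keep))
    return out, dropped


def _vst_like(counts: ExpressionMatrix, annotation: pd.DataFrame | None) -> np.ndarray:
    """Gene-level, variance-stabilized transform used for sample clustering.

    Transcript counts are summed to gene level (when annotation is given),
    normalized by median-of-ratios size factors over all-positive genes, and
    log2(x + 1) transformed — a light-weight stand-in for a full variance
    stabilizing transformation with the same monotone, scale-free behavior.
    """
    V = counts.values.copy()
    V[counts.mask] = 0.0
    if annotation is not None:
        gene_of = annotation.set_index("transcript")["gene"]
        genes = np.array([gene_of.get(t, t) for t in counts.transcripts], dtype=object)
        df = pd.DataFrame(V)
        V = df.groupby(genes, sort=True).sum().to_numpy()
    pos = np.all(V > 0, axis=1)
    if pos.any():
        logs = np.log(V[pos])
        ratios = np.exp(logs - logs.mean(axis=1, keepdims=True))
        factors = np.median(ratios, axis=0)
        V = V / factors
    return np.log2(V + 1.0)


def select_samples(
    counts: ExpressionMatrix,
    annotation: pd.DataFrame | None = None,
    max_iter: int = 20,
) -> tuple[list, QCReport]:
    """Iterative removal of outlier replicates by sample-to-sample distance.

    Each iteration: transform counts (gene-level, VST-like), compute
    all-pairs Euclidean distances between samples, and per strain compare
    each intra-strain replicate-pair distance to the median of the strain's
    inter-strain distances (pooled over all of its replicates):

    * all intra-pair distances < median  -> keep all replicates;
    * no intra-pair distance < median    -> drop the whole strain;
    * 3-replicate strain, 1-2 pairs pass -> keep the minimum-distance pair.

    Ties (intra == median) count as failing. Iterate on the reduced sample
    set until no sample is removed.
    """
    current = counts
    dropped_rows: list[tuple] = []
    for iteration in range(1, max_iter + 1):
        X = _vst_like(current, annotation).T  # samples x features
        D = squareform(pdist(X, metric="euclidean"))
        strains = current.samples["strain"].to_numpy()
        sample_ids = current.samples["sample"].to_numpy()
        drop_idx: list[int] = []
        for s in pd.unique(strains):
            own = np.flatnonzero(strains == s)
            others = np.flatnonzero(strains != s)
            if len(own) < 2 or len(others) == 0:
                continue
            inter = D[np.ix_(own, others)].ravel()
            med = np.median(inter)
            pairs = [
                (i, j, D[i, j]) for a, i in enumerate(own) for j in own[a + 1 :]
            ]
            passing = [p for p in pairs if p[2] < med]
            if len(passing) == len(pairs):
                continue  # all replicates kept
            if not passing:
                drop_idx.extend(own)
                dropped_rows.extend((sample_ids[i], "strain_removed") for i in own)
            else:
                # keep the minimum-distance pair among the replicates
                i, j, _ = min(pairs, key=lambda p: p[2])
                for k in own:
                    if k not in (i, j):
                        drop_idx.append(k)
                        dropped_rows.append((sample_ids[k], "outlier_replicate"))
        if not drop_idx:
            kept = list(current.samples["sample"])
            report = QCReport(
                kept_samples=kept,
                dropped_samples=pd.DataFrame(
                    dropped_rows, columns=["sample", "reason"]
                ),
                iterations_to_converge=iteration,
            )
            return kept, report
        keep = np.setdiff1d(np.arange(current.n_samples), np.array(drop_idx))
        current = current.subset(sample_idx=keep)
    raise ConvergenceError(f"sample selection did not converge in {max_iter} iterations")


def log_transform(expr: ExpressionMatrix, pseudocount: float = 0.5) -> ExpressionMatrix:
    """log2(x + pseudocount); masked entries stay masked."""
    return ExpressionMatrix(
        expr.transcripts,
        expr.samples,
        np.log2(expr.values + pseudocount),
        expr.mask.copy(),
        log_scale=True,
    )


def strain_means(expr: ExpressionMatrix) -> pd.DataFrame:
    """Average replicates to one value per (transcript, strain).

    Returns a transcripts x strains DataFrame with NaN where every replicate
    of a strain is masked.
    """
    strains = expr.samples["strain"].to_numpy()
    V = expr.masked_values()
    out = {}
    for s in pd.unique(strains):
        cols = strains == s
        block = V[:, cols]
        cnt = np.sum(np.isfinite(block), axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[s] = np.where(cnt > 0, np.nansum(block, axis=1) / cnt, np.nan)
    return pd.DataFrame(out, index=expr.transcripts)
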