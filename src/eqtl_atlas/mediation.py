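"""Mediation of organism-level traits by transcript expression.

Three sub-procedures:

1. A family-wise permutation screen over many candidate mediators
   (:func:`med_test`): per mediator, the statistic is S = |a * b| on
   standardized variables, where a is the exposure->mediator path and b the
   mediator->outcome path adjusted for the exposure. Mediator rows are
   permuted jointly (preserving the exposure-outcome pairing) and each
   mediator's adjusted p-value is the fraction of permutations in which the
   family maximum statistic reaches its observed S (add-one correction), so
   the null family-wise error is controlled by construction.
2. Effect decomposition for significant mediators
   (:func:`estimate_proportion`): total effect c from Y ~ X, direct effect
   c' from Y ~ X + M, indirect = c - c', proportion mediated =
   indirect / total. For linear least squares on one sample the difference
   method is identical to the product method a*b. Proportions outside
   [0, 1] are flagged uninterpretable.
3. A regression-drop scan (:func:`regression_drop_scan`): the outcome is
   residualized on each transcript's expression in turn and re-tested at a
   (pseudo) variant marker with the mixed model; true mediators show the
   largest drops in significance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import EmptyInputError
from .ioformats import GenotypeMatrix
from .mixedmodel import KinshipDecomposition, KinshipLMM

MEDIATION_COLUMNS = [
    "exposure",
    "mediator",
    "outcome",
    "n_strains",
    "estimate",
    "p_adj",
    "total_effect",
    "direct_effect",
    "indirect_effect",
    "proportion_mediated",
    "interpretable",
    "significant",
]


@dataclass
class MediationResult:
    exposure: str
    mediator: str
    outcome: str
    n_strains: int
    estimate: float
    p_adj: float
    total_effect: float = np.nan
    direct_effect: float = np.nan
    indirect_effect: float = np.nan
    proportion_mediated: float = np.nan
    interpretable: bool = False
    significant: bool = False


def mediation_frame(results) -> pd.DataFrame:
    if not results:
        return pd.DataFrame(columns=MEDIATION_COLUMNS)
    return pd.DataFrame([asdict(r) for r in results])[MEDIATION_COLUMNS]


def assemble_triples(
    organism_qtl,
    eqtl_table: pd.DataFrame,
    expr_means: pd.DataFrame,
    G: GenotypeMatrix,
    phenotype: pd.Series,
) -> pd.DataFrame:
    """Candidate (exposure, mediator, outcome) triples for one organism QTL.

    Mediator candidates are transcripts whose eQTL interval overlaps the
    organism QTL interval by >= 1 bp (closed intervals, same chromosome).
    Strains are restricted per mediator to those with nonmissing exposure
    dosage, mediator expression, and outcome value; triples where any
    component has zero variance are dropped.

    Returns a table (mediator, n_strains) with the usable strain count.
    """
    chrom = organism_qtl.chrom
    lo, hi = organism_qtl.interval_left_bp, organism_qtl.interval_right_bp
    cand = eqtl_table[
        (eqtl_table["chrom"] == chrom)
        & (eqtl_table["interval_left_bp"] <= hi)
        & (eqtl_table["interval_right_bp"] >= lo)
    ]
    if cand.empty:
        return pd.DataFrame(columns=["mediator", "n_strains"])
    x_full = pd.Series(G.dosage_of(organism_qtl.peak_marker), index=G.strains)
    shared = [s for s in expr_means.columns if s in x_full.index and s in phenotype.index]
    rows = []
    for tid in pd.unique(cand["trait"]):
        if tid not in expr_means.index:
            continue
        m = expr_means.loc[tid, shared].to_numpy(dtype=float)
        x = x_full[shared].to_numpy(dtype=float)
        yv = phenotype[shared].to_numpy(dtype=float)
        ok = np.isfinite(m) & np.isfinite(x) & np.isfinite(yv)
        if ok.sum() < 3:
            continue
        if np.var(m[ok]) == 0 or np.var(x[ok]) == 0 or np.var(yv[ok]) == 0:
            continue
        rows.append((tid, int(ok.sum())))
    return pd.DataFrame(rows, columns=["mediator", "n_strains"])


def _corr_with_vector(v: np.ndarray, M: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson r between vector v and each column of M.

    M must be zero-filled where invalid; W is the validity indicator.
    """
    n = W.sum(axis=0)
    sv = W.T @ v
    svv = W.T @ (v * v)
    sm = M.sum(axis=0)
    smm = (M * M).sum(axis=0)
    svm = M.T @ v
    num = n * svm - sv * sm
    den = np.sqrt(np.maximum(n * svv - sv**2, 0) * np.maximum(n * smm - sm**2, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _xy_corr_per_column(x, y, W):
    """Pearson r between x and y over each column's valid strain subset."""
    n = W.sum(axis=0)
    sx, sy = W.T @ x, W.T @ y
    sxx, syy, sxy = W.T @ (x * x), W.T @ (y * y), W.T @ (x * y)
    num = n * sxy - sx * sy
    den = np.sqrt(np.maximum(n * sxx - sx**2, 0) * np.maximum(n * syy - sy**2, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _mediation_stats(x, y, M, W):
    """|a*b| per mediator column on standardized variables."""
    a = _corr_with_vector(x, M, W)
    r_my = _corr_with_vector(y, M, W)
    r_xy = _xy_corr_per_column(x, y, W)
    with np.errstate(invalid="ignore", divide="ignore"):
        b = (r_my - r_xy * a) / (1.0 - a**2)
    collinear = np.abs(a) >= 1.0 - 1e-12
    S = np.abs(a * b)
    S[collinear] = np.nan
    return S, collinear


def med_test(
    X,
    M_matrix: np.ndarray | pd.DataFrame,
    Y,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-adjusted mediation screen over a family of mediators.

    Parameters
    ----------
    X, Y : arrays, shape (n_strains,)
        Exposure dosage and outcome; must be complete.
    M_matrix : array or DataFrame, shape (n_strains, n_mediators)
        Mediator expression; NaN entries restrict that mediator's strain
        subset (pairwise-complete statistics).

    Returns a DataFrame (mediator, estimate, p_adj, collinear).
    """
    x = np.asarray(X, dtype=float)
    y = np.asarray(Y, dtype=float)
    names = (
        list(M_matrix.columns)
        if isinstance(M_matrix, pd.DataFrame)
        else [f"M{i}" for i in range(np.asarray(M_matrix).shape[1])]
    )
    M = np.asarray(M_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != len(x) or len(y) != len(x):
        raise ValueError("X, Y, M_matrix must share the strain dimension")
    if M.shape[1] < 1:
        raise EmptyInputError("need at least one mediator")
    if len(x) < 30:
        warnings.warn("fewer than 30 strains for mediation", RuntimeWarning, stacklevel=2)
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives coarse adjusted p-values", RuntimeWarning,
                      stacklevel=2)
    W = np.isfinite(M).astype(float)
    M0 = np.where(np.isfinite(M), M, 0.0)
    S_obs, collinear = _mediation_stats(x, y, M0, W)
    rng = np.random.default_rng(seed)
    n = len(x)
    exceed = np.zeros(M.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(n)
        S_perm, _ = _mediation_stats(x, y, M0[perm], W[perm])
        smax = np.nanmax(S_perm) if np.isfinite(S_perm).any() else -np.inf
        exceed += smax >= S_obs
    p_adj = (exceed + 1.0) / (n_perm + 1.0)
    p_adj[~np.isfinite(S_obs)] = np.nan
    return pd.DataFrame(
        {
            "mediator": names,
            "estimate": S_obs,
            "p_adj": p_adj,
            "collinear": collinear,
        }
    )


def estimate_proportion(X, M, Y) -> tuple[float, float, float, float, bool]:
    """Total/direct/indirect effects and the proportion mediated.

    Difference method: total c from OLS Y ~ X, direct c' from Y ~ X + M,
    indirect = c - c' (identical to the product method a*b for linear
    least squares on the same sample). Returns (total, direct, indirect,
    proportion, interpretable).
    """
    x = np.asarray(X, dtype=float)
    m = np.asarray(M, dtype=float)
    y = np.asarray(Y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(m) & np.isfinite(y)
    x, m, y = x[ok], m[ok], y[ok]
    if np.var(x) == 0 or np.var(m) == 0 or np.var(y) == 0:
        raise EmptyInputError("zero variance in X, M, or Y")
    ones = np.ones_like(x)
    total = np.linalg.lstsq(np.column_stack([ones, x]), y, rcond=None)[0][1]
    direct = np.linalg.lstsq(np.column_stack([ones, x, m]), y, rcond=None)[0][1]
    indirect = total - direct
    if abs(total) < 1e-12:
        return float(total), float(direct), float(indirect), np.nan, False
    proportion = indirect / total
    # float slack at the exact boundaries (noiseless complete mediation
    # lands at 1 +- machine epsilon)
    interpretable = bool(-1e-9 <= proportion <= 1.0 + 1e-9)
    return float(total), float(direct), float(indirect), float(proportion), interpretable


def call_significant(
    results: pd.DataFrame, alpha: float = 0.05, pct: float = 99.0
) -> pd.DataFrame:
    """Flag significant mediators: p_adj < alpha OR estimate strictly above
    the per-analysis ``pct`` percentile of all estimates. The final reported
    set additionally requires an interpretable proportion when present."""
    if results.empty:
        raise EmptyInputError("no mediation results to flag")
    out = results.copy()
    est = out["estimate"].to_numpy(dtype=float)
    finite = est[np.isfinite(est)]
    cut = np.percentile(finite, pct) if finite.size else np.inf
    sig = (out["p_adj"].to_numpy() < alpha) | (est > cut)
    out["significant"] = np.where(np.isfinite(est), sig, False)
    if "interpretable" in out.columns:
        out["reported"] = out["significant"] & out["interpretable"].fillna(False)
    return out


def make_pseudo_marker(
    variant_table: pd.DataFrame, gene_id: str, strains
) -> np.ndarray:
    """Collapse a gene's heterogeneous variants into one carrier dosage.

    ``variant_table`` lists carrier strains per variant (columns gene,
    variant, strain). Dosage is 1 iff the strain carries at least one
    qualifying variant in the gene.
    """
    sub = variant_table[variant_table["gene"] == gene_id]
    if sub.empty:
        raise EmptyInputError(f"gene {gene_id!r} absent from variant table")
    carriers = set(sub["strain"])
    dosage = np.array([1.0 if s in carriers else 0.0 for s in strains])
    if dosage.std() == 0:
        warnings.warn(
            f"pseudo marker for {gene_id!r} is monomorphic", RuntimeWarning, stacklevel=2
        )
    return dosage


def _single_marker_neglogp(y, x, K) -> float:
    kd = K if isinstance(K, KinshipDecomposition) else KinshipDecomposition(K)
    scan = KinshipLMM(y, kd).fit().scan(x.reshape(-1, 1))
    return float(scan.neglog10p[0])


def regression_drop_scan(
    Y,
    expr_means: pd.DataFrame,
    pseudo_marker,
    K,
    min_strains: int = 30,
) -> pd.DataFrame:
    """Significance at a (pseudo) marker after regressing out each transcript.

    For every transcript t the outcome is residualized on t's strain-mean
    expression by least squares and the residual trait is re-tested at the
    pseudo marker with the mixed model. Returns a table (transcript,
    neglog10p, baseline) where ``baseline`` is the unregressed significance;
    transcripts with constant expression are skipped.
    """
    y = np.asarray(Y, dtype=float)
    x = np.asarray(pseudo_marker, dtype=float)
    Kmat = K.K if hasattr(K, "K") else np.asarray(K)
    ok0 = np.isfinite(y) & np.isfinite(x)
    idx0 = np.flatnonzero(ok0)
    kd0 = KinshipDecomposition(Kmat[np.ix_(idx0, idx0)])
    baseline = _single_marker_neglogp(y[idx0], x[idx0], kd0)
    rows = []
    for tid, mrow in expr_means.iterrows():
        m = mrow.to_numpy(dtype=float)
        ok = ok0 & np.isfinite(m)
        if ok.sum() < min_strains or np.var(m[ok]) == 0:
            continue
        idx = np.flatnonzero(ok)
        ones = np.ones(len(idx))
        Z = np.column_stack([ones, m[idx]])
        resid = y[idx] - Z @ np.linalg.lstsq(Z, y[idx], rcond=None)[0]
        if np.var(resid) <= 1e-12 * max(np.var(y[idx]), 1e-300):
            continue  # outcome fully explained: nothing left to test
        kd = kd0 if np.array_equal(idx, idx0) else KinshipDecomposition(
            Kmat[np.ix_(idx, idx)]
        )
        rows.append((tid, _single_marker_neglogp(resid, x[idx], kd), baseline))
    return pd.DataFrame(rows, columns=["transcript", "neglog10p", "baseline"])


def mediate_trait(
    organism_qtl,
    eqtl_table: pd.DataFrame,
    expr_means: pd.DataFrame,
    G: GenotypeMatrix,
    phenotype: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full mediation analysis for one organism-level QTL.

    Runs the permutation screen over all overlapping-eQTL mediators, then
    the effect decomposition for significant ones, and returns the combined
    table (one row per mediator).
    """
    triples = assemble_triples(organism_qtl, eqtl_table, expr_means, G, phenotype)
    if triples.empty:
        return mediation_frame([])
    x_full = pd.Series(G.dosage_of(organism_qtl.peak_marker), index=G.strains)
    shared = [s for s in expr_means.columns if s in x_full.index and s in phenotype.index]
    x = x_full[shared].to_numpy(dtype=float)
    yv = phenotype[shared].to_numpy(dtype=float)
    M = expr_means.loc[triples["mediator"], shared].T  # strains x mediators
    screen = med_test(x, M, yv, n_perm=n_perm, seed=seed)
    screen = call_significant(screen, alpha=alpha)
    results = []
    for _, row in screen.iterrows():
        res = MediationResult(
            exposure=str(organism_qtl.peak_marker),
            mediator=str(row["mediator"]),
            outcome=str(phenotype.name or "phenotype"),
            n_strains=int(
                triples.set_index("mediator")["n_strains"][row["mediator"]]
            ),
            estimate=float(row["estimate"]),
            p_adj=float(row["p_adj"]) if np.isfinite(row["p_adj"]) else np.nan,
        )
        if row["significant"]:
            m = expr_means.loc[row["mediator"], shared].to_numpy(dtype=float)
            try:
                tot, direct, ind, prop, interp = estimate_proportion(x, m, yv)
            except EmptyInputError:
                tot = direct = ind = prop = np.nan
                interp = False
            res.total_effect = tot
            res.direct_effect = direct
            res.indirect_effect = ind
            res.proportion_mediated = prop
            res.interpretable = interp
            res.significant = bool(interp)
        results.append(res)
    return mediation_frame(results)
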