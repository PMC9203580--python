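"""Broad- and narrow-sense heritability per expression trait.

Narrow-sense h^2 is the additive variance fraction sigma_g^2 /
(sigma_g^2 + sigma_e^2) from the kinship REML fit of the strain-mean trait.
Broad-sense H^2 is the strain-level variance fraction from a one-way
random-intercept model on replicate-level values (phenotype ~ 1 +
(1|strain)), fit by REML with the variance ratio profiled out, which
handles unbalanced replicate counts and reduces to the ANOVA closed form
for balanced designs. Negative variance estimates are truncated at zero, so
both statistics lie in [0, 1] by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import DegenerateInputError
from .mixedmodel import KinshipDecomposition, reml_null


@dataclass
class HeritabilityEstimate:
    trait: str
    H2: float
    h2: float


def narrow_h2(y, K, trait: str = "trait") -> float:
    """Kinship-based narrow-sense heritability of a strain-mean trait."""
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(y)
    if not ok.all():
        idx = np.flatnonzero(ok)
        Ksub = (K.K if hasattr(K, "K") else np.asarray(K))[np.ix_(idx, idx)]
        y, K = y[idx], Ksub
    vc = reml_null(y, K, trait=trait)
    return float(np.clip(vc.h2, 0.0, 1.0))


def _oneway_reml_negloglik(loggamma, n_i, ybar_i, ssw, N):
    """-2x profiled REML log-likelihood of the one-way random-intercept model
    at variance ratio gamma = sigma_strain^2 / sigma_resid^2 (up to const)."""
    gamma = np.exp(loggamma)
    w = n_i / (1.0 + gamma * n_i)
    mu = np.sum(w * ybar_i) / np.sum(w)
    Q = ssw + np.sum(n_i * (ybar_i - mu) ** 2 / (1.0 + gamma * n_i))
    s2 = Q / (N - 1)
    if s2 <= 0:
        return np.inf
    return (
        (N - 1) * np.log(s2)
        + np.sum(np.log1p(gamma * n_i))
        + np.log(np.sum(w))
    )


def broad_H2(y, strain_labels) -> float:
    """Strain-level variance fraction from replicate-level values.

    Requires at least two strains with two or more replicates and nonzero
    total variance. Returns sigma_strain^2 / (sigma_strain^2 + sigma_resid^2).
    """
    y = np.asarray(y, dtype=float)
    labels = np.asarray(strain_labels)
    ok = np.isfinite(y)
    y, labels = y[ok], labels[ok]
    groups = pd.Series(y).groupby(labels)
    n_i = groups.count().to_numpy(dtype=float)
    if (n_i >= 2).sum() < 2:
        raise DegenerateInputError("need >= 2 strains with >= 2 replicates")
    ybar_i = groups.mean().to_numpy()
    ssw = float(((y - groups.transform("mean").to_numpy()) ** 2).sum())
    N = len(y)
    if np.var(y) <= 0:
        raise DegenerateInputError("replicate values have zero variance")
    f = lambda lg: _oneway_reml_negloglik(lg, n_i, ybar_i, ssw, N)
    grid = np.linspace(-14.0, 14.0, 57)
    vals = np.array([f(g) for g in grid])
    k = int(np.argmin(vals))
    res = optimize.minimize_scalar(
        f,
        bounds=(grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]),
        method="bounded",
        options={"xatol": 1e-12},
    )
    best = res.x if res.fun <= vals[k] else grid[k]
    # compare against the gamma -> 0 boundary (no strain variance)
    if f(best) > f(-300.0):
        return 0.0
    gamma = float(np.exp(best))
    return gamma / (1.0 + gamma)


def heritability_table(
    trait_matrix: pd.DataFrame,
    replicate_expr,
    K,
) -> pd.DataFrame:
    """Per-trait H^2 and h^2 table.

    ``trait_matrix`` is transcripts x strains (strain means, mapping scale);
    ``replicate_expr`` is a log-scale ExpressionMatrix at replicate level.
    Traits failing either estimator are reported as NaN.
    """
    kd = KinshipDecomposition(K) if not isinstance(K, KinshipDecomposition) else K
    strains = list(trait_matrix.columns)
    rep_vals = replicate_expr.masked_values()
    rep_strains = replicate_expr.samples["strain"].to_numpy()
    rep_index = {t: i for i, t in enumerate(replicate_expr.transcripts)}
    rows = []
    for tid, y in trait_matrix.iterrows():
        yv = y.to_numpy(dtype=float)
        try:
            if np.isfinite(yv).all():
                from .mixedmodel import KinshipLMM

                h2 = float(np.clip(KinshipLMM(yv, kd, trait=str(tid)).fit().vc.h2, 0, 1))
            else:
                h2 = narrow_h2(yv, kd_to_matrix(kd), trait=str(tid))
        except DegenerateInputError:
            h2 = np.nan
        try:
            i = rep_index[tid]
            H2 = broad_H2(rep_vals[i], rep_strains)
        except (KeyError, DegenerateInputError):
            H2 = np.nan
        rows.append((tid, H2, h2))
    return pd.DataFrame(rows, columns=["trait", "H2", "h2"])


def kd_to_matrix(kd: KinshipDecomposition) -> np.ndarray:
    """Reconstruct K from its decomposition (for strain-subset refits)."""
    return (kd.U * kd.d) @ kd.U.T
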