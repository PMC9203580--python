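"""Linear mixed-model machinery for association mapping on inbred panels.

Model
-----
For a strain-level trait ``y`` (n strains) and kinship ``K``::

    y = mu + g + e,    g ~ N(0, sigma_g^2 K),    e ~ N(0, sigma_e^2 I)

Variance components are estimated by REML over the ratio
``delta = sigma_e^2 / sigma_g^2`` after a single eigendecomposition of K
(the EMMA trick). Per-marker association tests then fix the null-model
variance components for every marker (the P3D / EMMAX approximation) and
test each marker by generalized least squares in the whitened basis with an
F statistic on (1, n-2) degrees of freedom.

The module also computes the effective number of independent tests (Meff,
Li & Ji style: eigenvalues of the marker correlation matrix) and the
derived significance thresholds: EIGEN = -log10(0.05 / Meff) and the
Bonferroni analog over the full marker count.

The model/results pair (:class:`KinshipLMM` / :class:`KinshipLMMResults`)
is the object interface; :func:`reml_null` and :func:`gls_scan` are thin
functional wrappers used by the pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import DegenerateInputError, FormatError
from .genorel import KinshipMatrix

P_FLOOR = 1e-300  # keeps -log10(p) finite
DELTA_BOUNDS = (1e-5, 1e5)
DELTA_GRID = 100


@dataclass
class VarianceComponents:
    """REML variance components of the null (no-marker) mixed model."""

    sigma_g2: float
    sigma_e2: float
    reml_loglik: float
    boundary: bool = False

    @property
    def delta(self) -> float:
        if self.sigma_g2 <= 0:
            return np.inf
        return self.sigma_e2 / self.sigma_g2

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return 0.0 if tot <= 0 else self.sigma_g2 / tot


@dataclass
class ScanResult:
    """Per-marker association results for one trait."""

    trait: str
    neglog10p: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    monomorphic: np.ndarray
    n_used: int

    def pvalues(self) -> np.ndarray:
        return 10.0 ** (-self.neglog10p)


@dataclass
class ThresholdSpec:
    """Significance thresholds on the -log10(p) scale."""

    n_test: float
    m_markers: int
    eigen_threshold: float
    bf_threshold: float
    fdr5_eigen: float | None = None
    fdr5_bf: float | None = None

    def threshold(self, mode: str = "eigen", fdr: bool = False) -> float:
        if mode not in ("eigen", "bf"):
            raise ValueError(f"unknown threshold mode {mode!r}")
        if fdr:
            value = self.fdr5_eigen if mode == "eigen" else self.fdr5_bf
            if value is None:
                raise ValueError(f"no FDR calibration stored for mode {mode!r}")
            return value
        return self.eigen_threshold if mode == "eigen" else self.bf_threshold


class KinshipDecomposition:
    """Cached eigendecomposition of a kinship matrix.

    Eigendecomposing K once makes both REML (over many traits or
    permutations) and the per-marker scans cheap: every operation reduces to
    diagonal weighting in the rotated basis.
    """

    def __init__(self, K, strains=None):
        if isinstance(K, KinshipMatrix):
            strains = K.strains if strains is None else strains
            K = K.K
        K = np.asarray(K, dtype=float)
        n = K.shape[0]
        if K.shape != (n, n) or not np.allclose(K, K.T, atol=1e-8):
            raise FormatError("kinship must be a symmetric square matrix")
        d, U = np.linalg.eigh(0.5 * (K + K.T))
        if d.min() < -1e-8 * max(d.max(), 1.0):
            raise FormatError("kinship matrix is not positive semi-definite")
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.n = n
        self.strains = None if strains is None else np.asarray(strains, dtype=object)
        self.ones_rot = U.T @ np.ones(n)

    def rotate(self, A: np.ndarray) -> np.ndarray:
        """U' A for a vector or (n x m) matrix."""
        return self.U.T @ A


def _reml_loglik(logdelta: float, d: np.ndarray, yr: np.ndarray, xr: np.ndarray):
    """Profiled REML log-likelihood at delta = exp(logdelta).

    Returns (loglik, sigma_g2_hat) for the intercept-only model.
    """
    delta = np.exp(logdelta)
    n = len(yr)
    w = d + delta
    xtx = np.sum(xr * xr / w)
    beta = np.sum(xr * yr / w) / xtx
    r = yr - xr * beta
    q = 1
    s2 = np.sum(r * r / w) / (n - q)
    if s2 <= 0:
        return -np.inf, 0.0
    ll = -0.5 * (
        (n - q) * (np.log(2 * np.pi * s2) + 1.0)
        + np.sum(np.log(w))
        + np.log(xtx)
        - np.log(float(n))
    )
    return ll, s2


class KinshipLMM:
    """Null mixed model for one strain-level trait under a kinship covariance.

    Parameters
    ----------
    y : array, shape (n,)
        Strain-level trait values (no NaN; subset strains beforehand).
    kinship : KinshipMatrix, ndarray, or KinshipDecomposition
        Genetic covariance among the same n strains.
    trait : str
        Label carried through to scan results.
    """

    def __init__(self, y, kinship, trait: str = "trait"):
        self.y = np.asarray(y, dtype=float)
        if np.isnan(self.y).any():
            raise FormatError("trait vector contains NaN; restrict strains first")
        self.kd = (
            kinship
            if isinstance(kinship, KinshipDecomposition)
            else KinshipDecomposition(kinship)
        )
        if len(self.y) != self.kd.n:
            raise FormatError("trait length does not match kinship dimension")
        if np.var(self.y) <= 0:
            raise DegenerateInputError("trait has zero variance")
        self.trait = trait

    def fit(self, grid: int = DELTA_GRID, bounds=DELTA_BOUNDS) -> "KinshipLMMResults":
        """REML over delta: log-grid search plus local refinement."""
        yr = self.kd.rotate(self.y)
        xr = self.kd.ones_rot
        d = self.kd.d
        logs = np.log(np.logspace(np.log10(bounds[0]), np.log10(bounds[1]), grid))
        lls = np.array([_reml_loglik(ld, d, yr, xr)[0] for ld in logs])
        k = int(np.argmax(lls))
        lo = logs[max(k - 1, 0)]
        hi = logs[min(k + 1, grid - 1)]
        res = optimize.minimize_scalar(
            lambda ld: -_reml_loglik(ld, d, yr, xr)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        best = res.x if -res.fun >= lls[k] else logs[k]
        ll, sg2 = _reml_loglik(best, d, yr, xr)
        # boundary flag (e.g. sigma_g^2 effectively 0): components still valid
        vc = VarianceComponents(
            sigma_g2=float(sg2),
            sigma_e2=float(np.exp(best) * sg2),
            reml_loglik=float(ll),
            boundary=k in (0, grid - 1),
        )
        return KinshipLMMResults(self, vc)


class KinshipLMMResults:
    """Fitted variance components plus marker-scan machinery."""

    def __init__(self, model: KinshipLMM, vc: VarianceComponents):
        self.model = model
        self.vc = vc

    @property
    def h2(self) -> float:
        return self.vc.h2

    def scan(self, G, rotated: np.ndarray | None = None) -> ScanResult:
        """Per-marker GLS association tests with fixed variance components.

        Parameters
        ----------
        G : ndarray (n x m) or GenotypeMatrix
            Marker dosages for the same strains as the model.
        rotated : ndarray, optional
            Precomputed ``U' G`` (saves the rotation when scanning many
            traits against one marker set).
        """
        dosage = G if isinstance(G, np.ndarray) else G.dosage
        if np.isnan(dosage).any():
            raise FormatError("scan requires complete dosages; filter markers first")
        kd = self.model.kd
        Gr = kd.rotate(dosage) if rotated is None else rotated
        yr = kd.rotate(self.model.y)
        mono = np.ptp(dosage, axis=0) == 0
        return _scan_rotated(
            yr, Gr, kd.d, kd.ones_rot, self.vc, mono, trait=self.model.trait
        )

    def summary(self) -> str:
        vc = self.vc
        lines = [
            f"KinshipLMM REML fit: trait={self.model.trait!r}, n={len(self.model.y)}",
            f"  sigma_g^2 = {vc.sigma_g2:.6g}",
            f"  sigma_e^2 = {vc.sigma_e2:.6g}",
            f"  h^2       = {vc.h2:.4f}",
            f"  REML loglik = {vc.reml_loglik:.4f}"
            + ("  [delta at boundary]" if vc.boundary else ""),
        ]
        return "\n".join(lines)


def _scan_rotated(yr, Gr, d, ones_rot, vc: VarianceComponents, mono, trait="trait"):
    """Vectorized GLS scan in the rotated basis with V fixed from ``vc``."""
    n = len(yr)
    w = vc.sigma_g2 * d + vc.sigma_e2
    w = np.maximum(w, 1e-12 * max(w.max(), 1.0))
    sw = 1.0 / np.sqrt(w)
    yw = yr * sw
    iw = ones_rot * sw
    Gw = Gr * sw[:, None]
    ii = iw @ iw
    # residualize trait and markers against the whitened intercept
    yP = yw - iw * (iw @ yw) / ii
    XP = Gw - np.outer(iw, (iw @ Gw) / ii)
    sxx = np.einsum("ij,ij->j", XP, XP)
    sxy = XP.T @ yP
    syy = float(yP @ yP)
    bad = mono | (sxx <= 1e-12 * max(syy, 1.0))
    sxx_safe = np.where(bad, 1.0, sxx)
    beta = sxy / sxx_safe
    rss = np.maximum(syy - sxy * sxy / sxx_safe, 0.0)
    df = n - 2
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = (sxy * sxy / sxx_safe) / np.where(sigma2 > 0, sigma2, np.nan)
        se = np.sqrt(sigma2 / sxx_safe)
    fstat = np.where(np.isnan(fstat), np.inf, fstat)
    p = stats.f.sf(fstat, 1, df)
    p = np.clip(p, P_FLOOR, 1.0)
    p[bad] = 1.0
    beta = np.where(bad, 0.0, beta)
    se = np.where(bad, np.nan, se)
    return ScanResult(
        trait=trait,
        neglog10p=-np.log10(p),
        beta=beta,
        se=se,
        monomorphic=np.asarray(bad),
        n_used=n,
    )


# ---------------------------------------------------------------------------
# Functional wrappers and thresholds
# ---------------------------------------------------------------------------


def reml_null(y, K, trait: str = "trait") -> VarianceComponents:
    """REML variance components of the null model (see :class:`KinshipLMM`)."""
    return KinshipLMM(y, K, trait=trait).fit().vc


def gls_scan(y, G, K, vc: VarianceComponents | None = None, trait="trait") -> ScanResult:
    """Marker scan for one trait; fits the null model first if ``vc`` is None."""
    model = KinshipLMM(y, K, trait=trait)
    if vc is None:
        results = model.fit()
    else:
        results = KinshipLMMResults(model, vc)
    return results.scan(G)


def meff_li_ji(G) -> float:
    """Effective number of independent tests from the marker correlation spectrum.

    Meff = sum_i [ 1(lambda_i >= 1) + (lambda_i - floor(lambda_i)) ] over the
    eigenvalues of the marker-marker correlation matrix. The spectrum is
    computed on whichever side (marker or strain) of the standardized dosage
    matrix is smaller; both carry the same nonzero eigenvalues.
    """
    dosage = G if isinstance(G, np.ndarray) else G.dosage
    n, m = dosage.shape
    if m < 2:
        raise DegenerateInputError("Meff needs at least two markers")
    sd = dosage.std(axis=0)
    if (sd == 0).any():
        raise DegenerateInputError("Meff requires polymorphic markers")
    Z = (dosage - dosage.mean(axis=0)) / sd
    if m <= n:
        C = (Z.T @ Z) / n
    else:
        C = (Z @ Z.T) / n
    lam = np.clip(np.linalg.eigvalsh(C), 0.0, None)
    # exact-multiple eigenvalues (duplicated markers) land at integers up to
    # rounding noise; snap before the floor decomposition
    lam = np.round(lam, 9)
    return float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))


def make_thresholds(n_test: float, m: int, fdr_calibration=None) -> ThresholdSpec:
    """Derive EIGEN and Bonferroni -log10(p) thresholds.

    ``fdr_calibration`` optionally supplies permutation-calibrated cutoffs as
    a mapping with keys 'eigen' and/or 'bf'.
    """
    if n_test < 1:
        raise ValueError("n_test must be >= 1")
    if n_test > m:
        warnings.warn(
            f"n_test={n_test:.1f} exceeds marker count m={m}", RuntimeWarning, stacklevel=2
        )
    fdr_calibration = fdr_calibration or {}
    return ThresholdSpec(
        n_test=float(n_test),
        m_markers=int(m),
        eigen_threshold=float(-np.log10(0.05 / n_test)),
        bf_threshold=float(-np.log10(0.05 / m)),
        fdr5_eigen=fdr_calibration.get("eigen"),
        fdr5_bf=fdr_calibration.get("bf"),
    )
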