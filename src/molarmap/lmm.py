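"""Univariate linear mixed-model association with a kinship random effect.

Model per phenotype (a shape PC score, or centroid size)::

    y = W a + x b + u + e,   u ~ N(0, sg^2 K),   e ~ N(0, se^2 I)

with ``K`` the centered kinship matrix built from all SNPs.  The variance
ratio ``lambda = sg^2 / se^2`` is estimated once per phenotype by REML
under the null (no SNP term) using the eigendecomposition of K and a
one-dimensional search on log10(lambda); every SNP is then scored by
generalized least squares in the eigen-rotated frame with that lambda held
fixed (per-SNP re-optimisation is available behind a flag but makes a
negligible difference for small effects).

``pve`` — the proportion of phenotypic variance explained by the kinship
term — is ``sg^2 * tau / (sg^2 * tau + se^2)`` with ``tau = tr(K)/n``; its
standard error comes from the observed information of the REML surface via
the delta method.

Genome-wide significance is calibrated empirically: the phenotype is
permuted across individuals (kinship and genotypes jointly held fixed),
the best p-value of each permuted scan is recorded, and the threshold is
the quantile of that minimum-p distribution such that only 5% of null
scans beat it.  X-chromosome SNPs get their own threshold, computed over X
SNPs only.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.typing import NDArray
from scipy import optimize, stats

from .geno import GenotypePanel, mean_impute

__all__ = [
    "KinshipMatrix",
    "LMMFit",
    "ThresholdSet",
    "centered_kinship",
    "reml_loglik",
    "fit_lmm_null",
    "score_snp",
    "score_all_snps",
    "association_scan",
    "permutation_thresholds",
]

LOG10_LAMBDA_BRACKET = (-5.0, 5.0)


@dataclasses.dataclass
class KinshipMatrix:
    """Symmetric PSD relatedness matrix with its individual ids."""

    matrix: NDArray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        K = np.asarray(self.matrix, dtype=float)
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        self.matrix = (K + K.T) / 2


@dataclasses.dataclass
class LMMFit:
    """Null-model variance components for one phenotype."""

    lam: float                 # sg^2 / se^2
    pve: float
    pve_se: float
    sigma_g2: float
    sigma_e2: float
    loglik: float
    boundary: bool             # optimiser pinned at a bracket end


@dataclasses.dataclass
class ThresholdSet:
    """Per-phenotype permutation thresholds, autosomes and X separately."""

    thresholds: dict[str, dict[str, float | None]]
    n_perm: int
    quantile: float
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "thresholds": self.thresholds,
                    "n_perm": self.n_perm,
                    "quantile": self.quantile,
                    "seed": self.seed,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSet":
        d = json.loads(Path(path).read_text())
        return cls(d["thresholds"], d["n_perm"], d["quantile"], d["seed"])


# ---------------------------------------------------------------------------
# kinship


def centered_kinship(panel: GenotypePanel) -> KinshipMatrix:
    """Centered kinship ``K = Xc Xc^T / p`` from mean-imputed dosages.

    Columns are centered by their sample mean; monomorphic SNPs therefore
    contribute exactly zero.  ``p`` is the SNP count.
    """
    if panel.n_snps == 0:
        raise ValueError("cannot build kinship from an empty panel")
    X = mean_impute(panel)
    Xc = X - X.mean(axis=0, keepdims=True)
    K = Xc @ Xc.T / panel.n_snps
    return KinshipMatrix(matrix=K, individual_ids=list(panel.individual_ids))


class _EigenK:
    """Cached eigendecomposition of K with the rotated covariate block."""

    def __init__(self, K: NDArray, W: NDArray):
        K = np.asarray(K, dtype=float)
        s, U = np.linalg.eigh((K + K.T) / 2)
        if s.min() < -1e-8 * max(1.0, s.max()):
            raise ValueError("kinship matrix is not positive semi-definite")
        self.s = np.clip(s, 0.0, None)
        self.U = U
        self.tau = float(np.trace(K) / K.shape[0])
        self.Wt = U.T @ W

    def rotate(self, v: NDArray) -> NDArray:
        return self.U.T @ v


def _reml_core(
    log10_lam: float, eig: _EigenK, yt: NDArray
) -> tuple[float, float]:
    """REML log-likelihood and the residual quadratic form at one lambda."""
    lam = 10.0**log10_lam
    v = lam * eig.s + 1.0
    n, c = yt.shape[0], eig.Wt.shape[1]
    Wv = eig.Wt / v[:, None]
    WtVW = eig.Wt.T @ Wv
    beta = np.linalg.solve(WtVW, Wv.T @ yt)
    yv = yt / v
    R = float(yt @ yv - (Wv.T @ yt) @ beta)
    R = max(R, 1e-300)
    sign, logdet_WtVW = np.linalg.slogdet(WtVW)
    _, logdet_WtW = np.linalg.slogdet(eig.Wt.T @ eig.Wt)
    ll = -0.5 * (
        (n - c) * np.log(2.0 * np.pi * R / (n - c))
        + (n - c)
        + np.log(v).sum()
        + logdet_WtVW
        - logdet_WtW
    )
    return float(ll), R


def reml_loglik(
    lam: float, y: NDArray, K: NDArray, covariates: NDArray | None = None
) -> float:
    """Restricted log-likelihood at a given variance ratio ``lambda``.

    Exposed so the optimiser can be validated against brute-force grids.
    """
    y = np.asarray(y, dtype=float)
    W = _design(len(y), covariates)
    eig = _EigenK(np.asarray(K), W)
    ll, _ = _reml_core(np.log10(max(lam, 1e-300)), eig, eig.rotate(y))
    return ll


def _design(n: int, covariates: NDArray | None) -> NDArray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.hstack([np.ones((n, 1)), C])


def _optimize_log10_lambda(
    eig: _EigenK,
    yt: NDArray,
    bracket: tuple[float, float],
    n_grid: int,
) -> tuple[float, bool]:
    """Grid + Brent maximisation of the REML surface on log10(lambda)."""
    grid = np.linspace(bracket[0], bracket[1], n_grid)
    lls = np.array([_reml_core(g, eig, yt)[0] for g in grid])
    i = int(np.argmax(lls))
    boundary = i in (0, n_grid - 1)
    if boundary:
        return float(grid[i]), True
    res = optimize.minimize_scalar(
        lambda g: -_reml_core(g, eig, yt)[0],
        bracket=(grid[i - 1], grid[i], grid[i + 1]),
        method="brent",
        options={"xtol": 1e-8},
    )
    return float(np.clip(float(res.x), *bracket)), False


def fit_lmm_null(
    y: NDArray,
    K: KinshipMatrix | NDArray,
    covariates: NDArray | None = None,
    bracket: tuple[float, float] = LOG10_LAMBDA_BRACKET,
    n_grid: int = 80,
) -> LMMFit:
    """REML fit of the null mixed model (no SNP term) for one phenotype.

    A coarse grid on log10(lambda) brackets the optimum, Brent refines
    it.  ``boundary`` flags estimates pinned at either bracket end.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    Km = K.matrix if isinstance(K, KinshipMatrix) else np.asarray(K)
    W = _design(n, covariates)
    if n < W.shape[1] + 3:
        raise ValueError("too few individuals for a mixed-model fit")
    eig = _EigenK(Km, W)
    yt = eig.rotate(y)
    best, boundary = _optimize_log10_lambda(eig, yt, bracket, n_grid)
    ll, R = _reml_core(best, eig, yt)
    lam = 10.0**best
    c = W.shape[1]
    sigma_e2 = R / (n - c)
    sigma_g2 = lam * sigma_e2
    tau = eig.tau
    pve = lam * tau / (lam * tau + 1.0)

    # delta-method se on pve from the observed information in log10(lambda)
    h = 1e-3
    ll_p = _reml_core(min(best + h, bracket[1]), eig, yt)[0]
    ll_m = _reml_core(max(best - h, bracket[0]), eig, yt)[0]
    info = -(ll_p - 2 * ll + ll_m) / h**2
    dpve = np.log(10.0) * lam * tau / (lam * tau + 1.0) ** 2
    pve_se = float(dpve / np.sqrt(info)) if info > 0 else float("nan")

    return LMMFit(
        lam=float(lam),
        pve=float(pve),
        pve_se=pve_se,
        sigma_g2=float(sigma_g2),
        sigma_e2=float(sigma_e2),
        loglik=float(ll),
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# SNP scoring


def _batch_score(
    yt: NDArray, Gt: NDArray, at: NDArray, w: NDArray
) -> tuple[NDArray, NDArray, NDArray]:
    """Weighted GLS of each phenotype column on [intercept, SNP].

    ``yt`` (n, m) rotated phenotypes, ``Gt`` (n, p) rotated SNPs, ``at``
    (n,) rotated intercept, ``w`` (n,) inverse eigen-variances.  Returns
    beta, se, p with shape (p, m).  Wald p from t with n - 2 df.
    """
    n = yt.shape[0]
    wa = w * at
    A = float(at @ wa)                       # scalar
    Bv = Gt.T @ wa                           # (p,)
    Cv = np.einsum("ij,ij->j", Gt, w[:, None] * Gt)  # (p,)
    D = A * Cv - Bv**2                       # (p,)
    Say = yt.T @ wa                          # (m,)
    Syy = np.einsum("ij,ij->j", yt, w[:, None] * yt)  # (m,)
    Sgy = Gt.T @ (w[:, None] * yt)           # (p, m)

    degenerate = D <= 1e-12 * max(A, 1.0) ** 2
    D_safe = np.where(degenerate, 1.0, D)
    beta = (A * Sgy - Bv[:, None] * Say[None, :]) / D_safe[:, None]
    beta0 = (Cv[:, None] * Say[None, :] - Bv[:, None] * Sgy) / D_safe[:, None]
    rss = Syy[None, :] - beta0 * Say[None, :] - beta * Sgy
    rss = np.clip(rss, 1e-300, None)
    se2 = rss / (n - 2) * (A / D_safe)[:, None]
    se = np.sqrt(se2)
    t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    beta[degenerate] = 0.0
    se[degenerate] = np.nan
    p[degenerate] = 1.0
    return beta, se, p


def score_all_snps(
    y: NDArray,
    G: NDArray,
    K: KinshipMatrix | NDArray,
    lam: float,
) -> tuple[NDArray, NDArray, NDArray]:
    """Score every SNP column of ``G`` against one phenotype at fixed lambda."""
    y = np.asarray(y, dtype=float)
    Km = K.matrix if isinstance(K, KinshipMatrix) else np.asarray(K)
    eig = _EigenK(Km, np.ones((len(y), 1)))
    w = 1.0 / (lam * eig.s + 1.0)
    yt = eig.rotate(y)[:, None]
    Gt = eig.U.T @ np.asarray(G, dtype=float)
    at = eig.Wt[:, 0]
    beta, se, p = _batch_score(yt, Gt, at, w)
    return beta[:, 0], se[:, 0], p[:, 0]


def score_snp(
    y: NDArray,
    g: NDArray,
    K: KinshipMatrix | NDArray,
    lam: float,
) -> tuple[float, float, float]:
    """GLS Wald test of one SNP (monomorphic SNPs return beta 0, p 1)."""
    beta, se, p = score_all_snps(y, np.asarray(g, dtype=float)[:, None], K, lam)
    return float(beta[0]), float(se[0]), float(p[0])


def association_scan(
    phenotypes: pd.DataFrame | NDArray,
    panel: GenotypePanel,
    K: KinshipMatrix | None = None,
    reoptimize_per_snp: bool = False,
) -> tuple[pd.DataFrame, dict[str, LMMFit]]:
    """Scan every phenotype column against every SNP.

    Returns a long results table (phenotype, snp_id, chromosome, position,
    beta, se, p) and the per-phenotype null fits.  With
    ``reoptimize_per_snp`` the variance ratio is re-estimated for each SNP
    (exact but slow); the default reuses the null-model lambda.
    """
    if isinstance(phenotypes, np.ndarray):
        phenotypes = pd.DataFrame(
            phenotypes,
            columns=[f"PC{i+1}" for i in range(phenotypes.shape[1])],
        )
    if K is None:
        K = centered_kinship(panel)
    G = mean_impute(panel)
    eig = _EigenK(K.matrix, np.ones((panel.n_individuals, 1)))
    Gt = eig.U.T @ G
    at = eig.Wt[:, 0]
    fits: dict[str, LMMFit] = {}
    frames = []
    for name in phenotypes.columns:
        y = phenotypes[name].to_numpy(dtype=float)
        fit = fit_lmm_null(y, K)
        fits[name] = fit
        if reoptimize_per_snp:
            rows = []
            for j in range(panel.n_snps):
                g = G[:, j]
                if np.ptp(g) == 0:
                    rows.append((0.0, np.nan, 1.0))
                    continue
                fit_j = fit_lmm_null(y, K, covariates=g)
                rows.append(score_snp(y, g, K, fit_j.lam))
            beta, se, p = map(np.asarray, zip(*rows))
        else:
            w = 1.0 / (fit.lam * eig.s + 1.0)
            yt = eig.rotate(y)[:, None]
            b, s, pv = _batch_score(yt, Gt, at, w)
            beta, se, p = b[:, 0], s[:, 0], pv[:, 0]
        frames.append(
            pd.DataFrame(
                {
                    "phenotype": name,
                    "snp_id": panel.snp_ids,
                    "chromosome": panel.chrom,
                    "position": panel.pos,
                    "beta": beta,
                    "se": se,
                    "p": p,
                }
            )
        )
    return pd.concat(frames, ignore_index=True), fits


# ---------------------------------------------------------------------------
# permutation thresholds


def permutation_thresholds(
    phenotypes: pd.DataFrame | NDArray,
    panel: GenotypePanel,
    K: KinshipMatrix | None = None,
    n_perm: int = 10_000,
    quantile: float = 0.95,
    seed: int = 0,
    refit_lambda: bool = True,
) -> ThresholdSet:
    """Permutation-derived genome-wide significance thresholds.

    Per phenotype, the phenotype vector is permuted across individuals
    (genotypes and kinship jointly fixed), every permuted phenotype is
    scanned exactly as a real one — variance ratio re-estimated by REML
    (``refit_lambda=False`` reuses the observed phenotype's lambda for
    speed), all SNPs scored — and the minimum p is recorded; the
    threshold is the p-value such that a fraction ``1 - quantile`` of
    null scans produce a smaller minimum p.  Autosomal and X SNPs get
    separate thresholds; a class with fewer than 2 SNPs is reported as
    ``None`` with a warning.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    if isinstance(phenotypes, np.ndarray):
        phenotypes = pd.DataFrame(
            phenotypes,
            columns=[f"PC{i+1}" for i in range(phenotypes.shape[1])],
        )
    if K is None:
        K = centered_kinship(panel)
    G = mean_impute(panel)
    n = panel.n_individuals
    eig = _EigenK(K.matrix, np.ones((n, 1)))
    Gt = eig.U.T @ G
    at = eig.Wt[:, 0]
    is_x = panel.is_x
    classes = {"autosome": ~is_x, "X": is_x}

    rng = np.random.default_rng(seed)
    thresholds: dict[str, dict[str, float | None]] = {}
    for name in phenotypes.columns:
        y = phenotypes[name].to_numpy(dtype=float)
        fit = fit_lmm_null(y, K)
        w_fixed = 1.0 / (fit.lam * eig.s + 1.0)
        min_p = {cls: np.empty(n_perm) for cls in classes}
        for b in range(n_perm):
            yp = rng.permutation(y)
            yt = eig.U.T @ yp
            if refit_lambda:
                lam = 10.0 ** _optimize_log10_lambda(
                    eig, yt, LOG10_LAMBDA_BRACKET, 80
                )[0]
                w = 1.0 / (lam * eig.s + 1.0)
            else:
                w = w_fixed
            _, _, p = _batch_score(yt[:, None], Gt, at, w)
            for cls, mask in classes.items():
                if mask.sum() >= 2:
                    min_p[cls][b] = p[mask, 0].min()
        entry: dict[str, float | None] = {}
        for cls, mask in classes.items():
            if mask.sum() < 2:
                warnings.warn(
                    f"fewer than 2 {cls} SNPs: no {cls} threshold for {name}"
                )
                entry[cls] = None
            else:
                # Weibull (type-6) quantile: its expected exceedance over a
                # fresh null scan equals (1 - quantile) exactly, making the
                # threshold unbiased rather than slightly anti-conservative
                entry[cls] = float(
                    np.quantile(min_p[cls], 1.0 - quantile, method="weibull")
                )
        thresholds[name] = entry
    return ThresholdSet(
        thresholds=thresholds, n_perm=n_perm, quantile=quantile, seed=seed
    )
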