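"""Kinship, REML variance components, heritability and the EMMAX scan.

The model is the single-random-effect mixed model

    y = 1*mu + u + e,   u ~ N(0, sigma_a2 * K),   e ~ N(0, sigma_e2 * I),

with K a kinship matrix over accessions. REML estimation works in the
eigenbasis of S K S (S the projection removing fixed effects), where the
restricted likelihood is a cheap one-dimensional function of
delta = sigma_e2 / sigma_a2; it is maximised on a 100-point grid of
log(delta) in [-10, 10] refined by bounded local optimisation. Narrow-sense
heritability is h2 = sigma_a2 / (sigma_a2 + sigma_e2) = 1 / (1 + delta).

The association scan uses the EMMAX shortcut: variance components are
estimated once under the null (intercept-only) model and held fixed; each
SNP is then tested by generalised least squares, implemented by rotating
the phenotype and the (mean-imputed) SNP vectors through the eigenbasis of
K. The SNP coefficient is referred to a t distribution with n - 2 degrees
of freedom. An exact mode refitting delta per SNP is available for
debugging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import AssociationResult, GenotypeDataset, VarianceComponents
from .errors import ValidationError

logger = logging.getLogger(__name__)

LOG_DELTA_GRID = np.linspace(-10.0, 10.0, 100)
RARE_MAF_UPPER = 0.10


@dataclass
class KinshipMatrix:
    """Symmetric positive (semi)definite relatedness matrix over samples."""

    matrix: np.ndarray
    method: str
    sample_ids: list[str]

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _imputed_calls(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Float call matrix with per-SNP mean imputation.

    Returns (imputed matrix, allele frequency per SNP, n non-missing per SNP).
    """
    x = ds.calls.astype(float)
    miss = ds.calls < 0
    x[miss] = np.nan
    n_used = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(x, axis=0)
    rows, cols = np.where(miss)
    x[rows, cols] = p[cols]
    return x, p, n_used


def compute_kinship(ds: GenotypeDataset, method: str = "standardized") -> KinshipMatrix:
    """Kinship from the call matrix.

    ``standardized``: K = Z Z^T / m over the m polymorphic SNPs, Z columns
    centred by allele frequency and scaled by sqrt(p(1-p)).
    ``ibs``: mean proportion of shared alleles. Missing calls are
    mean-imputed for this computation only. A ridge of 1e-6 is added to the
    diagonal if the smallest eigenvalue is negative.
    """
    if ds.n_samples < 2:
        raise ValidationError("kinship needs at least 2 samples")
    x, p, n_used = _imputed_calls(ds)
    dropped = int((n_used == 0).sum())
    if dropped:
        logger.warning("dropped %d all-missing SNPs from kinship", dropped)
    keep = (n_used > 0) & (p > 0.0) & (p < 1.0)
    if keep.sum() < 2:
        raise ValidationError("fewer than 2 polymorphic SNPs; cannot form kinship")
    x = x[:, keep]
    p = p[keep]
    m = x.shape[1]
    if method == "standardized":
        z = (x - p) / np.sqrt(p * (1.0 - p))
        k = z @ z.T / m
    elif method == "ibs":
        # P(shared allele) for 0/1 calls: 1 - |x_i - x_j|, averaged over SNPs
        k = 1.0 - (x @ (1.0 - x).T + (1.0 - x) @ x.T) / m
    else:
        raise ValueError(f"unknown kinship method: {method!r}")
    k = (k + k.T) / 2.0
    if np.linalg.eigvalsh(k).min() < 0.0:
        k = k + 1e-6 * np.eye(len(k))
    return KinshipMatrix(matrix=k, method=method, sample_ids=list(ds.sample_ids))


def maf_filter(
    ds: GenotypeDataset, threshold: float = 0.05
) -> tuple[GenotypeDataset, np.ndarray, np.ndarray]:
    """Drop SNPs with minor allele frequency below ``threshold``.

    MAF is computed over non-missing calls; SNPs with no calls at all are
    removed (logged). Returns the filtered dataset, the per-SNP MAF and a
    rare-allele flag for 0.05 <= MAF < 0.1. MAF exactly at the threshold is
    retained ("smaller than" is read strictly).
    """
    _, p, n_used = _imputed_calls(ds)
    none = n_used == 0
    if none.any():
        logger.warning("removed %d SNPs with zero non-missing calls", int(none.sum()))
    maf = np.minimum(p, 1.0 - p)
    keep = ~none & (maf >= threshold)
    filtered = ds.subset_snps(keep)
    maf = maf[keep]
    rare = (maf >= threshold) & (maf < RARE_MAF_UPPER)
    return filtered, maf, rare


# ---------------------------------------------------------------------------
# REML


def _as_kinship_array(K) -> np.ndarray:
    return K.matrix if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)


def _reml_basis(K: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenbasis of S K S with S projecting out the fixed effects X.

    Returns (xi, U_r): the n-q leading eigenvalues (clipped at 0) and their
    eigenvectors.
    """
    n, q = X.shape
    s_x = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    m = s_x @ K @ s_x
    vals, vecs = np.linalg.eigh((m + m.T) / 2.0)
    order = np.argsort(vals)[::-1][: n - q]
    return np.maximum(vals[order], 0.0), vecs[:, order]


def _restricted_loglik(log_delta: float, xi: np.ndarray, eta2: np.ndarray) -> float:
    delta = np.exp(log_delta)
    d = xi + delta
    nq = len(xi)
    return 0.5 * (
        nq * (np.log(nq / (2.0 * np.pi)) - 1.0 - np.log(np.sum(eta2 / d)))
        - np.sum(np.log(d))
    )


def _fit_delta(xi: np.ndarray, eta2: np.ndarray) -> tuple[float, float, bool, np.ndarray]:
    """Maximise the restricted likelihood over log(delta).

    Returns (log_delta_hat, loglik, unidentifiable, grid log-likelihoods).
    """
    grid_ll = np.array([_restricted_loglik(g, xi, eta2) for g in LOG_DELTA_GRID])
    spread = grid_ll.max() - grid_ll.min()
    if spread < 1e-8 * max(1.0, abs(grid_ll.max())):
        return float(LOG_DELTA_GRID[grid_ll.argmax()]), float(grid_ll.max()), True, grid_ll
    i = int(grid_ll.argmax())
    lo = LOG_DELTA_GRID[max(i - 1, 0)]
    hi = LOG_DELTA_GRID[min(i + 1, len(LOG_DELTA_GRID) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_restricted_loglik(g, xi, eta2),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    if -res.fun >= grid_ll[i]:
        return float(res.x), float(-res.fun), False, grid_ll
    return float(LOG_DELTA_GRID[i]), float(grid_ll[i]), False, grid_ll


def _reml(y: np.ndarray, K: np.ndarray, X: np.ndarray) -> VarianceComponents:
    xi, u_r = _reml_basis(K, X)
    eta2 = (u_r.T @ y) ** 2
    log_delta, loglik, flat, _ = _fit_delta(xi, eta2)
    delta = float(np.exp(log_delta))
    if flat:
        return VarianceComponents(
            sigma_a2=np.nan, sigma_e2=np.nan, h2=np.nan,
            loglik=loglik, delta=np.nan, unidentifiable=True,
            profile=(xi, eta2),
        )
    sigma_a2 = float(np.sum(eta2 / (xi + delta)) / len(xi))
    sigma_e2 = float(delta * sigma_a2)
    denom = sigma_a2 + sigma_e2
    h2 = sigma_a2 / denom if denom > 0 else 0.0
    return VarianceComponents(
        sigma_a2=sigma_a2, sigma_e2=sigma_e2, h2=float(h2),
        loglik=loglik, delta=delta, profile=(xi, eta2),
    )


def reml_fit(y, K) -> VarianceComponents:
    """REML fit of the intercept-only mixed model.

    ``y`` may be an array aligned with K, or a pandas Series indexed by the
    kinship's sample ids. A flat restricted likelihood (e.g. K = I) yields
    ``unidentifiable=True`` with NaN components.
    """
    k = _as_kinship_array(K)
    if isinstance(y, pd.Series) and isinstance(K, KinshipMatrix):
        y = y.reindex(K.sample_ids).to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) != len(k):
        raise ValidationError("phenotype length does not match kinship dimension")
    if not np.all(np.isfinite(y)):
        raise ValidationError("phenotype contains missing values; drop them first")
    if np.var(y) == 0:
        raise ValidationError("phenotype is constant")
    return _reml(y, k, np.ones((len(y), 1)))


def heritability(vc: VarianceComponents, level: float = 0.95) -> tuple[float, float, tuple[float, float]]:
    """Point estimate, standard error and profile-likelihood CI for h2.

    The CI inverts the likelihood-ratio over delta: all delta with
    restricted log-likelihood within chi2_1(level)/2 of the maximum are
    retained and mapped through h2 = 1/(1 + delta). The SE is the CI width
    divided by 2 * z(level).
    """
    if vc.unidentifiable:
        return np.nan, np.nan, (np.nan, np.nan)
    if vc.profile is None:
        raise ValueError("variance components carry no likelihood profile")
    xi, eta2 = vc.profile
    cut = vc.loglik - stats.chi2.ppf(level, df=1) / 2.0
    grid = np.linspace(-12.0, 12.0, 481)
    ll = np.array([_restricted_loglik(g, xi, eta2) for g in grid])
    inside = grid[ll >= cut]
    if inside.size == 0:
        return vc.h2, np.nan, (np.nan, np.nan)
    # h2 = 1/(1+delta) decreases in delta
    h2_hi = 1.0 / (1.0 + np.exp(inside.min()))
    h2_lo = 1.0 / (1.0 + np.exp(inside.max()))
    if ll[-1] >= cut:  # profile open towards delta -> inf
        h2_lo = 0.0
    if ll[0] >= cut:  # open towards delta -> 0
        h2_hi = 1.0
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = (h2_hi - h2_lo) / (2.0 * z)
    return vc.h2, float(se), (float(h2_lo), float(h2_hi))


# ---------------------------------------------------------------------------
# association scan


class ScanEngine:
    """Precomputed spectral workspace for repeated scans on fixed genotypes/K.

    Rotating the genotype matrix through the eigenbasis of K dominates the
    cost of a scan; permutation analyses re-use one engine and only rotate
    each new phenotype vector.
    """

    def __init__(
        self,
        genotypes: GenotypeDataset,
        K,
        maf: np.ndarray | None = None,
        rare_flag: np.ndarray | None = None,
    ):
        self.dataset = genotypes
        k = _as_kinship_array(K)
        n = genotypes.n_samples
        if k.shape != (n, n):
            raise ValidationError("kinship dimension does not match sample count")
        x, p, n_used = _imputed_calls(genotypes)
        self.n = n
        self.n_used = n_used
        self.maf = np.minimum(p, 1.0 - p) if maf is None else np.asarray(maf)
        self.rare_flag = (
            (self.maf >= 0.05) & (self.maf < RARE_MAF_UPPER)
            if rare_flag is None
            else np.asarray(rare_flag, dtype=bool)
        )
        s, u = np.linalg.eigh((k + k.T) / 2.0)
        self.eigvals = np.maximum(s, 0.0)
        self.eigvecs = u
        self.g_rot = u.T @ x
        self.ones_rot = u.T @ np.ones(n)
        self.xi, self.u_r = _reml_basis(k, np.ones((n, 1)))
        self._k = k

    def reml(self, y: np.ndarray) -> VarianceComponents:
        eta2 = (self.u_r.T @ y) ** 2
        log_delta, loglik, flat, _ = _fit_delta(self.xi, eta2)
        if flat:
            return VarianceComponents(
                np.nan, np.nan, np.nan, loglik, np.nan, True, (self.xi, eta2)
            )
        delta = float(np.exp(log_delta))
        sigma_a2 = float(np.sum(eta2 / (self.xi + delta)) / len(self.xi))
        return VarianceComponents(
            sigma_a2, float(delta * sigma_a2),
            float(sigma_a2 / (sigma_a2 * (1.0 + delta))),
            loglik, delta, False, (self.xi, eta2),
        )

    def scan(self, y: np.ndarray, vc: VarianceComponents | None = None) -> AssociationResult:
        """GLS test of every SNP with variance components fixed from ``vc``.

        ``vc=None`` fits the null model first (the EMMAX procedure).
        """
        y = np.asarray(y, dtype=float)
        if vc is None:
            vc = self.reml(y)
        if vc.unidentifiable:
            raise ValidationError(
                "null variance components unidentifiable; pass vc with a fixed delta"
            )
        w = 1.0 / (self.eigvals + vc.delta)  # V^-1 up to the sigma_a2 scale
        y_rot = self.eigvecs.T @ y
        wo = w * self.ones_rot
        wy = w * y_rot
        a11 = float(self.ones_rot @ wo)
        b1 = float(y_rot @ wo)
        yy = float(y_rot @ wy)
        a12 = wo @ self.g_rot
        a22 = w @ self.g_rot**2
        b2 = wy @ self.g_rot
        det = a11 * a22 - a12**2
        degenerate = det <= 1e-12 * np.maximum(a11 * a22, 1e-300)
        if degenerate.any():
            logger.warning("%d SNPs constant after filtering; p set to 1", int(degenerate.sum()))
        safe_det = np.where(degenerate, 1.0, det)
        beta = (a11 * b2 - a12 * b1) / safe_det
        beta0 = (a22 * b1 - a12 * b2) / safe_det
        rss = np.maximum(yy - beta0 * b1 - beta * b2, 0.0)
        dof = self.n - 2
        sigma2 = rss / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(sigma2 * a11 / safe_det)
            tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
        beta = np.where(degenerate, 0.0, beta)
        se = np.where(degenerate, np.nan, se)
        tstat = np.where(degenerate, 0.0, tstat)
        pvals = np.where(degenerate, 1.0, pvals)
        pvals = np.maximum(pvals, np.finfo(float).tiny)  # p in (0, 1]
        ds = self.dataset
        table = pd.DataFrame(
            {
                "snp_id": ds.snp_ids,
                "chrom": ds.chrom,
                "pos": ds.pos,
                "maf": self.maf,
                "rare_flag": self.rare_flag,
                "beta": beta,
                "se": se,
                "stat": tstat,
                "p": pvals,
                "n_used": self.n_used,
            }
        )
        return AssociationResult(table=table, method="emmax")


def _align(y, ds: GenotypeDataset, K) -> tuple[np.ndarray, GenotypeDataset, np.ndarray]:
    """Align a phenotype Series/array with the genotype samples and kinship."""
    k = _as_kinship_array(K)
    if isinstance(y, pd.Series):
        y = y.reindex(ds.sample_ids)
        mask = y.notna().to_numpy()
        y = y.to_numpy(dtype=float)
    else:
        y = np.asarray(y, dtype=float)
        if len(y) != ds.n_samples:
            raise ValidationError("phenotype length does not match sample count")
        mask = np.isfinite(y)
    if not mask.all():
        idx = np.flatnonzero(mask)
        sub = GenotypeDataset(
            sample_ids=[ds.sample_ids[i] for i in idx],
            snp_ids=ds.snp_ids, chrom=ds.chrom, pos=ds.pos,
            ref=ds.ref, alt=ds.alt,
            calls=np.ascontiguousarray(ds.calls[idx]),
        )
        return y[idx], sub, k[np.ix_(idx, idx)]
    return y, ds, k


def emmax_scan(
    y,
    genotypes_filtered: GenotypeDataset,
    K,
    vc: VarianceComponents | None = None,
    maf: np.ndarray | None = None,
    rare_flag: np.ndarray | None = None,
    trait: str | None = None,
    exact: bool = False,
) -> AssociationResult:
    """EMMAX association scan of one trait over MAF-filtered genotypes.

    Pass ``vc`` to fix variance components externally (e.g. delta under
    K = I); otherwise they come from the intercept-only REML fit.
    ``exact=True`` refits delta per SNP (slow; debugging aid).
    """
    y_arr, ds, k = _align(y, genotypes_filtered, K)
    engine = ScanEngine(ds, k, maf=maf, rare_flag=rare_flag)
    if exact:
        res = _exact_scan(y_arr, ds, k, engine)
    else:
        res = engine.scan(y_arr, vc=vc)
    res.trait = trait
    if isinstance(K, KinshipMatrix):
        res.kinship_method = K.method
    return res


def _exact_scan(y, ds, k, engine: ScanEngine) -> AssociationResult:
    x_imp, _, _ = _imputed_calls(ds)
    n = len(y)
    rows = []
    for j in range(ds.n_snps):
        xj = x_imp[:, j]
        if np.var(xj) == 0:
            rows.append((0.0, np.nan, 0.0, 1.0))
            continue
        X = np.column_stack([np.ones(n), xj])
        vc = _reml(y, k, X)
        if vc.unidentifiable:
            rows.append((0.0, np.nan, 0.0, 1.0))
            continue
        v = vc.sigma_a2 * k + vc.sigma_e2 * np.eye(n)
        vinv_x = np.linalg.solve(v, X)
        xtvx_inv = np.linalg.inv(X.T @ vinv_x)
        beta = xtvx_inv @ (vinv_x.T @ y)
        se = np.sqrt(xtvx_inv[1, 1])
        t = beta[1] / se
        rows.append((beta[1], se, t, 2.0 * stats.t.sf(abs(t), n - 2)))
    beta, se, tstat, p = map(np.array, zip(*rows))
    table = pd.DataFrame(
        {
            "snp_id": ds.snp_ids, "chrom": ds.chrom, "pos": ds.pos,
            "maf": engine.maf, "rare_flag": engine.rare_flag,
            "beta": beta, "se": se, "stat": tstat,
            "p": np.maximum(p, np.finfo(float).tiny),
            "n_used": engine.n_used,
        }
    )
    return AssociationResult(table=table, method="exact-mixed")


def ols_scan(y, genotypes: GenotypeDataset, trait: str | None = None) -> AssociationResult:
    """Naive per-SNP ordinary least squares scan (no structure correction)."""
    y_arr, ds, _ = _align(y, genotypes, np.eye(genotypes.n_samples))
    engine = ScanEngine(ds, np.eye(len(y_arr)))
    vc = VarianceComponents(1.0, 1.0, 0.5, 0.0, 1.0)  # V propto I
    res = engine.scan(y_arr, vc=vc)
    res.trait = trait
    res.method = "ols"
    return res


def genomic_inflation(pvalues) -> float:
    """Genomic-control lambda: median scan chi-square over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
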