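"""Univariate mixed-linear-model association scan with kinship.

Model per SNP:  y = W a + x b + u + e,  u ~ N(0, s2 * lambda * K),
e ~ N(0, s2 * I), with W the intercept-plus-covariate block and K the
centered relatedness matrix.  K is eigendecomposed once; after rotating y, W
and x into the eigenbasis the covariance is diagonal (lambda * d + 1) and the
restricted likelihood is profiled over lambda on a log grid followed by
golden-section refinement — per SNP by default, or once at the null model
("null-lambda" mode, faster, EMMAX-style).  The SNP effect is tested with a
Wald F statistic on n - c residual degrees of freedom.

The lambda profile evaluation is vectorised over SNPs using the Schur
complement of the SNP column in X' H^-1 X, so a 500 x 1000 scan with per-SNP
lambda runs in seconds.
"""

from __future__ import annotations

import warnings
import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CollinearityError,
    DegenerateKinshipError,
    InvalidArgumentError,
    InvalidConfigError,
    NoSNPsError,
    ReducedRankWarning,
)
from .types import GenotypeMatrix, QTLInterval

UNIFORM_THRESHOLD = 2.60e-4
QTL_GAP_BP = 5_000_000
LOG10_LAMBDA_RANGE = (-5.0, 5.0)
_GOLD = (np.sqrt(5.0) - 1.0) / 2.0


# ---------------------------------------------------------------------------
# genotype preparation, kinship, PCA


def prepare_dosages(
    geno: GenotypeMatrix, maf: float = 0.05, missing_rate: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Filter SNPs by MAF and missingness; mean-impute residual missing calls.

    Returns (imputed float dosage matrix over kept SNPs, boolean keep mask).
    """
    X = geno.dosages.astype(float)
    X[X < 0] = np.nan
    miss = np.isnan(X).mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(X, axis=0) / 2.0
    m_af = np.minimum(p, 1.0 - p)
    keep = (miss <= missing_rate) & (m_af >= maf) & np.isfinite(m_af)
    X = X[:, keep]
    mu = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = mu[idx[1]]
    return X, keep


def kinship(
    geno: GenotypeMatrix, maf: float = 0.05, missing_rate: float = 0.1
) -> np.ndarray:
    """Centered relatedness matrix K = X_c X_c^T / m over filtered SNPs."""
    X, keep = prepare_dosages(geno, maf=maf, missing_rate=missing_rate)
    poly = X.std(axis=0) > 0
    X = X[:, poly]
    if X.shape[1] < 2:
        raise DegenerateKinshipError("fewer than 2 polymorphic SNPs after filters")
    Xc = X - X.mean(axis=0)
    return Xc @ Xc.T / X.shape[1]


def pca_covariates(geno: GenotypeMatrix, k: int) -> np.ndarray:
    """Top-k principal-component scores of the centered-scaled dosage matrix."""
    if k < 0 or k >= geno.n_acc:
        raise InvalidArgumentError("k must satisfy 0 <= k < n_acc")
    if k == 0:
        return np.empty((geno.n_acc, 0))
    X, _ = prepare_dosages(geno, maf=0.0, missing_rate=1.0)
    sd = X.std(axis=0)
    ok = sd > 0
    Z = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    rank = int((S > S[0] * 1e-10).sum()) if len(S) else 0
    if k > rank:
        warnings.warn(f"requested {k} PCs but rank is {rank}; reduced", ReducedRankWarning)
        k = rank
    return U[:, :k] * S[:k]


# ---------------------------------------------------------------------------
# REML profile machinery


def _shared_lambda_stats(lam, d, yr, Wr, Xr):
    """Schur-complement scan statistics for one lambda shared by all SNPs.

    Returns (crit, beta, s, rss) arrays over SNPs; crit is the (negated,
    scaled) restricted log-likelihood to minimise.
    """
    n, c0 = Wr.shape
    m = Xr.shape[1]
    h = lam * d + 1.0
    ih = 1.0 / h
    Wi = Wr * ih[:, None]
    S = Wr.T @ Wi
    r0 = Wi.T @ yr
    ytHiy = float(yr @ (yr * ih))
    WX = Wi.T @ Xr  # c0 x m
    v = ((Xr**2) * ih[:, None]).sum(axis=0)
    q = Xr.T @ (yr * ih)
    try:
        alpha0 = np.linalg.solve(S, r0)
        w = np.linalg.solve(S, WX)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError("covariate block is singular") from exc
    sign, logdetS = np.linalg.slogdet(S)
    if sign <= 0:
        raise CollinearityError("covariate block is singular")
    s = v - (WX * w).sum(axis=0)
    num = q - WX.T @ alpha0
    rss_null = ytHiy - float(r0 @ alpha0)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = num / s
        rss = rss_null - num**2 / s
    bad = (s <= 0) | (rss <= 0)
    nc = n - (c0 + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = 0.5 * (np.log(h).sum() + logdetS + np.log(s) + nc * np.log(rss))
    crit = np.where(bad, np.inf, crit)
    return crit, beta, s, rss


def _per_snp_lambda_stats(lam_vec, d, yr, Wr, Xr):
    """Same statistics with a separate lambda per SNP (vectorised)."""
    n, c0 = Wr.shape
    m = Xr.shape[1]
    h = np.outer(d, lam_vec) + 1.0  # n x m
    ih = 1.0 / h
    S = np.einsum("np,nj,nq->jpq", Wr, ih, Wr, optimize=True)
    r0 = np.einsum("np,nj,n->jp", Wr, ih, yr, optimize=True)
    ytHiy = np.einsum("n,nj,n->j", yr, ih, yr, optimize=True)
    WX = np.einsum("np,nj,nj->jp", Wr, ih, Xr, optimize=True)
    v = (Xr**2 * ih).sum(axis=0)
    q = (Xr * ih * yr[:, None]).sum(axis=0)
    try:
        alpha0 = np.linalg.solve(S, r0[..., None])[..., 0]
        w = np.linalg.solve(S, WX[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:
        raise CollinearityError("covariate block is singular") from exc
    sign, logdetS = np.linalg.slogdet(S)
    s = v - (WX * w).sum(axis=1)
    num = q - (WX * alpha0).sum(axis=1)
    rss = ytHiy - (r0 * alpha0).sum(axis=1) - num**2 / s
    beta = num / s
    bad = (s <= 0) | (rss <= 0) | (sign <= 0)
    nc = n - (c0 + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        crit = 0.5 * (np.log(h).sum(axis=0) + logdetS + np.log(s) + nc * np.log(rss))
    crit = np.where(bad, np.inf, crit)
    return crit, beta, s, rss


def _null_crit(lam, d, yr, Wr):
    n, c0 = Wr.shape
    h = lam * d + 1.0
    ih = 1.0 / h
    Wi = Wr * ih[:, None]
    S = Wr.T @ Wi
    r0 = Wi.T @ yr
    sign, logdetS = np.linalg.slogdet(S)
    if sign <= 0:
        raise CollinearityError("covariate block is singular")
    alpha0 = np.linalg.solve(S, r0)
    rss = float(yr @ (yr * ih)) - float(r0 @ alpha0)
    return 0.5 * (np.log(h).sum() + logdetS + (n - c0) * np.log(rss))


def fit_null_lambda(d, yr, Wr, n_grid: int = 61, n_refine: int = 60) -> float:
    """Profile the no-SNP restricted likelihood over lambda."""
    lo, hi = LOG10_LAMBDA_RANGE
    grid = np.linspace(lo, hi, n_grid)
    crits = [_null_crit(10.0**g, d, yr, Wr) for g in grid]
    j = int(np.argmin(crits))
    a = grid[max(j - 1, 0)]
    b = grid[min(j + 1, n_grid - 1)]
    for _ in range(n_refine):
        x1 = b - _GOLD * (b - a)
        x2 = a + _GOLD * (b - a)
        if _null_crit(10.0**x1, d, yr, Wr) < _null_crit(10.0**x2, d, yr, Wr):
            b = x2
        else:
            a = x1
    return 10.0 ** ((a + b) / 2.0)


def mlm_scan(
    y: np.ndarray | pd.Series,
    geno: GenotypeMatrix,
    K: np.ndarray,
    covariates: np.ndarray | None = None,
    mode: str = "per-snp-lambda",
    maf: float = 0.05,
    missing_rate: float = 0.1,
    n_grid: int = 41,
    n_refine: int = 50,
) -> pd.DataFrame:
    """Mixed-model association scan over all SNPs passing filters.

    Returns a DataFrame with one row per tested SNP: ``snp_id, chrom,
    pos_bp, maf, beta, se, lambda_, p_wald, r2_snp`` (r2_snp is the
    proportion of phenotypic variance, beta^2 var(x) / var(y)).
    """
    if mode not in ("per-snp-lambda", "null-lambda"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    y = np.asarray(y, dtype=float)
    n = geno.n_acc
    if len(y) != n or K.shape != (n, n):
        raise InvalidArgumentError("y, K, geno are not conformable")
    X, keep = prepare_dosages(geno, maf=maf, missing_rate=missing_rate)
    if X.shape[1] == 0:
        raise NoSNPsError("no SNP passes the MAF/missingness filters")
    W = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        W = np.hstack([W, np.asarray(covariates, dtype=float)])
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise CollinearityError("covariate block is rank deficient")

    d, U = np.linalg.eigh(K)
    d = np.clip(d, 0.0, None)
    yr = U.T @ y
    Wr = U.T @ W
    Xr = U.T @ X

    lo, hi = LOG10_LAMBDA_RANGE
    grid = np.linspace(lo, hi, n_grid)
    m = X.shape[1]

    if mode == "null-lambda":
        lam0 = fit_null_lambda(d, yr, Wr)
        crit, beta, s, rss = _shared_lambda_stats(lam0, d, yr, Wr, Xr)
        lam_best = np.full(m, lam0)
    else:
        crits = np.empty((n_grid, m))
        for i, g in enumerate(grid):
            crits[i], _, _, _ = _shared_lambda_stats(10.0**g, d, yr, Wr, Xr)
        j = np.argmin(crits, axis=0)
        a = grid[np.maximum(j - 1, 0)]
        b = grid[np.minimum(j + 1, n_grid - 1)]
        f_a = None  # evaluate both interior points each iteration (simple, robust)
        for _ in range(n_refine):
            x1 = b - _GOLD * (b - a)
            x2 = a + _GOLD * (b - a)
            c1, _, _, _ = _per_snp_lambda_stats(10.0**x1, d, yr, Wr, Xr)
            c2, _, _, _ = _per_snp_lambda_stats(10.0**x2, d, yr, Wr, Xr)
            take = c1 < c2
            b = np.where(take, x2, b)
            a = np.where(take, a, x1)
        lam_best = 10.0 ** ((a + b) / 2.0)
        crit, beta, s, rss = _per_snp_lambda_stats(lam_best, d, yr, Wr, Xr)

    nc = n - (W.shape[1] + 1)
    sigma2 = rss / nc
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 / s)
        fstat = beta**2 / (sigma2 / s)
    p = stats.f.sf(fstat, 1, nc)
    var_y = float(np.var(y))
    r2_snp = beta**2 * X.var(axis=0) / var_y if var_y > 0 else np.full(m, np.nan)
    with np.errstate(invalid="ignore"):
        p_all = geno.allele_freq()[keep]
    out = pd.DataFrame(
        {
            "snp_id": geno.snp_ids[keep],
            "chrom": geno.chrom[keep],
            "pos_bp": geno.pos_bp[keep],
            "maf": np.minimum(p_all, 1.0 - p_all),
            "beta": beta,
            "se": se,
            "lambda_": lam_best,
            "p_wald": p,
            "r2_snp": r2_snp,
        }
    )
    return out


# ---------------------------------------------------------------------------
# thresholds and QTL grouping


def effective_marker_number(
    geno: GenotypeMatrix, prune_r2: float = 0.2
) -> dict[str, int]:
    """Effective marker count per chromosome by greedy LD pruning.

    Walking each chromosome in position order, a SNP is dropped when its
    squared dosage correlation with any already-kept SNP reaches
    ``prune_r2``; the kept count is m_eff.  For mutually independent SNPs
    nothing is pruned and m_eff equals the marker count.
    """
    out = {}
    X = geno.dosages.astype(float)
    for c in np.unique(geno.chrom):
        sel = np.flatnonzero(geno.chrom == c)
        sel = sel[np.argsort(geno.pos_bp[sel], kind="stable")]
        Z = X[:, sel]
        mu = Z.mean(axis=0)
        sd = Z.std(axis=0)
        sd[sd == 0] = np.inf  # monomorphic: never correlated, never kept twice
        Z = (Z - mu) / sd
        kept_cols: list[np.ndarray] = []
        n = Z.shape[0]
        for j in range(Z.shape[1]):
            z = Z[:, j]
            if kept_cols:
                r = np.array([k @ z / n for k in kept_cols])
                if np.any(r**2 >= prune_r2):
                    continue
            kept_cols.append(z)
        out[str(c)] = len(kept_cols)
    return out


def significance_threshold(
    cutoff: float = UNIFORM_THRESHOLD,
    per_chromosome: bool = False,
    geno: GenotypeMatrix | None = None,
    prune_r2: float = 0.2,
):
    """Genome-wide p-value cutoff (uniform by default).

    With ``per_chromosome=True`` returns {chrom: 1 / m_eff} using the
    LD-pruned effective marker number of each chromosome.
    """
    if cutoff <= 0:
        raise InvalidConfigError("p-value cutoff must be positive")
    if not per_chromosome:
        return cutoff
    if geno is None:
        raise InvalidConfigError("per-chromosome thresholds need the genotype matrix")
    meff = effective_marker_number(geno, prune_r2=prune_r2)
    return {c: 1.0 / m for c, m in meff.items() if m > 0}


def group_qtl(
    assoc: pd.DataFrame,
    cutoff: float = UNIFORM_THRESHOLD,
    gap: int = QTL_GAP_BP,
    trait: str | None = None,
) -> list[QTLInterval]:
    """Chain significant SNPs within ``gap`` bp into QTL intervals.

    Single-linkage: consecutive significant SNPs on a chromosome belong to
    the same QTL when their distance is at most ``gap``; singletons form
    width-0 intervals.  The result is invariant to input row order.
    """
    sig = assoc.loc[assoc["p_wald"] <= cutoff].sort_values(["chrom", "pos_bp"])
    intervals: list[QTLInterval] = []
    for c, sub in sig.groupby("chrom", sort=True):
        pos = sub["pos_bp"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > gap)
        start_idx = np.concatenate([[0], breaks + 1])
        end_idx = np.concatenate([breaks, [len(pos) - 1]])
        for i0, i1 in zip(start_idx, end_idx):
            members = sub.iloc[i0 : i1 + 1]
            intervals.append(
                QTLInterval(
                    chrom=str(c),
                    start_bp=int(members["pos_bp"].min()),
                    end_bp=int(members["pos_bp"].max()),
                    snp_ids=list(members["snp_id"]),
                    peak_p=float(members["p_wald"].min()),
                    traits={trait} if trait else set(),
                )
            )
    return intervals


def candidate_gene_scan(
    y,
    geno: GenotypeMatrix,
    K: np.ndarray,
    interval: tuple[str, int, int],
    **scan_kwargs,
) -> pd.DataFrame:
    """Mixed-model scan restricted to the SNPs inside a gene interval."""
    chrom, start, end = interval
    mask = (geno.chrom == chrom) & (geno.pos_bp >= start) & (geno.pos_bp <= end)
    if not mask.any():
        raise NoSNPsError(f"no SNP inside {chrom}:{start}-{end}")
    sub = geno.subset_snps(mask)
    maf = scan_kwargs.get("maf", 0.05)
    missing_rate = scan_kwargs.get("missing_rate", 0.1)
    _, keep = prepare_dosages(sub, maf=maf, missing_rate=missing_rate)
    if not keep.any():
        raise NoSNPsError(f"no SNP inside {chrom}:{start}-{end} passes filters")
    return mlm_scan(y, sub, K, **scan_kwargs)
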