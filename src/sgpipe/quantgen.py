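"""Phenotype-level statistics: heritability, correlations, LD decay.

Broad-sense heritability across environments uses the one-way random model
y_ij = mu + g_i + e_ij and the expected-mean-squares (method-of-moments)
estimator: sigma2_e = MS_error, sigma2_G = (MS_geno - MS_error) / n0 with n0
the (possibly harmonic-mean-adjusted) replication, negatives clamped at
zero, and

    H2 = sigma2_G / (sigma2_G + sigma2_e / n)

with n the number of environments.  In balanced data this matches the REML
fit of the same model.  LD is the squared genotype-dosage (composite)
correlation, binned over physical distance; the decay distance is where the
monotone-smoothed binned curve first crosses a critical r².
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import (
    EmptyResultError,
    InsufficientEnvironmentsError,
    InvalidArgumentError,
    UndefinedCorrelationWarning,
)
from .types import GenotypeMatrix, HeritabilityEstimate, LDDecayResult


def heritability(trait: pd.DataFrame) -> HeritabilityEstimate:
    """EMS heritability from an accession x environment value table.

    Missing cells are allowed (unbalanced EMS with the standard
    n0 = (N - sum n_i^2 / N) / (a - 1) replication).
    """
    if trait.shape[1] < 2:
        raise InsufficientEnvironmentsError("need at least 2 environments")
    y = trait.to_numpy(dtype=float)
    counts = np.isfinite(y).sum(axis=1)
    keep = counts >= 1
    y = y[keep]
    counts = counts[keep]
    a = y.shape[0]
    if a < 3:
        raise InvalidArgumentError("need at least 3 accessions with data")
    N = int(counts.sum())
    if N <= a:
        raise InsufficientEnvironmentsError("no residual degrees of freedom")
    means = np.nanmean(y, axis=1)
    grand = np.nansum(y) / N
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(np.nansum((y - means[:, None]) ** 2))
    ms_g = ss_between / (a - 1)
    ms_e = ss_within / (N - a)
    n0 = (N - np.sum(counts**2) / N) / (a - 1)
    sigma2_e = ms_e
    sigma2_g = max((ms_g - ms_e) / n0, 0.0)
    n_env = trait.shape[1]
    denom = sigma2_g + sigma2_e / n_env
    h2 = sigma2_g / denom if denom > 0 else 0.0
    return HeritabilityEstimate(sigma2_G=sigma2_g, sigma2_e=sigma2_e, n_env=n_env, H2=h2)


def pearson_matrix(traits: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between trait columns.

    Constant columns yield missing entries and a warning.
    """
    const = [c for c in traits.columns if traits[c].dropna().nunique() <= 1]
    if const:
        warnings.warn(
            f"constant trait columns have undefined correlations: {const}",
            UndefinedCorrelationWarning,
        )
    return traits.corr(method="pearson", min_periods=min_pairs)


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """Squared composite (dosage) correlation between all SNP pairs."""
    X = dosages.astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    r = Z.T @ Z / X.shape[0]
    r2 = r**2
    r2[~ok, :] = np.nan
    r2[:, ~ok] = np.nan
    return r2


def ld_decay(
    geno: GenotypeMatrix,
    max_dist: int = 20_000_000,
    n_bins: int = 50,
    critical_r2: float = 0.1,
) -> LDDecayResult:
    """Binned intra-chromosomal LD decay and the critical-r² crossing distance.

    All same-chromosome SNP pairs within ``max_dist`` bp contribute their
    squared dosage correlation to equal-width distance bins; the decay
    distance interpolates linearly between the bin centers bracketing the
    first crossing of the monotone (running-minimum) smoothed curve below
    ``critical_r2``.
    """
    edges = np.linspace(0, max_dist, n_bins + 1)
    sums = np.zeros(n_bins)
    npairs = np.zeros(n_bins, dtype=np.int64)
    for c in np.unique(geno.chrom):
        sel = geno.chrom == c
        if sel.sum() < 2:
            continue
        pos = geno.pos_bp[sel]
        r2 = _pairwise_r2(geno.dosages[:, sel])
        iu, ju = np.triu_indices(len(pos), k=1)
        d = np.abs(pos[ju] - pos[iu]).astype(float)
        vals = r2[iu, ju]
        keep = (d <= max_dist) & np.isfinite(vals)
        if not keep.any():
            continue
        which = np.clip(np.digitize(d[keep], edges) - 1, 0, n_bins - 1)
        np.add.at(sums, which, vals[keep])
        np.add.at(npairs, which, 1)
    if npairs.sum() == 0:
        raise EmptyResultError("no intra-chromosomal pairs within max_dist")
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(npairs > 0, sums / np.maximum(npairs, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bins = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "mean_r2": mean_r2, "n_pairs": npairs}
    )
    # monotone smoothing: running minimum over populated bins
    pop = npairs > 0
    smoothed = np.minimum.accumulate(mean_r2[pop])
    cpop = centers[pop]
    decay = np.nan
    below = smoothed <= critical_r2
    if below.any():
        j = int(np.argmax(below))
        if j == 0:
            decay = float(cpop[0])
        else:
            x0, x1 = cpop[j - 1], cpop[j]
            y0, y1 = smoothed[j - 1], smoothed[j]
            decay = float(x0 + (y0 - critical_r2) / (y0 - y1) * (x1 - x0)) if y0 != y1 else float(x1)
    else:
        warnings.warn("smoothed r² never crosses the critical value", UserWarning)
    return LDDecayResult(bins=bins, decay_distance=decay, critical_r2=critical_r2)
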