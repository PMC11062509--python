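"""Population differentiation and selection scans.

Per-SNP two-population Weir–Cockerham (1984) variance components (a, b, c)
and theta = a / (a + b + c); sliding-window aggregation uses the
ratio-of-sums ("weighted") convention, window 1 Mb / step 100 kb by default.
Sweeps are called as the top fraction (default 5%) of defined windows per
statistic.

XP-CLR is implemented in a deliberately simplified, physical-distance form
(``xpclr_lite``): the likelihood of the object population's allele count at
SNP i given the reference frequency p1 is a binomial integrated over a
truncated-normal drift density with boundary point masses and variance

    sigma_i^2(c) = (omega / c_i(c)) * p1 (1 - p1),   c_i(c) = 1 - exp(-d_i / c)

where d_i is the distance of SNP i from the window center and c is the sweep
scale maximised over a grid.  Small c inflates drift variance only near the
center — the sweep signature; c -> 0+ recovers the neutral model, which is
included in the maximisation explicitly, so the score 2 * (max ll - ll_neutral)
is non-negative by construction.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyResultError,
    InsufficientGroupError,
    InvalidArgumentError,
    InvalidDriftVarianceError,
    InvalidPartitionError,
    MissingSNPError,
)
from .types import GenotypeMatrix, HaplotypeAssignment

FST_WINDOW_BP = 1_000_000
FST_STEP_BP = 100_000
SWEEP_TOP_FRACTION = 0.05


# ---------------------------------------------------------------------------
# Weir–Cockerham Fst


def _group_indices(geno: GenotypeMatrix, groups) -> tuple[np.ndarray, np.ndarray]:
    """Resolve a two-group accession partition to integer index arrays."""
    g1, g2 = groups
    acc_index = pd.Index(geno.accessions)

    def to_idx(g):
        g = np.asarray(g)
        if g.dtype == bool:
            return np.flatnonzero(g)
        if np.issubdtype(g.dtype, np.integer):
            return g
        return acc_index.get_indexer(g)

    i1, i2 = to_idx(g1), to_idx(g2)
    if len(i1) == 0 or len(i2) == 0:
        raise InvalidPartitionError("both groups must be non-empty")
    if np.intersect1d(i1, i2).size:
        raise InvalidPartitionError("groups overlap")
    if np.any(i1 < 0) or np.any(i2 < 0):
        raise InvalidPartitionError("unknown accession in group")
    return i1, i2


def fst_per_snp(geno: GenotypeMatrix, groups) -> pd.DataFrame:
    """Two-population Weir–Cockerham components per SNP.

    Returns columns ``chrom, pos_bp, snp_id, n1, n2, a, b, c, fst``.  SNPs
    monomorphic across both groups, or with fewer than two called diploids in
    either group, get NaN components (excluded from ratio-of-sums windows).
    """
    i1, i2 = _group_indices(geno, groups)
    out = {}
    D = geno.dosages.astype(float)
    D[D < 0] = np.nan
    r = 2.0
    stats_by_group = []
    for idx in (i1, i2):
        sub = D[idx]
        n = np.isfinite(sub).sum(axis=0).astype(float)  # diploid counts
        with np.errstate(invalid="ignore"):
            p = np.nansum(sub, axis=0) / (2.0 * np.maximum(n, 1))
            h = np.nansum(sub == 1, axis=0) / np.maximum(n, 1)  # het frequency
        stats_by_group.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats_by_group
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar)
            - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        theta = a / (a + b + c)
    bad = (n1 < 2) | (n2 < 2) | (pbar <= 0) | (pbar >= 1)
    for arr in (a, b, c, theta):
        arr[bad] = np.nan
    return pd.DataFrame(
        {
            "chrom": geno.chrom,
            "pos_bp": geno.pos_bp,
            "snp_id": geno.snp_ids,
            "n1": n1,
            "n2": n2,
            "a": a,
            "b": b,
            "c": c,
            "fst": theta,
        }
    )


def global_fst(components: pd.DataFrame) -> float:
    """Genome-wide weighted Fst: sum(a) / sum(a + b + c) over defined SNPs."""
    ok = components[["a", "b", "c"]].notna().all(axis=1)
    a = components.loc[ok, "a"].sum()
    abc = components.loc[ok, ["a", "b", "c"]].to_numpy().sum()
    return float(a / abc) if abc != 0 else np.nan


def _window_starts(length: int, window: int, step: int) -> np.ndarray:
    """Window starts on the step grid from position 1 (full windows only)."""
    if length >= window:
        n = (length - window) // step + 1
    else:
        n = 1
    return 1 + step * np.arange(n, dtype=np.int64)


def window_fst(
    components: pd.DataFrame,
    window: int = FST_WINDOW_BP,
    step: int = FST_STEP_BP,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window weighted Fst (ratio of sums of variance components).

    Windows are [start, start + window) with starts on the step grid from
    position 1.  Empty windows carry n_snps = 0 and a missing value.
    Returns ``chrom, start, end, n_snps, stat, value, sweep``.
    """
    rows = []
    for chrom, sub in components.groupby("chrom", sort=True):
        length = (
            int(chrom_lengths[chrom]) if chrom_lengths else int(sub["pos_bp"].max())
        )
        ok = sub[["a", "b", "c"]].notna().all(axis=1)
        pos = sub.loc[ok, "pos_bp"].to_numpy()
        a = sub.loc[ok, "a"].to_numpy()
        abc = sub.loc[ok, ["a", "b", "c"]].to_numpy().sum(axis=1)
        for start in _window_starts(length, window, step):
            end = start + window
            sel = (pos >= start) & (pos < end)
            n = int(sel.sum())
            denom = abc[sel].sum() if n else 0.0
            value = a[sel].sum() / denom if n and denom != 0 else np.nan
            rows.append((chrom, int(start), int(end), n, "fst", value, False))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snps", "stat", "value", "sweep"]
    )


# ---------------------------------------------------------------------------
# simplified XP-CLR


def estimate_drift_variance(p1: np.ndarray, p2: np.ndarray) -> float:
    """Genome-wide drift variance omega.

    Median of (p2 - p1)^2 / (p1 (1 - p1)) over SNPs with p1 in (0.05, 0.95).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    sel = (p1 > 0.05) & (p1 < 0.95) & np.isfinite(p2)
    if not sel.any():
        raise InvalidDriftVarianceError("no informative SNPs for omega")
    omega = float(np.median((p2[sel] - p1[sel]) ** 2 / (p1[sel] * (1 - p1[sel]))))
    if omega <= 0:
        raise InvalidDriftVarianceError(f"omega must be positive, got {omega}")
    return omega


def _log_likelihood(k2, n2c, p1, sigma2, nodes, weights):
    """log P(k2 | p1, sigma2): binomial over truncated normal + point masses.

    All arguments broadcast over SNPs; ``nodes``/``weights`` are quadrature
    points on (0, 1).
    """
    sigma = np.sqrt(sigma2)
    mass0 = stats.norm.cdf((0.0 - p1) / sigma)
    mass1 = stats.norm.sf((1.0 - p1) / sigma)
    # interior: sum_k w_k phi((x_k - p1)/sigma)/sigma * Binom(k2; n2c, x_k)
    x = nodes[None, :]
    dens = stats.norm.pdf((x - p1[:, None]) / sigma[:, None]) / sigma[:, None]
    pmf = stats.binom.pmf(k2[:, None], n2c[:, None], x)
    interior = (weights[None, :] * dens * pmf).sum(axis=1)
    like = interior
    like = like + np.where(k2 == 0, mass0, 0.0)
    like = like + np.where(k2 == n2c, mass1, 0.0)
    return np.log(np.maximum(like, 1e-300))


def xpclr_score(
    geno: GenotypeMatrix,
    ref_group,
    obj_group,
    window: int = FST_WINDOW_BP,
    step: int = FST_STEP_BP,
    c_grid: Sequence[float] = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0),
    omega: float | None = None,
    n_quad: int = 40,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Simplified cross-population composite-likelihood sweep scan.

    ``c_grid`` entries are sweep decay scales as fractions of the window
    size.  Returns a window table like :func:`window_fst` with
    ``stat = "xpclr_lite"``; the score is 2 * (max_c ll(c) - ll_neutral),
    with the neutral model included in the max, hence >= 0.
    """
    i_ref, i_obj = _group_indices(geno, (ref_group, obj_group))
    D = geno.dosages.astype(float)
    D[D < 0] = np.nan
    ref = D[i_ref]
    obj = D[i_obj]
    with np.errstate(invalid="ignore"):
        n1 = np.isfinite(ref).sum(axis=0).astype(float)
        p1 = np.nansum(ref, axis=0) / (2 * np.maximum(n1, 1))
        n2c = (2 * np.isfinite(obj).sum(axis=0)).astype(int)  # chromosomes sampled
        k2 = np.nansum(obj, axis=0).astype(int)  # alt allele count
    if omega is None:
        with np.errstate(invalid="ignore"):
            p2 = np.where(n2c > 0, k2 / np.maximum(n2c, 1), np.nan)
        omega = estimate_drift_variance(p1, p2)
    if omega <= 0:
        raise InvalidDriftVarianceError("omega must be positive")

    gl_nodes, gl_weights = np.polynomial.legendre.leggauss(n_quad)
    nodes = 0.5 * (gl_nodes + 1.0)
    weights = 0.5 * gl_weights

    rows = []
    for chrom, idx in pd.Series(range(geno.n_snp)).groupby(pd.Series(geno.chrom)):
        ii = idx.to_numpy()
        pos = geno.pos_bp[ii]
        length = (
            int(chrom_lengths[chrom]) if chrom_lengths else int(pos.max())
        )
        usable = (p1[ii] > 0) & (p1[ii] < 1) & (n2c[ii] > 0) & (n1[ii] >= 2)
        for start in _window_starts(length, window, step):
            end = start + window
            sel = ii[(pos >= start) & (pos < end) & usable]
            n = int(len(sel))
            if n == 0:
                rows.append((chrom, int(start), int(end), 0, "xpclr_lite", np.nan, False))
                continue
            center = start + window / 2.0
            dist = np.abs(geno.pos_bp[sel] - center)
            pp1 = p1[sel]
            kk2 = k2[sel]
            nn2 = n2c[sel]
            base_var = omega * pp1 * (1 - pp1)
            ll_neutral = _log_likelihood(kk2, nn2, pp1, base_var, nodes, weights).sum()
            best = ll_neutral
            for frac in c_grid:
                ci = 1.0 - np.exp(-dist / (frac * window))
                ci = np.clip(ci, 1e-8, 1.0)
                ll = _log_likelihood(kk2, nn2, pp1, base_var / ci, nodes, weights).sum()
                best = max(best, ll)
            score = 2.0 * (best - ll_neutral)
            rows.append((chrom, int(start), int(end), n, "xpclr_lite", score, False))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "n_snps", "stat", "value", "sweep"]
    )


def call_sweeps(windows: pd.DataFrame, top_fraction: float = SWEEP_TOP_FRACTION) -> pd.DataFrame:
    """Flag the top fraction of defined windows as selective sweeps.

    Flags ceil(top_fraction * n_defined) windows by decreasing value; ties at
    the cut break toward the leftmost genomic coordinate.  Windows with no
    SNPs are never flagged.
    """
    if not 0 < top_fraction <= 1:
        raise InvalidArgumentError("top_fraction must be in (0, 1]")
    out = windows.copy()
    defined = out["value"].notna() & (out["n_snps"] > 0)
    n_def = int(defined.sum())
    if n_def == 0:
        raise EmptyResultError("no window with a defined value")
    k = int(np.ceil(top_fraction * n_def))
    sub = out.loc[defined].sort_values(
        ["value", "chrom", "start"], ascending=[False, True, True], kind="stable"
    )
    out["sweep"] = False
    out.loc[sub.index[:k], "sweep"] = True
    return out


# ---------------------------------------------------------------------------
# haplotypes


def assign_haplotypes(
    geno: GenotypeMatrix,
    snp_pair: tuple[str, str],
    hap1_alleles: tuple[str, str],
    hap2_alleles: tuple[str, str],
) -> HaplotypeAssignment:
    """Label accessions Hap1/Hap2/other at a defining SNP pair.

    Hap1 requires homozygosity for the Hap1 allele at both SNPs (likewise
    Hap2); heterozygous, recombinant or missing accessions are "other".
    Alleles may be given as bases (matched against ref/alt) or literally as
    "ref"/"alt".
    """
    idx = [geno.snp_index(s) for s in snp_pair]

    def target_dosage(j, allele):
        if allele == "ref" or allele == np.asarray(geno.ref)[j]:
            return 0
        if allele == "alt" or allele == np.asarray(geno.alt)[j]:
            return 2
        raise MissingSNPError(
            f"allele {allele!r} is neither ref nor alt at {geno.snp_ids[j]}"
        )

    d = geno.dosages[:, idx]
    lab = np.full(geno.n_acc, "other", dtype=object)
    for name, alleles in (("Hap1", hap1_alleles), ("Hap2", hap2_alleles)):
        want = np.array([target_dosage(j, al) for j, al in zip(idx, alleles)])
        lab[np.all(d == want, axis=1)] = name
    return HaplotypeAssignment(
        snp_pair=tuple(snp_pair),
        hap1_alleles=tuple(hap1_alleles),
        hap2_alleles=tuple(hap2_alleles),
        labels=pd.Series(lab, index=pd.Index(geno.accessions, name="accession")),
    )


def haplotype_trend(
    assign: HaplotypeAssignment,
    labels: pd.DataFrame,
    stratum: str = "era",
    order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Haplotype frequencies per stratum plus a Cochran–Armitage trend test.

    Frequencies are among the accessions assigned Hap1 or Hap2 in each
    stratum; empty strata are reported with missing frequencies.  The trend
    statistic (linear-by-linear association with integer scores over the
    given stratum order) and its p-value are returned alongside the table.
    """
    if stratum not in labels.columns:
        raise InvalidArgumentError(f"labels have no column {stratum!r}")
    strat = labels.loc[assign.labels.index, stratum]
    cats = list(order) if order is not None else sorted(strat.dropna().unique())
    rows = []
    counts = []
    for s in cats:
        in_s = strat == s
        n1 = int(((assign.labels == "Hap1") & in_s).sum())
        n2 = int(((assign.labels == "Hap2") & in_s).sum())
        n_other = int(((assign.labels == "other") & in_s).sum())
        tot = n1 + n2
        rows.append(
            (s, n1, n2, n_other, n1 / tot if tot else np.nan, n2 / tot if tot else np.nan)
        )
        counts.append([n1, n2])
    table = pd.DataFrame(
        rows, columns=[stratum, "n_hap1", "n_hap2", "n_other", "freq_hap1", "freq_hap2"]
    )
    counts = np.array([c for c in counts if sum(c) > 0])
    if len(counts) >= 2 and counts.sum(axis=0).min() > 0:
        import statsmodels.api as sm

        res = sm.stats.Table(counts).test_ordinal_association()
        stat, p = float(res.zscore), float(res.pvalue)
    else:
        stat, p = np.nan, np.nan
    return table, stat, p


def group_compare(
    traits: pd.DataFrame, assign: HaplotypeAssignment
) -> pd.DataFrame:
    """Welch two-tailed t-tests of every trait between Hap1 and Hap2 groups.

    Returns ``trait, mean_hap1, mean_hap2, diff, t, df, p``.
    """
    g1 = assign.labels.index[assign.labels == "Hap1"]
    g2 = assign.labels.index[assign.labels == "Hap2"]
    rows = []
    for col in traits.columns:
        x = traits.loc[traits.index.intersection(g1), col].dropna()
        y = traits.loc[traits.index.intersection(g2), col].dropna()
        if len(x) < 2 or len(y) < 2:
            raise InsufficientGroupError(f"trait {col!r}: need >= 2 per group")
        res = stats.ttest_ind(x, y, equal_var=False)
        rows.append(
            (col, x.mean(), y.mean(), x.mean() - y.mean(), float(res.statistic),
             float(res.df), float(res.pvalue))
        )
    return pd.DataFrame(rows, columns=["trait", "mean_hap1", "mean_hap2", "diff", "t", "df", "p"])
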