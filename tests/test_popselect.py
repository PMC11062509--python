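"""Weir–Cockerham Fst vs an independent 1984-formula oracle, windows,
xpclr_lite, sweep calling, haplotypes and trend tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from conftest import toy_genotypes
from sgpipe import popselect, simdata
from sgpipe.errors import (
    EmptyResultError,
    InsufficientGroupError,
    InvalidDriftVarianceError,
    InvalidPartitionError,
    MissingSNPError,
)


def wc_theta_oracle(geno1, geno2):
    """Scalar Weir–Cockerham (1984) two-population theta from genotype lists.

    Independent transcription of the r=2 formulas: sample sizes n_i, allele
    frequencies p_i and heterozygote frequencies h_i per population.
    """
    g1 = [g for g in geno1 if g >= 0]
    g2 = [g for g in geno2 if g >= 0]
    n1, n2 = len(g1), len(g2)
    p1 = sum(g1) / (2 * n1)
    p2 = sum(g2) / (2 * n2)
    h1 = sum(1 for g in g1 if g == 1) / n1
    h2 = sum(1 for g in g2 if g == 1) / n2
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a, b, c, a / (a + b + c)


class TestFstPerSNP:
    def test_identical_counts_no_differentiation(self):
        # 10/20 alt alleles in both groups (five 2s, ten 0s, five... use hets)
        col = np.array([2] * 5 + [0] * 5 + [2] * 5 + [0] * 5, dtype=np.int8)
        g = toy_genotypes(col[:, None])
        out = popselect.fst_per_snp(g, (np.arange(10), np.arange(10, 20)))
        assert out["fst"].iloc[0] <= 1e-12

    def test_fixed_difference_theta_one(self):
        col = np.array([0] * 20 + [2] * 20, dtype=np.int8)
        g = toy_genotypes(col[:, None])
        out = popselect.fst_per_snp(g, (np.arange(20), np.arange(20, 40)))
        assert out["fst"].iloc[0] == pytest.approx(1.0)

    def test_specified_frequencies_match_oracle(self):
        # p1 = 0.8 over 10 diploids, p2 = 0.3 over 15, with heterozygotes
        g1 = [2] * 6 + [1] * 4  # 16/20 alt
        g2 = [1] * 9 + [0] * 6  # 9/30 alt
        col = np.array(g1 + g2, dtype=np.int8)
        g = toy_genotypes(col[:, None])
        out = popselect.fst_per_snp(g, (np.arange(10), np.arange(10, 25)))
        a, b, c, theta = wc_theta_oracle(g1, g2)
        assert out["fst"].iloc[0] == pytest.approx(theta, abs=1e-12)
        assert out["a"].iloc[0] == pytest.approx(a, abs=1e-12)

    def test_random_instances_match_oracle_property(self):
        """1000 random two-population instances agree with the independent
        oracle to 1e-12."""
        rng = np.random.default_rng(1)
        checked = 0
        while checked < 1000:
            n1, n2 = rng.integers(2, 40, 2)
            p1, p2 = rng.uniform(0.05, 0.95, 2)
            g1 = rng.binomial(2, p1, n1)
            g2 = rng.binomial(2, p2, n2)
            col = np.concatenate([g1, g2]).astype(np.int8)
            pbar = col.sum() / (2 * len(col))
            if pbar in (0.0, 1.0):
                continue
            g = toy_genotypes(col[:, None])
            out = popselect.fst_per_snp(g, (np.arange(n1), np.arange(n1, n1 + n2)))
            *_, theta = wc_theta_oracle(list(g1), list(g2))
            assert out["fst"].iloc[0] == pytest.approx(theta, abs=1e-12)
            checked += 1

    def test_empty_group_raises(self):
        g = toy_genotypes(np.ones((4, 2), dtype=np.int8))
        with pytest.raises(InvalidPartitionError):
            popselect.fst_per_snp(g, (np.arange(4), np.array([], dtype=int)))


class TestWindowFst:
    def test_window_count_on_three_mb_chromosome(self):
        """3 Mb chromosome, 1 Mb windows stepping 100 kb: 21 windows."""
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.5, (40, 30)).astype(np.int8)
        pos = np.sort(rng.integers(1, 3_000_000, 30))
        g = toy_genotypes(d, pos=pos)
        comp = popselect.fst_per_snp(g, (np.arange(20), np.arange(20, 40)))
        w = popselect.window_fst(comp, chrom_lengths={"1A": 3_000_000})
        assert len(w) == 21

    def test_single_window_equals_per_snp_value_when_equal(self):
        col = np.array([0] * 10 + [2] * 10, dtype=np.int8)
        d = np.column_stack([col, col, col])
        g = toy_genotypes(d, pos=np.array([10, 20, 30]))
        comp = popselect.fst_per_snp(g, (np.arange(10), np.arange(10, 20)))
        w = popselect.window_fst(comp, window=1000, step=1000, chrom_lengths={"1A": 1000})
        assert w["value"].iloc[0] == pytest.approx(comp["fst"].iloc[0])

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, rng.uniform(0.1, 0.9, 50), (60, 50)).astype(np.int8)
        pos = np.sort(rng.integers(1, 2_500_000, 50))
        g = toy_genotypes(d, pos=pos)
        comp = popselect.fst_per_snp(g, (np.arange(30), np.arange(30, 60)))
        w = popselect.window_fst(comp, window=1_000_000, step=250_000,
                                 chrom_lengths={"1A": 2_500_000})
        for _, row in w.iterrows():
            num = den = 0.0
            n = 0
            for _, s in comp.iterrows():
                if row["start"] <= s["pos_bp"] < row["end"] and np.isfinite(s["a"]):
                    num += s["a"]
                    den += s["a"] + s["b"] + s["c"]
                    n += 1
            assert n == row["n_snps"]
            if n and den != 0:
                assert row["value"] == pytest.approx(num / den, rel=1e-10)


class TestXPCLR:
    def _panel(self, seed, sweep=False):
        geno = simdata.simulate_genotypes(
            200, 400, n_subpop=2, fst_b=0.02, seed=seed, chrom_sizes={"2A": 20_000_000}
        )
        obj = np.arange(100, 200)
        if sweep:
            rng = np.random.default_rng(seed + 1000)
            idx = np.flatnonzero(
                (geno.pos_bp >= 10_000_000) & (geno.pos_bp < 11_000_000)
            )
            d = geno.dosages.copy()
            d[np.ix_(obj, idx)] = rng.binomial(2, 0.97, (100, len(idx))).astype(np.int8)
            geno = geno.__class__(
                dosages=d, chrom=geno.chrom, pos_bp=geno.pos_bp, snp_ids=geno.snp_ids,
                accessions=geno.accessions, labels=geno.labels, ref=geno.ref, alt=geno.alt,
            )
        return geno, np.arange(100), obj

    def test_identical_frequencies_score_near_zero(self):
        geno = simdata.simulate_genotypes(
            400, 200, n_subpop=1, fst_b=0.0, seed=4, chrom_sizes={"1A": 10_000_000}
        )
        dup = np.vstack([geno.dosages, geno.dosages])
        labels = pd.concat(
            [geno.labels,
             geno.labels.set_index(pd.Index([a + "b" for a in geno.accessions], name="accession"))]
        )
        g2 = geno.__class__(
            dosages=dup, chrom=geno.chrom, pos_bp=geno.pos_bp, snp_ids=geno.snp_ids,
            accessions=np.concatenate([geno.accessions, [a + "b" for a in geno.accessions]]),
            labels=labels, ref=geno.ref, alt=geno.alt,
        )
        w = popselect.xpclr_score(
            g2, np.arange(400), np.arange(400, 800),
            window=1_000_000, step=1_000_000, omega=0.01,
        )
        assert w["value"].max() < 1.0

    def test_scores_non_negative(self):
        geno, ref, obj = self._panel(5)
        w = popselect.xpclr_score(geno, ref, obj, window=1_000_000, step=500_000)
        assert (w["value"].dropna() >= 0).all()

    def test_planted_sweep_window_exceeds_95th_percentile(self):
        geno, ref, obj = self._panel(6, sweep=True)
        w = popselect.xpclr_score(geno, ref, obj, window=1_000_000, step=500_000)
        q95 = w["value"].quantile(0.95)
        sweep_scores = w.loc[w["start"].isin([10_000_001, 10_500_001]), "value"]
        assert sweep_scores.max() > q95

    def test_allele_relabel_invariance(self):
        geno, ref, obj = self._panel(7)
        w1 = popselect.xpclr_score(geno, ref, obj, window=2_000_000, step=2_000_000)
        flipped = geno.__class__(
            dosages=(2 - geno.dosages).astype(np.int8), chrom=geno.chrom,
            pos_bp=geno.pos_bp, snp_ids=geno.snp_ids, accessions=geno.accessions,
            labels=geno.labels, ref=geno.alt, alt=geno.ref,
        )
        w2 = popselect.xpclr_score(flipped, ref, obj, window=2_000_000, step=2_000_000)
        np.testing.assert_allclose(w1["value"], w2["value"], rtol=1e-6)

    def test_single_snp_likelihood_matches_quadrature_oracle(self):
        from sgpipe.popselect import _log_likelihood

        gl_nodes, gl_weights = np.polynomial.legendre.leggauss(40)
        nodes, weights = 0.5 * (gl_nodes + 1), 0.5 * gl_weights
        for k2, n2c, p1, s2 in [(7, 20, 0.35, 0.02), (0, 30, 0.1, 0.05), (30, 30, 0.9, 0.01)]:
            mine = _log_likelihood(
                np.array([k2]), np.array([n2c]), np.array([p1]), np.array([s2]),
                nodes, weights,
            )[0]
            sig = np.sqrt(s2)
            f = lambda x: stats.norm.pdf((x - p1) / sig) / sig * stats.binom.pmf(k2, n2c, x)
            val, _ = integrate.quad(f, 0, 1, limit=200)
            val += stats.norm.cdf(-p1 / sig) * (k2 == 0)
            val += stats.norm.sf((1 - p1) / sig) * (k2 == n2c)
            assert np.exp(mine) == pytest.approx(val, rel=1e-6)

    def test_invalid_omega_raises(self):
        geno, ref, obj = self._panel(8)
        with pytest.raises(InvalidDriftVarianceError):
            popselect.xpclr_score(geno, ref, obj, omega=-1.0)


class TestCallSweeps:
    def _windows(self, values):
        n = len(values)
        return pd.DataFrame(
            {
                "chrom": "1A",
                "start": np.arange(n) * 100 + 1,
                "end": np.arange(n) * 100 + 1001,
                "n_snps": 5,
                "stat": "fst",
                "value": values,
                "sweep": False,
            }
        )

    def test_exactly_ceil_fraction_flagged(self):
        rng = np.random.default_rng(9)
        w = popselect.call_sweeps(self._windows(rng.uniform(size=100)), 0.05)
        assert w["sweep"].sum() == 5

    def test_fraction_one_flags_all_defined(self):
        w = self._windows([0.1, 0.2, np.nan])
        w.loc[2, "n_snps"] = 0
        out = popselect.call_sweeps(w, 1.0)
        assert out["sweep"].sum() == 2 and not out.loc[2, "sweep"]

    def test_ties_break_to_leftmost(self):
        out = popselect.call_sweeps(self._windows([0.5] * 40), 0.05)
        assert out.loc[out["sweep"], "start"].tolist() == [1, 101]

    def test_empty_raises(self):
        w = self._windows([np.nan])
        with pytest.raises(EmptyResultError):
            popselect.call_sweeps(w)


class TestHaplotypes:
    def _panel(self):
        # 86 Hap1 (C-C hom), 158 Hap2 (G-T hom), 6 other (het)
        col1 = np.array([2] * 86 + [0] * 158 + [1] * 6, dtype=np.int8)
        col2 = np.array([2] * 86 + [0] * 158 + [1] * 6, dtype=np.int8)
        return toy_genotypes(
            np.column_stack([col1, col2]),
            ref=np.array(["G", "T"]),
            alt=np.array(["C", "C"]),
        )

    def test_paper_style_cohort_counts_exact(self):
        g = self._panel()
        assign = popselect.assign_haplotypes(g, ("s0", "s1"), ("C", "C"), ("G", "T"))
        counts = assign.counts()
        assert counts["Hap1"] == 86 and counts["Hap2"] == 158 and counts["other"] == 6
        freqs = assign.frequencies()
        assert freqs["Hap1"] == pytest.approx(86 / 250)
        assert freqs["Hap2"] == pytest.approx(158 / 250)
        assert freqs.sum() == pytest.approx(1.0)

    def test_heterozygote_is_other(self):
        g = self._panel()
        assign = popselect.assign_haplotypes(g, ("s0", "s1"), ("C", "C"), ("G", "T"))
        assert (assign.labels.iloc[-6:] == "other").all()

    def test_missing_snp_raises(self):
        g = self._panel()
        with pytest.raises(MissingSNPError):
            popselect.assign_haplotypes(g, ("s0", "nope"), ("C", "C"), ("G", "T"))

    def test_two_strata_exact_frequencies(self):
        col = np.array([2] * 60 + [0] * 140, dtype=np.int8)
        labels = pd.DataFrame(
            {
                "flowering_class": "MF",
                "era": ["pre-1950"] * 100 + ["post-2010"] * 100,
                "region": "I",
                "group": "CL",
            },
            index=pd.Index([f"a{i}" for i in range(200)], name="accession"),
        )
        # era 1: 10 Hap1 / 90 Hap2; era 2: 50 / 50
        col = np.array([2] * 10 + [0] * 90 + [2] * 50 + [0] * 50, dtype=np.int8)
        g = toy_genotypes(np.column_stack([col, col]), labels=labels)
        assign = popselect.assign_haplotypes(g, ("s0", "s1"), ("alt", "alt"), ("ref", "ref"))
        table, z, p = popselect.haplotype_trend(
            assign, labels, "era", order=["pre-1950", "post-2010"]
        )
        assert table["freq_hap1"].tolist() == [pytest.approx(0.10), pytest.approx(0.50)]
        assert p < 1e-6


class TestGroupCompare:
    def _assign(self, n1, n2):
        labels = pd.Series(
            ["Hap1"] * n1 + ["Hap2"] * n2,
            index=pd.Index([f"a{i}" for i in range(n1 + n2)], name="accession"),
        )
        return popselect.HaplotypeAssignment(("s0", "s1"), ("C", "C"), ("G", "T"), labels)

    @staticmethod
    def _exact_sample(rng, n, mean, sd):
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std(ddof=1)
        return x * sd + mean

    def test_textbook_welch_t(self):
        """Means 5 vs 6, sd 1, n = 25 each: t = -1 / sqrt(2/25) = -3.536."""
        rng = np.random.default_rng(10)
        x = self._exact_sample(rng, 25, 5.0, 1.0)
        y = self._exact_sample(rng, 25, 6.0, 1.0)
        traits = pd.DataFrame({"sg": np.concatenate([x, y])},
                              index=[f"a{i}" for i in range(50)])
        out = popselect.group_compare(traits, self._assign(25, 25))
        assert out["t"].iloc[0] == pytest.approx(-3.536, abs=5e-4)

    def test_equal_means_t_zero_p_one(self):
        rng = np.random.default_rng(11)
        x = self._exact_sample(rng, 30, 10.0, 1.0)
        y = self._exact_sample(rng, 30, 10.0, 1.0)
        traits = pd.DataFrame({"sg": np.concatenate([x, y])},
                              index=[f"a{i}" for i in range(60)])
        out = popselect.group_compare(traits, self._assign(30, 30))
        assert out["t"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_null_pvalues_uniform_under_label_shuffles(self):
        """With identical group distributions, permuted-label p-values are
        Uniform(0,1) (KS p > 0.01 over 200 permutations)."""
        rng = np.random.default_rng(12)
        vals = rng.normal(size=60)
        idx = [f"a{i}" for i in range(60)]
        ps = []
        for _ in range(200):
            perm = rng.permutation(vals)
            traits = pd.DataFrame({"sg": perm}, index=idx)
            ps.append(popselect.group_compare(traits, self._assign(30, 30))["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_tiny_group_raises(self):
        traits = pd.DataFrame({"sg": np.arange(3.0)}, index=["a0", "a1", "a2"])
        with pytest.raises(InsufficientGroupError):
            popselect.group_compare(traits, self._assign(1, 2))
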