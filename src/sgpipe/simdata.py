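"""Synthetic trial generator with known ground truth.

Emulates everything the pipeline consumes: a daily mean-temperature series, a
structured biallelic SNP panel with planted senescence-rate loci, logistic
post-anthesis greenness curves on the accumulated-temperature (AT) axis, and
five-band plot imagery with soil background, a calibration panel and hidden
per-band sensor gains.  Every operation is a pure function of its arguments
and a seed, so recovery tests can compare pipeline output against analytic
truth.

The greenness model is logistic in AT with a per-accession rate r and a
shared shape constant c0 (the decline midpoint sits at AT = c0/r):

    g(AT) = g_min + (1 - g_min) * (1 + exp(-c0)) / (1 + exp(r*AT - c0))

g(0) = 1 exactly and g is strictly decreasing in r for AT > 0, so additive
allele effects that lower r are stay-green alleles in every downstream score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import imaging
from .errors import (
    InfeasibleGradientError,
    InvalidArgumentError,
    InvalidPlotMapError,
    MissingDataError,
)
from .types import (
    BANDS,
    CANOPY_SPECTRUM,
    ERA_BINS,
    FLOWERING_CLASSES,
    GROUPS,
    PANEL_REFLECTANCES,
    REGIONS,
    BandStack,
    GenotypeMatrix,
    PlotMap,
    Rect,
    SenescenceCurves,
    SITrajectory,
    SOIL_SPECTRUM,
    TraitArchitecture,
    validate_weather,
)

# Default logistic-curve constants: rate 0.012 / (°C·day) puts the decline
# midpoint at c0/r = 450 °C·day, matching a slow-then-fast senescence with
# acceleration past ~400 °C·day.
DEFAULT_R0 = 0.012
DEFAULT_C0 = 5.4
DEFAULT_G_MIN = 0.15


# ---------------------------------------------------------------------------
# weather


def simulate_weather(
    n_days: int,
    base: float = 20.0,
    amplitude: float = 5.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    start: str = "2021-04-01",
    period: float = 365.0,
) -> pd.DataFrame:
    """Sinusoid-plus-noise daily mean temperatures (°C).

    Returns a DataFrame with columns ``date`` (consecutive calendar days)
    and ``tmean``; deterministic given the seed.
    """
    if n_days < 1:
        raise InvalidArgumentError("n_days must be >= 1")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_days)
    tmean = base + amplitude * np.sin(2 * np.pi * t / period)
    if noise_sd > 0:
        tmean = tmean + rng.normal(0.0, noise_sd, size=n_days)
    dates = pd.date_range(start, periods=n_days, freq="D")
    return pd.DataFrame({"date": dates, "tmean": tmean})


# ---------------------------------------------------------------------------
# genotypes and cohort labels


def simulate_genotypes(
    n_acc: int,
    n_snp: int,
    n_subpop: int = 3,
    fst_b: float = 0.05,
    seed: int = 0,
    chrom_sizes: Mapping[str, int] | None = None,
    era_probs: Sequence[float] | None = None,
    region_probs: Sequence[float] | None = None,
) -> GenotypeMatrix:
    """Structured biallelic panel via the Balding–Nichols model.

    Each SNP draws an ancestral frequency p ~ U(0.05, 0.95); each of the
    ``n_subpop`` subpopulations draws its own frequency from
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``fst_b`` (F = 0 means no
    differentiation), and dosages are Binomial(2, p_subpop).  Accessions are
    split evenly across subpopulations; the population ``group`` label cycles
    CL/IMC/MCC over subpopulations, and era/region labels are drawn from the
    configured proportions (uniform by default).
    """
    if not 0 <= fst_b < 1:
        raise InvalidArgumentError("fst_b must be in [0, 1)")
    if n_subpop > n_acc:
        raise InvalidArgumentError("n_subpop cannot exceed n_acc")
    rng = np.random.default_rng(seed)

    if chrom_sizes is None:
        chrom_sizes = {"1A": 600_000_000, "2A": 600_000_000, "3A": 600_000_000}
    chrom_names = list(chrom_sizes)
    per = np.full(len(chrom_names), n_snp // len(chrom_names))
    per[: n_snp % len(chrom_names)] += 1
    chrom, pos = [], []
    for name, m in zip(chrom_names, per):
        chrom.extend([name] * m)
        pos.append(np.sort(rng.integers(1, chrom_sizes[name], size=m)))
    chrom = np.array(chrom)
    pos = np.concatenate(pos) if pos else np.array([], dtype=np.int64)

    p_anc = rng.uniform(0.05, 0.95, size=n_snp)
    subpop = np.repeat(np.arange(n_subpop), int(np.ceil(n_acc / n_subpop)))[:n_acc]
    if fst_b == 0:
        p_sub = np.tile(p_anc, (n_subpop, 1))
    else:
        f = (1.0 - fst_b) / fst_b
        p_sub = rng.beta(p_anc * f, (1.0 - p_anc) * f, size=(n_subpop, n_snp))
    dosages = rng.binomial(2, p_sub[subpop, :]).astype(np.int8)

    accessions = np.array([f"acc{i:04d}" for i in range(n_acc)])
    era_probs = np.full(len(ERA_BINS), 1 / len(ERA_BINS)) if era_probs is None else np.asarray(era_probs)
    region_probs = (
        np.full(len(REGIONS), 1 / len(REGIONS)) if region_probs is None else np.asarray(region_probs)
    )
    labels = pd.DataFrame(
        {
            "flowering_class": "MF",  # placeholder until anthesis dates exist
            "era": rng.choice(ERA_BINS, size=n_acc, p=era_probs / era_probs.sum()),
            "region": rng.choice(REGIONS, size=n_acc, p=region_probs / region_probs.sum()),
            "group": np.array(GROUPS)[subpop % len(GROUPS)],
        },
        index=pd.Index(accessions, name="accession"),
    )
    snp_ids = np.array([f"s{c}_{p}" for c, p in zip(chrom, pos)])
    return GenotypeMatrix(
        dosages=dosages, chrom=chrom, pos_bp=pos, snp_ids=snp_ids,
        accessions=accessions, labels=labels,
    )


def simulate_anthesis(
    accessions: Sequence[str], start: str = "2021-04-20", spread_days: int = 3, seed: int = 0
) -> pd.Series:
    """Per-accession anthesis dates, uniform over ``spread_days`` + 1 days."""
    rng = np.random.default_rng(seed)
    offsets = rng.integers(0, spread_days + 1, size=len(accessions))
    dates = pd.Timestamp(start) + pd.to_timedelta(offsets, unit="D")
    return pd.Series(dates, index=pd.Index(accessions, name="accession"), name="anthesis")


def assign_flowering_classes(geno: GenotypeMatrix, anthesis: pd.Series) -> GenotypeMatrix:
    """Label accessions EF/MF/LF by terciles of the anthesis date."""
    ranks = anthesis.loc[geno.accessions].rank(method="first")
    classes = pd.cut(ranks, bins=3, labels=list(FLOWERING_CLASSES)).astype(str)
    labels = geno.labels.copy()
    labels.loc[classes.index, "flowering_class"] = classes
    return geno.with_labels(labels)


# ---------------------------------------------------------------------------
# senescence trajectories


def genetic_rates(
    geno: GenotypeMatrix, arch: TraitArchitecture, r0: float = DEFAULT_R0
) -> np.ndarray:
    """Genetic value of the senescence rate: r0 + QTL effects + polygenic term.

    The polygenic breeding value is standardized dosages times small normal
    effects seeded from ``arch.polygenic_seed``, hence identical across
    simulated seasons.
    """
    X = geno.dosages.astype(float)
    r = np.full(geno.n_acc, r0)
    if len(arch.qtl_snps):
        r = r + X[:, arch.qtl_snps] @ arch.effects
    if arch.polygenic_sd > 0:
        prng = np.random.default_rng(arch.polygenic_seed)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        u = prng.normal(0.0, arch.polygenic_sd / np.sqrt(geno.n_snp), size=geno.n_snp)
        r = r + Z @ u
    return r


def environmental_noise_sd(
    genetic: np.ndarray, h2_target: float, n_env: int
) -> float:
    """Per-season rate-noise SD giving broad-sense H² = h2_target over n_env
    environments (H² = σ²G / (σ²G + σ²e / n))."""
    if not 0 < h2_target < 1:
        raise InvalidArgumentError("h2_target must be in (0, 1)")
    vg = float(np.var(genetic))
    return float(np.sqrt(n_env * vg * (1.0 - h2_target) / h2_target))


def simulate_trajectories(
    geno: GenotypeMatrix,
    arch: TraitArchitecture,
    weather: pd.DataFrame,
    anthesis_dates: pd.Series,
    noise_sd: float = 0.0,
    seed: int = 0,
    r0: float = DEFAULT_R0,
    c0: float = DEFAULT_C0,
    g_min: float = DEFAULT_G_MIN,
) -> SenescenceCurves:
    """Per-accession greenness curves for one season.

    ``noise_sd`` is the per-season environmental SD added to the genetic
    senescence rate; rates are floored at a small positive value so every
    curve declines.
    """
    weather = validate_weather(weather)
    missing = [a for a in geno.accessions if a not in anthesis_dates.index]
    if missing:
        raise MissingDataError(f"no anthesis date for {missing[:3]} ...")
    anth = pd.to_datetime(anthesis_dates.loc[geno.accessions])
    lo, hi = weather["date"].iloc[0], weather["date"].iloc[-1]
    if (anth < lo).any() or (anth > hi).any():
        raise MissingDataError("anthesis dates outside the weather span")
    rng = np.random.default_rng(seed)
    rates = genetic_rates(geno, arch, r0)
    if noise_sd > 0:
        rates = rates + rng.normal(0.0, noise_sd, size=geno.n_acc)
    rates = np.clip(rates, 1e-4, None)
    return SenescenceCurves(
        accessions=geno.accessions, rates=rates, c0=c0, g_min=g_min, anthesis=anth
    )


# ---------------------------------------------------------------------------
# scene geometry and rendering


def make_plot_grid(
    plot_ids: Sequence[str],
    plot_shape: tuple[int, int] = (8, 8),
    gap: int = 2,
    n_cols: int = 10,
    margin: int = 2,
    panel_shape: tuple[int, int] = (6, 6),
) -> tuple[PlotMap, tuple[int, int], Rect]:
    """Lay plots out on a grid with a calibration panel above them.

    Returns (plot map, raster shape, panel region).
    """
    pr, pc = plot_shape
    panel_region = (margin, margin, margin + panel_shape[0], margin + panel_shape[1])
    top = panel_region[2] + gap
    rows = []
    for i, pid in enumerate(plot_ids):
        r = i // n_cols
        c = i % n_cols
        r0 = top + r * (pr + gap)
        c0 = margin + c * (pc + gap)
        rows.append((pid, r0, c0, r0 + pr, c0 + pc))
    plots = pd.DataFrame(rows, columns=["plot_id", "row0", "col0", "row1", "col1"])
    shape = (int(plots["row1"].max()) + margin, max(int(plots["col1"].max()), panel_region[3]) + margin)
    return PlotMap(plots), shape, panel_region


def draw_band_gains(seed: int, low: float = 2000.0, high: float = 8000.0) -> dict[str, float]:
    """Hidden per-band DN gains for one season (forces calibration)."""
    rng = np.random.default_rng(seed)
    return {b: float(rng.uniform(low, high)) for b in BANDS}


def render_orthomosaic(
    plot_map: PlotMap,
    greenness: pd.Series | Mapping[str, float],
    panel_region: Rect,
    shape: tuple[int, int],
    panel_reflectances: Mapping[str, float] | None = None,
    soil_fraction: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    gains: Mapping[str, float] | None = None,
    date="2021-04-20",
) -> tuple[BandStack, dict[str, float]]:
    """Render one flight date as raw digital numbers.

    Plot pixels mix the fixed canopy and soil endmember spectra linearly by
    plot greenness; a ``soil_fraction`` of pixels per plot is pure soil, and
    all background (and nothing else) is soil.  The panel region renders at
    exactly the panel reflectances.  Reflectance noise is added per pixel,
    then every band is multiplied by its hidden gain; returns the stack and
    the gains used.
    """
    greenness = pd.Series(greenness)
    if not ((greenness >= 0) & (greenness <= 1)).all():
        raise InvalidArgumentError("greenness must lie in [0, 1]")
    if not 0 <= soil_fraction < 1:
        raise InvalidArgumentError("soil_fraction must be in [0, 1)")
    missing = set(plot_map.plot_ids) - set(greenness.index)
    if missing:
        raise MissingDataError(f"greenness missing for plots {sorted(missing)[:3]} ...")
    p = plot_map.plots
    if int(p["row1"].max()) > shape[0] or int(p["col1"].max()) > shape[1]:
        raise InvalidPlotMapError("plots outside raster shape")
    pr0, pc0, pr1, pc1 = panel_region
    cover = np.zeros(shape, dtype=bool)
    for r0, c0, r1, c1 in p[["row0", "col0", "row1", "col1"]].itertuples(index=False):
        cover[r0:r1, c0:c1] = True
    if cover[pr0:pr1, pc0:pc1].any():
        raise InvalidPlotMapError("panel region overlaps a plot")

    coeffs = dict(PANEL_REFLECTANCES if panel_reflectances is None else panel_reflectances)
    if gains is None:
        gains = draw_band_gains(seed + 7919)
    gains = dict(gains)
    rng = np.random.default_rng(seed)

    bands: dict[str, np.ndarray] = {
        b: np.full(shape, SOIL_SPECTRUM[b], dtype=float) for b in BANDS
    }
    for row in p.itertuples(index=False):
        g = float(greenness[row.plot_id])
        r0, c0, r1, c1 = int(row.row0), int(row.col0), int(row.row1), int(row.col1)
        npix = (r1 - r0) * (c1 - c0)
        n_soil = int(np.floor(soil_fraction * npix))
        soil_idx = rng.choice(npix, size=n_soil, replace=False) if n_soil else np.array([], int)
        for b in BANDS:
            val = g * CANOPY_SPECTRUM[b] + (1.0 - g) * SOIL_SPECTRUM[b]
            patch = np.full(npix, val)
            patch[soil_idx] = SOIL_SPECTRUM[b]
            bands[b][r0:r1, c0:c1] = patch.reshape(r1 - r0, c1 - c0)
    for b in BANDS:
        bands[b][pr0:pr1, pc0:pc1] = coeffs[b]
        if noise_sd > 0:
            bands[b] = bands[b] + rng.normal(0.0, noise_sd, size=shape)
        bands[b] = np.clip(bands[b], 0.0, 1.2) * gains[b]
    return BandStack(bands=bands, date=pd.Timestamp(date), panel_region=panel_region), gains


def analytic_plot_index(greenness, index_name: str):
    """Exact spectral-index value of a pure canopy/soil mix at greenness g."""
    g = np.asarray(greenness, dtype=float)
    bands = {
        b: g * CANOPY_SPECTRUM[b] + (1.0 - g) * SOIL_SPECTRUM[b] for b in BANDS
    }
    return imaging.compute_index(bands, index_name)


def analytic_index_trajectory(
    curves: SenescenceCurves,
    weather: pd.DataFrame,
    flight_dates: Sequence,
    indices: Sequence[str] = ("ndvi", "gndvi", "ndre", "osavi"),
) -> SITrajectory:
    """Ground-truth trajectory straight from the greenness curves (no imagery)."""
    from .staygreen import at_table

    weather = validate_weather(weather)
    dates = sorted(pd.Timestamp(d) for d in flight_dates)
    at = at_table(weather, curves.anthesis, dates)  # acc x date, signed
    rows = []
    for j, d in enumerate(dates):
        g = curves.greenness(at.iloc[:, j].to_numpy(), accession_idx=np.arange(len(curves.accessions)))
        for name in indices:
            vals = analytic_plot_index(g, name)
            rows.extend(zip(curves.accessions, [d] * len(g), [name] * len(g), np.atleast_1d(vals)))
    values = pd.DataFrame(rows, columns=["plot_id", "date", "index", "value"])
    return SITrajectory(values=values, anthesis_date=dates[0])


# ---------------------------------------------------------------------------
# era-cohort resampling


def _largest_remainder(quota: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative quotas to integers summing exactly to ``total``."""
    base = np.floor(quota).astype(int)
    base = np.minimum(base, total)
    rem = total - base.sum()
    if rem > 0:
        order = np.argsort(-(quota - np.floor(quota)), kind="stable")
        base[order[:rem]] += 1
    elif rem < 0:
        order = np.argsort(quota - np.floor(quota), kind="stable")
        for j in order:
            if rem == 0:
                break
            if base[j] > 0:
                base[j] -= 1
                rem += 1
    return base


def assign_cohorts(
    geno: GenotypeMatrix,
    snp_pair: tuple[str, str],
    hap1_alleles: tuple[str, str],
    hap2_alleles: tuple[str, str],
    era_targets: Mapping[str, float],
    seed: int = 0,
    freq_tol: float = 0.02,
) -> GenotypeMatrix:
    """Reassign era labels so the favorable-haplotype frequency follows a trend.

    ``era_targets`` maps era bin -> target Hap1 frequency among the
    accessions carrying either haplotype in that bin.  Every accession keeps
    a label; era bin sizes are adapted (as in real panels, eras need not be
    equally represented) so that the whole carrier pool is distributed while
    each era's realized frequency matches its target to within ``freq_tol``.
    Raises :class:`InfeasibleGradientError` when no such allocation exists
    (e.g. a target of 1.0 with only 10% carriers).
    """
    from .popselect import assign_haplotypes

    for e, t in era_targets.items():
        if not 0 <= t <= 1:
            raise InvalidArgumentError(f"target frequency for {e} outside [0, 1]")
    assign = assign_haplotypes(geno, snp_pair, hap1_alleles, hap2_alleles)
    labels = assign.labels
    rng = np.random.default_rng(seed)
    hap1_pool = list(labels.index[labels == "Hap1"])
    hap2_pool = list(labels.index[labels == "Hap2"])
    other_pool = list(labels.index[labels == "other"])
    rng.shuffle(hap1_pool)
    rng.shuffle(hap2_pool)
    rng.shuffle(other_pool)

    eras = list(era_targets)
    tau = np.array([era_targets[e] for e in eras], dtype=float)
    n1, n2 = len(hap1_pool), len(hap2_pool)
    n_assigned = n1 + n2
    if n_assigned == 0:
        raise InfeasibleGradientError("no accession carries either haplotype")
    # Solve for era sizes t_e with sum t_e = n_assigned and
    # sum tau_e t_e = n1 (all carriers placed), staying close to even bins.
    tbar = tau.mean()
    var = float(((tau - tbar) ** 2).sum())
    pool_freq = n1 / n_assigned
    if var == 0:
        if abs(pool_freq - tbar) > freq_tol:
            raise InfeasibleGradientError(
                f"uniform target {tbar:.3f} vs pool frequency {pool_freq:.3f}"
            )
        t = np.full(len(eras), n_assigned / len(eras))
    else:
        lam = (n1 - n_assigned * tbar) / var
        t = n_assigned / len(eras) + lam * (tau - tbar)
    if np.any(t < 1):
        raise InfeasibleGradientError(
            "gradient incompatible with the carrier pool (an era bin would be empty)"
        )
    sizes = _largest_remainder(t, n_assigned)
    k1 = _largest_remainder(tau * sizes, n1)
    k2 = sizes - k1
    if np.any(k2 < 0) or np.any(k1 > sizes):
        raise InfeasibleGradientError("rounding produced a negative group count")
    realized = k1 / np.maximum(sizes, 1)
    if np.any(np.abs(realized - tau) > freq_tol):
        raise InfeasibleGradientError(
            f"realized frequencies {np.round(realized, 3)} miss targets beyond ±{freq_tol}"
        )
    others_per = _largest_remainder(
        np.full(len(eras), len(other_pool) / len(eras)), len(other_pool)
    )
    new_era = {}
    for e, a_, b_, c_ in zip(eras, k1, k2, others_per):
        chosen = [hap1_pool.pop() for _ in range(int(a_))]
        chosen += [hap2_pool.pop() for _ in range(int(b_))]
        chosen += [other_pool.pop() for _ in range(int(c_))]
        for acc in chosen:
            new_era[acc] = e
    out_labels = geno.labels.copy()
    out_labels["era"] = pd.Series(new_era).reindex(out_labels.index)
    return geno.with_labels(out_labels)


# ---------------------------------------------------------------------------
# end-to-end scene


@dataclass
class Scene:
    """A fully rendered synthetic season with its ground truth."""

    weather: pd.DataFrame
    geno: GenotypeMatrix
    arch: TraitArchitecture
    anthesis: pd.Series
    curves: SenescenceCurves
    plot_map: PlotMap
    shape: tuple[int, int]
    panel_region: Rect
    flight_dates: list
    stacks: list
    gains: dict[str, float]


def simulate_scene(
    n_acc: int = 100,
    n_snp: int = 500,
    n_flights: int = 12,
    cadence_days: int = 3,
    soil_fraction: float = 0.1,
    noise_sd: float = 0.0,
    weather_base: float = 22.0,
    weather_amplitude: float = 2.0,
    weather_noise_sd: float = 0.0,
    anthesis_spread: int = 3,
    rate_noise_sd: float = 0.0,
    arch: TraitArchitecture | None = None,
    seed: int = 0,
) -> Scene:
    """Simulate a full season: weather, panel, curves and temporal imagery.

    Flights start on the earliest anthesis date at a fixed cadence.  The
    defaults give flights spanning roughly 0–790 °C·day so all four stage
    boundaries fall within the stage-assignment tolerance.
    """
    rng = np.random.default_rng(seed)
    weather = simulate_weather(
        n_days=cadence_days * n_flights + anthesis_spread + 30,
        base=weather_base,
        amplitude=weather_amplitude,
        noise_sd=weather_noise_sd,
        seed=seed + 1,
        start="2021-04-10",
    )
    geno = simulate_genotypes(n_acc, n_snp, seed=seed + 2)
    anthesis = simulate_anthesis(
        geno.accessions, start="2021-04-12", spread_days=anthesis_spread, seed=seed + 3
    )
    geno = assign_flowering_classes(geno, anthesis)
    if arch is None:
        q = int(rng.integers(0, n_snp))
        arch = TraitArchitecture(
            qtl_snps=np.array([q]),
            effects=np.array([-0.0015]),
            polygenic_sd=0.001,
            polygenic_seed=seed + 4,
        )
    curves = simulate_trajectories(
        geno, arch, weather, anthesis, noise_sd=rate_noise_sd, seed=seed + 5
    )
    plot_map, shape, panel_region = make_plot_grid(geno.accessions)
    start = anthesis.min()
    flights = [start + pd.Timedelta(days=cadence_days * i) for i in range(n_flights)]
    gains = draw_band_gains(seed + 6)
    from .staygreen import at_table

    at = at_table(weather, curves.anthesis, flights)
    stacks = []
    for j, d in enumerate(flights):
        g = curves.greenness(
            at.iloc[:, j].to_numpy(), accession_idx=np.arange(n_acc)
        )
        stack, _ = render_orthomosaic(
            plot_map,
            pd.Series(g, index=geno.accessions),
            panel_region,
            shape,
            soil_fraction=soil_fraction,
            noise_sd=noise_sd,
            seed=seed + 100 + j,
            gains=gains,
            date=d,
        )
        stacks.append(stack)
    return Scene(
        weather=weather, geno=geno, arch=arch, anthesis=anthesis, curves=curves,
        plot_map=plot_map, shape=shape, panel_region=panel_region,
        flight_dates=flights, stacks=stacks, gains=gains,
    )
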