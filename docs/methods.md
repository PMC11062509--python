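# Methods

## Scope and data flow

`sgpipe` turns temporal five-band plot imagery plus daily weather into
stage-wise stay-green traits, then performs the genetics on those traits:

    simdata → imaging → staygreen → quantgen / gwas / popselect

All tabular interchange is plain text (CSV, VCF, GeoJSON, single-band
TIFF). Nothing below depends on geo-referencing: plot polygons live in
raster pixel coordinates (0-based, half-open rectangles), and registration
of orthomosaics is assumed done upstream.

## Imaging

**Calibration.** Reflectance = raw digital number × gain, with
gain = panel reflectance coefficient / mean DN over the panel region. Each
band uses its own panel coefficient (blue 0.542, green 0.542, red 0.539,
red edge 0.533, NIR 0.537). A non-positive panel mean is an error, not a
silent passthrough.

**Indices.** NDVI, GNDVI and NDRE are plain normalized differences; OSAVI
uses the standard soil-adjustment constant L = 0.16 *including* the (1+L)
numerator factor. Index definitions are data (`SpectralIndexDefinition`),
so alternates can be swapped without touching the pipeline. Indices are
always computed per pixel and then averaged over the plot; the index of the
mean reflectances is a different quantity and is never used (a test pins
this ordering).

**Masking.** A single canopy mask is built from the first (anthesis) flight
as NDVI ≥ 0.6 and reused for all later dates, mirroring a one-off
segmentation of the trial. The comparison is ≥ (the boundary pixel is
canopy). Missing pixels propagate as NaN and are never zero-filled; a plot
whose masked intersection is empty becomes a missing cell with a warning.

## Thermal time and scoring

Accumulated temperature (AT) is the sum of daily mean temperatures over
(anthesis, target] — exclusive of the anthesis day, inclusive of the target
day. Stages default to AT boundaries S1 = 300, S2 = 400, S3 = 550,
S4 = 700 °C·day, consistent with senescence accelerating beyond roughly
400 °C·day after anthesis; the exact values are configurable because they
are calibration constants of a given trial, not universal biology. Each
stage maps to the flight whose AT is nearest the boundary (ties to the
earlier date); if no flight is within 60 °C·day (configurable) the stage is
left missing with a warning rather than extrapolated.

RSS/RSGS follow the ratio form given in the README. RSS may be negative
(an index momentarily above its anthesis baseline, e.g. noise); it is kept
so RSS + RSGS = 100 holds identically. The flowering correction
k_i = AT(MF at S_i) / AT(class at S_i) uses the mean *attained* AT of each
flowering class at the chosen flights, computed per season; k = 1 exactly
for the MF class. Flowering classes are input labels; the synthetic
generator assigns them by terciles of the anthesis date, since any real
trial will carry its own definition.

## Synthetic data

The generator's role is ground truth, not photorealism.

- **Weather** is a sinusoid plus Gaussian noise (defaults: base 20–22 °C,
  amplitude a few °C, noise 1 °C) — enough to make AT a non-trivial,
  date-dependent axis.
- **Genotypes** follow the Balding–Nichols model: ancestral frequency
  ~ U(0.05, 0.95), subpopulation frequencies Beta-distributed with the
  differentiation parameter F, dosages Binomial(2, p). Defaults: 3
  subpopulations, F = 0.05, three 600-Mb chromosomes with uniform SNP
  placement. Cohort labels (group CL/IMC/MCC by subpopulation; era and
  region by configurable proportions) ride along.
- **Senescence curves** are logistic in AT with a per-accession rate r and
  shared shape constant c0 = 5.4:
  g(AT) = g_min + (1−g_min)(1+e^(−c0)) / (1+e^(r·AT−c0)). The decline
  midpoint sits at AT = c0/r (450 °C·day at the default r₀ = 0.012),
  g(0) = 1 exactly, and g is strictly decreasing in r for every AT > 0 —
  the parametrisation was chosen over a fixed-midpoint logistic precisely
  so that allele effects on r translate monotonically into greenness at
  every stage. Rates are r₀ + QTL effects·dosage + a polygenic term
  (standardised dosages × small normal effects, seeded independently so it
  is stable across seasons) + per-season noise. The helper
  `environmental_noise_sd` returns the noise SD that yields a target
  broad-sense H² for a given number of environments.
- **Imagery** mixes fixed canopy and soil endmember spectra linearly by
  greenness (canopy NDVI ≈ 0.90, soil NDVI = 0.20, so the 0.6 mask
  separates them by construction), renders a configurable fraction of pure
  soil pixels inside plots, soil everywhere else, and the panel region at
  exactly the panel coefficients. Hidden per-band gains (drawn once per
  season) convert reflectance to digital numbers, so calibration is
  exercised non-trivially.
- **Era cohorts**: `assign_cohorts` relabels eras so the favorable
  two-SNP haplotype follows a target frequency trajectory. Era bin sizes
  adapt to the carrier pool (real panels are not era-balanced); the
  allocation solves one linear constraint and distributes carriers by
  largest-remainder rounding, raising an error when no allocation can meet
  the targets within ±0.02.

What the generator does **not** emulate: radiative transfer, BRDF/sun
angle, shadows, plot-boundary mixed pixels, spatial field trends, linkage
disequilibrium beyond subpopulation structure (SNPs are exchangeable given
ancestry), and real flight-date jitter (fixed cadence, default 3 days).
Passing recovery tests therefore demonstrate internal consistency of the
estimators under the stated generative model, not robustness to these
real-data effects.

Scene defaults use 12 flights at a 3-day cadence (AT span ≈ 0–790 °C·day,
flight spacing ≈ 70 °C·day, safely inside the 60 °C·day stage tolerance on
each side of a boundary). The round-trip checks use 100 plots with 8
flights at a 5-day cadence — the same AT span sampled more coarsely —
with all noise sources at zero.

## Quantitative genetics

**Heritability** uses the one-way random model y_ij = μ + g_i + e_ij and
the expected-mean-squares estimator (σ²e = MS_error,
σ²G = (MS_geno − MS_error)/n₀, negatives clamped at 0), with
n₀ = (N − Σn_i²/N)/(a−1) for unbalanced tables;
H² = σ²G/(σ²G + σ²e/n) over n environments. In balanced data this equals
the REML fit; the moment estimator was chosen as the canonical path because
it is closed-form and oracle-checkable.

**LD decay** is the squared dosage correlation (composite LD — phase is not
modeled) over intra-chromosomal pairs, averaged in equal-width distance
bins. The decay distance interpolates the running-minimum-smoothed binned
curve at the critical r² (default 0.1). Binned means were preferred over a
locally weighted curve because they have no bandwidth parameter and are
exactly reproducible.

## Mixed-model scan

K = X_c X_cᵀ/m over filtered, mean-imputed dosages (MAF ≥ 0.05,
missingness ≤ 0.1 by default). After one eigendecomposition K = UDUᵀ, the
model per SNP has diagonal covariance λD + I in the rotated basis. The
restricted likelihood is profiled over λ on log₁₀λ ∈ [−5, 5]: a 41-point
grid followed by golden-section refinement, per SNP by default (a shared
null-model λ is available as a faster mode). The per-SNP profile is
vectorised across SNPs via the Schur complement of the SNP column in
XᵀH⁻¹X, so the grid stage costs a handful of matrix products per λ and the
refinement stage operates on per-SNP λ vectors; a 500 × 1000 scan takes
seconds. β is tested with a Wald F on n − c degrees of freedom; with K = I
the profile is flat in λ and the scan reduces exactly to OLS F-tests.
Per-SNP variance explained is reported as β²·var(x)/var(y).

The genome-wide threshold defaults to the uniform 2.6 × 10⁻⁴; optional
per-chromosome cutoffs use 1/m_eff with m_eff the greedy LD-pruned marker
count (a SNP is dropped at r² ≥ 0.2 with any kept SNP) — for independent
markers nothing prunes and m_eff equals the marker count. QTL are
single-linkage chains of significant SNPs with inter-marker gaps ≤ 5 Mb;
singletons form width-0 intervals, and the per-QTL R² convention is the
peak single-SNP value in the interval. Candidate-gene scans are the same
model restricted to an interval.

## Selection scans

**Fst** is the two-population Weir–Cockerham (1984) estimator from per-SNP
variance components (a, b, c); windows aggregate by ratio of sums
(Σa / Σ(a+b+c)), the "weighted" convention, over [start, start+1 Mb)
windows stepping 100 kb from position 1. Monomorphic SNPs and groups with
fewer than two called diploids yield undefined components, excluded from
the sums.

**xpclr_lite** is a deliberately simplified composite-likelihood sweep
statistic: with no genetic map available, the original recombination-
distance model is replaced by a physical-distance kernel. For a window, the
object population's allele count at SNP i is binomial with success
probability integrated over a truncated normal centred at the reference
frequency with variance (ω/c_i)·p₁(1−p₁) plus boundary point masses, where
c_i(c) = 1 − exp(−d_i/c) and d_i is the distance to the window centre. The
genome-wide drift scale ω is the median of (p̂₂−p̂₁)²/(p̂₁(1−p̂₁)) over
reference-informative SNPs. The score maximises over a grid of decay
scales c (fractions 0.01–1 of the window size) and *includes the neutral
model in the maximum*, so 2·(max ll − ll_neutral) ≥ 0 holds exactly.
Integration uses 40-point Gauss–Legendre quadrature on (0, 1), accurate to
~10⁻⁶ relative against adaptive quadrature. Sweep calling flags the top
5% (ceil) of defined windows per statistic independently; ties at the cut
break toward the leftmost coordinate.

**Haplotypes.** Hap1/Hap2 assignment at a defining SNP pair requires
homozygosity at both SNPs (appropriate for inbred wheat); heterozygous or
recombinant accessions are "other" and excluded from frequency
denominators. Era trends report per-stratum Hap1/Hap2 fractions among
assigned accessions plus a Cochran–Armitage-type trend test
(linear-by-linear association with integer era scores, via statsmodels).
Trait contrasts between haplotype groups are Welch two-tailed t-tests.

## Numerical conventions

- Missing data are NaN throughout; dosage −1 codes a missing call in the
  integer matrix and is mean-imputed only inside the GWAS filters.
- All randomness flows through `numpy.random.default_rng(seed)` passed
  explicitly; no global state. Repeated calls with the same arguments are
  byte-identical.
- RSS is not clamped; stage cells without a qualifying flight are missing,
  and missingness propagates to the trait table rather than being imputed.
- Eigenvalues of K are clipped at 0; a singular covariate block raises
  rather than silently dropping columns.

## Known limitations

- The stage boundaries and the flight cadence interact: sparse flights
  (spacing > 2× tolerance in AT) produce unresolved stages by design.
- The EMS heritability assumes accession-mean-per-season inputs; plot-level
  replication within season is not modeled.
- `xpclr_lite` scores are not comparable to genetic-map-based XP-CLR
  values; only within-scan rankings (and hence top-fraction sweep calls)
  are meaningful.
- The mixed model fits one variance component; dominance, epistasis and
  multi-trait models are out of scope, as are genomic-control corrections.
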