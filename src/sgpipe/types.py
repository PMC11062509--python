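"""Core containers shared across the pipeline.

The pipeline moves data through a small set of typed containers: a daily
weather table, a biallelic dosage matrix with cohort labels, a plot map in
raster pixel coordinates, five-band image stacks, per-plot spectral-index
trajectories, and the stage schedule used to score stay-green.  Tabular data
are plain :class:`pandas.DataFrame` objects with documented columns; the
dataclasses below add validation and the small amount of behaviour (greenness
curves, trajectory pivots) the pipeline needs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidPlotMapError

# Five bands of the multispectral camera, in canonical order.
BANDS: tuple[str, ...] = ("blue", "green", "red", "rededge", "nir")

# Reflectance calibration coefficients of the camera's calibrated panel,
# one per band (unitless reflectance of the grey panel in that band).
PANEL_REFLECTANCES: dict[str, float] = {
    "blue": 0.542,
    "green": 0.542,
    "red": 0.539,
    "rededge": 0.533,
    "nir": 0.537,
}

# Fixed endmember spectra used by the scene renderer.  Chosen so that full
# canopy has NDVI ~ 0.90 and bare soil NDVI = 0.20, which the 0.6 NDVI mask
# threshold separates cleanly.
CANOPY_SPECTRUM: dict[str, float] = {
    "blue": 0.04,
    "green": 0.08,
    "red": 0.03,
    "rededge": 0.30,
    "nir": 0.55,
}
SOIL_SPECTRUM: dict[str, float] = {
    "blue": 0.10,
    "green": 0.15,
    "red": 0.20,
    "rededge": 0.25,
    "nir": 0.30,
}

# Breeding-era bins (release decades) in chronological order.
ERA_BINS: tuple[str, ...] = (
    "pre-1950",
    "1951-1970",
    "1971-1990",
    "1991-2010",
    "post-2010",
)

REGIONS: tuple[str, ...] = ("I", "II", "III")
GROUPS: tuple[str, ...] = ("CL", "IMC", "MCC")
FLOWERING_CLASSES: tuple[str, ...] = ("EF", "MF", "LF")
STAGES: tuple[str, ...] = ("S1", "S2", "S3", "S4")

#: Rectangle in raster pixel coordinates: (row0, col0, row1, col1),
#: 0-based, half-open on both axes.
Rect = tuple[int, int, int, int]


def validate_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """Validate a daily weather table (columns ``date``, ``tmean``).

    Dates must be strictly increasing calendar days with no gaps and tmean
    finite.  Returns the frame with ``date`` coerced to datetime64.
    """
    if not {"date", "tmean"} <= set(weather.columns):
        raise InvalidArgumentError("weather needs 'date' and 'tmean' columns")
    out = weather.copy()
    out["date"] = pd.to_datetime(out["date"])
    d = out["date"].to_numpy()
    if len(d) == 0:
        raise InvalidArgumentError("weather series is empty")
    if len(d) > 1:
        steps = np.diff(d) / np.timedelta64(1, "D")
        if not np.all(steps == 1.0):
            raise InvalidArgumentError("weather dates must be consecutive days")
    if not np.all(np.isfinite(out["tmean"].to_numpy(dtype=float))):
        raise InvalidArgumentError("tmean contains non-finite values")
    return out


@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix with marker metadata and cohort labels.

    Attributes
    ----------
    dosages : (n_acc, n_snp) int8 array with values in {0, 1, 2} (-1 = missing)
    chrom : per-SNP chromosome label
    pos_bp : per-SNP physical position (bp), non-decreasing within chromosome
    snp_ids : per-SNP identifiers
    accessions : accession identifiers
    labels : DataFrame indexed by accession with columns
        ``flowering_class`` (EF/MF/LF), ``era``, ``region``, ``group``
    ref, alt : per-SNP allele bases
    """

    dosages: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    snp_ids: np.ndarray
    accessions: np.ndarray
    labels: pd.DataFrame
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.chrom = np.asarray(self.chrom)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.snp_ids = np.asarray(self.snp_ids)
        self.accessions = np.asarray(self.accessions)
        if self.ref is None:
            self.ref = np.full(self.n_snp, "A")
        if self.alt is None:
            self.alt = np.full(self.n_snp, "C")
        if self.dosages.shape != (len(self.accessions), len(self.snp_ids)):
            raise InvalidArgumentError("dosage shape does not match ids")
        vals = np.unique(self.dosages)
        if not np.all(np.isin(vals, [-1, 0, 1, 2])):
            raise InvalidArgumentError("dosages must be in {0,1,2} (-1 missing)")
        for c in np.unique(self.chrom):
            p = self.pos_bp[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise InvalidArgumentError(
                    f"positions not non-decreasing on chromosome {c}"
                )
        missing = set(self.accessions) - set(self.labels.index)
        if missing:
            raise InvalidArgumentError(f"labels missing for accessions: {sorted(missing)[:3]} ...")

    @property
    def n_acc(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snp(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP, ignoring missing calls."""
        d = self.dosages.astype(float)
        d[d < 0] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def snp_index(self, snp_id: str) -> int:
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if len(idx) == 0:
            from .errors import MissingSNPError

            raise MissingSNPError(snp_id)
        return int(idx[0])

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            dosages=self.dosages[:, mask],
            chrom=self.chrom[mask],
            pos_bp=self.pos_bp[mask],
            snp_ids=self.snp_ids[mask],
            accessions=self.accessions,
            labels=self.labels,
            ref=np.asarray(self.ref)[mask],
            alt=np.asarray(self.alt)[mask],
        )

    def with_labels(self, labels: pd.DataFrame) -> "GenotypeMatrix":
        return dataclasses.replace(self, labels=labels)


@dataclass
class TraitArchitecture:
    """Planted genetic architecture of the senescence-rate parameter.

    ``effects`` act additively on the logistic senescence rate per unit
    dosage; negative effects slow senescence (stay-green).  ``polygenic_sd``
    adds a genome-wide breeding value (standardised dosages times small
    normal effects) that is deterministic given ``polygenic_seed`` and hence
    stable across simulated seasons.
    """

    qtl_snps: np.ndarray
    effects: np.ndarray
    h2_target: float | None = None
    polygenic_sd: float = 0.0
    polygenic_seed: int = 0

    def __post_init__(self) -> None:
        self.qtl_snps = np.asarray(self.qtl_snps, dtype=int)
        self.effects = np.asarray(self.effects, dtype=float)
        if len(np.unique(self.qtl_snps)) != len(self.qtl_snps):
            raise InvalidArgumentError("qtl_snps must be distinct")
        if not np.all(np.isfinite(self.effects)):
            raise InvalidArgumentError("effects must be finite")
        if len(self.qtl_snps) != len(self.effects):
            raise InvalidArgumentError("qtl_snps and effects differ in length")


@dataclass
class PlotMap:
    """Rectangular plot polygons in raster pixel coordinates.

    ``plots`` is a DataFrame with columns ``plot_id, row0, col0, row1, col1``
    (0-based, half-open).  Plot ids are unique and rectangles non-overlapping.
    """

    plots: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"plot_id", "row0", "col0", "row1", "col1"}
        if not req <= set(self.plots.columns):
            raise InvalidPlotMapError(f"plot map needs columns {sorted(req)}")
        if self.plots["plot_id"].duplicated().any():
            raise InvalidPlotMapError("duplicate plot_id")
        p = self.plots
        if ((p["row1"] <= p["row0"]) | (p["col1"] <= p["col0"])).any():
            raise InvalidPlotMapError("empty plot rectangle")
        # Overlap check by rasterised coverage counting.
        nr = int(p["row1"].max())
        nc = int(p["col1"].max())
        cover = np.zeros((nr, nc), dtype=np.int16)
        for r0, c0, r1, c1 in p[["row0", "col0", "row1", "col1"]].itertuples(index=False):
            cover[r0:r1, c0:c1] += 1
        if (cover > 1).any():
            raise InvalidPlotMapError("plot rectangles overlap")

    @property
    def plot_ids(self) -> np.ndarray:
        return self.plots["plot_id"].to_numpy()

    def rect(self, plot_id) -> Rect:
        row = self.plots.loc[self.plots["plot_id"] == plot_id].iloc[0]
        return (int(row.row0), int(row.col0), int(row.row1), int(row.col1))

    def __len__(self) -> int:
        return len(self.plots)


@dataclass
class BandStack:
    """Five co-registered band rasters for one flight date.

    ``bands`` maps band name -> 2-D float array.  Values are raw digital
    numbers straight from the renderer/sensor, or unitless reflectance after
    :func:`sgpipe.imaging.calibrate_stack`.  ``panel_region`` is the rectangle
    covering the calibrated reflectance panel.
    """

    bands: dict[str, np.ndarray]
    date: pd.Timestamp
    panel_region: Rect

    def __post_init__(self) -> None:
        shapes = {b: a.shape for b, a in self.bands.items()}
        if len(set(shapes.values())) > 1:
            raise InvalidArgumentError(f"band shapes differ: {shapes}")
        self.date = pd.Timestamp(self.date)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape


@dataclass
class SenescenceCurves:
    """Per-accession post-anthesis greenness curves.

    Greenness declines logistically in accumulated temperature (AT):

        g(AT) = g_min + (1 - g_min) * (1 + exp(-c0)) / (1 + exp(r*AT - c0))

    with a per-accession rate ``r`` (1/°C·day) and a shared shape constant
    ``c0``; g(0) = 1 exactly and g is strictly decreasing in both AT and r,
    so a smaller rate means stay-green.  The midpoint of the decline sits at
    AT = c0 / r.
    """

    accessions: np.ndarray
    rates: np.ndarray
    c0: float
    g_min: float
    anthesis: pd.Series  # accession -> anthesis date

    def greenness(self, at, accession_idx=None) -> np.ndarray:
        """Greenness at accumulated temperature ``at`` (clipped below at 0).

        With ``accession_idx=None`` and ``at`` of shape (n_at,), returns an
        (n_acc, n_at) matrix; otherwise evaluates elementwise for the given
        accession indices.
        """
        at = np.clip(np.asarray(at, dtype=float), 0.0, None)
        if accession_idx is None:
            r = self.rates[:, None]
            at = np.atleast_1d(at)[None, :]
        else:
            r = self.rates[np.asarray(accession_idx)]
        top = 1.0 + np.exp(-self.c0)
        return self.g_min + (1.0 - self.g_min) * top / (1.0 + np.exp(r * at - self.c0))


@dataclass
class SITrajectory:
    """Per-plot, per-date spectral-index values.

    ``values`` is a long DataFrame with columns ``plot_id, date, index,
    value`` sorted by (plot_id, date, index); a missing plot/date cell is a
    NaN value, never a zero.  ``anthesis_date`` marks the flight used as the
    anthesis (maximum-greenness) reference.
    """

    values: pd.DataFrame
    anthesis_date: pd.Timestamp

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values["date"] = pd.to_datetime(self.values["date"])
        self.values = self.values.sort_values(["plot_id", "date", "index"]).reset_index(drop=True)
        self.anthesis_date = pd.Timestamp(self.anthesis_date)

    @property
    def dates(self) -> np.ndarray:
        return np.sort(self.values["date"].unique())

    @property
    def indices(self) -> list[str]:
        return sorted(self.values["index"].unique())

    @property
    def plot_ids(self) -> np.ndarray:
        return self.values["plot_id"].unique()

    def pivot(self, index_name: str) -> pd.DataFrame:
        """plot x date table for one spectral index."""
        sub = self.values[self.values["index"] == index_name]
        return sub.pivot(index="plot_id", columns="date", values="value")

    def anthesis_values(self) -> pd.DataFrame:
        """plot x index table of values at the anthesis flight."""
        sub = self.values[self.values["date"] == self.anthesis_date]
        return sub.pivot(index="plot_id", columns="index", values="value")


@dataclass
class PlotMask:
    """Boolean canopy mask built once from the first-flight NDVI."""

    mask: np.ndarray
    source_date: pd.Timestamp
    threshold: float = 0.6


@dataclass
class StageSchedule:
    """Accumulated-temperature boundaries of the four senescence stages.

    Defaults (°C·day after anthesis): S1=300, S2=400, S3=550, S4=700,
    spanning milk-ripe to late mealy-ripe; fully configurable.  ``tolerance``
    is the maximum |AT(flight) - boundary| accepted when mapping stages to
    flights.
    """

    boundaries: dict[str, float] = field(
        default_factory=lambda: {"S1": 300.0, "S2": 400.0, "S3": 550.0, "S4": 700.0}
    )
    tolerance: float = 60.0

    def __post_init__(self) -> None:
        vals = list(self.boundaries.values())
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise InvalidArgumentError("stage boundaries must be strictly increasing")
        if self.tolerance <= 0:
            raise InvalidArgumentError("tolerance must be positive")

    @property
    def stages(self) -> list[str]:
        return list(self.boundaries)


@dataclass
class HeritabilityEstimate:
    """Variance components and broad-sense heritability across environments."""

    sigma2_G: float
    sigma2_e: float
    n_env: int
    H2: float


@dataclass
class LDDecayResult:
    """Binned LD decay curve and the distance where r² crosses a critical value."""

    bins: pd.DataFrame  # bin_start, bin_end, mean_r2, n_pairs
    decay_distance: float
    critical_r2: float


@dataclass
class QTLInterval:
    """A run of significant SNPs chained within a physical-distance gap."""

    chrom: str
    start_bp: int
    end_bp: int
    snp_ids: list
    peak_p: float
    traits: set = field(default_factory=set)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass
class HaplotypeAssignment:
    """Per-accession haplotype labels at a defining SNP pair."""

    snp_pair: tuple[str, str]
    hap1_alleles: tuple[str, str]
    hap2_alleles: tuple[str, str]
    labels: pd.Series  # accession -> "Hap1" | "Hap2" | "other"

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(["Hap1", "Hap2", "other"], fill_value=0)

    def frequencies(self) -> pd.Series:
        c = self.counts()
        return c / c.sum()
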