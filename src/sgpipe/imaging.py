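"""Raster front end: panel calibration, spectral indices, masking, extraction.

Turns raw multispectral band rasters into per-plot, per-date spectral-index
values.  The processing order is fixed: calibrate each band against the grey
reference panel, compute each index per pixel, build a canopy mask once from
the first-flight NDVI (threshold 0.6), then average the index over the masked
pixels of each plot rectangle.  Indices are always computed per pixel and
averaged afterwards — the index of the mean reflectances is a different (and
not used) quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CalibrationError,
    EmptyPlotWarning,
    InvalidArgumentError,
    InvalidDefinitionError,
    InvalidPlotError,
)
from .types import (
    PANEL_REFLECTANCES,
    BandStack,
    PlotMap,
    PlotMask,
    Rect,
    SITrajectory,
)

DEFAULT_MASK_THRESHOLD = 0.6


@dataclass(frozen=True)
class SpectralIndexDefinition:
    """A spectral index as a normalized difference with optional soil term.

    ``(1 + soil_l) * (b1 - b2) / (b1 + b2 + soil_l)``; with ``soil_l = 0``
    this is the plain normalized difference.  OSAVI uses the standard soil
    adjustment constant L = 0.16, including the (1 + L) numerator factor.
    """

    name: str
    band_plus: str
    band_minus: str
    soil_l: float = 0.0

    def compute(self, bands: Mapping[str, np.ndarray | float]):
        for b in (self.band_plus, self.band_minus):
            if b not in bands:
                raise InvalidDefinitionError(
                    f"index {self.name!r} needs band {b!r}, have {sorted(bands)}"
                )
        b1 = np.asarray(bands[self.band_plus], dtype=float)
        b2 = np.asarray(bands[self.band_minus], dtype=float)
        denom = b1 + b2 + self.soil_l
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (1.0 + self.soil_l) * (b1 - b2) / denom
        out = np.where(denom == 0, np.nan, out)
        if out.ndim == 0:
            return float(out)
        return out


#: The four indices used for stay-green scoring.
INDEX_DEFINITIONS: dict[str, SpectralIndexDefinition] = {
    "ndvi": SpectralIndexDefinition("ndvi", "nir", "red"),
    "gndvi": SpectralIndexDefinition("gndvi", "nir", "green"),
    "ndre": SpectralIndexDefinition("ndre", "nir", "rededge"),
    "osavi": SpectralIndexDefinition("osavi", "nir", "red", soil_l=0.16),
}


def panel_gain(raw_band: np.ndarray, panel_region: Rect, panel_reflectance: float) -> float:
    """Multiplicative gain mapping digital numbers to reflectance.

    gain = panel_reflectance / mean(DN over the panel region).
    """
    r0, c0, r1, c1 = panel_region
    patch = np.asarray(raw_band, dtype=float)[r0:r1, c0:c1]
    if patch.size == 0:
        raise CalibrationError("panel region is empty")
    m = float(np.nanmean(patch))
    if not np.isfinite(m) or m <= 0:
        raise CalibrationError(f"panel mean DN must be positive, got {m}")
    return panel_reflectance / m


def calibrate_reflectance(
    raw_band: np.ndarray, panel_region: Rect, panel_reflectance: float
) -> np.ndarray:
    """Scale a raw digital-number raster to reflectance via the panel gain."""
    gain = panel_gain(raw_band, panel_region, panel_reflectance)
    return np.asarray(raw_band, dtype=float) * gain


def calibrate_stack(
    stack: BandStack, panel_reflectances: Mapping[str, float] | None = None
) -> BandStack:
    """Calibrate every band of a stack against its panel coefficient."""
    coeffs = dict(PANEL_REFLECTANCES if panel_reflectances is None else panel_reflectances)
    bands = {
        b: calibrate_reflectance(a, stack.panel_region, coeffs[b])
        for b, a in stack.bands.items()
    }
    return BandStack(bands=bands, date=stack.date, panel_region=stack.panel_region)


def compute_index(
    stack: BandStack | Mapping[str, np.ndarray], defn: SpectralIndexDefinition | str
) -> np.ndarray:
    """Per-pixel spectral index raster; zero-denominator pixels become NaN."""
    if isinstance(defn, str):
        try:
            defn = INDEX_DEFINITIONS[defn.lower()]
        except KeyError:
            raise InvalidDefinitionError(f"unknown index {defn!r}") from None
    bands = stack.bands if isinstance(stack, BandStack) else stack
    return defn.compute(bands)


def build_mask(
    ndvi_first_flight: np.ndarray,
    threshold: float = DEFAULT_MASK_THRESHOLD,
    source_date=None,
) -> PlotMask:
    """Canopy mask: NDVI >= threshold on the first (anthesis) flight.

    Missing (NaN) pixels are excluded.  The mask is built once and reused for
    every later flight date.
    """
    arr = np.asarray(ndvi_first_flight, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = arr >= threshold
    mask &= np.isfinite(arr)
    return PlotMask(mask=mask, source_date=pd.Timestamp(source_date or 0), threshold=threshold)


def extract_plot_values(
    index_raster: np.ndarray, mask: PlotMask | np.ndarray, plots: PlotMap
) -> pd.Series:
    """Mean index over (plot ∩ mask) pixels for every plot.

    Pixel membership is by pixel center in the 0-based half-open rectangle,
    i.e. plain array slicing.  A plot whose masked intersection is empty gets
    NaN and raises :class:`EmptyPlotWarning`.
    """
    arr = np.asarray(index_raster, dtype=float)
    m = mask.mask if isinstance(mask, PlotMask) else np.asarray(mask, dtype=bool)
    if m.shape != arr.shape:
        raise InvalidArgumentError("mask shape differs from raster shape")
    out = {}
    for row in plots.plots.itertuples(index=False):
        r0, c0, r1, c1 = int(row.row0), int(row.col0), int(row.row1), int(row.col1)
        if r0 < 0 or c0 < 0 or r1 > arr.shape[0] or c1 > arr.shape[1]:
            raise InvalidPlotError(f"plot {row.plot_id!r} outside raster bounds")
        patch = arr[r0:r1, c0:c1]
        keep = m[r0:r1, c0:c1] & np.isfinite(patch)
        if not keep.any():
            warnings.warn(f"plot {row.plot_id!r} has no masked pixels", EmptyPlotWarning)
            out[row.plot_id] = np.nan
        else:
            out[row.plot_id] = float(patch[keep].mean())
    return pd.Series(out, name="value")


def assemble_trajectories(
    per_date_values: Mapping, flight_dates: Sequence, anthesis_flight
) -> SITrajectory:
    """Stack per-date plot means into a trajectory.

    ``per_date_values`` maps flight date -> {index name -> Series plot_id ->
    value}.  Dates may arrive in any order; the result is sorted.  The
    anthesis flight supplies the maximum-greenness reference values.
    """
    dates = [pd.Timestamp(d) for d in flight_dates]
    if len(set(dates)) != len(dates):
        raise InvalidArgumentError("duplicate flight dates")
    anthesis = pd.Timestamp(anthesis_flight)
    if anthesis not in dates:
        raise InvalidArgumentError("anthesis flight not among flight dates")
    rows = []
    for d in dates:
        by_index = per_date_values[d]
        for index_name, series in by_index.items():
            for plot_id, value in series.items():
                rows.append((plot_id, d, index_name, value))
    values = pd.DataFrame(rows, columns=["plot_id", "date", "index", "value"])
    return SITrajectory(values=values, anthesis_date=anthesis)


def extract_trajectories(
    stacks: Iterable[BandStack],
    plots: PlotMap,
    panel_reflectances: Mapping[str, float] | None = None,
    indices: Sequence[str] = ("ndvi", "gndvi", "ndre", "osavi"),
    threshold: float = DEFAULT_MASK_THRESHOLD,
) -> SITrajectory:
    """Full raster-to-trajectory pipeline over a season of flights.

    Calibrates each stack, builds the NDVI mask from the earliest flight,
    and extracts plot means of every requested index at every date.
    """
    stacks = sorted(stacks, key=lambda s: s.date)
    if not stacks:
        raise InvalidArgumentError("no band stacks given")
    calibrated = [calibrate_stack(s, panel_reflectances) for s in stacks]
    first = calibrated[0]
    mask = build_mask(compute_index(first, "ndvi"), threshold, source_date=first.date)
    per_date = {}
    for s in calibrated:
        per_date[s.date] = {
            name: extract_plot_values(compute_index(s, name), mask, plots)
            for name in indices
        }
    return assemble_trajectories(per_date, [s.date for s in calibrated], first.date)
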