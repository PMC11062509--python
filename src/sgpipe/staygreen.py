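"""Thermal-time-corrected relative stay-green scoring.

Converts spectral-index trajectories plus daily weather into stage-wise
stay-green scores.  The thermal axis is accumulated temperature (AT): the sum
of daily mean temperatures over the days after anthesis (exclusive of the
anthesis day, inclusive of the target day).  For each accession and stage,
the flight whose AT lies nearest the stage boundary provides the index value
Index_Si; scoring is then

    RSS_Si  = (Index_anthesis - Index_Si) / Index_anthesis * 100
    RSGS_Si = 100 - RSS_Si
    RSGS_Si_corrected = 100 - k_i * RSS_Si

where k_i is the ratio of the mid-flowering (MF) class's attained AT at
stage Si to the attained AT of the accession's own flowering class, so
early- and late-flowering accessions become comparable to MF ones.  RSS may
go negative (an index above its anthesis baseline, e.g. sensor noise); it is
kept, not clamped, so RSS + RSGS = 100 holds exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    InvalidArgumentError,
    InvalidATError,
    MissingDataError,
    StageUnresolvedWarning,
    UndefinedBaselineError,
)
from .types import SITrajectory, StageSchedule, validate_weather


# ---------------------------------------------------------------------------
# accumulated temperature


def accumulated_temperature(weather: pd.DataFrame, anthesis, target) -> float:
    """Sum of daily mean temperatures over (anthesis, target].

    The anthesis day itself does not count; the target day does.
    """
    weather = validate_weather(weather)
    anthesis = pd.Timestamp(anthesis)
    target = pd.Timestamp(target)
    if target < anthesis:
        raise InvalidArgumentError("target date before anthesis")
    lo, hi = weather["date"].iloc[0], weather["date"].iloc[-1]
    for d in (anthesis, target):
        if d < lo or d > hi:
            raise MissingDataError(f"{d.date()} outside the weather span")
    sel = (weather["date"] > anthesis) & (weather["date"] <= target)
    return float(weather.loc[sel, "tmean"].sum())


def at_table(weather: pd.DataFrame, anthesis: pd.Series, dates: Sequence) -> pd.DataFrame:
    """Signed AT for every accession (rows) at every flight date (columns).

    Dates before an accession's anthesis get negative values (useful for
    nearest-boundary lookups); the op-level function raises instead.
    """
    weather = validate_weather(weather)
    cum = pd.Series(
        np.concatenate([[0.0], np.cumsum(weather["tmean"].to_numpy())]),
        index=[weather["date"].iloc[0] - pd.Timedelta(days=1)] + list(weather["date"]),
    )
    anthesis = pd.to_datetime(anthesis)
    dates = [pd.Timestamp(d) for d in dates]
    for d in list(dates) + list(anthesis.unique()):
        if d not in cum.index:
            raise MissingDataError(f"{pd.Timestamp(d).date()} outside the weather span")
    base = cum.loc[anthesis].to_numpy()
    cols = {d: cum.loc[d] - base for d in dates}
    return pd.DataFrame(cols, index=anthesis.index)


@dataclass
class ThermalContext:
    """Per-accession thermal-time context of one season."""

    at: pd.DataFrame  # accession x flight date, signed AT
    anthesis: pd.Series
    flowering_class: pd.Series  # accession -> EF/MF/LF


def build_thermal_context(
    weather: pd.DataFrame,
    anthesis: pd.Series,
    flowering_class: pd.Series,
    flight_dates: Sequence,
) -> ThermalContext:
    at = at_table(weather, anthesis, flight_dates)
    return ThermalContext(
        at=at,
        anthesis=pd.to_datetime(anthesis),
        flowering_class=flowering_class.reindex(at.index),
    )


# ---------------------------------------------------------------------------
# stage assignment


@dataclass
class StageAssignment:
    """Stage -> flight mapping per accession, with the AT actually attained."""

    dates: pd.DataFrame  # accession x stage, chosen flight date (NaT missing)
    at: pd.DataFrame  # accession x stage, attained AT (NaN missing)


def assign_stages(
    traj: SITrajectory, thermal: ThermalContext, schedule: StageSchedule
) -> StageAssignment:
    """Pick, per accession and stage, the flight with AT nearest the boundary.

    Ties go to the earlier date.  If no flight lies within
    ``schedule.tolerance`` °C·day of a boundary, the stage is left missing
    and a :class:`StageUnresolvedWarning` is emitted.
    """
    flight_dates = [pd.Timestamp(d) for d in traj.dates]
    at = thermal.at[flight_dates]
    dates_out = pd.DataFrame(index=at.index, columns=schedule.stages, dtype="datetime64[ns]")
    at_out = pd.DataFrame(index=at.index, columns=schedule.stages, dtype=float)
    n_unresolved = 0
    vals = at.to_numpy(dtype=float)
    for stage, boundary in schedule.boundaries.items():
        diff = np.abs(vals - boundary)
        j = np.argmin(diff, axis=1)  # first minimum = earlier date on ties
        best = diff[np.arange(len(j)), j]
        ok = best <= schedule.tolerance
        n_unresolved += int((~ok).sum())
        chosen = pd.Series(pd.NaT, index=at.index)
        chosen.loc[ok] = pd.Series([flight_dates[k] for k in j], index=at.index).loc[ok]
        dates_out[stage] = chosen
        at_out[stage] = np.where(ok, vals[np.arange(len(j)), j], np.nan)
    if n_unresolved:
        warnings.warn(
            f"{n_unresolved} accession/stage combinations had no flight within "
            f"{schedule.tolerance} °C·day of the boundary",
            StageUnresolvedWarning,
        )
    return StageAssignment(dates=dates_out, at=at_out)


# ---------------------------------------------------------------------------
# scoring algebra


def rss(index_anthesis, index_si):
    """Relative senescence score on the 0–100 scale.

    (Index_anthesis - Index_Si) / Index_anthesis * 100.  The anthesis value
    must be positive; values greener than anthesis give a negative RSS.
    """
    a = np.asarray(index_anthesis, dtype=float)
    if np.any(a <= 0):
        raise UndefinedBaselineError("anthesis index value must be positive")
    out = (a - np.asarray(index_si, dtype=float)) / a * 100.0
    return float(out) if out.ndim == 0 else out


def rsgs(rss_value):
    """Relative stay-green score: 100 - RSS (100 at the anthesis reference)."""
    out = 100.0 - np.asarray(rss_value, dtype=float)
    return float(out) if out.ndim == 0 else out


def correction_factor(at_mf_si, at_group_si):
    """Flowering correction k_i = AT(MF at Si) / AT(class at Si)."""
    a = np.asarray(at_mf_si, dtype=float)
    b = np.asarray(at_group_si, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise InvalidATError("accumulated temperatures must be positive")
    out = a / b
    return float(out) if out.ndim == 0 else out


def corrected_rsgs(rss_value, k_i):
    """Flowering-corrected stay-green score: 100 - k_i * RSS."""
    k = np.asarray(k_i, dtype=float)
    if np.any(k <= 0):
        raise InvalidATError("correction factor must be positive")
    out = 100.0 - k * np.asarray(rss_value, dtype=float)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# table assembly


def class_stage_at(assignment: StageAssignment, flowering_class: pd.Series) -> pd.DataFrame:
    """Mean attained AT per flowering class (rows) per stage (columns)."""
    at = assignment.at.copy()
    at["__class"] = flowering_class.reindex(at.index)
    return at.groupby("__class").mean()


def build_rsgs_table(
    traj: SITrajectory, thermal: ThermalContext, schedule: StageSchedule
) -> pd.DataFrame:
    """One SG_indexSi row per accession x index x stage.

    Columns: ``accession, index, stage, flowering_class, k, rss, rsgs,
    rsgs_corrected, sg`` where ``sg`` is the trait used downstream — the
    plain RSGS for MF accessions and the corrected RSGS for EF/LF.  Missing
    stages propagate as NaN rows.
    """
    assignment = assign_stages(traj, thermal, schedule)
    anth = traj.anthesis_values()
    if (anth.min().min() if anth.size else 1.0) <= 0:
        raise UndefinedBaselineError("non-positive index value at the anthesis flight")
    cls = thermal.flowering_class
    cls_at = class_stage_at(assignment, cls)
    if "MF" not in cls_at.index:
        raise InvalidATError("no MF accessions; correction factors undefined")
    rows = []
    for index_name in traj.indices:
        wide = traj.pivot(index_name)  # plot x date
        for acc in assignment.dates.index:
            a_val = anth.loc[acc, index_name]
            fc = cls.loc[acc]
            for stage in schedule.stages:
                d = assignment.dates.loc[acc, stage]
                if fc == "MF":
                    k = 1.0
                else:
                    at_cls = cls_at.loc[fc, stage]
                    at_mf = cls_at.loc["MF", stage]
                    k = (
                        correction_factor(at_mf, at_cls)
                        if np.isfinite(at_cls) and at_cls > 0 and np.isfinite(at_mf) and at_mf > 0
                        else np.nan
                    )
                if pd.isna(d) or pd.isna(a_val):
                    rows.append((acc, index_name, stage, fc, k, np.nan, np.nan, np.nan, np.nan))
                    continue
                v = wide.loc[acc, d]
                if pd.isna(v):
                    rows.append((acc, index_name, stage, fc, k, np.nan, np.nan, np.nan, np.nan))
                    continue
                r = rss(a_val, v)
                g = rsgs(r)
                gc = corrected_rsgs(r, k) if np.isfinite(k) else np.nan
                sg = g if fc == "MF" else gc
                rows.append((acc, index_name, stage, fc, k, r, g, gc, sg))
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "index", "stage", "flowering_class", "k",
            "rss", "rsgs", "rsgs_corrected", "sg",
        ],
    )
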