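"""Climate-envelope extraction and the humid-hours microclimate statistic.

The envelope of a species is the distribution of gridded climate values
(July mean and maximum temperature) at its occurrence records; its upper
edge approximates the thermal range limit, which can then be compared
with a physiological viability threshold.  The microclimate statistic
counts daily hours of near-saturating humidity (RH above 95%), and the
warm subset of those hours (air temperature above 20 °C) where the
carbon cost of liquid hydration would bite hardest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gasex_io import ClimateGrid

logger = logging.getLogger(__name__)

ENVELOPE_QUANTILES = (0.5, 0.95, 0.99)


class ExtractionError(ValueError):
    """Envelope extraction cannot proceed (grid mismatch, nothing retained)."""


@dataclass
class ClimateEnvelope:
    """Per-occurrence July temperatures plus distribution summaries."""

    values: pd.DataFrame  # record_id, july_tmean_C, july_tmax_C
    summaries: dict[str, dict[str, float]]
    n_used: int
    n_dropped_nodata: int
    n_dropped_outside: int


def _summaries(values: pd.DataFrame) -> dict[str, dict[str, float]]:
    out = {}
    for col, name in (("july_tmean_C", "tmean"), ("july_tmax_C", "tmax")):
        v = values[col].to_numpy(float)
        entry = {"max": float(v.max()), "mean": float(v.mean())}
        for q in ENVELOPE_QUANTILES:
            entry[f"q{q:g}"] = float(np.quantile(v, q))
        out[name] = entry
    return out


def extract_envelope(
    occurrences: pd.DataFrame, grid_tmean: ClimateGrid, grid_tmax: ClimateGrid
) -> ClimateEnvelope:
    """Nearest-cell-center lookup of both grids at every occurrence.

    Occurrences outside the grid extent or on nodata cells are dropped
    and counted separately; summaries (max, mean, quantiles) are
    computed on the retained values.
    """
    same = (
        grid_tmean.values.shape == grid_tmax.values.shape
        and grid_tmean.xllcorner == grid_tmax.xllcorner
        and grid_tmean.yllcorner == grid_tmax.yllcorner
        and grid_tmean.cellsize == grid_tmax.cellsize
    )
    if not same:
        raise ExtractionError("tmean and tmax grids differ in extent or resolution")

    rows = []
    n_nodata = n_outside = 0
    for _, occ in occurrences.iterrows():
        loc = grid_tmean.locate(float(occ["longitude"]), float(occ["latitude"]))
        if loc is None:
            n_outside += 1
            continue
        r, c = loc
        tmean = grid_tmean.values[r, c]
        tmax = grid_tmax.values[r, c]
        if np.isnan(tmean) or np.isnan(tmax):
            n_nodata += 1
            continue
        rows.append({"record_id": occ["record_id"], "july_tmean_C": float(tmean), "july_tmax_C": float(tmax)})
    if not rows:
        raise ExtractionError("no occurrence retained (all outside extent or on nodata)")
    values = pd.DataFrame(rows)
    return ClimateEnvelope(
        values=values,
        summaries=_summaries(values),
        n_used=len(values),
        n_dropped_nodata=n_nodata,
        n_dropped_outside=n_outside,
    )


def compare_threshold(envelope: ClimateEnvelope, t_star: float) -> dict[str, float]:
    """Align a physiological viability threshold with the range limit.

    Reports the gap between T* and the envelope's maximum and 99th
    percentile July mean temperature, and the fraction of occurrences
    already beyond T*.
    """
    if not np.isfinite(t_star):
        raise ValueError(f"t_star must be finite, got {t_star}")
    tmean = envelope.values["july_tmean_C"].to_numpy(float)
    return {
        "t_star": float(t_star),
        "gap_to_max": float(t_star - tmean.max()),
        "gap_to_q99": float(t_star - np.quantile(tmean, 0.99)),
        "fraction_above": float((tmean > t_star).mean()),
    }


def humid_hours(
    series: pd.DataFrame,
    rh_threshold: float = 95.0,
    temp_threshold: float = 20.0,
    cadence_min: float | None = None,
) -> pd.DataFrame:
    """Daily hours above the humidity threshold, and the warm subset.

    Both thresholds are strict (RH > rh_threshold, T > temp_threshold);
    records exactly on a threshold do not count.  Hours are the count of
    qualifying records times the cadence.  The cadence defaults to the
    median timestamp spacing; gaps are tolerated (only existing records
    count) and the gap fraction is logged.
    """
    ts = pd.to_datetime(series["timestamp"])
    if ts.duplicated().any():
        dup = ts[ts.duplicated()].iloc[0]
        raise ValueError(f"duplicate timestamp in microclimate series: {dup}")
    if cadence_min is None:
        diffs = ts.sort_values().diff().dropna()
        # default cadence when spacing cannot be inferred from one record
        cadence_min = float(diffs.median().total_seconds() / 60.0) if len(diffs) else 30.0
        expected = (ts.max() - ts.min()).total_seconds() / 60.0 / cadence_min + 1
        gap_fraction = 1.0 - len(ts) / expected
        if gap_fraction > 1e-9:
            logger.info("microclimate series has %.1f%% missing records", 100 * gap_fraction)
    cadence_h = cadence_min / 60.0

    humid = series["rh_pct"].to_numpy(float) > rh_threshold
    warm = humid & (series["temp_C"].to_numpy(float) > temp_threshold)
    frame = pd.DataFrame({"date": ts.dt.date, "humid": humid, "warm_humid": warm})
    table = (
        frame.groupby("date", sort=True)[["humid", "warm_humid"]]
        .sum()
        .reset_index()
        .rename(columns={"humid": "hours_humid", "warm_humid": "hours_humid_warm"})
    )
    table["hours_humid"] = table["hours_humid"] * cadence_h
    table["hours_humid_warm"] = table["hours_humid_warm"] * cadence_h
    return table
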