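"""Headline carbon-balance statistics of the dual-hydration contrast.

Given per-curve physiology summaries for paired vapor/liquid
measurements, this module computes:

* through-origin regressions of liquid-hydrated on vapor-hydrated rates
  (gross assimilation and dark respiration), whose slopes quantify how
  much each flux is amplified by liquid water relative to vapor;
* the respiration : gross-assimilation ratio as a function of
  temperature and the viability threshold T* where it reaches 1 (net
  carbon balance can no longer be positive at any light level);
* the carbon-balance asymmetry index ``A_prop - R_prop`` per specimen,
  with genus-level averaging for comparative work, where ``A_prop`` is
  the vapor:liquid ratio of gross assimilation and ``R_prop`` the
  vapor:liquid ratio of respiration.  Positive index: humid air
  activates photosynthesis relatively more than respiration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .light_response import PhysiologySummary

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ("unit_id", "species", "genus", "ga_vapor", "ga_liquid", "r_vapor", "r_liquid")


class RegressionError(ValueError):
    """The paired regression is singular or under-determined."""


@dataclass
class RegressionResult:
    slope: float
    r2: float
    f_stat: float
    df: tuple[int, int]
    p_value: float
    n: int
    intercept: float | None = None  # only for the diagnostic free-intercept fit


@dataclass
class AsymmetryRecord:
    unit_id: str
    species: str
    genus: str
    a_prop: float
    r_prop: float
    index: float


def build_pairs(summaries: list[PhysiologySummary]) -> pd.DataFrame:
    """Pair vapor and liquid summaries per thallus × temperature.

    Units with a missing hydration side are excluded and logged.
    """
    by_unit: dict[tuple, dict] = {}
    for s in summaries:
        key = (s.thallus_id, s.temperature_C)
        by_unit.setdefault(key, {"species": s.species, "genus": s.genus})[s.hydration] = s
    rows = []
    for (thallus, temp), sides in by_unit.items():
        if "vapor" not in sides or "liquid" not in sides:
            logger.warning("pair (%s, %s): missing %s side, excluded", thallus, temp,
                           "liquid" if "vapor" in sides else "vapor")
            continue
        v, l = sides["vapor"], sides["liquid"]
        rows.append(
            {
                "unit_id": f"{thallus}@{temp:g}C",
                "species": sides["species"],
                "genus": sides["genus"],
                "ga_vapor": v.ga_max,
                "ga_liquid": l.ga_max,
                "r_vapor": v.r_dark,
                "r_liquid": l.r_dark,
            }
        )
    return pd.DataFrame(rows, columns=list(PAIR_COLUMNS))


def paired_regression(
    pairs: pd.DataFrame, quantity: str = "R", through_origin: bool = True
) -> RegressionResult:
    """Regress liquid-hydrated rates on vapor-hydrated rates.

    The default model is ``liquid = beta * vapor`` (no intercept), so the
    slope reads directly as the liquid:vapor activation ratio against the
    1:1 line; r² is computed about the origin and the F test has
    (1, n-1) degrees of freedom.  ``through_origin=False`` gives the
    free-intercept diagnostic fit.
    """
    if quantity not in ("GA", "R"):
        raise ValueError(f"quantity must be 'GA' or 'R', got {quantity!r}")
    x = pairs["ga_vapor" if quantity == "GA" else "r_vapor"].to_numpy(float)
    y = pairs["ga_liquid" if quantity == "GA" else "r_liquid"].to_numpy(float)
    if len(x) < 3:
        raise RegressionError(f"need >= 3 pairs, got {len(x)}")
    if np.all(x == 0):
        raise RegressionError("all vapor-hydrated rates are zero: singular fit")
    if through_origin:
        model = sm.OLS(y, x[:, None]).fit()
        return RegressionResult(
            slope=float(model.params[0]),
            r2=float(model.rsquared),  # uncentered: about the origin
            f_stat=float(model.fvalue),
            df=(1, int(model.df_resid)),
            p_value=float(model.f_pvalue),
            n=len(x),
        )
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(model.params[1]),
        r2=float(model.rsquared),
        f_stat=float(model.fvalue),
        df=(1, int(model.df_resid)),
        p_value=float(model.f_pvalue),
        n=len(x),
        intercept=float(model.params[0]),
    )


def respiration_ratio(summaries: list[PhysiologySummary]) -> pd.DataFrame:
    """R_dark / GA_max per temperature and hydration source.

    Per-curve ratios are averaged over thalli within each temperature ×
    hydration cell.  A ratio at or above 1 means respiration outruns the
    maximum gross assimilation — no light level yields a positive net
    carbon balance — and the cell is flagged unsustainable.  Curves with
    GA_max <= 0 contribute an infinite ratio.
    """
    rows = []
    for s in summaries:
        if s.ga_max > 0:
            ratio = s.r_dark / s.ga_max
        else:
            ratio = math.inf
        rows.append(
            {
                "thallus_id": s.thallus_id,
                "hydration": s.hydration,
                "temperature_C": s.temperature_C,
                "ratio": ratio,
            }
        )
    per_curve = pd.DataFrame(rows)
    table = (
        per_curve.groupby(["hydration", "temperature_C"], sort=True)["ratio"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "ratio", "count": "n_thalli"})
    )
    table["unsustainable"] = table["ratio"] >= 1.0
    return table


def viability_threshold(temperatures, ratios) -> float | None:
    """Lowest temperature where R:GA reaches 1, by linear interpolation.

    Returns None ("none in range") when the ratio stays below 1 across
    the whole grid.  Requires ratios on at least 3 temperatures.
    """
    temps = np.asarray(temperatures, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if len(temps) < 3:
        raise ValueError(f"need ratios on >= 3 temperatures, got {len(temps)}")
    order = np.argsort(temps)
    temps, r = temps[order], r[order]
    if r[0] >= 1.0:
        return float(temps[0])
    for i in range(1, len(temps)):
        if r[i] >= 1.0:
            t0, t1, r0, r1 = temps[i - 1], temps[i], r[i - 1], r[i]
            return float(t0 + (1.0 - r0) * (t1 - t0) / (r1 - r0))
    return None


def asymmetry_index(pair: pd.Series | dict) -> AsymmetryRecord | None:
    """Carbon-balance asymmetry of one paired specimen.

    With all rates efflux-/uptake-positive, ``A_prop = GA_v / GA_l`` and
    ``R_prop = R_v / R_l`` (equivalent to the net-minus-respiration form
    written in the instrument's sign convention).  Pairs with a zero
    liquid denominator are excluded with a logged reason.
    """
    ga_l, r_l = float(pair["ga_liquid"]), float(pair["r_liquid"])
    if ga_l <= 0 or r_l <= 0:
        logger.warning(
            "pair %s: zero/negative liquid denominator (GA_l=%g, R_l=%g), excluded",
            pair.get("unit_id", "?"), ga_l, r_l,
        )
        return None
    a_prop = float(pair["ga_vapor"]) / ga_l
    r_prop = float(pair["r_vapor"]) / r_l
    return AsymmetryRecord(
        unit_id=str(pair.get("unit_id", "")),
        species=str(pair.get("species", "")),
        genus=str(pair.get("genus", "")),
        a_prop=a_prop,
        r_prop=r_prop,
        index=a_prop - r_prop,
    )


def asymmetry_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """Specimen-level asymmetry table; excluded pairs are dropped."""
    records = [asymmetry_index(row) for _, row in pairs.iterrows()]
    records = [r for r in records if r is not None]
    return pd.DataFrame(
        [
            {
                "unit_id": r.unit_id,
                "species": r.species,
                "genus": r.genus,
                "a_prop": r.a_prop,
                "r_prop": r.r_prop,
                "index": r.index,
            }
            for r in records
        ]
    )


def aggregate_by_genus(specimens: pd.DataFrame) -> pd.DataFrame:
    """Genus-level asymmetry: unweighted mean over specimens.

    Adds specimen counts and the positive/negative sign split of the
    specimen indices within each genus.
    """
    if "genus" not in specimens.columns:
        raise ValueError("specimen table must carry a 'genus' column")
    grouped = specimens.groupby("genus", sort=True)["index"]
    table = grouped.agg(
        index="mean",
        n_specimens="count",
        n_positive=lambda v: int((v > 0).sum()),
        n_negative=lambda v: int((v < 0).sum()),
    ).reset_index()
    return table
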