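"""Reduce raw gas-exchange logs to per-curve physiological summaries.

A *curve* is one thallus × hydration source × chamber temperature: the
replicate instrument readings at each PAR step are averaged, repeated
visits to the same light level (the protocol revisits its first
saturating step as a hysteresis check) are pooled, and the reduced curve
is summarized into dark respiration, maximum gross assimilation, a
nonrectangular-hyperbola (NRH) fit and the light compensation point.

The NRH net-assimilation model, with gross plateau ``a_max``, apparent
quantum yield ``phi``, curvature ``theta`` and dark respiration ``r_d``::

    A_net(I) = [phi*I + a_max - sqrt((phi*I + a_max)^2
               - 4*theta*phi*I*a_max)] / (2*theta) - r_d

``theta -> 0`` degenerates to the rectangular hyperbola
``phi*I*a_max / (phi*I + a_max) - r_d``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

#: Programmed -> chamber-realized PAR (µmol photons m⁻² s⁻¹) after wall
#: attenuation, for the protocol's standard levels.
PAR_ATTENUATION_TABLE = {
    0.0: 0.0,
    50.0: 27.0,
    100.0: 55.0,
    250.0: 136.0,
    500.0: 273.0,
    1000.0: 544.0,
    2000.0: 1086.0,
    2500.0: 1357.0,
}

#: Realized level logged by the protocol with no unambiguous programmed
#: counterpart; kept out of the lookup table.
ORPHAN_REALIZED_PAR = 815.0

#: Generic wall-attenuation factor for levels not in the table.
ATTENUATION_FACTOR = 0.543

MIN_DISTINCT_LEVELS_FOR_FIT = 4


class CurveError(ValueError):
    """A record group cannot be reduced to a valid light-response curve."""


def apply_attenuation(par_programmed: float) -> float:
    """Realized in-chamber PAR for a programmed head-light level."""
    if par_programmed < 0:
        raise ValueError(f"programmed PAR must be >= 0, got {par_programmed}")
    try:
        return PAR_ATTENUATION_TABLE[float(par_programmed)]
    except KeyError:
        return float(par_programmed) * ATTENUATION_FACTOR


@dataclass
class LightStep:
    par_realized: float
    mean_a_net: float
    sd_a_net: float
    n_reps: int


@dataclass
class LightResponseCurve:
    thallus_id: str
    hydration: str
    temperature_C: float
    steps: list[LightStep]
    species: str = ""
    genus: str = ""

    @property
    def par(self) -> np.ndarray:
        return np.array([s.par_realized for s in self.steps])

    @property
    def a_net(self) -> np.ndarray:
        return np.array([s.mean_a_net for s in self.steps])


@dataclass
class NRHFit:
    phi: float
    a_max: float
    theta: float
    r_d: float
    rss: float
    converged: bool
    degenerate: bool = False


@dataclass
class PhysiologySummary:
    """Headline physiology of one reduced curve.

    ``r_dark`` and ``ga_max`` are efflux-/uptake-positive respectively
    (µmol CO2 g⁻¹ s⁻¹); ``lcp`` is None when the thallus never reaches
    positive net carbon balance over the measured PAR range.
    """

    thallus_id: str
    hydration: str
    temperature_C: float
    r_dark: float
    ga_max: float
    lcp: float | None
    never_compensates: bool
    fit: NRHFit | None
    species: str = ""
    genus: str = ""


def reduce_records(records: pd.DataFrame) -> list[LightResponseCurve]:
    """Collapse replicate readings into one curve per thallus × hydration × T.

    Replicates at the same realized PAR — including separate protocol
    visits to the same level — are pooled into a single step with pooled
    n.  Steps come out sorted by ascending PAR.  A hysteresis diagnostic
    (spread of visit means at revisited levels) is logged, not acted on.
    """
    curves: list[LightResponseCurve] = []
    for (thallus, hydration, temp), group in records.groupby(
        ["thallus_id", "hydration", "temperature_C"], sort=True
    ):
        if not (group["par_realized"] == 0).any():
            raise CurveError(
                f"group thallus={thallus} hydration={hydration} T={temp}: no PAR = 0 step"
            )
        # hysteresis diagnostic: compare means of distinct programmed visits
        # that share a realized level
        for par, sub in group.groupby("par_realized"):
            visits = sub.groupby("par_programmed")["a_net"].mean()
            if len(visits) > 1 and visits.max() - visits.min() > 0:
                logger.debug(
                    "hysteresis at %s/%s/%s PAR=%s: visit means span %.4g",
                    thallus, hydration, temp, par, visits.max() - visits.min(),
                )
        steps = []
        for par, sub in group.groupby("par_realized", sort=True):
            vals = sub["a_net"].to_numpy()
            steps.append(
                LightStep(
                    par_realized=float(par),
                    mean_a_net=float(vals.mean()),
                    sd_a_net=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                    n_reps=len(vals),
                )
            )
        curves.append(
            LightResponseCurve(
                thallus_id=str(thallus),
                hydration=str(hydration),
                temperature_C=float(temp),
                steps=steps,
                species=str(group["species"].iloc[0]),
                genus=str(group["genus"].iloc[0]),
            )
        )
    return curves


def dark_respiration(curve: LightResponseCurve) -> float:
    """Dark respiration, efflux-positive: the negated net flux at PAR = 0."""
    for step in curve.steps:
        if step.par_realized == 0:
            return -step.mean_a_net
    raise CurveError(f"curve {curve.thallus_id}: no PAR = 0 step")


def gross_assimilation(curve: LightResponseCurve, r_dark: float) -> tuple[np.ndarray, float]:
    """Per-step gross assimilation GA = A_net + R_dark, and its maximum.

    By construction GA = 0 at the dark step, so GA_max reflects the
    light-driven CO2 fixation capacity of the curve.
    """
    ga = curve.a_net + r_dark
    return ga, float(ga.max())


def nrh_net(par, phi, a_max, theta, r_d):
    """Nonrectangular-hyperbola net assimilation (theta -> 0 safe)."""
    par = np.asarray(par, dtype=float)
    if theta < 1e-9:
        with np.errstate(divide="ignore", invalid="ignore"):
            gross = np.where(phi * par + a_max > 0, phi * par * a_max / (phi * par + a_max), 0.0)
        return gross - r_d
    s = phi * par + a_max
    disc = np.maximum(s * s - 4.0 * theta * phi * par * a_max, 0.0)
    return (s - np.sqrt(disc)) / (2.0 * theta) - r_d


def fit_nrh(curve: LightResponseCurve) -> NRHFit:
    """Least-squares NRH fit with three deterministic multistarts.

    Curves with fewer than four distinct PAR levels, or with no dynamic
    range at all, are flagged degenerate and not fitted.
    """
    par = curve.par
    y = curve.a_net
    if len(np.unique(par)) < MIN_DISTINCT_LEVELS_FOR_FIT:
        return NRHFit(math.nan, math.nan, math.nan, math.nan, math.nan, False, degenerate=True)
    if np.ptp(y) == 0:
        return NRHFit(math.nan, math.nan, math.nan, math.nan, math.nan, False, degenerate=True)

    r_d0 = max(-y[par == 0].mean(), 0.0) if (par == 0).any() else 0.0
    a_max0 = max(y.max() + r_d0, 1e-8)
    lit = par > 0
    phi0 = max((y[lit].min() + r_d0) / par[lit].min(), a_max0 / par.max()) if lit.any() else 1e-3
    phi0 = max(phi0, 1e-12)

    def residuals(params):
        phi, a_max, theta, r_d = params
        return nrh_net(par, phi, a_max, theta, r_d) - y

    best = None
    lower = [1e-12, 1e-12, 0.0, 0.0]
    upper = [np.inf, np.inf, 0.999, np.inf]
    for theta0 in (0.1, 0.5, 0.9):
        x0 = np.clip([phi0, a_max0, theta0, r_d0], lower, upper)
        try:
            res = optimize.least_squares(
                residuals, x0, bounds=(lower, upper),
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
            )
        except Exception:
            continue
        rss = float(np.sum(res.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        return NRHFit(math.nan, math.nan, math.nan, math.nan, math.nan, False)
    rss, res = best
    phi, a_max, theta, r_d = (float(v) for v in res.x)
    return NRHFit(phi, a_max, theta, r_d, rss, bool(res.success))


def light_compensation_point(
    fit: NRHFit | None,
    curve: LightResponseCurve,
    rel_tol: float = 1e-6,
) -> tuple[float | None, bool]:
    """Smallest irradiance with zero net carbon exchange.

    Uses the fitted curve (bracketing + Brent root-finding to *rel_tol*
    relative) when a converged fit is available; otherwise falls back to
    linear interpolation between the bracketing measured steps.  Returns
    ``(lcp, never_compensates)``.
    """
    max_par = float(curve.par.max())
    if fit is not None and fit.converged and not fit.degenerate:
        if fit.r_d <= 0:
            return 0.0, False
        f = lambda i: float(nrh_net(i, fit.phi, fit.a_max, fit.theta, fit.r_d))
        # NRH net assimilation is nondecreasing in I: a single sign check
        # at max PAR decides compensation
        if f(max_par) < 0:
            return None, True
        if f(0.0) >= 0:
            return 0.0, False
        root = optimize.brentq(f, 0.0, max_par, rtol=rel_tol, xtol=1e-12)
        return float(root), False
    # interpolation fallback on measured step means
    par, y = curve.par, curve.a_net
    order = np.argsort(par)
    par, y = par[order], y[order]
    if y[0] >= 0:
        return 0.0, False
    pos = np.nonzero(y >= 0)[0]
    if len(pos) == 0:
        return None, True
    j = pos[0]
    i = j - 1
    lcp = par[i] + (0 - y[i]) * (par[j] - par[i]) / (y[j] - y[i])
    return float(lcp), False


def rectangular_lcp(phi: float, a_max: float, r_d: float) -> float | None:
    """Closed-form LCP of the rectangular hyperbola (theta = 0).

    Solving ``phi*I*a_max/(phi*I + a_max) = r_d`` gives
    ``I = r_d*a_max / (phi*(a_max - r_d))``; None when the gross plateau
    never covers respiration.
    """
    if r_d <= 0:
        return 0.0
    if r_d >= a_max:
        return None
    return r_d * a_max / (phi * (a_max - r_d))


def summarize(curve: LightResponseCurve, fit_curve: bool = True) -> PhysiologySummary:
    """Full reduction of one curve: R_dark, GA_max, NRH fit, LCP.

    ``fit_curve=False`` skips the NRH fit (the LCP then comes from step
    interpolation) — useful when only R_dark/GA_max are needed.
    """
    r_dark = dark_respiration(curve)
    _, ga_max = gross_assimilation(curve, r_dark)
    fit = fit_nrh(curve) if fit_curve else None
    lcp, never = light_compensation_point(fit, curve)
    return PhysiologySummary(
        thallus_id=curve.thallus_id,
        hydration=curve.hydration,
        temperature_C=curve.temperature_C,
        r_dark=r_dark,
        ga_max=ga_max,
        lcp=lcp,
        never_compensates=never,
        fit=fit,
        species=curve.species,
        genus=curve.genus,
    )


def summaries_frame(summaries: list[PhysiologySummary]) -> pd.DataFrame:
    """Tabulate summaries, one row per curve (for the summary CSV)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "thallus_id": s.thallus_id,
                "species": s.species,
                "genus": s.genus,
                "hydration": s.hydration,
                "temperature_C": s.temperature_C,
                "r_dark": s.r_dark,
                "ga_max": s.ga_max,
                "lcp": s.lcp if s.lcp is not None else np.nan,
                "never_compensates": s.never_compensates,
                "fit_phi": s.fit.phi if s.fit else np.nan,
                "fit_a_max": s.fit.a_max if s.fit else np.nan,
                "fit_theta": s.fit.theta if s.fit else np.nan,
                "fit_r_d": s.fit.r_d if s.fit else np.nan,
                "fit_rss": s.fit.rss if s.fit else np.nan,
                "fit_converged": s.fit.converged if s.fit else False,
            }
        )
    return pd.DataFrame(rows)
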