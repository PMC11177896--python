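"""Hydration-activation kinetics from chlorophyll-fluorescence time series.

A dry thallus placed in saturating humidity regains photosystem II
efficiency (Fv/Fm) over minutes to hours.  The rise is modelled as a
single saturating exponential

    F(t) = F0 + (F_inf - F0) * (1 - exp(-t / tau))

whose time constant ``tau`` summarizes activation speed; the derived
``time_to_fraction`` converts it to the time needed to complete a given
fraction of the rise (e.g. 95% of maximum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize


@dataclass
class ActivationFit:
    f0: float
    f_inf: float
    tau_min: float
    rss: float
    converged: bool
    degenerate: bool = False


def activation_model(t, f0, f_inf, tau):
    t = np.asarray(t, dtype=float)
    return f0 + (f_inf - f0) * (1.0 - np.exp(-t / tau))


def fit_activation(minutes, fvfm) -> ActivationFit:
    """Least-squares saturating-exponential fit.

    Deterministic initialization: F0 from the first point, F_inf from
    the last, tau from the time of half-rise divided by ln 2.  Flat
    series are flagged degenerate (tau undefined); series with no net
    rise (monotone decreasing) are flagged non-converged.
    """
    t = np.asarray(minutes, dtype=float)
    y = np.asarray(fvfm, dtype=float)
    if len(t) < 5:
        raise ValueError(f"need >= 5 points, got {len(t)}")
    if np.ptp(y) == 0:
        return ActivationFit(float(y[0]), float(y[0]), math.nan, 0.0, False, degenerate=True)
    if y[-1] <= y[0]:
        return ActivationFit(float(y[0]), float(y[-1]), math.nan, math.nan, False)

    f0_0, finf_0 = float(y[0]), float(y[-1])
    half = f0_0 + 0.5 * (finf_0 - f0_0)
    above = np.nonzero(y >= half)[0]
    t_half = float(t[above[0]]) if len(above) else float(t[len(t) // 2])
    tau0 = max(t_half / math.log(2.0), 1e-6)

    def residuals(params):
        f0, f_inf, tau = params
        return activation_model(t, f0, f_inf, tau) - y

    res = optimize.least_squares(
        residuals,
        [f0_0, finf_0, tau0],
        bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=5000,
    )
    f0, f_inf, tau = (float(v) for v in res.x)
    rss = float(np.sum(res.fun ** 2))
    converged = bool(res.success) and f_inf > f0 and tau > 0
    return ActivationFit(f0, f_inf, tau, rss, converged)


def time_to_fraction(fit: ActivationFit, fraction: float = 0.95) -> float:
    """Minutes to complete *fraction* of the rise: ``-tau * ln(1 - f)``."""
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    if not fit.converged or not math.isfinite(fit.tau_min):
        raise ValueError("time_to_fraction requires a converged fit")
    return -fit.tau_min * math.log(1.0 - fraction)
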