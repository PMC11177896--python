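"""Synthetic inputs with known generative truth, for parameter recovery.

Every input the pipeline consumes can be generated here from explicit
models whose parameters are recorded in a ground-truth sidecar, so each
downstream estimator can be checked against the value it should recover.

Generative physiology
---------------------
Dark respiration follows a Q10 law, scaled by a hydration-source factor
``rho_v`` (vapor) vs 1 (liquid)::

    R(T, h) = R_ref * Q10^((T - T_ref)/10) * (rho_v if vapor else 1)

Gross assimilation is a nonrectangular hyperbola in irradiance whose
plateau carries a Gaussian thermal optimum and a hydration factor
``alpha_v``::

    GA_max(T) = GA_opt * exp(-((T - T_opt)/sigma_T)^2)
    GA(T, I, h) = NRH(I; phi, (alpha_v if vapor else 1) * GA_max(T), theta)

Net exchange per logged replicate is ``GA - R + Normal(0, noise_sd)``.
The defaults put the liquid:vapor respiration ratio at 2.13 and the
assimilation ratio at 1.00 — the hydration asymmetry the pipeline is
built to measure.  Vapor and liquid share each thallus's random size
effect (paired design; vapor is always measured first).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import gasex_io
from .light_response import apply_attenuation

DEFAULT_TEMPERATURES_C = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
DEFAULT_PAR_PROGRAMMED = (0.0, 1000.0, 2000.0, 2500.0, 1000.0, 500.0, 250.0, 100.0, 50.0)

#: Liquid respiration is about double vapor respiration; the vapor
#: fraction 1/2.13 makes that published-scale ratio the simulation truth.
DEFAULT_RHO_V = 1.0 / 2.13


class ParameterError(ValueError):
    """A generator parameter is non-finite or out of its valid range."""


def _require_finite(**kwargs) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ParameterError(f"{name} must be finite, got {value}")


@dataclass
class RespirationParams:
    """Q10 dark-respiration model with a vapor-hydration fraction.

    r_ref: efflux at T_ref, µmol CO2 g⁻¹ s⁻¹ (liquid hydration).
    vapor_fraction: multiplicative factor on vapor-hydrated respiration.
    """

    r_ref: float = 0.020
    t_ref: float = 25.0
    q10: float = 2.5
    vapor_fraction: float = DEFAULT_RHO_V

    def __post_init__(self):
        _require_finite(r_ref=self.r_ref, t_ref=self.t_ref, q10=self.q10,
                        vapor_fraction=self.vapor_fraction)
        if self.r_ref <= 0:
            raise ParameterError(f"r_ref must be > 0, got {self.r_ref}")
        if self.q10 <= 0:
            raise ParameterError(f"q10 must be > 0, got {self.q10}")
        if not 0 < self.vapor_fraction <= 1:
            raise ParameterError(f"vapor_fraction must be in (0, 1], got {self.vapor_fraction}")

    def rate(self, temp_C, hydration: str = "liquid"):
        r = self.r_ref * self.q10 ** ((np.asarray(temp_C, dtype=float) - self.t_ref) / 10.0)
        if hydration == "vapor":
            r = r * self.vapor_fraction
        return r


@dataclass
class PhotosynthesisParams:
    """Gaussian-thermal-optimum NRH light response.

    phi: apparent quantum yield, µmol CO2 (µmol photons)⁻¹ scaled per g.
    ga_opt: gross-assimilation plateau at T_opt, µmol CO2 g⁻¹ s⁻¹ (liquid).
    vapor_fraction: multiplicative factor on the vapor-hydrated plateau.
    """

    phi: float = 5.0e-4
    ga_opt: float = 0.060
    t_opt: float = 15.0
    sigma_t: float = 15.0
    theta: float = 0.70
    vapor_fraction: float = 1.0

    def __post_init__(self):
        _require_finite(phi=self.phi, ga_opt=self.ga_opt, t_opt=self.t_opt,
                        sigma_t=self.sigma_t, theta=self.theta,
                        vapor_fraction=self.vapor_fraction)
        if self.ga_opt <= 0:
            raise ParameterError(f"ga_opt must be > 0, got {self.ga_opt}")
        if self.sigma_t <= 0:
            raise ParameterError(f"sigma_t must be > 0, got {self.sigma_t}")
        if not 0 <= self.theta < 1:
            raise ParameterError(f"theta must be in [0, 1), got {self.theta}")
        if self.vapor_fraction <= 0:
            raise ParameterError(f"vapor_fraction must be > 0, got {self.vapor_fraction}")

    def ga_max(self, temp_C, hydration: str = "liquid"):
        amp = self.ga_opt * np.exp(-(((np.asarray(temp_C, dtype=float) - self.t_opt) / self.sigma_t) ** 2))
        if hydration == "vapor":
            amp = amp * self.vapor_fraction
        return amp

    def gross(self, par, temp_C, hydration: str = "liquid"):
        """NRH gross assimilation at irradiance *par* and temperature."""
        a_max = self.ga_max(temp_C, hydration)
        par = np.asarray(par, dtype=float)
        if self.theta < 1e-12:
            denom = self.phi * par + a_max
            return np.where(denom > 0, self.phi * par * a_max / denom, 0.0)
        s = self.phi * par + a_max
        disc = np.maximum(s * s - 4.0 * self.theta * self.phi * par * a_max, 0.0)
        return (s - np.sqrt(disc)) / (2.0 * self.theta)


@dataclass
class GeneratorConfig:
    """Design of one simulated gas-exchange campaign.

    replicates_per_step mirrors the logging protocol (10 readings per
    stabilized step); thallus_cv is the between-thallus coefficient of
    variation of a shared lognormal size effect applied to both the
    respiratory and photosynthetic capacity of a thallus (paired across
    hydration sources).
    """

    seed: int = 0
    n_thalli: int = 5
    temperatures_C: tuple[float, ...] = DEFAULT_TEMPERATURES_C
    par_programmed: tuple[float, ...] = DEFAULT_PAR_PROGRAMMED
    replicates_per_step: int = 10
    noise_sd: float = 0.002
    thallus_cv: float = 0.15
    respiration: RespirationParams = field(default_factory=RespirationParams)
    photosynthesis: PhotosynthesisParams = field(default_factory=PhotosynthesisParams)
    species: str = "Evernia mesomorpha"
    genus: str = "Evernia"
    chamber: str = "aquatic"

    def __post_init__(self):
        if self.n_thalli < 1:
            raise ParameterError(f"n_thalli must be >= 1, got {self.n_thalli}")
        if self.replicates_per_step < 1:
            raise ParameterError(f"replicates_per_step must be >= 1, got {self.replicates_per_step}")
        _require_finite(noise_sd=self.noise_sd, thallus_cv=self.thallus_cv)
        if self.noise_sd < 0:
            raise ParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.thallus_cv < 0:
            raise ParameterError(f"thallus_cv must be >= 0, got {self.thallus_cv}")


def generate_gas_exchange(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate a full paired campaign and return records in log order.

    Every thallus is measured under vapor hydration first, then liquid,
    at every configured temperature, stepping through the programmed PAR
    protocol with `replicates_per_step` readings 2 s apart.
    """
    rng = np.random.default_rng(config.seed)
    n_t = config.n_thalli
    # shared thallus size effect, mean 1; applied to R and GA alike
    if config.thallus_cv > 0:
        sd_log = math.sqrt(math.log(1.0 + config.thallus_cv ** 2))
        effects = np.exp(rng.normal(-0.5 * sd_log ** 2, sd_log, size=n_t))
    else:
        effects = np.ones(n_t)
    dry_mass = rng.uniform(0.1, 0.3, size=n_t)

    par_prog = np.array(config.par_programmed, dtype=float)
    par_real = np.array([apply_attenuation(p) for p in par_prog])
    temps = np.array(config.temperatures_C, dtype=float)
    reps = config.replicates_per_step
    n_temps, n_steps = len(temps), len(par_prog)

    # record order: thallus (outer) > hydration (vapor first) > temperature
    # > protocol step > replicate, logged 2 s apart
    n_per_thallus = 2 * n_temps * n_steps * reps
    n_records = n_t * n_per_thallus
    idx_thallus = np.repeat(np.arange(n_t), n_per_thallus)
    hyd_block = np.repeat(np.array(["vapor", "liquid"]), n_temps * n_steps * reps)
    hydration = np.tile(hyd_block, n_t)
    temp_block = np.repeat(temps, n_steps * reps)
    temperature = np.tile(temp_block, n_t * 2)
    prog = np.tile(np.repeat(par_prog, reps), n_t * 2 * n_temps)
    real = np.tile(np.repeat(par_real, reps), n_t * 2 * n_temps)

    is_vapor = hydration == "vapor"
    resp = config.respiration.rate(temperature)
    resp = np.where(is_vapor, resp * config.respiration.vapor_fraction, resp)
    # the vapor fraction scales the NRH *plateau*, not the NRH output
    gross_v = config.photosynthesis.gross(real, temperature, "vapor")
    gross_l = config.photosynthesis.gross(real, temperature, "liquid")
    gross = np.where(is_vapor, gross_v, gross_l)
    mean_flux = (gross - resp) * effects[idx_thallus]
    a_net = mean_flux
    if config.noise_sd > 0:
        a_net = mean_flux + rng.normal(0.0, config.noise_sd, size=n_records)

    t0 = np.datetime64("2022-09-15T08:00:00")
    timestamps = t0 + np.arange(n_records) * np.timedelta64(2, "s")
    thallus_labels = np.array([f"thallus_{i + 1:03d}" for i in range(n_t)])

    return pd.DataFrame(
        {
            "timestamp": np.datetime_as_string(timestamps, unit="s"),
            "thallus_id": thallus_labels[idx_thallus],
            "species": config.species,
            "genus": config.genus,
            "hydration": hydration,
            "chamber": config.chamber,
            "temperature_C": temperature,
            "par_programmed": prog,
            "par_realized": real,
            "rh_pct": 91.0,
            "flow_umol_s": 500.0,
            "co2_ref_ppm": 400.0,
            "a_net": a_net,
            "dry_mass_g": dry_mass[idx_thallus],
        },
        columns=list(gasex_io.GASEX_COLUMNS),
    )


def gas_exchange_truth(config: GeneratorConfig) -> dict:
    """Noise-free generative quantities per temperature and hydration."""
    temps = list(config.temperatures_C)
    truth: dict = {
        "respiration": asdict(config.respiration),
        "photosynthesis": asdict(config.photosynthesis),
        "noise_sd": config.noise_sd,
        "thallus_cv": config.thallus_cv,
        "per_temperature": [],
    }
    for t in temps:
        entry = {"temperature_C": t}
        for h in ("vapor", "liquid"):
            r = float(config.respiration.rate(t, h))
            ga = float(config.photosynthesis.ga_max(t, h))
            entry[h] = {"r_dark": r, "ga_max": ga, "ratio": r / ga if ga > 0 else math.inf}
        truth["per_temperature"].append(entry)
    return truth


# ---------------------------------------------------------------------------
# microclimate
# ---------------------------------------------------------------------------

@dataclass
class MicroclimateRegime:
    """Diurnal bog microclimate with injected high-humidity spells.

    Baseline temperature and RH are sinusoidal over the day (RH peaking
    at night, in antiphase with temperature).  Each day additionally
    receives ``spells_per_day`` contiguous spells during which RH is
    pinned to ``spell_rh`` and temperature to ``spell_temp_C`` — the
    known-duration humid episodes the humid-hours statistic must find.
    """

    t_mean: float = 15.0
    t_amplitude: float = 8.0
    rh_mean: float = 70.0
    rh_amplitude: float = 15.0
    noise_sd_t: float = 0.0
    noise_sd_rh: float = 0.0
    spells_per_day: int = 1
    spell_hours: float = 2.0
    spell_rh: float = 98.0
    spell_temp_C: float = 22.0
    spell_start_hour: float = 13.0
    cadence_min: float = 30.0


def generate_microclimate(
    seed: int, n_days: int, regime: MicroclimateRegime | None = None
) -> tuple[pd.DataFrame, dict]:
    """Half-hourly (T, RH) series plus a per-day ground-truth ledger.

    The ledger records, per calendar day, the hours with RH above 95 and
    the subset of those hours with T above 20 °C, counted directly off
    the generated records (strict inequalities, cadence-weighted).
    """
    if n_days < 1:
        raise ParameterError(f"n_days must be >= 1, got {n_days}")
    regime = regime or MicroclimateRegime()
    rng = np.random.default_rng(seed)
    per_day = int(round(24 * 60 / regime.cadence_min))
    times = pd.date_range("2018-06-01", periods=n_days * per_day, freq=f"{int(regime.cadence_min)}min")
    hours = (times.hour + times.minute / 60.0).to_numpy(float)
    temp = regime.t_mean + regime.t_amplitude * np.sin(2 * np.pi * (hours - 9.0) / 24.0)
    rh = regime.rh_mean - regime.rh_amplitude * np.sin(2 * np.pi * (hours - 9.0) / 24.0)
    if regime.noise_sd_t > 0:
        temp = temp + rng.normal(0, regime.noise_sd_t, len(times))
    if regime.noise_sd_rh > 0:
        rh = rh + rng.normal(0, regime.noise_sd_rh, len(times))

    spell_records = int(round(regime.spell_hours * 60 / regime.cadence_min))
    for day in range(n_days):
        base = day * per_day
        for s in range(regime.spells_per_day):
            start = base + int(round(regime.spell_start_hour * 60 / regime.cadence_min)) + s * (spell_records + 4)
            stop = min(start + spell_records, base + per_day)
            rh[start:stop] = regime.spell_rh
            temp[start:stop] = regime.spell_temp_C

    n_clamped = int(((rh < 0) | (rh > 100)).sum())
    if n_clamped:
        import logging

        logging.getLogger(__name__).warning("clamped %d RH value(s) to [0, 100]", n_clamped)
    rh = np.clip(rh, 0.0, 100.0)

    df = pd.DataFrame(
        {"timestamp": times.strftime("%Y-%m-%dT%H:%M:%S"), "temp_C": temp, "rh_pct": rh}
    )
    cadence_h = regime.cadence_min / 60.0
    dates = times.normalize()
    humid = rh > 95.0
    warm = humid & (temp > 20.0)
    ledger = {}
    for date in dates.unique():
        m = dates == date
        ledger[str(date.date())] = {
            "humid_hours": float(humid[m].sum() * cadence_h),
            "warm_humid_hours": float(warm[m].sum() * cadence_h),
        }
    truth = {"regime": asdict(regime), "n_clamped": n_clamped, "per_day": ledger}
    return df, truth


# ---------------------------------------------------------------------------
# climate grids and occurrences
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    xllcorner: float = -100.0
    yllcorner: float = 42.0
    cellsize: float = 0.5
    ncols: int = 60
    nrows: int = 30
    t_south: float = 25.0  # July mean at the southern edge, °C
    lapse_per_degree: float = 0.6  # cooling per degree of latitude northward
    tmax_offset: float = 6.5  # July maximum above July mean
    noise_sd: float = 0.25


def generate_range_data(
    seed: int,
    grid_spec: GridSpec | None = None,
    envelope: tuple[float | None, float | None] = (None, 21.5),
    n_occurrences: int = 300,
) -> tuple[gasex_io.ClimateGrid, gasex_io.ClimateGrid, pd.DataFrame, dict]:
    """Latitudinal-gradient climate grids plus envelope-limited occurrences.

    July mean temperature declines linearly with latitude (plus optional
    cell noise); July maximum is a constant offset above it.  Occurrence
    records are placed at the centers of cells whose July mean lies
    inside the thermal *envelope* — the simulated species' range limit —
    and the envelope is stored as ground truth.
    """
    spec = grid_spec or GridSpec()
    rng = np.random.default_rng(seed)
    rows = np.arange(spec.nrows)
    lat_centers = spec.yllcorner + (spec.nrows - rows - 0.5) * spec.cellsize
    base = spec.t_south - spec.lapse_per_degree * (lat_centers - spec.yllcorner)
    tmean = np.tile(base[:, None], (1, spec.ncols))
    if spec.noise_sd > 0:
        tmean = tmean + rng.normal(0, spec.noise_sd, tmean.shape)
    tmax = tmean + spec.tmax_offset

    grid_mean = gasex_io.ClimateGrid(tmean, spec.xllcorner, spec.yllcorner, spec.cellsize)
    grid_max = gasex_io.ClimateGrid(tmax, spec.xllcorner, spec.yllcorner, spec.cellsize)

    lo, hi = envelope
    ok = np.ones(tmean.shape, dtype=bool)
    if lo is not None:
        ok &= tmean >= lo
    if hi is not None:
        ok &= tmean <= hi
    candidates = np.argwhere(ok)
    if len(candidates) == 0:
        raise ParameterError("thermal envelope excludes every grid cell")
    picks = candidates[rng.integers(0, len(candidates), size=n_occurrences)]
    occ_rows = []
    for k, (r, c) in enumerate(picks):
        lon, lat = grid_mean.cell_center(int(r), int(c))
        occ_rows.append((f"occ_{k + 1:05d}", lat, lon))
    occurrences = pd.DataFrame(occ_rows, columns=list(gasex_io.OCCURRENCE_COLUMNS))

    sampled_tmean = tmean[picks[:, 0], picks[:, 1]]
    sampled_tmax = tmax[picks[:, 0], picks[:, 1]]
    truth = {
        "grid_spec": asdict(spec),
        "envelope": [lo, hi],
        "n_occurrences": n_occurrences,
        "sampled_tmean_max": float(sampled_tmean.max()),
        "sampled_tmean_mean": float(sampled_tmean.mean()),
        "sampled_tmax_max": float(sampled_tmax.max()),
        "sampled_tmean": [float(v) for v in sampled_tmean],
        "sampled_tmax": [float(v) for v in sampled_tmax],
    }
    return grid_mean, grid_max, occurrences, truth


# ---------------------------------------------------------------------------
# chlorophyll-fluorescence activation
# ---------------------------------------------------------------------------

def generate_fvfm_series(
    seed: int,
    f0: float = 0.10,
    f_inf: float = 0.70,
    tau_min: float = 30.0,
    cadence_min: float = 10.0,
    duration_min: float = 510.0,
    noise_sd: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Saturating-exponential Fv/Fm rise during vapor rehydration.

    ``F(t) = F0 + (F_inf - F0) (1 - exp(-t/tau)) + noise`` sampled every
    *cadence_min* over *duration_min* (defaults: a pulse every 10 min for
    8.5 h).
    """
    if not (0 <= f0 <= f_inf <= 1):
        raise ParameterError(f"need 0 <= f0 <= f_inf <= 1, got f0={f0}, f_inf={f_inf}")
    if tau_min <= 0:
        raise ParameterError(f"tau_min must be > 0, got {tau_min}")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + 1e-9, cadence_min)
    f = f0 + (f_inf - f0) * (1.0 - np.exp(-t / tau_min))
    if noise_sd > 0:
        f = f + rng.normal(0, noise_sd, len(t))
    df = pd.DataFrame({"minutes": t, "fvfm": f})
    truth = {"f0": f0, "f_inf": f_inf, "tau_min": tau_min, "noise_sd": noise_sd}
    return df, truth


# ---------------------------------------------------------------------------
# cross-genus asymmetry panel and cladogram
# ---------------------------------------------------------------------------

DEFAULT_GENUS_TRUTH = {
    # genus: (assimilation vapor:liquid ratio, respiration vapor:liquid ratio)
    "Evernia": (1.00, 0.47),
    "Usnea": (0.95, 0.55),
    "Cladonia": (0.80, 0.70),
    "Peltigera": (0.35, 0.90),
    "Umbilicaria": (0.60, 0.75),
    "Flavoparmelia": (0.90, 0.60),
}


def generate_asymmetry_panel(
    seed: int,
    genus_truth: dict[str, tuple[float, float]] | None = None,
    n_specimens: int = 3,
    noise_cv: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Paired vapor/liquid rates for a multi-genus specimen panel.

    Each genus has a true assimilation ratio ``a`` and respiration ratio
    ``r`` (vapor:liquid); its true asymmetry index is ``a - r``.
    Specimen liquid rates vary lognormally; *noise_cv* perturbs the
    vapor:liquid ratios multiplicatively per specimen.
    """
    genus_truth = genus_truth or DEFAULT_GENUS_TRUTH
    rng = np.random.default_rng(seed)
    rows = []
    for genus, (a_ratio, r_ratio) in genus_truth.items():
        for k in range(n_specimens):
            ga_l = 0.05 * np.exp(rng.normal(0, 0.3))
            r_l = 0.02 * np.exp(rng.normal(0, 0.3))
            jitter_a = np.exp(rng.normal(0, noise_cv)) if noise_cv > 0 else 1.0
            jitter_r = np.exp(rng.normal(0, noise_cv)) if noise_cv > 0 else 1.0
            rows.append(
                {
                    "unit_id": f"{genus.lower()}_{k + 1}",
                    "species": f"{genus} sp{k + 1}",
                    "genus": genus,
                    "ga_vapor": ga_l * a_ratio * jitter_a,
                    "ga_liquid": ga_l,
                    "r_vapor": r_l * r_ratio * jitter_r,
                    "r_liquid": r_l,
                }
            )
    truth = {
        genus: {"a_prop": a, "r_prop": r, "index": a - r}
        for genus, (a, r) in genus_truth.items()
    }
    return pd.DataFrame(rows), truth


def write_cladogram(genera: list[str], path: str | Path) -> None:
    """Write a synthetic ladder cladogram with one tip per genus.

    A stand-in topology for annotation runs — it encodes no real
    phylogenetic relationships.
    """
    tree = genera[0]
    for g in genera[1:]:
        tree = f"({tree},{g})"
    with gasex_io.atomic_write(path) as handle:
        handle.write(tree + ";\n")


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------

def write_dataset(
    out_dir: str | Path,
    config: GeneratorConfig | None = None,
    n_days: int = 30,
    regime: MicroclimateRegime | None = None,
    grid_spec: GridSpec | None = None,
    envelope: tuple[float | None, float | None] = (None, 21.5),
    n_occurrences: int = 300,
    fvfm_noise_sd: float = 0.01,
) -> dict:
    """Write the full synthetic input bundle plus a ground-truth sidecar.

    Files: gas_exchange.csv, microclimate.csv, occurrences.csv,
    july_tmean.asc, july_tmax.asc, fvfm.csv, panel.csv, cladogram.nwk,
    truth.json.  All derived seeds come from ``config.seed``.
    """
    config = config or GeneratorConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    records = generate_gas_exchange(config)
    gasex_io.write_gas_exchange(records, out / "gas_exchange.csv")

    micro, micro_truth = generate_microclimate(seed + 1, n_days, regime)
    gasex_io.write_microclimate(micro, out / "microclimate.csv")

    grid_mean, grid_max, occurrences, range_truth = generate_range_data(
        seed + 2, grid_spec, envelope, n_occurrences
    )
    gasex_io.write_ascii_grid(grid_mean, out / "july_tmean.asc")
    gasex_io.write_ascii_grid(grid_max, out / "july_tmax.asc")
    gasex_io.write_occurrences(occurrences, out / "occurrences.csv")

    fvfm, fvfm_truth = generate_fvfm_series(seed + 3, noise_sd=fvfm_noise_sd)
    gasex_io.write_fvfm(fvfm, out / "fvfm.csv")

    panel, panel_truth = generate_asymmetry_panel(seed + 4)
    with gasex_io.atomic_write(out / "panel.csv") as handle:
        panel.to_csv(handle, index=False)
    write_cladogram(sorted(panel_truth), out / "cladogram.nwk")

    truth = {
        "seed": seed,
        "gas_exchange": gas_exchange_truth(config),
        "microclimate": micro_truth,
        "range": range_truth,
        "fvfm": fvfm_truth,
        "panel": panel_truth,
    }
    with gasex_io.atomic_write(out / "truth.json") as handle:
        json.dump(truth, handle, indent=1, sort_keys=True)
    return truth
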