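"""End-to-end orchestration: simulate inputs, run every analysis stage.

`run_analyze` executes only the stages whose input files exist in the
data directory, writes each stage's tables, and aggregates the headline
numbers into one deterministic ``results.json`` (floats rounded to six
decimals, keys sorted).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import carbon_balance, climate, gasex_io, kinetics, light_response, synthetic

logger = logging.getLogger(__name__)

RESULT_FLOAT_DECIMALS = 6


def _round(obj):
    if isinstance(obj, float):
        return round(obj, RESULT_FLOAT_DECIMALS)
    if isinstance(obj, dict):
        return {k: _round(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v) for v in obj]
    return obj


def run_simulate(out_dir: str | Path, config: synthetic.GeneratorConfig | None = None, **kwargs) -> dict:
    """Write the full synthetic input bundle (see synthetic.write_dataset)."""
    return synthetic.write_dataset(out_dir, config, **kwargs)


def analyze_gas_exchange(gasex_path: Path, out_dir: Path) -> dict:
    records = gasex_io.read_gas_exchange(gasex_path, strict=True)
    curves = light_response.reduce_records(records)
    summaries = [light_response.summarize(c) for c in curves]
    frame = light_response.summaries_frame(summaries)
    with gasex_io.atomic_write(out_dir / "curve_summaries.csv") as handle:
        frame.to_csv(handle, index=False)

    pairs = carbon_balance.build_pairs(summaries)
    with gasex_io.atomic_write(out_dir / "pairs.csv") as handle:
        pairs.to_csv(handle, index=False)

    out: dict = {"n_curves": len(curves), "n_pairs": len(pairs)}
    if len(pairs) >= 3:
        for quantity, key in (("R", "respiration"), ("GA", "assimilation")):
            reg = carbon_balance.paired_regression(pairs, quantity=quantity)
            out[f"slope_{key}"] = reg.slope
            out[f"r2_{key}"] = reg.r2
            out[f"f_{key}"] = reg.f_stat
            out[f"p_{key}"] = reg.p_value

    ratios = carbon_balance.respiration_ratio(summaries)
    with gasex_io.atomic_write(out_dir / "ratios.csv") as handle:
        ratios.to_csv(handle, index=False)
    out["t_star"] = {}
    for hydration, sub in ratios.groupby("hydration"):
        if len(sub) >= 3:
            t_star = carbon_balance.viability_threshold(sub["temperature_C"], sub["ratio"])
            out["t_star"][hydration] = t_star
    return out


def analyze_asymmetry(panel_path: Path, out_dir: Path, tree_path: Path | None = None) -> dict:
    pairs = pd.read_csv(panel_path)
    specimens = carbon_balance.asymmetry_table(pairs)
    genera = carbon_balance.aggregate_by_genus(specimens)
    with gasex_io.atomic_write(out_dir / "asymmetry_specimens.csv") as handle:
        specimens.to_csv(handle, index=False)
    with gasex_io.atomic_write(out_dir / "asymmetry_genera.csv") as handle:
        genera.to_csv(handle, index=False)
    out = {
        "genus_index": dict(zip(genera["genus"], genera["index"])),
        "n_genera_positive": int((genera["index"] > 0).sum()),
        "n_genera_negative": int((genera["index"] < 0).sum()),
    }
    if tree_path is not None and Path(tree_path).exists():
        unmatched = gasex_io.annotate_newick(
            tree_path, dict(zip(genera["genus"], genera["index"])), out_dir / "cladogram_annotated.nwk"
        )
        out["n_tips_unmatched"] = len(unmatched)
    return out


def analyze_climate(
    occ_path: Path, tmean_path: Path, tmax_path: Path, out_dir: Path, t_star: float | None = None
) -> dict:
    occurrences = gasex_io.read_occurrences(occ_path)
    grid_mean = gasex_io.read_ascii_grid(tmean_path)
    grid_max = gasex_io.read_ascii_grid(tmax_path)
    envelope = climate.extract_envelope(occurrences, grid_mean, grid_max)
    with gasex_io.atomic_write(out_dir / "envelope.csv") as handle:
        envelope.values.to_csv(handle, index=False)
    out = {
        "summaries": envelope.summaries,
        "n_used": envelope.n_used,
        "n_dropped_nodata": envelope.n_dropped_nodata,
    }
    if t_star is not None:
        out["threshold_alignment"] = climate.compare_threshold(envelope, t_star)
    return out


def analyze_microclimate(micro_path: Path, out_dir: Path, rh_threshold=95.0, temp_threshold=20.0) -> dict:
    series = gasex_io.read_microclimate(micro_path)
    table = climate.humid_hours(series, rh_threshold, temp_threshold)
    with gasex_io.atomic_write(out_dir / "humid_hours.csv") as handle:
        table.to_csv(handle, index=False)
    return {
        "mean_daily_humid_hours": float(table["hours_humid"].mean()),
        "mean_daily_warm_humid_hours": float(table["hours_humid_warm"].mean()),
        "n_days": len(table),
    }


def analyze_kinetics(fvfm_path: Path, out_dir: Path) -> dict:
    series = gasex_io.read_fvfm(fvfm_path)
    fit = kinetics.fit_activation(series["minutes"], series["fvfm"])
    out = {
        "f0": fit.f0,
        "f_inf": fit.f_inf,
        "tau_min": fit.tau_min,
        "converged": fit.converged,
    }
    if fit.converged:
        out["minutes_to_fraction"] = {
            f"{f:g}": kinetics.time_to_fraction(fit, f) for f in (0.90, 0.95, 0.99)
        }
    with gasex_io.atomic_write(out_dir / "activation_fit.json") as handle:
        json.dump(_round(out), handle, indent=1, sort_keys=True)
    return out


def run_analyze(
    data_dir: str | Path,
    out_dir: str | Path,
    rh_threshold: float = 95.0,
    temp_threshold: float = 20.0,
) -> dict:
    """Run every stage whose inputs exist under *data_dir*.

    Missing inputs skip their stage with a logged notice; a corrupt
    input raises.  Returns (and writes) the aggregated results dict.
    """
    data = Path(data_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    gasex = data / "gas_exchange.csv"
    if gasex.exists():
        results["gas_exchange"] = analyze_gas_exchange(gasex, out)
    else:
        logger.info("no gas_exchange.csv: skipping physiology stage")

    panel = data / "panel.csv"
    if panel.exists():
        results["asymmetry"] = analyze_asymmetry(panel, out, data / "cladogram.nwk")
    else:
        logger.info("no panel.csv: skipping asymmetry stage")

    occ, tmean, tmax = data / "occurrences.csv", data / "july_tmean.asc", data / "july_tmax.asc"
    if occ.exists() and tmean.exists() and tmax.exists():
        t_star = results.get("gas_exchange", {}).get("t_star", {}).get("liquid")
        results["climate"] = analyze_climate(occ, tmean, tmax, out, t_star)
    else:
        logger.info("missing occurrence/grid inputs: skipping envelope stage")

    micro = data / "microclimate.csv"
    if micro.exists():
        results["microclimate"] = analyze_microclimate(micro, out, rh_threshold, temp_threshold)
    else:
        logger.info("no microclimate.csv: skipping humid-hours stage")

    fvfm = data / "fvfm.csv"
    if fvfm.exists():
        results["kinetics"] = analyze_kinetics(fvfm, out)
    else:
        logger.info("no fvfm.csv: skipping kinetics stage")

    with gasex_io.atomic_write(out / "results.json") as handle:
        json.dump(_round(results), handle, indent=1, sort_keys=True)
    return results
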