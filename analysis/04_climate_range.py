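"""Climate envelope at occurrence records and the humid-hours statistic.

Extracts July mean/maximum temperature at every occurrence, compares the
envelope's upper edge with the liquid-hydration viability threshold from
the physiology stage, and computes daily hours of RH > 95% (and the
warm subset, T > 20 degC) from the microclimate series.
"""

from pathlib import Path

import pandas as pd

from lichenflux import pipeline
from lichenflux.carbon_balance import viability_threshold

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main() -> None:
    t_star = None
    ratios_csv = OUT / "ratios.csv"  # written by the carbon-balance stage
    if ratios_csv.exists():
        liquid = pd.read_csv(ratios_csv).query("hydration == 'liquid'")
        if len(liquid) >= 3:
            t_star = viability_threshold(liquid["temperature_C"], liquid["ratio"])

    env = pipeline.analyze_climate(
        DATA / "occurrences.csv", DATA / "july_tmean.asc", DATA / "july_tmax.asc", OUT, t_star
    )
    tm = env["summaries"]["tmean"]
    print(f"envelope over {env['n_used']} occurrences: "
          f"July T_mean max {tm['max']:.1f} degC, q99 {tm['q0.99']:.1f}, median {tm['q0.5']:.1f}")
    if "threshold_alignment" in env:
        al = env["threshold_alignment"]
        print(f"liquid T* = {al['t_star']:.1f} degC sits {al['gap_to_max']:+.1f} degC from the range-limit maximum")

    micro = pipeline.analyze_microclimate(DATA / "microclimate.csv", OUT)
    print(f"microclimate ({micro['n_days']} days): "
          f"{micro['mean_daily_humid_hours']:.1f} humid h/day, "
          f"{micro['mean_daily_warm_humid_hours']:.1f} of them warm")


if __name__ == "__main__":
    main()
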