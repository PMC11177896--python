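"""Carbon-balance statistics: hydration slopes, thermal ratios, asymmetry.

Fits the through-origin liquid-on-vapor regressions for respiration and
gross assimilation, tabulates the R:GA ratio against temperature with
the viability thresholds T*, and builds the specimen- and genus-level
asymmetry index tables (annotating the cladogram tips).
"""

from pathlib import Path

import pandas as pd

from lichenflux import carbon_balance as cb
from lichenflux import gasex_io, light_response, pipeline

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main() -> None:
    results = pipeline.analyze_gas_exchange(DATA / "gas_exchange.csv", OUT)
    print(f"paired regression over {results['n_pairs']} thallus x temperature pairs:")
    print(f"  respiration:  slope {results['slope_respiration']:.3f}, r2 {results['r2_respiration']:.3f}")
    print(f"  assimilation: slope {results['slope_assimilation']:.3f}, r2 {results['r2_assimilation']:.3f}")
    t_liquid = results["t_star"].get("liquid")
    t_vapor = results["t_star"].get("vapor")
    print(f"viability threshold T*: liquid {t_liquid and round(t_liquid, 1)} degC, "
          f"vapor {t_vapor and round(t_vapor, 1) or 'none in range'}")

    asym = pipeline.analyze_asymmetry(DATA / "panel.csv", OUT, DATA / "cladogram.nwk")
    print("genus-level asymmetry index (positive: vapor favors assimilation):")
    for genus, value in sorted(asym["genus_index"].items(), key=lambda kv: -kv[1]):
        print(f"  {genus:<14} {value:+.2f}")


if __name__ == "__main__":
    main()
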