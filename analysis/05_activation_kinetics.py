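"""Fit the Fv/Fm vapor-activation time course.

Quantifies how fast a dry thallus regains photosystem II efficiency in
saturating humidity: the saturating-exponential time constant tau and
the derived times to 90/95/99% of the full rise.
"""

from pathlib import Path

from lichenflux import pipeline

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results"


def main() -> None:
    fit = pipeline.analyze_kinetics(DATA / "fvfm.csv", OUT)
    print(f"activation fit: F0 {fit['f0']:.3f} -> F_inf {fit['f_inf']:.3f}, tau {fit['tau_min']:.1f} min")
    for frac, minutes in fit["minutes_to_fraction"].items():
        print(f"  {float(frac):.0%} of full activation after {minutes / 60:.1f} h")


if __name__ == "__main__":
    main()
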