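# lichenflux

Carbon-balance analysis of lichens hydrated by water vapor versus liquid
water: from raw light-response gas-exchange logs to the carbon-balance
asymmetry index, thermal viability thresholds, and climate-envelope
statistics.

Lichens are poikilohydric — their metabolic activity tracks external
hydration. Many species can activate photosynthesis from humid air
alone, and the two hydration routes are not metabolically equivalent:
liquid water can roughly double dark respiration while leaving gross
assimilation unchanged, so warm rain becomes a carbon cost while humid
nights are nearly free. This package quantifies that asymmetry for
ecophysiologists working with chamber gas-exchange data and connects it
to species distributions.

## What it computes

For paired vapor/liquid measurements of the same thalli:

* **Light-response reduction** — replicate-averaged curves per thallus ×
  hydration × temperature; dark respiration `R = −A_net(0)`; gross
  assimilation `GA = A_net + R` with its maximum `GA_max`;
  nonrectangular-hyperbola fits
  `A_net(I) = [φI + Am − √((φI+Am)² − 4θφI·Am)]/(2θ) − Rd`; light
  compensation points with a "never compensates" flag.
* **Hydration slopes** — through-origin regression `liquid = β·vapor`
  for R and GA_max; β is the liquid:vapor activation ratio (1 on the
  1:1 line), reported with r² about the origin and F(1, n−1).
* **Thermal viability** — the ratio `R/GA_max` per temperature and the
  threshold temperature T\* where it reaches 1 (no positive carbon
  balance possible at any light level).
* **Asymmetry index** — `A_prop − R_prop` with
  `A_prop = GA_v/GA_l`, `R_prop = R_v/R_l`, per specimen and averaged
  per genus; optional annotation of the values onto cladogram tips.
* **Climate context** — July mean/maximum temperature at occurrence
  records from ASCII-grid rasters (envelope distributions, range-limit
  maximum, alignment with T\*), and daily hours of RH > 95% (and the
  warm subset, T > 20 °C) from half-hourly microclimate series.
* **Activation kinetics** — saturating-exponential fits of Fv/Fm
  rehydration time courses, with time-to-95%-activation.

A synthetic-data module generates every input from explicit generative
models (Q10 respiration, Gaussian-optimum NRH photosynthesis,
multiplicative hydration fractions) with ground-truth sidecars, so all
estimators are covered by parameter-recovery tests. See
`docs/methods.md` for models, defaults and limitations.

## Worked example

Simulate a default campaign (5 thalli, six temperatures 5–30 °C, paired
vapor-then-liquid protocol) and analyze it end to end:

```sh
lichenflux simulate --out demo/data --seed 20220915
lichenflux analyze --data demo/data --out demo/results
```

or run the numbered drivers, which narrate each stage
(`python analysis/01_simulate.py`, then `02`–`06`). On the default
seed the drivers print:

```
paired regression over 30 thallus x temperature pairs:
  respiration:  slope 2.141, r2 0.993
  assimilation: slope 1.001, r2 0.999
viability threshold T*: liquid 27.7 degC, vapor none in range
```

— liquid hydration roughly doubles respiration (slope ≈ 2.1) while
assimilation is unchanged (slope ≈ 1.0), and above ~27.7 °C a
liquid-hydrated thallus cannot reach positive carbon balance at any
light level, while a vapor-hydrated one still can at 30 °C.

```
envelope over 600 occurrences: July T_mean max 21.5 degC, q99 21.4, median 18.8
liquid T* = 27.7 degC sits +6.3 degC from the range-limit maximum
microclimate (120 days): 2.0 humid h/day, 2.0 of them warm
```

— the species' simulated range limit sits below the liquid-hydration
viability threshold, and the bog microclimate delivers ~2 h/day of
near-saturating humidity.

```
activation fit: F0 0.099 -> F_inf 0.700, tau 29.6 min
  95% of full activation after 1.5 h
```

— vapor activation completes within one to two hours, fast enough for
nightly humid periods to matter.

All outputs land as CSV/JSON under the chosen results directory, with
one machine-readable `results.json` aggregating the headline numbers.

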