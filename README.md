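# ecocouple

Grid-scale analysis of the relationship between human activity intensity
and terrestrial ecosystem condition, for landscape ecologists studying
coupled human–nature systems in urbanising regions.

The package takes aligned raster time series of a **human footprint index
(HFI)** and vegetation indicators, and quantifies how the human and
natural subsystems co-evolve cell by cell:

- **Ecosystem quality index.** EQI = 100·(LAI + GPP + FVC)/3, with leaf
  area index and gross primary productivity min–max normalized to [0, 1]
  and fractional vegetation cover derived from the enhanced vegetation
  index, FVC = (EVI − EVI_soil)/(EVI_veg − EVI_soil), using the 5th/95th
  EVI percentiles as the bare-soil and full-vegetation references.
- **Four-quadrant change typing.** Between two epochs each cell is
  classified by the signs of (ΔHFI, ΔEQI): coordination (+,+),
  good-for-nature (−,+), degradation (−,−), conflict (+,−); changes
  smaller than 10% of the change raster's standard deviation are
  *insignificant*.
- **Coupling coordination degree.** With both indices rescaled to [0, 1]:
  C = 2·√(HFI·EQI)/(HFI+EQI), T = a·HFI + b·EQI (a = b = 0.5),
  CCD = √(C·T), classified into five levels from severely disordered
  ([0, 0.2)) to highly coordinated ([0.8, 1]).
- **Driver screening.** Candidate drivers of CCD pass two filters and
  only the intersection survives: VIF = 1/(1 − R²) ≤ 6 (collinearity),
  and a 500-tree permutation importance (%IncMSE, out-of-bag) whose
  significance is judged against a response-permutation null.
- **PLS path modeling.** A from-scratch partial-least-squares path model
  estimates how terrain, human activity, climate and vegetation
  constructs drive CCD, directly and through each other: Mode A
  measurement blocks, path-scheme inner weighting, GOF =
  √(mean communality × mean R²), effect decomposition
  (total = direct + Σ path products), and bootstrap inference with
  significance stars at p < 0.05 / 0.01 / 0.001.

A first-class synthetic-data module generates all of these inputs with
planted ground truth — block-structured HFI/EQI trends, drivers with
known collinearity, and indicator tables simulated from a known latent
path model — so every stage can be scored against what was planted.

## Worked example

```python
from ecocouple import (SyntheticRasterSpec, generate_coupled_stacks,
                       period_change, classify_quadrant, area_proportions,
                       ccd_pipeline, default_latent_model, generate_sem_table,
                       fit_pls_pm)
from ecocouple.indices import minmax_normalize

# Paired HFI/EQI stacks for 2000/2010/2020 with planted block trends
spec = SyntheticRasterSpec(shape=(60, 60), seed=42)
hfi, eqi = generate_coupled_stacks(spec)

qmap = classify_quadrant(period_change(hfi, eqi, 2000, 2020))
print(area_proportions(qmap).round(2))
res = ccd_pipeline(minmax_normalize(hfi).grid(2020),
                   minmax_normalize(eqi).grid(2020))
print(res.proportions.round(2))

table, truth = generate_sem_table(default_latent_model(n=4000, seed=42))
fit = fit_pls_pm(table)
print(f"GOF = {fit.gof:.3f} ({fit.gof_label})")
print("Veg->CCD:", round(float(fit.path_coefficients.loc['CCD', 'Veg']), 3))
```

prints

```
coordination       25.53
good_for_nature    13.63
degradation        12.04
conflict           42.21
insignificant       6.59
severely disordered        0.06
nearly disordered          2.91
primarily coordinated     42.61
moderately coordinated    29.29
highly coordinated        25.13
GOF = 0.373 (strong)
Veg->CCD: 0.407
```

Read: over 2000–2020 the synthetic region's human footprint rose while
ecosystem quality declined, so conflict cells (rising pressure, falling
quality) dominate at 42% against 26% coordinated cells; most cells sit
in the middle coordination levels of the CCD scale; and the fitted path
model recovers vegetation as the strongest positive driver of
coordination (planted standardized path 0.50, estimated 0.41 — PLS
attenuates paths slightly when indicators carry measurement noise).

The same analysis runs end-to-end from one config —
`run_pipeline(RunConfig(...))` or `ecocouple run --config run.yaml` —
producing quadrant maps, CCD levels, per-region screening reports and
PLS fits with full provenance. Each module also has a CLI subcommand
(`ecocouple eqi | classify | quadrant | ccd | screen | sem | synth`).

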