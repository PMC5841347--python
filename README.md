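# traitgrid

Trait–environment analysis of species assemblages on equal-area grids.

`traitgrid` asks a spatial-macroecology question: do reproductive traits of
birds — the shape of their eggs and the architecture of their nests — track
climatic stress across a continent?  Starting from a species trait table
(egg length *L* and breadth *B* in mm, nest type ∈ {cup, dome, cavity}) and
point occurrence records, it

1. computes **egg elongation** E = L/B per species and compares it across
   nest types (one-way ANOVA, Tukey HSD with the Tukey–Kramer unequal-n
   adjustment, and a taxonomic-family random-intercept REML model as a
   shared-ancestry robustness check);
2. projects occurrences with an **Albers equal-area conic** transform,
   assigns them to 100 km × 100 km cells, and builds per-cell **species
   assemblages**: mean elongation of cup- and dome-nesting species, the
   proportion of dome nesters, and a **Chao2** sampling-completeness index
   used to drop poorly surveyed cells (along with cells holding fewer than
   ten cup or ten dome species);
3. derives **vapour pressure deficit** VPD = e_sat(T_max) − VP (kPa), with
   e_sat(T) = 0.61375·exp(17.502 T / (240.97 + T)), averages it over time
   and aggregates fine rasters to the analysis grid by exact area weighting;
   leaf area index (LAI) is treated the same way;
4. regresses each assemblage response on VPD, LAI and their interaction:
   OLS first, then — when Moran's I correlograms of the residuals detect
   spatial autocorrelation — a maximum-likelihood **simultaneous
   autoregressive (SAR) error model**

   y = Xβ + u,  u = λWu + ε,  ε ~ N(0, σ²I),

   where W is a distance-band spatial weights matrix (200 km neighbourhood,
   binary or row-standardised).  λ is found by bounded search of the profile
   likelihood, with log|I − λW| obtained from the eigenvalues of W; model
   fit is summarised by a likelihood-ratio pseudo-R².

A **synthetic-world generator** produces complete inputs with known
parameters — ~300 species with realistic elongation and nest-type
marginals, spatially autocorrelated VPD/LAI surfaces, occurrence records
whose niches track the VPD axis, and SAR responses with known (β, λ, σ) —
so the whole pipeline is testable end to end without any data downloads.

## Worked example

Fit a full synthetic world (30 × 30 grid of 100 km cells, 300 species):

```sh
cat > example.yaml <<EOF
seed: 11
outdir: example_run
cell_size: 100000.0
origin: [-1500000.0, -4500000.0]
extent: [30, 30]
EOF
traitgrid fit --config example.yaml
traitgrid report --run-dir example_run
```

prints

```
species ANOVA: F(2, 297) = 2.40, p = 0.0922
mean_elong_dome: final model ols, n = 900
mean_elong_cup: final model ols, n = 900
prop_dome: final model sar, n = 900
...
mean_elong_dome: mean 1.363 [1.330, 1.402], 80% quantile 1.371
mean_elong_cup: mean 1.367 [1.334, 1.399], 80% quantile 1.374
prop_dome: mean 0.370 [0.197, 0.559], 80% quantile 0.410
dome vs cup ANOVA: F = 88.83, p = 1.27e-20
```

The species-level ANOVA compares elongation across the three nest types
(this seed's species pool shows only a weak cavity effect).  Each
assemblage response is fitted by OLS; for `prop_dome` residual
autocorrelation was detected, so the SAR error model was fitted as well and
reported as the final model (`model_prop_dome.json` records λ = −0.013 and
pseudo-R² = 0.438).  The per-cell summaries give the range, mean and 80 %
quantile of each mapped quantity; the dome-vs-cup ANOVA contrasts per-cell
mean elongations of the two nest types.

The run directory also contains `cells.csv` (one row per grid cell),
residual correlograms (`correlogram_*.csv`), prediction curves at the 5th
percentile / mean / 95th percentile of LAI (`curves_*.csv`), ASCII-grid
maps (`map_*.asc`) and a `provenance.json` with the config digest, seed,
library versions and row counts.  `traitgrid weights-select` tabulates SAR
fits across candidate neighbourhood distances (200–1000 km) and both
weight codings.

Library use mirrors the CLI:

```python
from traitgrid import RunConfig, run_all
report = run_all(RunConfig(seed=11, outdir="example_run"))
```

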