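# Methods

This note records the statistical models implemented in `traitgrid`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that matter.

## Species-level trait comparison

Egg elongation E = L/B is always recomputed from length and breadth; a
supplied elongation column is only cross-checked (warning on >0.1 %
relative disagreement), because published trait tables often mix
measurement sources.  Rows lacking either measurement are dropped with a
logged count.

Differences in elongation across nest types are tested with a classical
one-way ANOVA (for a single factor the Type II Wald F reduces to this) and
Tukey HSD pairwise comparisons.  Group sizes are heavily unbalanced in data
of this kind (cavity nesters are rare), so adjusted p-values use the
Tukey–Kramer form: q = |ȳ_a − ȳ_b| / √(MS_w/2·(1/n_a + 1/n_b)) referred to
the studentized-range distribution with the pooled residual df.  Summary
values are reported as mean ± SE with SE = s/√n and s the n−1 sample
standard deviation; a single-species group reports SE = 0 with a warning.

Shared ancestry is addressed with a linear mixed model: nest type fixed,
taxonomic family as a random intercept, fitted by REML (statsmodels
MixedLM; the group variance is profiled out as a single variance
component).  Gradient-based optimisers can fail when the family variance
sits on the zero boundary, so the fit falls back through lbfgs → powell →
Nelder–Mead.  Inference on the fixed factor is a plain Wald F with residual
degrees of freedom; degrees-of-freedom corrections such as Kenward–Roger
are deliberately out of scope (they matter only for small numbers of
groups and change nothing qualitatively here).

Outlier screening flags species with |E − mean| > k·sd (default k = 3) and
analyses are run on both the full and the screened pool.

## Gridding and assemblages

Occurrences are projected with an ellipsoidal (GRS80) Albers equal-area
conic transform.  The default parameter set is the standard Australian
Albers (central meridian 132° E, standard parallels −18° and −36°, origin
latitude 0, no false offsets), but all parameters are configurable; the
inverse transform iterates the authalic-latitude relation to 1e-12.  Cells
are half-open squares [x, x+c) × [y, y+c) in projected metres with integer
ids from the lower-left origin, so every point belongs to exactly one cell.
Pre-gridded occurrence tables (`cell_ix`, `cell_iy`) bypass the projection,
which is the ingestion path for data already distributed at cell
resolution.

Assemblages have set semantics: duplicate (species, cell) records collapse.
Per cell the module reports nest-type counts, mean elongation of cup and of
dome nesters (cavity nesters are excluded from elongation summaries — they
are few and have distinctly rounder eggs, which would distort cell means),
and the proportion of dome nesters.  The proportion's denominator defaults
to all trait-classified species in the cell; a `cup_dome` alternative is
provided because either convention is defensible and the choice is not
derivable from first principles.

Sampling completeness uses the bias-corrected Chao2 incidence estimator,
with sampling events as the incidence unit:

S_est = S_obs + ((m−1)/m) · Q1(Q1−1) / (2(Q2+1)),   index = S_obs/S_est.

Cells with fewer than two events get a missing index.  Retention requires
at least `min_per_type` (default 10) dome **and** cup species and a
completeness index above `ci_threshold` (default 0.7).  Both defaults are
configuration keys, and 0.7 in particular is a placeholder chosen as a
conventional "well-surveyed" cut-off — the estimator and threshold are the
kind of survey-design detail that should be revisited per dataset.  Cells
with a missing index are retained by default (`missing_completeness`)
because completeness requires event-level data that many occurrence tables
lack.

Empirical quantiles (e.g. the 80 % threshold used to describe where the
most elongate assemblages sit) use linear interpolation between order
statistics, the default convention of most statistical environments.

## Environmental surfaces

Saturation vapour pressure uses the Jones (1992) empirical fit
e_sat(T) = 0.61375·exp(17.502·T/(240.97+T)) kPa; the constants are fixed so
tests are bit-stable.  VPD = max(e_sat(T_max) − VP, 0); supersaturated
inputs clamp to zero with a counted warning, negative VP is an error.

Long-term VPD is computed **daily first**: the deficit is evaluated per day
and then averaged.  Because e_sat is convex in temperature, averaging the
inputs first gives a systematically smaller deficit; the daily-first order
is the faithful reading of a daily-defined quantity, and the
`average_first` alternative is exposed for sensitivity analysis only.

Aggregation of fine rasters to the analysis grid is an area-weighted mean
over exact rectangle intersections, so nested fine cells automatically get
equal weights; missing fine cells leave the weight sum, and a coarse cell
with zero covered area is missing.  Rasters travel as 2-D arrays with NaN
as missing; the ESRI ASCII (.asc) reader/writer flips row order so array
row 0 is always the southern edge, matching cell ids.

## Spatial statistics

**Weights.**  Neighbours are centroid pairs within a distance threshold
(default 200 km, inclusive at the boundary), no self-neighbours; binary or
row-standardised coding.  Isolated cells are allowed in the structure
(logged) but not in SAR fits — `nonisolated_subset()` restricts and
re-standardises.

**Moran's I** uses the analytic normality-null mean −1/(n−1) and variance;
a seeded permutation p-value (999 permutations) is available as an
alternative.  Correlograms compute I per half-open distance band with
binary weights; the default band width equals the grid cell size, a natural
increment for distance classes on a cell-based design.  Empty bands are
reported missing.

**SAR error model.**  The spatial model is the error form — regression
errors follow u = λWu + ε — not the spatial-lag form, because the
phenomenon being corrected is autocorrelated *residuals*, not a lagged
response.  For fixed λ the GLS coefficients and σ² have closed forms, so
only λ is searched (bounded scalar optimisation, xatol 1e-9) inside the
stability interval (1/ω_min, 1/ω_max) given by the extreme eigenvalues of
W.  The log-Jacobian log|I − λW| = Σ log(1 − λω_i) uses eigenvalues
computed once per weights matrix; for row-standardised W (asymmetric) the
spectrum of the similar symmetric matrix D^(−1/2)BD^(−1/2) is used, which
is exact when no rows are empty.  All cross-products entering the profile
likelihood are precomputed as quadratic polynomials in λ, making each
profile evaluation O(k³).  A λ within 1e-4 of a bound triggers a
boundary-solution warning.

**Pseudo-R².**  The null model is the intercept-only, *non-spatial*
Gaussian model, the convention of the spatial-regression software family
this model class comes from.  Nagelkerke's statistic divides the Cox–Snell
R² by its maximum attainable value 1 − exp((2/n)·ll₀).  For continuous
responses with very small variance (per-cell mean elongation has sd ≈ 0.01)
the null log-likelihood is *positive* and the divisor is negative, so the
rescaling is undefined; `nagelkerke_r2` raises, and the SAR fit then
reports the plain likelihood-ratio (Cox–Snell) value — which for Gaussian
ML equals a classical R² and lies in [0, 1) — recording which kind was used
(`pseudo_r2_kind`).

**Model-selection logic.**  OLS is always fitted.  The SAR model is
additionally fitted when any informative correlogram band is significant at
a Bonferroni-corrected threshold α/#bands.  With ~20 bands, triggering at
the raw per-band α would false-fire on roughly half of white-noise worlds;
the correction keeps the family-wise trigger rate at α while leaving real
autocorrelation (which concentrates enormous z-values in the short-range
bands) easily detected.  Both fits are always written, so the comparison is
never hidden.  The weights-selection report fits all 6 candidate distances
× 2 codings and tabulates mean |I| over the first 20 bands; no winner is
declared automatically because the criterion is a heuristic.

**Prediction curves** are trend-only (Xβ, spatial error excluded) over a
VPD grid at the 5th percentile, mean and 95th percentile of LAI.

## Synthetic worlds

The generator emulates the study conditions the pipeline is meant for:

- **Species pool** (default 300): nest types multinomial with probabilities
  (0.62 cup, 0.33 dome, 0.05 cavity); elongation truncated-normal
  (mean 1.37, sd 0.07, bounds [1.05, 1.70]) sampled by rejection (the
  truncation is mild), with the cavity mean shifted by −0.07 to reproduce
  the distinctly rounder eggs of cavity nesters; breadth ~ U(14, 18) mm and
  length = breadth·E, so recomputing E from the measurements is exact;
  families in consecutive blocks of 10 to give the mixed model a grouping
  structure.
- **Surfaces**: Gaussian random fields (kernel-smoothed white noise,
  correlation length 300 km by default) mapped affinely to VPD ∈
  [0.2, 4.5] kPa and LAI ∈ [0.05, 5.5], correlated at about −0.6 — arid
  cells carry sparse canopies.
- **Occurrences**: each species has a VPD niche optimum; with positive
  `niche_strength` dome nesters and round-egged species are pulled toward
  the arid end.  Cell occupancy is Bernoulli with probability
  logistic(−(VPD − optimum)²/width), width 3 kPa²; occupied cells emit 1–3
  point records at uniform in-cell coordinates (inverse-projected to
  lon/lat) tagged with per-cell sampling-event ids (12 events per cell) so
  Chao2 is exercised.  These defaults yield ~25–60 cup and ~10–50 dome
  species per 100 km cell and dome proportions spanning roughly 0.15–0.55
  across a 30 × 30 continent — magnitudes a field macroecologist would call
  plausible.
- **SAR responses**: y = Xβ + (I − λW)⁻¹ε drawn by linear solve, for
  parameter-recovery tests with known (β, λ, σ).

Every output is a pure function of (config, seed); stage sub-streams derive
from the root seed with fixed offsets so stages regenerate independently.

What the generator does **not** emulate: spatial range cohesion beyond the
environmental niche (cell occupancies are conditionally independent given
VPD, so OLS residuals of assemblage summaries are nearly white — real data
carry residual autocorrelation from dispersal and shared history, which is
why the SAR machinery is exercised separately with `generate_sar_response`);
phylogenetic trait conservatism beyond family blocks; observation effort
gradients; temporal dynamics.  Passing end-to-end tests therefore
demonstrates that the machinery recovers known gradients under realistic
marginals, not that any particular empirical dataset satisfies the model.

## Interpreting the fitted VPD effect

All regressions include a VPD×LAI interaction, so the sign of the raw VPD
main effect depends on the covariate origin.  Recovery checks and reports
therefore evaluate the *marginal* VPD effect at the mean LAI,
β_VPD + β_int·LAI̅, which is origin-invariant and matches the quantity a
reader takes from the prediction curves.

## Problem sizes and determinism

Simulation-based checks use 500 random fields for the Moran oracle, 200
simulated 20 × 20 lattices for SAR recovery, 1000 random incidence tables
for Chao2, 100 simulations for the SAR-vs-OLS residual-whiteness property,
and 50 (test) / 30 (acceptance script) complete 30 × 30 worlds for
end-to-end sign recovery — sizes at which the medians and rates being
asserted are stable across seeds.  All stochastic routines take explicit
seeds; there is no global random state, and pipeline reruns with the same
configuration are byte-identical.

## Known limitations

- The SAR eigenvalue route assumes the row-standardised weights matrix is
  similar to a symmetric one, which fails if isolated cells are included;
  the code refuses such fits rather than silently using complex spectra.
- Chao2 requires event-level incidence; occurrence tables without event
  ids get no completeness filter (cells pass by default).
- The family random-intercept model is a robustness check, not a full
  phylogenetic regression; no PGLS is attempted.
- Missing egg measurements are dropped, never imputed.
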