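# Methods

## The daily stress index

The index scores one day as the sum of a water term and a heat term.

**Water term** — `deficit / EAWR · 100`, the percentage of the soil's
easily accessible water reserve currently depleted. The deficit comes
either from the built-in bucket model,
`deficit' = max(0, deficit + ETP − rain − irrigation)` (all mm), or
from an external `deficit` column in the weather CSV; the index is
agnostic to the source. The term is deliberately uncapped: utilisation
above 100 % *is* the water-stress regime. The initial deficit at the
series start defaults to 0 mm (configurable) — appropriate for a
spring-sown crop on a recharged soil profile.

**Heat term** — `((h + 1) · (Tmax / T₀)) / 2400 + 1` with `h` the hours
above the threshold `T₀ = 30 °C` (maize) and 2400 a fixed scaling
constant. As printed, the grouping of the trailing `/2400 + 1` is
typographically ambiguous; we implement the most literal reading (the
whole product divided by 2400, plus 1), isolated in one function
(`weather.heat_term`) so an alternative reading is a one-line change.
Under this reading the heat term lives in `[1, 1 + 50/2400]` for
`Tmax ≤ 60 °C` — a small daily bonus relative to the water term, which
matters mainly through the +1 accumulating over period sums and via
ranking of equally dry environments. Sub-threshold days still
contribute `Tmax/T₀ < 1`; negative `Tmax` is floored at 0 so the term
never drops below 1.

**Heat hours** are counted from hourly temperatures when available;
otherwise a cosine diurnal curve between `tmin` (midnight) and `tmax`
(noon) is sampled at the 24 hour midpoints — the standard
agro-meteorological stand-in. Tests hold it to a dense numerical
sampling of the same curve within ±1 h.

**Aggregation and classification.** Daily values are summed over Pflo
(Jul 1–15, flowering) and Ptot (May 16 – Aug 15, culture window), both
closed intervals, and averaged per half-month (1–15, 16–end). An
environment is *humid* when no complete half-month mean exceeds 100,
*severe* when the Pflo mean exceeds 180, *moderate-to-severe*
otherwise. The humid ceiling applies to the full SID rather than the
water term alone (the difference is ≈ 1 and does not change any
generated classification); the severe cutoff of 180 is a configuration
default chosen so that the four generated irrigation scenarios rank and
classify as the corresponding field regimes do. Both thresholds are
configurable (`ClassificationThresholds`).

## Derived and histological traits

Digestible yield (`yield × DM digestibility / 100`) is computed at
block level and averaged upward — the aggregation order used in the
trial analysis; computing it on condition means instead gives slightly
different values (means of products vs product of means) and is left to
the caller via `digestible_yield` on whatever inputs they choose.

Segmentation counts for the 44 zones are validated as a partition of
the cross-section, converted to %ICS (`count · 100 / total`), and
summed into synthetic traits by a data-driven membership registry
(`traits.SYNTHETIC_GROUPS`): blue/red groups per compartment, the four
pith digestibility classes, dark/light rind totals and their
rind-share ratios. Zone naming differences between segmentation-plugin
versions are a registry edit, not a code change. The epidermis subzones
are registered as `ET1`–`ET11` placeholders; they complete the
partition but enter no synthetic trait.

## Trial statistics

**ANOVA.** `Y = µ + H + C + (HC) + column + row + ε` fitted by OLS
(statsmodels), type-II sums of squares. Row/column field covariates are
screened on the full interaction model and kept only when their F test
has p < 0.05; the interaction is then tested and, when non-significant
at α = 0.05, the additive model is refitted and reported. Degenerate
designs (no residual df, zero residual variance) raise. Per-trait
ANOVAs are *not* corrected for multiple testing across traits — the
tables report per-trait inference, as is conventional for trial
summaries; treat families of traits accordingly.

**Tukey letters.** Pairwise Tukey HSD p-values (statsmodels) feed an
insert-and-absorb compact-letter construction with the exact guarantee
that two groups share a letter iff their pairwise test is
non-significant — verified exhaustively in tests against
studentized-range p-values computed from scratch for up to 8 groups.
With unbalanced groups the pooled-variance Tukey test is used as-is.

**PCA.** Correlation PCA by eigendecomposition (eigenvalues sum to the
number of active variables); loadings are variable–PC correlations;
signs are fixed so each axis's dominant active variable loads
positively. Illustrative variables never shape the axes — they are
projected afterwards as correlations with the PC scores. Cross-checked
against scikit-learn's PCA in the test suite.

**Stepwise decomposition.** Forward selection maximising R²; a
candidate enters only if it adds at least `delta_r2 = 4` percentage
points of R² (the cutoff is expressed in points, matching how entry
increments are reported) *and* reduces RMSE by a relative
`rmse_eps = 1 %` (our quantification of "notably decreased"; no
published number exists). RMSE is `sqrt(RSS/n)`. Ties break by lower
RMSE then lexicographic name, making the path deterministic. Per-entry
increments sum exactly to the final R² and the RMSE path is
nonincreasing by construction; category shares are sums of increments
over a trait→category map. Increments are entry-order gains (not an
averaged partition such as LMG), which matches how stepwise models are
narrated and keeps the identity `Σ increments = R²` exact. If no
candidate qualifies at step 1 the result is an empty model with a
warning, not an error. The implementation is held to an independent
greedy oracle on every tested instance and, on orthonormal designs, to
an exhaustive all-subsets search.

## Synthetic data

**Weather.** Rain is a marked Poisson process (exponential depths);
temperature a seasonal sinusoid peaking mid-July plus AR(1) noise and
scenario heatwaves; reference evapotranspiration a seasonal curve with
small noise. Four scenarios are provided: a wet oceanic rainfed site
(rain ≈ 5 mm/day average, ETP peaking at 3.8 mm/day) and a dry
Mediterranean site (ETP peaking at 6.5–8.2 mm/day, sparse summer rain)
under three irrigation regimes — 20 mm every 3 days (well-watered),
15 mm triggered at 60 % reserve depletion (moderate deficit, standing
in for a −125 kPa tensiometer trigger) and 13 mm at 85 % depletion
(severe, for −300 kPa). Tensiometry itself is out of scope; the
fraction triggers emulate it at the bucket-model level. Deficit
triggers apply from 25 days post-sowing (establishment watering
before); triggered doses keep a 3-day minimum spacing, matching the
calendar cadence — a deliberate choice that lets the severe regime's
13 mm dose fall behind peak evapotranspiration so its deficit outruns
the reserve, reproducing the qualitative behaviour of a severe field
season (Pflo means ≈ 210 vs ≈ 130 moderate and < 100 humid). EAWR
defaults to 100 mm.

**Trial tables.** Every trait follows
`Y = µ + hybrid + condition + interaction + column·slope + row·slope + ε`
on its own scale; defaults (11 hybrids, 3 blocks, hybrid SD 0.6,
interaction SD 0.25, residual SD 0.55 in scale units) are
order-of-magnitude choices, since within-condition variance components
are not published. CW digestibility is built differently: it is the
planted linear combination of the *standardized latent deviations* of
its predictor traits, with condition-specific weights expressed in R²
points (a weight `w` contributes `sqrt(w/100)` of the response scale)
plus matching residual noise — so the planted biochemistry/histology
split is the true decomposition and stepwise recovery can be measured.
The default weights plant biochemistry-dominant humid/severe conditions
and a histology peak at moderate stress.

**Segmentation.** Dirichlet-multinomial counts around a plausible
default profile (58 % pith, 24 % rind split between dark and light,
10 % bundles, 8 % epidermis); `concentration` controls between-sample
variability.

**What passing tests show — and don't.** The generators reproduce the
*effect structure* the analysis assumes (balanced blocks, Gaussian
effects, linear trait links, independent predictors). Real trials have
unbalanced losses, spatially correlated residuals, non-Gaussian traits
and collinear predictors; recovery results here bound behaviour under
the model's own assumptions, not under field messiness.

## Numerical and design notes

- Date windows are closed on both ends; month lengths are calendar
  (leap-day aware), with no other special-casing.
- Aggregation identity: the Ptot sum equals the sum over the six
  half-month windows tiling May 16 – Aug 15, exactly.
- The water balance equals a clipped cumulative sum and is tested
  against a day-loop oracle to machine precision.
- Type-I calibration of the interaction test is simulated on a
  4-hybrid × 2-condition × 3-block null design, 1000 replicates — the
  F test is exact under normality, so the design choice only affects
  Monte-Carlo noise.
- Planted-share recovery is evaluated at 11 hybrids × 2 blocks
  (n = 22 per environment) over 100 seeds and summarised by the median:
  single-seed estimates at n = 22 are noisy (entry cutoffs can drop a
  planted predictor; small-sample R² is inflated by selection), which
  is itself a faithful property of stepwise modelling at this scale.

## Known limitations

- No mixed/random-effect models and no spatial field-trend correction
  beyond the row/column covariates.
- The heat term's printed grouping is ambiguous at source; results that
  hinge on the *magnitude* (not ranking) of the heat contribution
  should be interpreted with that in mind.
- `heat_hours` from daily extremes is an interpolation; hourly records
  are preferred when available.
- The stepwise decomposition inherits the usual caveats of forward
  selection: entry-order increments are not unique variance partitions
  when predictors are correlated.
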