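# Methods

## The quality index model

QIM grades freshness with integer demerit points per sensory parameter;
the Quality Index is their sum, so it lives on [0, max_qi] where max_qi is
the sum of per-parameter maxima (25 for the packaged amberjack scheme).
Parameters keep their own score range: attributes that never develop a
fourth distinguishable degradation stage (anus, eye shape) top out at 2,
and assuming a uniform 0–3 range would corrupt both the ceiling and
validation. Observations with missing or out-of-range scores are rejected,
never imputed — there is no defensible imputation rule for ordinal sensory
slips, and a panel sheet with holes should be fixed upstream.

## QI–time calibration

Panel scores are averaged to one mean QI per sampling day and fitted by
ordinary least squares against days on ice. Two choices matter:

* **Saturation guard.** The index cannot exceed its ceiling, so once the
  panel mean comes within one demerit point of max_qi the index has stopped
  discriminating time; that day and all later days are dropped from the
  fit (the latent index is non-decreasing, so days after first ceiling
  contact carry no slope information). Without the guard, plateau days
  late in a long trial visibly flatten the fitted slope and push the
  predicted rejection day out. The guard never reduces the fit below three
  days.
* **Error in days.** The calibration's practical use is inverse: given a
  QI, how long has the fish been on ice? The reported `rmse_days` is the
  RMS of inverse-predicted minus true day over the fitted days, with a
  leave-one-day-out variant (`rmse_days_loo`) as an honesty check. A
  one-latent-variable PLS of a single predictor is algebraically the OLS
  line, so no separate PLS machinery exists.

Inverse-prediction intervals use simple propagation, ±t₀.₉₇₅(n−2)·rmse_days,
clipped at day 0. This understates uncertainty far outside the calibrated
range (Fieller-type intervals are out of scope); the interval is a guide,
not a guarantee.

Panel diagnostics regress each assessor's per-day mean QI on the consensus
of the *other* assessors (excluding the assessor under test avoids
self-correlation inflating every slope toward 1); slopes outside a
configurable band (default 0.8–1.2) are flagged. Attribute importance is
|Pearson r| between an attribute's mean score and day, flagged relevant
above 0.8 — the natural reading when importance values are reported on a
correlation scale — while PCA loadings of the standardized day × attribute
matrix are reported separately so a variance-based reading is also
available. Constant attributes get importance 0 and are excluded from the
standardization.

## Spoilage kinetics

**Torrymeter.** Dielectric readings fall in two linear phases (autolysis,
then microbial degradation). The segmented fit searches every split of the
observed times leaving ≥ 3 points per side, fits an independent OLS line
per side, and keeps the split with minimal summed SSE; ties go to the
earliest breakpoint. The search is discrete because sampling is daily —
candidate breakpoints (midpoints between adjacent observation times) are
the only resolvable positions, and a discrete search is exactly
reproducible. Segments are deliberately *not* forced continuous: the two
phases are reported as two separate regressions with their own r². A
consequence of the discrete grid: the breakpoint estimate is quantized to
~1-day steps, so at trial-realistic noise (sd ≈ 0.2 instrument units,
which reproduces the per-segment r² ≈ 0.99 seen in real trials) the median
breakpoint error equals one grid step; at sd 0.1 it is 0.

**Microbial counts** are stored as log₁₀ cfu/cm² at ingest (zero or
negative raw counts are rejected — no pseudo-counts) and fitted log-linearly,
optionally windowed to the exponential phase for populations such as H₂S
producers that lag early in storage. The crossing day solves the fitted
line at the threshold.

**TMA** uses monotone piecewise-linear interpolation between observed
means, taking the first up-crossing of the threshold; no parametric form
is defensible for a slow-then-accelerating accumulation sampled at a
handful of days. An exponential (log-linear) alternative is available
behind a flag. Transient dips are tolerated; the first crossing wins.

**pH** gets an OLS slope with a two-sided t-test against zero; an exactly
collinear series is flagged degenerate and its p-value reported as
numerically minimal rather than zero-by-division.

All crossings are reported with a whole-day (floor, ceil) bracket, the
resolution at which storage trials tabulate rejection windows.

## Analytical method validation

The TMA calibration is a least-squares polynomial (degree 1 or 2) on all
replicate points individually. Adequacy of the functional form uses the
lack-of-fit decomposition: SS_residual = SS_pure-error (within replicate
groups) + SS_lack-of-fit (group means vs curve), with
F_exp = (SS_lof/df_lof)/(SS_pe/df_pe), df_lof = levels − parameters,
df_pe = observations − levels, accepted when F_exp < F₀.₉₅(df_lof, df_pe).
Six levels in triplicate under a straight-line model give (4, 12) and a
critical value of 3.26; the quadratic model gives (3, 12). The degrees of
freedom are always computed from the data in (numerator, denominator)
order — the F critical value is not symmetric in its arguments, so a
hand-swapped (12, 4) would give a different cutoff. If replicates are
numerically identical *and* the curve passes through every group mean, the
test degenerates to 0/0 and is reported as trivially accepted with
F_exp = 0 (this arises only for noiseless synthetic data).

LOD and LOQ use the ICH-style multipliers 3.3 and 10 on
sd(intercept)/|linear coefficient|, so LOQ/LOD ≡ 10/3.3 regardless of the
data. The matrix effect is 100·(matrix slope)/(solvent slope) with a
pooled-SE t-test for slope equality; the pass flag follows the 70–125 %
band on the ratio, while the t-test p-value is reported separately.
Recovery passes in 80–115 %, precision below 15 % RSD (sample sd, n−1).
Weighted regression is not implemented; replicate noise in this
concentration range is treated as homoscedastic enough for unweighted fits.
Concentration-to-tissue conversion (µg/mL → mg/100 g) is upstream
bookkeeping; the pipeline accepts TMA already expressed in mg/100 g.

## Shelf-life integration

Sensory analysis is the reference method; the instruments corroborate it.
The integrated shelf life is therefore the day the fitted QI line reaches
the sensory rejection threshold (QI 17.5), rounded to the nearest half day
(half-up), with uncertainty = the calibration's rmse_days rounded to the
nearest half day and floored at 0.5 — half a day being the honest floor on
a daily sampling grid. Corroborating assays never move the estimate; they
set a consistency flag, true when every crossed assay's whole-day interval
midpoint lies within ±1.5 days of the integrated value. Removing
corroborating assays thus never changes the estimate, only the flag.

Default rejection criteria: QI ≥ 17.5 (off-odors), Torrymeter ≤ 8 (the
slope-change value, also used for other species), TVC ≥ 8.0 log₁₀ cfu/cm²
(within the accepted 7–9 band), H₂S producers ≥ 7.5, TMA ≥ 12.5 mg/100 g
(the observed value at rejection; the regulatory limit is 12). All are
overridable from a YAML/JSON file. The QI threshold 17.5 is stored as a
criteria constant, not derived from any fit.

## Synthetic trials

The generator's defaults are the study conditions the analysis is tested
under:

| block | defaults | rationale |
|---|---|---|
| panel | 9 sampling days {0,2,4,7,9,12,15,17,20}, 3 fish/day, 6 assessors, slip probability ε = 0.1 | trial design; ε chosen so the clip-at-zero bias gives a day-0 mean QI ≈ 9·ε/2 = 0.45, matching the observed ~0.4 |
| QI truth | slope 1.45 points/day via 25 pooled transitions at days (k−½)/1.45, apportioned largest-deficit | ordinal step schedules are the honest sensory ground truth; the near-linear QI *emerges* from summing staggered steps |
| Torrymeter | start 16.8, slopes −0.809/−0.375, break day 11.5, sd 0.2 | printed decay parameters; sd reproduces per-segment r² ≈ 0.99 |
| microbial | intercept 3.0 log₁₀, rate 0.45/day, sd 0.2; H₂S one decade low until day 9, converged by 13 | 10³ → 10⁶ by day 7, limits crossed near day 11 |
| TMA | control points (0, 5.6), (7, 9.0), (12, 11.1), (15, 20.7) mg/100 g, sd 0.5 | tabulated trajectory |
| pH | 6.4 → 6.7 over 20 days, sd 0.15 | weak drift that should usually fail significance |
| calibration | 6 levels 0.1–15 µg/mL × 3 replicates, y = −0.0108x² + 1.080x + 0.1102, 2 % proportional + 0.01 absolute noise, matrix slope ×1.06 | printed calibration function and 106 % matrix effect |

Each generator draws from its own child stream
(`SeedSequence(seed, spawn_key=(i,))`), so identical (config, seed) pairs
are byte-identical and adding a generator never perturbs another.

What the generator does **not** emulate: fish-to-fish covariance (every
fish on a day shares the latent state), assessor-specific bias structure
(slips are symmetric and independent), seasonal or temperature variation
(storage fixed at 0 ± 1 °C), count saturation at stationary phase, and
chromatographic artefacts. Passing tests therefore demonstrate that the
estimators recover the assumed data-generating process at realistic noise,
not that real trials satisfy those assumptions.

## Problem sizes

Stochastic checks use 50 seeds for single-assay recovery (Torrymeter
slope, growth rate, QI slope), 20 full trials for the end-to-end shelf
life, 100 seeds for the matrix-effect mean, 200 for the pH significance
rate, and 500 simulated calibrations for the size of the lack-of-fit test
— enough replication for median/mean statistics to stabilize while the
whole suite stays fast.

## Known limitations

- Inverse-prediction intervals are propagation-based, not Fieller.
- The breakpoint estimate is quantized to the sampling grid.
- One-component PLS only; no mixed-effects modelling of assessors.
- No predictive-microbiology growth models (Baranyi/Gompertz); log-linear
  growth with an optional window is the only count model.
- The integration rule is sensory-anchored by construction; it does not
  pool uncertainty across assays.
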