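# Methods

## Model and scope

`cogpoint` asks whether the cross-sectional relation between a CSF
biomarker concentration *y* (pg/mL) and a cognitive score *c* (CAMCOG
total, integer 0–107, higher = better cognition) changes regime at some
score θ. Three complementary notions of "changes regime" are implemented
and then reconciled:

- a change in **level**: E[y] differs between the sides of θ;
- a change in **slope**: dE[y]/dc differs between the sides;
- a change in **variance**: Var[y] differs between the sides.

The analysis is purely cross-sectional: it orders participants by their
cognitive score and never uses time, diagnosis or follow-up. Diagnostic
labels appear only in the demographics table and as plotting symbols.

## Synthetic cohorts

No suitable public cohort exists at the relevant design (paired CSF panel
+ CAMCOG in cases and controls), so the generator is a first-class module
and defines the study conditions for every test.

**CAMCOG mixture.** Scores are drawn by inverse-CDF interpolation through
quantile anchors — non-demented (min 45, Q1 81, median 99, Q3 106,
max 107), AD (0, 10, 57, 96, 107) — then rounded and clipped to [0, 107].
This reproduces the intended medians/IQRs by construction rather than by
tuning a parametric family; the non-demented component is strongly
left-skewed with mass near the ceiling, the AD component near-uniform over
the low range. Group sizes default to 95 + 97.

**Biomarker response.** For each biomarker, a broken stick anchored at
`level_at_theta` with per-side slopes, an optional `level_shift` jump for
the upper regime, and Gaussian noise with side-specific SD. Contamination
replaces the noise SD of a random fraction with `contamination_scale`
times itself (symmetric variance inflation — enough to exercise
breakdown behaviour without moving the mean). Batch (assay-group) and
covariate (age, gender, storage time) effects are additive and default to
zero so change-point tests are unconfounded unless a test opts in.
Negative draws are clipped at zero (concentrations are non-negative).

**Why a level jump?** The side-median contrasts this kind of analysis is
built to detect are far larger than a continuous stick can produce, and a
strictly continuous mean makes the constant-per-regime level breakpoint
sit systematically inside the steeper arm (the noiseless argmax of the
split-RSS profile lies mid-ramp), so the level and slope estimates would
disagree by construction. With the jump the two estimators agree closely —
which is precisely the empirical regime in which averaging them is
sensible. `level_shift` defaults to 0.0; the four built-in archetypes
carry jumps (+1100, +330, −310, −30 pg/mL).

**Default archetypes.** θ ∈ {90, 90, 94, 93} for Aβ1-40, Aβ1-42, Tau,
phospho-Tau; slope signs follow the published per-biomarker pattern
(biphasic Aβ1-40: +93 above / −6 below; Aβ1-42 −15 above / ≈0 below;
Tau +12 / +0.5; phospho-Tau +1.5 / +0.05, all pg/mL per point).
Magnitudes and side SDs (800/600, 130/180, 90/160, 9/18) are package
choices scaled to each analyte's range under two constraints: the upper
arm must not re-cross the lower arm's level inside the score range (each
side occupies its own level regime, as the published side medians imply),
and slope contrasts must exceed roughly twice the local-slope standard
error at the default segmentation windows so the regimes are detectable
at cohort size ~200. These configs are fixtures for validating the
machinery, not claims about any real cohort.

**What the generator does not emulate.** Assay-specific measurement error
models, floor effects near detection limits, informative missingness,
non-Gaussian biology (beyond the optional variance-inflation
contamination), correlations *between* biomarkers given CAMCOG, and any
longitudinal structure. Passing tests therefore demonstrate that the
estimators recover the generating regimes under heteroscedastic broken-
stick truth — not that real CSF panels contain such change-points.

## Level change-point

Observations are stably sorted by CAMCOG (ties keep input order). For a
split with k observations on the left, the structural-change F compares
one mean per regime with the pooled mean. Candidates are trimmed to
[trim, 1 − trim] of the ordered sample (default trim 0.15; breakpoint
search uses min_seg = max(5, ⌈0.15 n⌉)). The sup-F split equals the
RSS-minimizing split; exact RSS ties break toward the split whose CAMCOG
value is nearest the sample median, then toward the smaller split. The
breakpoint is reported as the CAMCOG of the last left-regime observation.
Significance uses permutation of y against the ordering (default 1000
draws, seeded; the add-one estimator (1 + #{F*≥F})/(B + 1) keeps the test
valid). Permutation was chosen over asymptotic sup-F theory because it is
assumption-light and verifiable by simulation at desk scale.

## Slope change-point

CAMCOG ties are split uniformly at random (observations with distinct
scores never swap), giving an equally spaced rank series of biomarker
values. The series is winsorized at median ± 5 scaled-MADs and passed
through a width-5 running median before segmentation: both window fits
and the split refinement are least-squares operations, and a handful of
gross outliers would otherwise dominate any window they fall in (measured
effect before the prefilter: 10% contamination moved the slope
change-point by 9–16 CAMCOG points; after: < 1).

Segmentation fits OLS lines in the two length-w windows adjacent at each
candidate split (both axes normalized to unit range) and flags the split
when the angle |atan s_R − atan s_L| exceeds the tolerance; runs of flags
closer than one window collapse to their maximal-angle member. Window and
tolerance escalate window-major along a schedule until exactly one flag
remains; if the count jumps from ≥2 to 0, the last multi-flag setting's
maximal-angle point is used. The default windows are length-scaled
(1/4, 1/3, 5/12 of the series, floor 8, cap n/2) because a local slope
from w points has standard error ≈ σ·(n−1)·√(12/w³) on the unit square —
fixed small windows are pure noise at realistic noise levels. The
accepted flag then seeds a **global two-segment least-squares split
search** (prefix-sum vectorized) that fixes the reported index: the angle
statistic is a plateau around a break and is blind to a level jump
falling exactly between its windows, whereas the two-line RSS pins kinks
and jumps sharply and selects the dominant break when several exist —
consistent with the escalation's own selection rule. Noiseless broken
sticks are recovered exactly.

The whole procedure repeats (default 1000 times) with per-repetition
seeds derived from one master seed by a counter scheme; the slope
change-point is the median of the per-repetition CAMCOG values (the
change index maps back to the CAMCOG of the observation at that series
position). If more than half the repetitions find no change-point the
analysis is flagged failed rather than silently reporting a median.

## Side statistics and model comparison

"Above" is strict (c > θ̂; the boundary score joins the lower regime, so
counts are reproducible). Each side reports median, variance (ddof 1),
Spearman ρ (mid-ranks), and the MM-regression slope with its t and
df = n − 2. Between sides: WMW p for medians and the two-sided
variance-ratio F. The segmented-vs-linear comparison uses ordinary least
squares on both models — F = ((RSS₀ − RSS₁)/2)/(RSS₁/(n − 4)) — because
the nested-F distribution theory holds for LS, while the reported side
slopes use MM estimation; this split mirrors the analysis tradition the
package implements.

## Robust primitives

- **MM regression**: S-estimate via 2-point subsampling (50 subsets,
  internal fixed seed, so fits are deterministic) scored by the bisquare
  M-scale (c = 1.548, δ = 0.5 → 50% breakdown), refined by S-IRLS, then
  an M-step IRLS with c = 4.685 (95% efficiency) at fixed S-scale;
  convergence when the max coefficient change falls below 1e-8 (cap 200
  iterations, non-convergence flagged). Standard errors use the standard
  asymptotic M-estimator covariance, df = n − 2. The tuning pair
  (1.548, 4.685) is the canonical choice delivering the stated breakdown
  and efficiency.
- **Lowess**: k-nearest-neighbour local linear fits with tricube weights
  (span default 2/3) and 3 bisquare robustifying iterations scaled by
  6·median|r|.
- **WMW**: exact two-sided p by full enumeration of group assignments for
  combined n ≤ 12 (doubled smaller tail, capped at 1); otherwise normal
  approximation with tie and continuity corrections.
- **Variance ratio**: larger variance over smaller, p doubled and capped.
- **2×2 tables**: Pearson χ² without continuity correction; Fisher exact
  two-sided p sums hypergeometric probabilities ≤ the observed table's
  (with a 1e-7 relative slack against ties in floating point).

## Inflection MANOVA

Design: intercept, age, gender indicator, storage time, assay-group
indicators (first group reference), CAMCOG, below-indicator 1[c < θ₀] and
hinge (c − θ₀)·1[c < θ₀], θ₀ default 89 (configurable; the boundary score
belongs to the upper regime). Rows with any missing response or covariate
are dropped listwise, and all dfs come from the complete cases actually
analysed. For a single-df term with m responses, Wilks Λ = |E|/|E + H|
converts exactly to F = ((1 − Λ)/Λ)·(n − p − m + 1)/m on
(m, n − p − m + 1) df; for single-df hypotheses all four classical
multivariate statistics coincide in this conversion, so the choice of Λ
is innocuous. Rank-deficient designs raise an error naming the collinear
columns (an inflection below all observed scores is caught this way, and
an inflection outside the observed range is rejected outright).

## Numerical and procedural choices

- All randomness flows from integer seeds through `numpy` Generators;
  per-purpose seeds are derived from the master seed via CRC-tagged
  SeedSequences, so runs are reproducible across processes.
- Change-point combination is the arithmetic mean of level and slope
  estimates; if one is missing the other is used and the result flagged.
- Infinite F statistics (zero residual denominators) are flagged results,
  never exceptions; degenerate designs and undefined correlations raise
  informative errors.
- Problem sizes in the test-suite simulations (20 master seeds, 100–200
  tie-splitting repetitions, 500 null simulations with 999 permutations)
  are package choices balancing Monte-Carlo resolution against a
  desk-scale test run; the acceptance script uses the full 1000
  repetitions and 999 permutations.

## Known limitations

- One change-point per biomarker by design; no multiple-breakpoint
  dynamic programming.
- The slope-change segmentation estimates location consistently only when
  a single break dominates; with several comparable breaks the reported
  point is the dominant one, and the per-repetition distribution (exported
  for diagnostics) is the place to look for multimodality.
- MM standard errors are asymptotic; no small-sample correction.
- The level model regresses on a constant per regime — a deliberate
  minimal reading that makes level and slope analyses complementary; a
  trend-plus-break level model would behave differently on strongly
  sloped data.
- Raw-scale analysis throughout: no variance-stabilizing transform is
  applied, matching the generator's raw-scale output; heteroscedasticity
  is treated as a finding (variance-ratio tests), not a nuisance to
  remove.
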