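# Methods

`tcrquant` implements the quantitative procedures used to characterise an
allosterically activating TCRβ transmembrane mutation: dose-response
modelling of proximal signaling under kinetic proofreading, nested-model
inference, detergent-stability immunoblot quantitation, and dSTORM spatial
statistics. This note records the models, the defaults and why they were
chosen, the numerical choices, and the limits of what the synthetic-data
validation can show.

## Dose-response models

Ligand binding is described by an effective 1:1 model,
`C(L) = Bmax · L / (Kd + L)`, optionally with a Hill slope
(`L^h / (Kd^h + L^h)`). Dissociation follows a one-phase exponential,
`plateau + span · exp(−koff · t)`. Pharmacological dose-response uses the
three- and four-parameter logistic families
(`bottom + (top − bottom)/(1 + (EC50/L)^hill)`, Hill slope fixed at 1 for
the three-parameter form).

Signaling (pErk, pζ) is modelled by occupancy-coupled kinetic proofreading:

    Y(L) = scale · L/(Kd + L) · (kp/(kp + koff))^N

A bound receptor must complete `N` sequential steps at forward rate `kp`
(s⁻¹) before the ligand unbinds at `koff` (s⁻¹); the second factor is the
probability of finishing all steps before unbinding, and `scale` maps that
probability to the measured response units. Parameters and defaults:

| parameter | units | role | default |
|---|---|---|---|
| Kd | nM | effective binding constant, shared between conditions in the joint fit | free (start = dose nearest half-max) |
| kp | s⁻¹ | proofreading rate, one per condition | free, log-scale bounds [1e−4, 1e4] |
| koff | s⁻¹ | unbinding rate | **required**, fixed (0.85 in the canonical scenario, the independently measured value) |
| N | steps | number of proofreading steps | **required**, fixed; 2.7 is used in the canonical scenario as a literature-suggested value, recorded as an assumption |
| scale | response units | probability → response mapping | free and shared, or fixed via `scale_fixed` |

`koff` and `N` have no silent defaults: both must be supplied, because with
either free the model is unidentifiable from a single dose-response pair.

### Identifiability of kp

With `koff` and `N` fixed, the proofreading factor does not depend on
concentration, so each condition's data determine only `Kd` and the
amplitude `scale · (kp/(kp+koff))^N`. If `scale` is free, `kp` and `scale`
lie on an exact ridge: the residual sum of squares — and therefore every
nested F-test — is unaffected, but absolute `kp` values and the WT/mutant
`kp` ratio are not identified. The fit reports this confounding in its
notes. To estimate absolute `kp` (as the parameter-recovery studies do),
the probability-to-response mapping must be calibrated by passing
`scale_fixed`. The *sign* of a kp difference is ridge-invariant: with a
shared scale, the condition with the larger amplitude has the larger kp in
every gauge.

## Fitting

All fits minimise the residual sum of squares jointly over one or more
datasets with `scipy.optimize.least_squares` (TRF, bounded). Positive
parameters (Kd, EC50, koff, Hill slope, kp, scale) are optimised as log10
values, which keeps them positive and stabilises ratio estimates.
Optimisation is multi-start: the first start comes from data heuristics
(scale-like parameters from the response extrema, midpoint parameters from
the dose nearest half-maximal response), the remaining starts are seeded
log-scale jitters of it; the best optimum is kept and the number of starts
is recorded. Nested-model comparisons warm-start the alternative fit from
the null optimum so the alternative can never end up worse than the null
beyond optimizer jitter.

Parameter uncertainty is the asymptotic covariance from the Jacobian at the
optimum (`ss/df · (JᵀJ)⁻¹`), mapped to the natural scale by the delta
method. A nearly rank-deficient Jacobian (condition number > 1e12) marks
the fit non-identifiable. Degenerate data with all responses equal
short-circuit to the exact answer (scale parameter = that value) with
location parameters reported as NaN and the fit flagged non-identifiable.

Residuals are unweighted by default, matching the standard behaviour of the
named regression families. A relative-residual option
(`weighted=True`, residual = (fit − data)/fit) is available for
CV-parameterised noise — see the calibration section.

## Nested inference

Two nested least-squares fits of the same data are compared with the
extra-sum-of-squares F-test,
`F = ((SS0 − SS1)/(df0 − df1)) / (SS1/df1)`, p from the upper tail of
`F(df0−df1, df1)`. Fits carry a fingerprint of the data they were computed
on, and the test refuses fingerprint mismatches. `SS0 < SS1` within a
relative tolerance of 1e−8 (optimizer jitter) clamps F to 0 with a warning;
a larger inversion raises, since it means the alternative fit did not
converge. The same machinery serves three hypotheses: shared Kd (binding),
shared kp (signaling), and shared maximal response (logistic `top` shared
versus free, all other parameters per condition).

Replicate-level comparisons use two-tailed t-tests; unpaired comparisons
default to the Welch unequal-variance form (the safer default when the
variance homogeneity is unverified), with a pooled-variance option. No
multiple-testing correction is applied; raw p-values are reported.

### Calibration under multiplicative noise

`calibrate_test` measures empirical size and power of any test by
simulation. For the shared-kp F-test under the canonical noise model
(multiplicative, CV 0.1), the *unweighted* F-test is anticonservative
(empirical size ≈ 0.16 at α = 0.05) because the variance grows with the
squared mean and the amplitude contrast concentrates in the high-variance
doses. The calibration and power studies therefore use the
relative-residual (weighted) fits, the variance-matched analysis for
CV-parameterised noise, which restores the nominal size (≈ 0.04–0.05) while
keeping power at 1.0 against a 5-fold kp difference. Single fits keep
unweighted residuals as the default.

## DSA immunoblot quantitation

Band signal is `median − local background`; non-positive signals are
physically meaningless abundances and are excluded from ratios, with the
exclusions listed in the result. Total β is `β1 + β2 + β3`. Ratio schemes
(ζ/β₂, ε/β_T, γ/β_T, δ/β_T, β/ε, ζ/ε, plus band/actin loading schemes for
input-lysate panels) are computed per lane and normalised by the reference
condition's mean raw ratio, so the reference normalised mean is 1 by
construction. When lanes carry a `blot_id`, normalisation pairs within
blots (within-experiment normalisation); otherwise it is global. Per-lane
loading factors cancel in every ratio, so no loading correction is needed
before ratio computation.

## SMLM localization statistics

Processing order: photon filtering (strictly > 400 photons by default),
blink merging, drift correction, then spatial statistics.

**Blink merging.** Chains of localizations in consecutive frames, each
within one camera pixel (107 nm default, an assumption consistent with a
150× objective on an EMCCD and flagged as such — the pixel size is an
explicit input) of the chain's previous member, merge to their
photon-weighted centroid with summed photons, capped at 5 frames; longer
on-events split into successive records (7 frames → 5 + 2). Chain caps use
the up-to-5-frames reading of the merge rule; merged records carry the
frames they span, which makes the operation idempotent at the cap.

**Drift correction.** Localization images are reconstructed from 500-frame
segments at 20 nm bins and registered to the first segment by sub-pixel
phase cross-correlation; per-segment shifts (anchored at segment centres)
are linearly interpolated across frames and subtracted. Segments with
fewer than 10 localizations get their shift interpolated from neighbours,
with a warning. On synthetic data a 50 nm linear drift leaves a mean
residual well under one bin.

**Pair auto-correlation.** g(r) is estimated from the localization density
binned at 5 nm inside the region mask: the image autocorrelation (zero-
padded FFTs) divided by the mask autocorrelation, which counts the pixel
pairs available at each lag and thereby corrects edges for arbitrarily
shaped masks. The zero-lag self-pair term is subtracted, so complete
spatial randomness gives g = 1 at every radius including the first bin.
Lags are radially averaged, weighting by the mask pair counts. A direct
O(n²) pairwise estimator (exact distances, set-covariance normalisation) is
kept in the test suite as the independent oracle; the two agree within a
few percent per bin when the radial bins are several image pixels wide
(the estimator-equivalence checks use 50 nm bins on 5 nm pixels — narrower
bins amplify lag-quantisation differences at short range).

**DBSCAN.** Cluster detection uses scikit-learn's DBSCAN with the
convention that a core point has at least `min_neighbors` *other* points
within `radius` (defaults 7 within 25 nm, i.e. `min_samples =
min_neighbors + 1`). Records are scanned in (x, y, frame) sort order so
border-point assignment is deterministic; the label partition is verified
against a naive O(n²) reference on random clustered instances. Cluster-size
summaries (mean ± SD) are over clusters, not localizations.

## Synthetic data

The generators are pure functions of (truth, seed); every dataset records
its generating parameters and seed in metadata.

* **Dose-response / dissociation**: model mean times multiplicative
  Gaussian noise `1 + N(0, CV)` truncated at zero — fluorescence-intensity
  spread is approximately proportional to the signal; a mean-one log-normal
  option exists. Default dose grid: 1:2 dilution series of 10 doses from
  600 nM; default 3 replicates per dose.
* **Canonical KPR scenario** (`tcrquant.scenarios`): Kd = 30 nM (within the
  dose grid's resolvable range), koff = 0.85 s⁻¹, N = 2.7,
  kp = 0.1 s⁻¹ (WT) vs 0.5 s⁻¹ (mutant), scale = 4.3e5 (maximum response
  ≈ 10³ MFI-like units at the WT kp), CV = 0.1.
* **Band tables**: subunit abundances derived from the requested true
  ratios over a fixed β-glycoform split (β1:β2:β3 = 0.25:0.55:0.20,
  β_T = 1); each lane has a shared loading factor `1 + N(0, lane_scale_sd)`
  truncated at 0.05, plus optional per-band multiplicative noise; recorded
  backgrounds are exact, so the zero-noise round trip is exact.
* **Point patterns**: parent–offspring Gaussian clusters plus uniform
  background inside the mask (offspring re-drawn until inside, so all
  molecules lie in the mask); geometric blink counts (mean `blink_mean`,
  memoryless re-activation) in consecutive frames from a uniform start
  frame; Gaussian localization jitter; log-normal photon counts (median
  1000, σ = 0.5) — only their ordering against the photon threshold
  matters.

What the generators do **not** emulate: flow-cytometry gating and spillover,
camera noise and PSF shape, gel-image densitometry (band tables start from
extracted intensities), dye photophysics beyond memoryless re-blinking, and
anisotropic or non-stationary drift beyond what the linear-interpolation
model captures. Passing the validation suite therefore demonstrates
correctness of the estimators and inference under these idealised
conditions, not robustness to every artefact of real instruments.

## Problem sizes used in validation

The study-scale checks use 500 simulated experiments for parameter
recovery, 2000/500 replicates for F-test size/power, 200 seeds for
immunoblot-ratio recovery, 10⁴ points for the CSR g(r) check, 2000 points
for estimator equivalence, 50 instances (n ≤ 500) for the DBSCAN oracle,
and one 5 μm / 5000-frame acquisition for drift correction — sizes chosen
to keep Monte-Carlo error a small fraction of each tolerance.

## Known limitations

* The ESS F-test's residual degrees of freedom count free parameters, not
  effective ridge dimensions; with a free scale the alternative fit counts
  one more parameter than its effective dimension, making the test slightly
  conservative (empirically ≈ 0.04 size at α = 0.05).
* g(r) assumes a stationary pattern within the mask; strongly clustered
  patterns with few clusters show the usual finite-window negative bias at
  long range.
* Blink merging is greedy (nearest eligible chain) and can merge distinct
  molecules closer than one pixel in consecutive frames, as any
  position-based merge must.
* The drift model is piecewise-linear between segment centres; drift with
  strong curvature within a 500-frame segment is under-corrected.
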