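# Methods

This note documents the models, defaults, and numerical choices behind the
package, and what its synthetic-data experiments do and do not demonstrate.

## Response-surface regression

Both affect-change outcomes are modeled as a second-order polynomial in the
three predictors, with a fixed term order (intercept, Δθ, Δγ, AS, Δθ·AS,
Δγ², AS²). The interaction and quadratic columns are exact products and
squares of the *raw* predictors — the features are never standardized,
matching the convention that EEG change scores are analyzed unscaled.

**Conditioning.** Raw columns span ~1e−23 (Δγ²) to ~1e2 (AS²). The solver
therefore z-scores every non-intercept column internally, fits OLS on the
standardized design (via statsmodels), and maps back:
βⱼ = bⱼ/σⱼ, β0 = b0 − Σⱼ bⱼ μⱼ/σⱼ. The back-transformation is exact
algebra, so predictions from original-scale coefficients agree with the
standardized fit to machine precision (tested at ≤ 1e−8 relative).
Rank-deficient designs raise an error naming the offending columns (found
by pivoted QR) rather than silently dropping terms. Ridge or any other
regularization is deliberately excluded to keep coefficients directly
interpretable.

**Uncertainty.** All confidence intervals are 95% percentile bootstrap over
participant rows, 1,000 resamples by default, with the design rebuilt from
the resampled raw rows on every refit. Percentile (rather than BCa) is the
minimal, jackknife-free reading of "bootstrapped CI"; resample failures are
tolerated up to 1% and counted. No multiple-testing correction is applied;
raw p-values are reported together with the number of tests run.

**Identifiability, not just conditioning.** Under the reference generative
configuration the EEG-scale coefficients (β1 ≈ 2.7e−11, β2 ≈ 1.7e−12,
β4 ≈ 1.8e−10, β5 ≈ 1e−23) contribute ~1e−21 PANAS points or less to
outcomes whose noise SD is 4 points. Two hard consequences, both verified
by the test suite and reported honestly rather than patched:

1. *Statistical*: the OLS sampling SE of, e.g., the theta coefficient at
   n = 100,000 is σ/(√n·sd(Δθ)) ≈ 9e7 — eighteen orders of magnitude above
   the true value. No sample size in realistic reach identifies these
   coefficients; fitted values for them are noise.
2. *Numerical*: even with zero noise, the EEG-term contributions lie
   16–50 orders of magnitude below the outcome, beneath float64's relative
   resolution (~2.2e−16), so the information is destroyed when the outcome
   is computed. Exact recovery of every coefficient from noiseless data is
   an algebraic identity of least squares and holds to ~1e−9 relative when
   all terms contribute within float64 range (demonstrated with a
   unit-scale coefficient set); for the reference set only the
   affective-shift-scale coefficients (−3.96, 1.69, 79.43) are recoverable
   — those recover to better than 1e−6 noiselessly and to ~0.1% at
   n = 100,000 under noise.

**Mediation.** Exploratory mediation uses the product-of-coefficients
method: path a from regressing the mediator on the predictor, path b as the
mediator coefficient in the outcome ~ mediator + predictor regression, with
a percentile bootstrap CI for a·b over case resamples. The affective shift
is constructed from the same PANAS deltas that define the outcomes; that
circularity is a property of the design and is preserved, not residualized
away.

**Model comparison.** The multimodal/EEG-only/PANAS-only comparison uses
repeated k-fold cross-validation (5 folds × 20 repeats by default) — the
most defensible reading of a "mean" RMSE/R² — with fold assignments shared
across models within a repeat, out-of-fold predictions pooled per repeat,
and metrics averaged over repeats. Each unimodal model keeps the nonlinear
terms built from its own predictors (EEG-only: Δθ, Δγ, Δγ²; PANAS-only:
AS, AS²), since the source equation ties those terms to their predictors.

## Payoff simulation

The fitted polynomial is treated as a payoff ΔE(Δθ, Δγ, AS) and ascended by
x_{t+1} = clip(x_t + η ⊙ ∇ΔE(x_t)). Defaults: payoff mode `net`
(predicted Δ_Positive − predicted Δ_Negative, since a single payoff is
plotted while two outcomes are fitted; `positive` and `negative_reduction`
are first-class alternatives), η = (0.1, 0.1, 0.1), ε = 1e−6 on the payoff
change, max 50 iterations, origin start.

The simulation runs in standardized coordinates (per-predictor
center/scale from a cohort or a generative config) so one η scale works
across raw scales spanning 1e−12 to 1e1. Because the fitted quadratic
terms (Δγ², AS²) are *positive*, the surface is convex in those directions
and unconstrained ascent diverges; a bounded box (±3 standardized units per
coordinate) with projection is therefore mandatory. Under the reference
coefficients the trajectory reaches the AS box edge within two steps and
then satisfies the tolerance — the reported "local equilibrium" is a
constrained fixed point on the boundary, not an interior optimum. This is
the single largest modeling gap in the source analysis and is surfaced in
the trajectory's `stop_reason = "boundary_fixed"`. The second update
equation of the source describes updating Δγ from Δθ; this is treated as a
typo for Δγ (the only reading consistent with per-parameter updates). No
game-theoretic best-response machinery is implemented — none is specified.

## Synthetic data

The cohort generator emulates the study conditions: n = 50 participants;
predictors drawn independently Gaussian with moments back-derived from the
published 95% bootstrap CIs of the cohort means (SE = (hi − lo)/(2·1.96),
SD = SE·√50, giving theta ≈ 2.67e−11 ± 1.37e−10, gamma ≈ 1.66e−12 ±
4.53e−12, shift ≈ 5.58 ± 10.93 where the shift moments combine the two
reported outcome-delta rows assuming independence); outcomes generated from
the response surface using the published fitted coefficients as generative
truth, plus Gaussian noise of SD 4.0 PANAS points (the error distribution
is unstated; Gaussian is the standard OLS reading). The interaction
coefficient is assigned to the negative-affect equation (theta is
hypothesized to drive downregulation of negative affect) and the Δγ²/AS²
terms to the positive-affect equation; the published table never states the
outcome-to-row mapping, and the unexplained standalone shift row (5.63) is
left unmodeled rather than guessed.

Each participant draws from an independent substream seeded by
(seed, index), so identical configs are bit-identical and extending a
cohort never perturbs existing participants. With the reference
coefficients the AS² term pushes Δ_Positive far outside the ±40-point range
an actual PANAS instrument could produce; scores are clipped to legal
ranges (with clipping counted) only in item-emitting mode, where 20 Likert
items per instrument are back-filled from subscale scores by deterministic
round-robin increments. `shift_mode="latent"` (default) draws the shift
directly as the generative predictor; `shift_mode="derived"` records
instead the circular instrument-based shift ΔPA − ΔNA computed from the
realized scores, while a latent shift drives the generative equation (the
two specifications cannot hold simultaneously for one variable).

The EEG generator emits matched 32-channel, 128 Hz pre/post recordings:
shared 1/f-weighted background noise plus band-limited theta and gamma
components whose post amplitudes scale by √multiplier, so band power scales
by the multiplier exactly and change-score signs are known by
construction. It does not simulate blinks, EMG, inter-channel covariance,
or nonstationarity — passing EEG tests show the band-power pipeline tracks
known power changes, not robustness to real artifacts (artifact removal
such as ICA is out of scope). Likewise, passing cohort-level tests show
estimator correctness under the assumed generative model, not that the
published real-data coefficient values are right.

## EEG features

Filter: 4th-order Butterworth band-pass 1–50 Hz applied forward-backward
(zero phase; effective magnitude order doubles). Epochs: 2-s,
non-overlapping, 0-based half-open windows, trailing remainder dropped.
Baseline correction is per-epoch, per-channel mean subtraction — the
minimal deterministic interpretation, since continuous sessions have no
pre-stimulus interval. PSD: Welch inside each epoch, 1-s Hann segments,
50% overlap (variance reduction while keeping ≤1 Hz resolution), density
scaling so the spectral integral approximates the variance. Band power is
the trapezoidal integral with linearly interpolated band edges, making
adjacent bands exactly additive; gamma is capped at 50 Hz (the filter
ceiling). Absolute (not relative) power is used, aggregated by arithmetic
mean over epochs and then over the channel set — theta over {Fz, FCz, Cz}
(frontal-midline), gamma over {F3, F4, Fz, P3, P4, Pz} (frontal–parietal);
both sets are configurable since regions, not channels, are named in the
source. These choices are isolated behind `band_power_summary`.

## Nonparametric battery

Standard tests delegate to scipy (Shapiro–Wilk, Mann–Whitney U with
midranks, Kruskal–Wallis with tie correction, Spearman ρ); the Shapiro
p ≥ 0.05 gate routes analyses to the nonparametric path. Mann–Whitney
reports U = min(Ux, Uy), exact p when nx·ny ≤ 400 and the pooled sample is
tie-free, otherwise the tie- and continuity-corrected normal
approximation; the exact path is verified in tests against full
enumeration of group assignments. Cliff's δ is implemented directly
(sorted-merge fast path, proven equal to the O(n²) definition on random
instances). Tie handling is midrank everywhere.

## Problem sizes used in tests

Parameter recovery uses one n = 100,000 cohort; bootstrap coverage uses
1,000 replicates of n = 30 with 1,000 resamples; the cross-validation
pattern check uses 20 replicate n = 50 cohorts with 5×20 repeated k-fold;
EEG monotonicity averages 10 seeds per multiplier with 8-s recordings.
These sizes give Monte-Carlo error comfortably inside the asserted
tolerances while keeping the default test run fast.

## Known limitations

* The generative model is the analysis model; recovery experiments cannot
  detect misspecification of the response surface itself.
* Predictors are drawn independently; real EEG/affect correlations are not
  emulated.
* The payoff "equilibrium" depends on the box: enlarging the bounds moves
  the fixed point, because the fitted surface is convex in AS.
* The reported real-data coefficient table mixes rows that cannot all
  belong to one regression; the adopted mapping is one defensible reading.
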