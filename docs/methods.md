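# Methods

This note documents the models, conventions and numerical choices behind
`cuedreach`, and what the synthetic generator does and does not emulate.

## Behavioral model and windows

All behavioral statistics operate on trials carrying a cue time, pellet
and inhibition flags, and a list of reaches timestamped at the moment
the arm is outstretched (`t_arm`), with outcomes success / drop /
missed-pellet / pellet-missing (the last three are failures).

Windows relative to cue onset (`WindowSpec`): cued [0, 0.4) s; uncued
[−3.0, −0.25) s; false-alarm windows [−0.4, 0) s and [−1.0, −0.6) s; a
cued reach must fall within 1 s of the cue; the uncued reach window is
the closed interval [3.5, 7] s; a reach within 1.5 s of the cue excludes
the trial from the uncued classes. All event-in-window tests are
half-open [start, end) except intervals described as "between a and b",
which are closed. "Did not reach before the cue" defaults to the full
span from trial start to the cue; an alternative restricting it to the
uncued window is a config switch (`pre_cue_scope`).

d′ = z(hit) − z(FA) uses the inverse standard-normal CDF on the fraction
of trials with ≥1 reach in the relevant window. Saturated rates are
clipped (0 → 1/2N, 1 → 1 − 1/2N) before the quantile transform; this
makes segment-wise d′ comparisons mildly dependent on segment length
when a rate saturates, which is why calibration tests avoid zero-FA
constructions. The dual-FA variant computes d′ against both FA windows
and keeps the lower value; the single-FA variant uses only the window
immediately before the cue. Within-session learning contrasts Δd′₁
(last 75% − first 25%), Δd′₂ (halves) and Δd′₃ (last 25% − first 75%)
flag a session as learned when any exceeds 0.1 (strict). New learning
days are pre-expert sessions (d′ < 0.75) beating every previous day,
with each session's final 10% of trials discarded first.

If a success and a failure both land in the cued window, the trial
counts as a cued success (success takes precedence); reaches on catch
trials are pellet-missing failures.

QC: a session is excluded when the reach rate immediately before the
cue exceeds `cheat_ratio` (default 2) times the session's uncued-window
baseline — the paper-described "cheating" judgment operationalized with
a configurable threshold and a 0.05-Hz baseline floor — or when
inhibition trials show cued reaching exceeding control by more than 20%
of the control rate (direct opsin-excitation artifact).

The condition-contrast mixed model `metric ~ condition + (1 | mouse)` is
fitted by REML via statsmodels `MixedLM`; with a single mouse the random
intercept is unidentifiable and the fit falls back to OLS with a
warning.

## Synthetic generator

The generator is the package's study-conditions definition. Defaults:
baseline reaching 0.25 Hz; cue gain 1 (naive mouse — analyses of learned
behavior pass a higher gain explicitly); 250-ms cue; pellet withdrawn
8 s after cue onset; presenter travel + pre-cue delay 1.5 s; ITI =
U(0, 3.5) s plus, with probability 0.7, U(9.5, 13) s; 10% catch trials;
30% pellet availability at cue time; P(success | pellet present) = 0.75.

Catch trials are an explicit flag (cue on, pellet deliberately
omitted). Non-catch trials carry a pellet with probability
occupancy/(1 − catch), so the overall pellet-at-cue fraction equals the
`pellet_occupancy` knob exactly. This treats occupancy as a trial-level
availability probability; pellet-absent non-catch trials model presenter
cycles that loaded no pellet.

Reaching is an inhomogeneous Poisson process, piecewise constant within
a trial: baseline everywhere, baseline × cue_gain + s_cued in the cued
window, baseline + s_uncued in the uncued window. After a cued
(uncued) success the matching state jumps by `reinforcement_delta` (Hz)
and decays geometrically with a default half-life of one trial; the
update is blocked when optogenetic inhibition overlaps the conditioned
reach (interval test against instantaneous `t_arm`, configurable
padding; gate can be disabled). Negative rates are floored at zero with
a counter in the planted truth. Trial spans start 3 s before the cue so
the uncued window always lies inside its own trial; reaches later than
that boundary belong to the next trial's pre-cue span, mirroring how an
ongoing session is segmented.

Spike trains: each unit's rate in 0.1-s bins is baseline + Σ events ⊛
kernel on the −2…+5 s lag grid (linear link, floored at 0), Poisson
counts per bin, uniform spike times within bins. The default planted
kernels give group 1 a decaying post-success elevation and group 2 a
sustained post-failure elevation with mild cue suppression; baselines
are drawn low (0.5–2 Hz) so realized rates stay under the 4-Hz SPN
bound. Waveform widths are drawn so group units classify as SPNs and
"other" units as TAN/FS distractors.

Photometry: a 167-Hz sine carrier at 2 kHz whose envelope is a constant
baseline plus Gaussian success bumps (+, peak 0.83 s after `t_arm`, SD
0.25 s) and failure dips (−, 1.6 s, SD 0.35 s), plus white sample noise.
The default transient-to-noise amplitude ratio is 2.

What the generator does **not** emulate: reach kinematics, chewing
artifacts, session-to-session nonstationarity, bleaching or motion
artifacts in photometry, spike-sorting errors, or correlated
(non-Poisson) spiking. Passing recovery tests therefore demonstrates
estimator correctness under the stated statistical assumptions, not
robustness to those real-data complications.

## Reinforcement bootstrap

The resampling unit is the triplet (n−1, n, n+1); the point estimate,
mean(behavior at n+1) − mean(behavior at n−1), uses no resampling and is
deterministic. Bootstrap draws resample the m triplets with replacement
(100 draws for scatter, 1000 for the smoothed 2-D histogram, which uses
a 101×101 grid over the draw range ±10% and an axis-aligned Gaussian
filter with SD 0.0096 Hz along the uncued axis and 0.024 Hz along the
cued axis, then normalizes to unit integral). Interleaving filters keep
control (inhibition) center trials only when an inhibition (control)
trial occurs at position n+2…n+5. The backwards-time control applies
the condition at n+2 while still measuring the n−1 → n+1 shift. The
timing-resolved variant bins trial-n successful reaches by time relative
to the cue (per-bin window lengths are caller-specified, e.g. 1.2 s
before the cue, 0.2–1 s after), reports mean ± SE across triplets per
control/inhibition split, and indexes the difference curve by
midpoint(t_inh) − midpoint(reach bin); empty bins are NaN, not zero.

The measured conditioned shift slightly underestimates a planted update
(a few percent at the default one-trial half-life) because the state
also contributes to trial n−1 and because conditioning on a success
selects trials with elevated state; recovery experiments therefore use
a low conditioning probability (e.g. 10% pellet occupancy), where the
bias is well inside the bootstrap CI.

## Event GLM

The design matrix has one indicator column per (event, lag) pair,
event-major, lags −2.0…+5.0 s ascending in 0.1-s steps (9 × 71 = 639
columns); column (e, τ) is 1 in time bin t when event e occurred in bin
t − τ, with out-of-session shifts zeroed and coincident events collapsed
to a single indicator. The response is raw spike counts per 0.1-s bin
(no standardization of response or regressors). The final 10% of bins
is a contiguous outer holdout; on the rest, each hyperparameter
combination (α = 0 OLS, plus α × l1_ratio elastic net in scikit-learn's
parameterization; pure-L2 points use an equivalent Ridge solve for
numerical stability) is scored by mean R² over contiguous 5-fold CV;
the argmax (ties toward larger α, then larger l1_ratio) is refit on all
training bins and reported with its holdout R². The intercept is always
included and unpenalized; all-zero columns are retained with a warning.

Because every reach also emits an outcome event (and cued outcomes emit
both a base and a cued channel), the reach channel equals the sum of
outcome channels and the design is exactly collinear: individual channel
kernels are identified only up to that null space (OLS returns the
minimum-norm split; penalties shrink it). Identifiable — and what
recovery is scored on — are the *effective* event responses, the sums of
co-occurring channels (e.g. reach + success + cued-success for a cued
success). Post-outcome-period kernels are the coefficients at lags
[0, 5] s (51 bins) for success, failure (mean of the dropped-pellet and
pellet-missing channels; a missed-pellet reach with the pellet present
is routed to the drop channel), cued success and cued failure.

## Kernel grouping

Kernels are boxcar-smoothed with a 0.08-s window (identity on the 0.1-s
grid; on finer grids the window rounds to `width/bin` samples via a
uniform filter with nearest-edge padding), max-normalized by the largest
absolute entry of the unit's concatenated four kernels (per-kernel
normalization is an option), and concatenated in the fixed order
success, failure, cued success, cued failure. Units with no positive
post-outcome coefficient are excluded. k-means (k = 2, best of
`restarts` initializations) partitions the vectors; the label is
canonicalized so group 1 is the success-preferring cluster. The metric
windows are m: [2, 5] vs [0, 2) s and s: [1, 5] s (averaged over the
stated kernel pairs; m is missing when its denominator is zero). The
boundary in the (m, s) plane is a two-class linear discriminant fitted
to the k-means labels of training units only — standing in for the
line drawn by eye in the original analysis — with on-line ties assigned
to group 1 and the misassignment count reported; frozen, it classifies
any unit, including test-split data, so no test information can alter
the groups.

## Tensor regression

The condition tensor holds trial-averaged rates (0.1-s bins, window
0–5 s after `t_arm`) for success, failure, cued success, cued failure;
the two failure slices are shifted 8 bins (round(0.77/0.1)) earlier to
align the post-failure dopamine dip (≈1.6 s) with the post-success peak
(≈0.83 s), and the trailing 8 bins are dropped from every condition so
T stays equal (T = 42 for the 0–5 s window). The training samples of
the multinomial regression are the four condition-average slices with
their own condition as label; logits are inner products of a slice with
the rank-R Kruskal β tensor. Optimization: ADAM (lr 0.007, β₁ 0.9,
β₂ 0.999), factors initialized U(0, 1) × 0.625, L2 penalty 1e-3 on all
factors (the strength is config-exposed since no canonical value
exists), non-negativity on neuron factors enforced by clamping after
each step, stopping when the relative loss change over 50 epochs falls
below 1e-6 or at 20,000 epochs. The restart × rank sweep (ranks 1–5,
10 runs each by default) always emits the loss table so the elbow
judgment is auditable; rank 2 is the default choice. Among chosen-rank
runs the returned solution minimizes J (final loss for rank 1, where J
is undefined; identical factors give an ∞ sentinel). Component weights
are per-factor sums of |mean-subtracted| parameters with the mean taken
per factor. Validation predicts success-vs-failure on the test tensor
over neuron resamples; shuffles permute the stated test-tensor axis
before prediction.

## Decoding

Rates are averaged 1–5 s after `t_arm` (the first second is excluded so
the cue offset precedes the window). Each bootstrap iteration draws n
units per group with replacement (independently; single-trial mode also
draws one trial per unit per condition) and emits one
(group-2 mean, group-1 mean) point per condition. LDA is fit and scored
on the same points (resubstitution — the quantity of interest is the
geometric separation of the clouds; a held-out variant is available by
splitting iterations). Chance is reported empirically via the
condition-label shuffle: with finitely many units the bootstrap clouds
concentrate around condition-specific sample means, so shuffle accuracy
sits well above the nominal class prior — matching how chance is
reported in the source analyses. The group-identity shuffle deals the
pooled units back into groups of the original sizes.

## Photometry

Demodulation: 4th-order Butterworth band-pass 120–200 Hz applied
zero-phase, then a multitaper spectrogram (0.1-s windows stepped 0.01 s,
time-bandwidth 3, 2 DPSS tapers), with band power the mean over
frequency bins inside the band (the carrier bin alone is an option).
The z-score uses a trailing (causal) 30-s rolling mean/SD — "rolling"
left uncentered in the source; a centered option exists — with z = 0
and a warning where the SD is zero, followed by a 5-sample median
filter (width unstated in the source; 1 disables). Event alignment
extracts segments on the 0.01-s output grid, subtracts the mean over a
caller-chosen pre-event baseline window (0.5 s before the cue for
cue-aligned averages, 2 s before the reach for reach-aligned ones),
drops events whose window exceeds the trace (count reported), and
returns per-class mean ± SE.

## Problem sizes

Tests and the acceptance script run everything at desk scale, chosen as
the smallest sizes at which each planted effect is comfortably
recoverable: ≥10,000 trials for trial-structure calibration; ~2,000
triplets (≈140 sessions of 400 trials at 10% occupancy) for
reinforcement recovery; 400 trials / 4 units for GLM kernel recovery;
40–60 neurons for tensor analyses; 100 null sessions for CI coverage;
20 sessions of 30 trials for the photometry round trip.

## Known limitations

* The GLM's channel-level kernels are reported as fitted even though
  only effective sums are identifiable; consumers comparing individual
  channels across regularization settings should expect split
  differences.
* The reinforcement estimator's small conditioning-selection bias is
  inherent to conditioning on outcomes that the state itself makes more
  likely; it is documented rather than corrected.
* `session_learned` has a substantial false-positive rate on short
  noisy sessions (the max of three noisy contrasts against a fixed 0.1
  threshold); it mirrors the source definition rather than adding a
  significance test.
* The Kruskal optimization is non-convex; reproducibility is per seed,
  and solution quality is managed by restarts plus min-J selection, not
  guaranteed global optimality.
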