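# Methods

This note documents the models, defaults, and design choices behind
`metaphysio`, and what the synthetic-data tests do and do not establish
about real recordings.

## Stimulus statistics and staircase

A motion stimulus is summarised by its per-dot direction distribution:
`direction = s·μ + N(0, σ)` degrees, with sign `s = ±1` for right/left,
unsigned mean offset `μ ≥ 0`, and direction SD `σ` (15° low-variance, 25°
high-variance; `n_dots` = 1000).  Directions are plain real-valued angles:
with `μ ≲ 10°` and `σ ≤ 25°` the probability mass beyond ±180° is
negligible (< 10⁻¹²), so no circular wrapping is applied; users supplying
much larger σ should be aware of this caveat.

The staircase is Levitt's 2-down-1-up rule expressed in difficulty space:
two consecutive correct responses *reduce* the mean offset by one step
(harder), any error *increases* it (easier).  Its equilibrium satisfies
`P(correct)² = 1/2`, i.e. 70.7 % correct.  The rule is sometimes labelled
"2-up-1-down" in stimulus-intensity terms; only the 2-correct-harder
direction converges to 70.7 %, which is the convention implemented.
Defaults: initial level 8°, fixed additive step 0.5°, levels clipped to
[0.1°, 45°].  Step halving at reversals (down to 0.1°) is available
(`StaircaseConfig(halving=True)`) but off by default; with the fixed step
the converged accuracy sits ~0.3–0.5 points above the nominal 70.7 %
(finite-step oscillation), well inside the tolerance used anywhere.

High-variance trials never feed the staircase; their signal mean is yoked
to the most recent low-variance trial of the same cue condition (the
staircase's initial level before any exists).  Disgust and neutral trials
run independent staircases.  Yoking makes the variance condition
statistically orthogonal to signal mean by construction, which the tests
verify via a near-zero correlation.

## Generative observer

The decision variable for a trial is `x = s·μ + N(0, σ_eff)` with
`σ_eff² = σ_int² + σ²/n_eff`: internal noise (`σ_int`, default 1°) plus
the stimulus' own direction variability averaged over `n_eff` effectively
independent dots (default 25 — a deliberately small fraction of the 1000
drawn dots, standing in for spatial pooling inefficiency; it makes
high-variance stimuli genuinely harder at matched means, as required for
the design).  Choice compares `z = x/σ_eff` to a condition criterion
`c + Δc(cue, variance)`; confidence is a logistic map of
`|z − criterion|` to [0, 100] (`100·(2/(1+e^(−d/1.5)) − 1)`, zero at zero
distance), degraded by Gaussian type-2 noise added to the distance
(`conf_noise`, default 0.25) and shifted by a per-condition confidence
bias `Δconf(cue, variance)` before rounding/clipping to the integer
scale.  Any strictly monotone confidence map yields M-Ratio = 1 at
`conf_noise = 0`, so the particular squashing is immaterial to the
sensitivity results; it only shapes the rating histogram.

Default injected condition patterns (rows neutral/disgust × columns
low/high variance): criterion shifts `[[0, 0], [+0.15, −0.05]]` (a
cue×variance interaction on c) and confidence-bias shifts
`[[0, −5], [−2.5, −2.5]]` (noise lowers confidence after neutral cues,
flat after disgust — the reversal pattern of interest).  RTs are
log-normal (median 0.40 s, σ 0.35, ×1.08 on high-variance trials);
responses slower than the 0.8 s deadline are flagged missed, which makes
the miss rate ≈ 2 % without a separate parameter.

## Experiment structure

Sessions default to 640 trials in 10 blocks, each block containing equal
counts of the four cue×variance cells randomly interleaved (160 per cell
per session).  Within-trial event timing (forward mask 250 ms → ~16.7 ms
cue → 100 ms neutral-face mask → 250 ms static dots → 250 ms motion →
800 ms choice → 2500 ms rating) sums to 4166.7 ms, the epoch end used by
the physiological analyses; ITIs are uniform 2–3 s, giving ≥ 6 s between
successive responses so evoked pupil responses return to baseline.

## Physiological generator

Pupil: the evoked kernel is the Erlang/gamma pupillary impulse response
`h(t) = (t/t_p)^k e^{k(1−t/t_p)}` with time-to-peak `t_p = 0.93 s` and
shape `k = 10.1`, delayed 1.15 s after mask onset so the grand-mean
response peaks near 2.1 s, riding on a 3000 a.u. baseline with amplitude
`200 + β·x` a.u. (β defaults: noise +25, cue +20, confidence +10,
cue×noise −20 — magnitudes chosen to match the scale of plausible evoked
effects and to exercise the reversal pattern), white measurement noise
(SD 30 a.u.), and blinks injected as ~150 ms excursions to 100 a.u.
(0.3 blinks/trial).  Kernel onsets are snapped to the sampling grid so the
evoked shape is exactly trial-invariant.

Cardiac: instantaneous rate `r(t) = 65 + (−3 + β·x)·K(t − onset)` bpm with
a gamma kernel troughing 1.9 s post-onset (the orientation-response
deceleration; β defaults: confidence +0.3, cue +0.3, cue×confidence −0.3
bpm) plus slow smoothed noise; R-peaks fire when `∫ r/60 dt` crosses
integers.  An optional template-QRS waveform (R wave 1 mV, small Q/S) at
1024 Hz makes QRS detection testable end-to-end.

What the generator does *not* emulate: luminance-driven pupil components,
gaze/eye-position artifacts, respiratory sinus arrhythmia, P/T-wave
morphology, drift or electrode noise nonstationarity, and between-subject
parameter heterogeneity (all simulated subjects share observer and physio
parameters; only their random streams differ).  Passing recovery tests
therefore establish correctness of the estimators under the stated model,
not robustness to every artifact structure of real recordings.

## Behavioural analysis

Exclusions: the first 25 % of trials (staircase burn-in), then missed
trials, then |z(RT)| > 3 computed per subject on the survivors (z ≡ 0 when
the RT distribution is degenerate).  The burn-in can alternatively be
specified in whole blocks (`burn_in_blocks`); the fraction rule is the
default.  A per-rule ledger is kept and must conserve trials.

Confidence is quartile-binned per subject *across all analysed trials*
(not per condition) using order-statistic edges with ties going to the
lower bin — this makes the binning purely rank-based and hence exactly
invariant to monotone rescalings of the confidence scale, and it lets
condition-wise confidence biases survive into the per-condition counts.
With fewer than four distinct values the function falls back to fixed
equal-width bins and warns.

Type-1 SDT uses "right" as the signal response; the log-linear
(+0.5 / n+1) correction is applied only when a rate is 0 or 1.

### Meta-d′

The meta-d′ model places unit-variance Gaussians at ±meta-d′/2, fixes the
type-1 criterion at the observed relative position
(meta-c = c·meta-d′/d′), and fits six response-conditional type-2
criteria (three per side, ordered outward) by maximizing the multinomial
likelihood of confidence counts conditional on the type-1 response.
Criteria are parameterised as exponentiated increments from meta-c
(ordering enforced by construction) and optimized with bounded L-BFGS-B,
5 random restarts, tolerance 1e-8; empty cells are padded with
1/(2·n_bins) (configurable `always`/`never`/`auto`).  Fits are refused
for d′ ≤ 0, where the relative-criterion convention is undefined.

M-Ratio = meta-d′/d′.  **M-Bias** defaults to the mean absolute distance
of the six fitted type-2 criteria from meta-c: larger values mean the
confidence criteria sit farther out on the evidence axis, i.e. more
evidence is required to report high confidence (a conservative confidence
bias).  This operationalisation was chosen over reporting meta-c itself
because, under the fixed relative-criterion convention, meta-c is a
deterministic function of (c, d′, meta-d′) and carries no independent
information about confidence conservativeness, whereas the criterion
spread responds to confidence-bias shifts with the correct sign — which
is what the recovery tests require of a bias measure.  `meta_c` and
`meta_c − c` remain available via `m_bias_definition`.

Estimator validation is dual-route: an independent forward sampler (plain
normal-CDF arithmetic, no shared code with the fitting routine) generates
counts at known meta-d′, and the MLE recovers them within 5 % at 10⁴
trials; M-Ratio is ≈ 1 for ideal confidence, ≈ 0 for random confidence,
and strictly decreasing in injected type-2 noise.

### 2×2 repeated-measures ANOVA

Each effect in the cue×variance design has 1 df, so the classical
within-subject F is computed as the squared paired t of the corresponding
difference contrast (sphericity is moot), with partial
η² = F/(F + df_error).  A test cross-checks the F values against
`pingouin.rm_anova`.

## Physiological preprocessing

Pupil: blinks are samples below 600 a.u. (the threshold is an absolute
instrument-specific value and is configurable; the generator's 3000 a.u.
baseline puts 600 deep below any physiological excursion).  Interior blink
runs are linearly interpolated between flanking reliable samples; runs
touching a recording edge take the nearest reliable value.  The operation
is idempotent and leaves reliable samples bit-identical.  Trials with
> 25 % blink samples are rejected.  Per-trial processing is linear detrend
→ zero-phase 4th-order Butterworth low-pass at 30 Hz (Butterworth chosen
as the standard maximally-flat zero-phase choice; requires fs > 60 Hz) →
rejection of trials whose max |first derivative| (computed after
filtering) exceeds the across-trial mean by 3 SD → subtraction of the
−500…0 ms baseline mean.  Epochs run −500…4166 ms around the forward
mask; partial epochs at recording edges are rejected, never truncated.

Cardiac: ECG is polyphase-resampled to 200 Hz (the rate the Pan-Tompkins
constants assume) and passed through the classic stages — 5–15 Hz
band-pass, five-point derivative, squaring, 150 ms moving-window
integration, adaptive signal/noise thresholds with a half-threshold
search-back when 1.66×RR̄ passes without a beat — then peak positions are
refined to the band-passed R maximum and mapped back to the original
sampling grid.  Artifact flags: 30 s segments with mean HR outside
50–120 bpm, and beats adjacent to any IBI outside 0.45–1.40 s (the bounds
are read as the *normal* range, flags marking excursions outside it).
Instantaneous HR assigns 60/IBI to interbeat midpoints, cubic-spline
interpolates (exactly through the knots), samples a uniform 10 Hz grid,
and holds edge values constant rather than extrapolating.  HR epochs use
a −1000…0 ms baseline (the full second, matching the longer pre-stimulus
window available for the slower signal).

## Trial-wise GLM and cluster inference

Design coding: variance low/high → −1/+1, cue neutral/disgust → −1/+1,
confidence entered raw on its 0–100 scale (binning is a behavioural-model
concern only); interactions are products of the coded columns; every
non-intercept column — nuisance covariates included — is z-scored across
a subject's analysed trials (population SD), so βs are signal units per
1 SD of regressor.  The cue×noise two-way term is included by default
(10 columns; `include_cue_by_noise=False` gives the 9-column variant).
Constant or collinear columns raise errors naming the column.

First level: OLS independently at each time point.  Group level: for each
regressor, a one-sample t across subjects at each time point; separate
positive (t > +2) and negative (t < −2) tests; maximal contiguous
supra-threshold runs form clusters whose extent (sample count; Σ|t| mass
optional) is compared to the permutation null of the *maximum* cluster
statistic under random whole-subject sign flips of the β time course;
`p = (1 + #{null ≥ observed}) / (n_perm + 1)` (the +1 keeps the test
valid and p > 0).  Defaults: t-height 2, 500 permutations, cluster
α = 0.05, recorded seed.  A structural note: with the extent statistic
and a very strong, temporally constant effect, strongly imbalanced sign
flips (probability ~2 % at typical n) also produce full-window null
clusters, so the minimal p of 1/(n_perm+1) is attainable with the mass
statistic but not with extent — the saturated-effect test covers both.
Under a global null the empirical family-wise rate per regressor measures
~0.01 (200 datasets), comfortably below the nominal 0.05: extent-based
cluster tests are conservative because the integer statistic has large
atoms.

Condition means within a significant window are adjusted by subtracting
the fitted contributions of the nuisance regressors (signal mean, RT)
before cell averaging; an optional within-cue median split on confidence
reproduces the illustrative high/low-confidence traces.

## Pipeline, problem sizes, determinism

`RunConfig` (YAML) carries the seed and every module's parameters; all
per-subject random streams derive from `(seed, subject, stream)` tuples,
so outputs are bit-reproducible and independent of execution order.  The
pipeline drops subjects whose physiological chain fails, with a logged
reason, rather than aborting.

Default problem sizes were chosen so a full demonstration (6 subjects,
320 trials, 100 Hz pupil) simulates and analyses in seconds while leaving
every estimator in its asymptotically valid regime; the per-trial epoch
grids and the 640-trial design of the full protocol are available by
config.  The benchmark script uses 20 staircase runs × 2000 trials,
20 full 640-trial sessions, and 200 null datasets (10 subjects ×
300 trials × 100 time points, 200 permutations).

## Known limitations

- No hierarchical/Bayesian meta-d′ and no response-specific meta-d′.
- No deconvolution GLM; overlapping evoked responses are handled only by
  the ≥ 6 s inter-response spacing of the design.
- The pupil blink model is a threshold excursion, not an eyelid/occlusion
  model; the artifact screen consequently sees idealised blinks.
- ECG synthesis is QRS-template-based; detector performance on
  pathological morphologies is untested.
- Group inference assumes exchangeable subjects under sign flip, i.e.
  symmetric null distributions of subject βs.
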