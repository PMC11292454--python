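# Methods

## Pipeline overview

The analysis consumes per-frame multi-person 2-D keypoint detections
(OpenPose dialect: one JSON record per frame, each person a flat
`(x, y, confidence)` keypoint array in COCO-17, COCO-18 or BODY-25 layout)
and produces, per surgical case, six team motion features and their
statistical association with team NOTSS ratings.  Stages:

1. **neck extraction** — each detection is reduced to its neck keypoint
   (index 1 in COCO-18/BODY-25); COCO-17 has no neck, so the midpoint of
   the two shoulders is used with confidence `min(left, right)`.  An
   all-zero keypoint triple is OpenPose's undetected marker and propagates
   as missingness, never as a coordinate.  Coordinates stay in image
   pixels (origin top-left); nothing is normalised by image size.
2. **identity association** — greedy frame-to-frame nearest-neighbour
   assignment of detections to open tracks on neck positions, gated at a
   constant radius `max_jump` (default 100 px).  The gate is deliberately
   not scaled by the elapsed gap, so spurious far-away detections start
   isolated throwaway tracks instead of chaining into phantom members.
   Tracks unmatched for more than `max_gap` frames (default 30 = 1 s at
   30 fps) are closed.  No appearance model, no Kalman filtering: OR roles
   are few and largely station-keeping, and a member returning after a
   shift change legitimately starts a new track.
3. **cleaning** — per track, in order: drop samples below the confidence
   floor (default 0.2); drop samples whose per-frame displacement exceeds
   `median + k_mad x MAD` of the track's displacement distribution
   (default `k_mad` 5, single pass); linearly interpolate gaps of at most
   `max_gap` frames, giving filled samples the minimum flanking
   confidence.  Leading/trailing gaps are never filled.  The pipeline
   additionally discards cleaned tracks shorter than `min_track_s`
   (default 5 s) — fragments and spurious-detection remnants carry no
   usable kinematics.
4. **features** (below), 5. **statistics** (below).

Every stage is a pure function of inputs and configuration; the pipeline
writes each intermediate artifact (tracks.csv, features.csv) so stages can
be audited or resumed, and reruns are byte-identical.

## Motion features

With neck position $p_i(t)$ of member $i$ at frame $t$ and frame rate
`fps`:

| feature | definition | units |
|---|---|---|
| mean displacement | mean of the team displacement series (per-transition mean over members of $\lVert p_i(t{+}1)-p_i(t)\rVert$) | px/frame |
| mean trajectory | mean over members of $\sum_t \lVert p_i(t{+}1)-p_i(t)\rVert$ | px |
| mean speed | mean over members of mean $v_i(t)$, where speed across a $g$-frame span divides by $g/\mathrm{fps}$ | px/s |
| speed variability | time-average of the within-team SD (ddof = 0) of member speeds at transitions with ≥ 2 contributors | px/s |
| mean \|acceleration\| | mean over members of mean $\lvert v_i(t{+}1)-v_i(t)\rvert$ | px/s per frame step |
| displacement entropy | mean per-window Shannon entropy of the symbolised team displacement series | bits |

Conventions: displacement is only defined between samples on adjacent
frames — pairs spanning an unfilled gap are skipped, never counted as zero
motion.  Trajectory is averaged over members, not summed, so team size
does not inflate it.  Acceleration is aggregated as a mean absolute value:
the signed mean telescopes to (last − first)/n ≈ 0 and carries no
information.  All features are invariant under translation and rotation of
the camera frame; the five pixel-valued features scale linearly under
uniform coordinate scaling while quantile-symbolised entropy is scale-free
(these invariances are enforced by tests).

### Symbolic entropy

The team displacement series is discretised into `n_symbols` = 5 bins.
The default scheme places bin edges at the empirical quantiles of the
whole case's series (an `equal_width` scheme over `[min, max]` is
available); a value lying exactly on an edge goes to the higher bin, and a
constant series maps to symbol 0 everywhere.  Edges are estimated once per
case — not per window — so the per-window entropies share one alphabet and
are comparable within the case.  The symbol stream is cut into
nonoverlapping windows of 60 s of frame transitions; each complete window
contributes $H = -\sum_k \hat p_k \log_2 \hat p_k$ and the case value is
the mean over windows.  The trailing partial window is discarded (short
remainders would inject high-variance entropy estimates); a session
shorter than one window falls back to whole-series entropy with a warning.
Base-2 logarithms throughout; the base only rescales entropy and cannot
affect any correlation.

Smooth motion whose intensity drifts on the minutes scale keeps each
window inside a few quantile bins (entropy well below $\log_2 5 \approx
2.32$ bits); temporally unstructured, heavy-tailed motion spreads every
window across the full alphabet.

## Statistics

- **Rater aggregation.** Category score = mean of its 3 items across
  raters; total = mean of the 4 category scores (all in 1–4).  Cases with
  any missing item are excluded with a warning.
- **Interrater reliability.** Mean-measures consistency ICC from the
  two-way mixed model, ICC(3,k) = (BMS − EMS)/BMS, where BMS and EMS are
  the between-cases and residual mean squares of the two-way ANOVA.  The
  residual sum of squares is formed directly from
  $x_{ij} - \bar x_{i\cdot} - \bar x_{\cdot j} + \bar x$ rather than by
  subtracting sums of squares, so per-rater additive offsets cancel to
  exactly ICC = 1 instead of leaving cancellation dust.  95% CI and
  p-value come from $F = \mathrm{BMS}/\mathrm{EMS}$ with
  $(n-1, (n-1)(k-1))$ df (exact F interval).  Incomplete rating matrices
  are handled by listwise deletion.
- **Normality screen.** One-sample KS against a normal with estimated
  mean/SD — the Lilliefors variant (statsmodels), flagged as such; a
  zero-variance feature is reported as non-normal with a degenerate flag.
- **Association.** Spearman rank correlation by default (motion features
  are typically non-normal); Pearson by flag; the method is always
  recorded in the output.  Two-sided p-values, significance at P < .05.
  Five features are tested per analysis with no correction by default, for
  fidelity to common practice in this literature; a Benjamini–Hochberg
  q-value column is available by flag.
- **Adjusted regression.** OLS of the total score on
  `[1, feature, bypass_minutes, morbidity30d]` (statsmodels); reports
  coefficients, SEs, t-based p-values, 95% CIs, R² and adjusted
  R² $= 1-(1-R^2)(n-1)/(n-p-1)$.  Rank-deficient designs are rejected
  naming the collinear columns.

## The cohort simulator

No OR keypoint dataset with paired ratings is public, so validation runs
on simulated cohorts whose generating parameters are returned with the
data.  Defaults emulate the intended study setting: 30 cases, 4-member
teams (surgeon, anesthesiologist, perfusionist, scrub nurse at fixed
anchor positions in a 1920×1080 frame), 30 fps, phase length log-normal
around 480 s (σ = 0.3), 5% missing detections, 1% spurious outlier
detections, 3 raters.

Member dynamics follow a mean-reverting walk around the role anchor:

    x_{t+1} = x_t + λ (anchor − x_t) + a ( κ s_t + (1−κ) u_t )

with reversion rate λ = 0.005/frame, a team-shared smooth innovation
$s_t$ (AR(1), ρ = 0.95, unit stationary variance) and an individual
innovation $u_t = (1-\varepsilon) g_t + \varepsilon j_t$ mixing a smooth
AR(1) component $g_t$ with white Student-t(3) jumps $j_t$.  All smooth
components share one session-wide log-normal amplitude envelope (AR(1)
ρ = 0.9998, σ = 1.0, unit mean): quiet and busy minutes are a property of
the room, not of one member, which is what gives smooth cases low
windowed entropy.  Positions are clipped to the camera frame.  The three
per-case latents drive the features monotonically and are drawn per case
unless fixed: erraticity ε ~ U(0.15, 0.85) → entropy; activity
a ~ 3 px · lognormal(0, 0.4) → trajectory/displacement/speed;
coordination κ ~ U(0.2, 0.8) → (inversely) speed variability.

Ratings are generated at item level.  Latent skill
$S = \sum_f \beta_f\, z(\text{feature}_f) + \mathcal N(0, 0.6)$ uses the
*measured* features (z-scored within cohort); default effects mirror the
study conditions, β = +0.6 on mean trajectory and −0.6 on displacement
entropy, all others 0.  An item score is
`clip(round(3.2 + 0.45 S + bias_r + N(0, 0.5)), 1, 4)` with per-rater
biases ~ N(0, 0.3); the anchor 3.2 places cohort means where experienced
OR teams rate (≈ 3.2 on the 1–4 scale).  Covariates are log-normal on
clinical scales (bypass median 112 min, 30-day morbidity median 6.9%),
independent of skill.

Because the 1–4 scale is discrete and bounded, the expected total score is
a mildly compressive function of the linear predictor, not the predictor
itself:
$E[\text{item}] = 1 + \sum_{k=1}^{3} \Phi\big((\mu + b_r - (k+\tfrac12))/\sigma\big)$
with $\sigma^2$ pooling skill noise and item noise.
`expected_total_score` / `implied_adjusted_coefficients` compute, from
ground truth only, the exact estimand of any single-feature adjusted
regression (the projection of that expectation onto the design matrix,
omitted-variable terms included); recovery tests compare fitted CIs
against these values.  Comparing against the raw linear β would build in a
~10–15% attenuation bias.

### What the simulator does and does not emulate

It reproduces the data's *statistical shape*: role-anchored station
keeping, shared activity bursts, heavy-tailed erratic episodes, detection
dropouts and spurious detections, bounded discrete ratings from noisy
raters linked to latent skill.  It does not model surgical task phases,
appearance, camera geometry, or rater idiosyncrasies beyond additive bias
and item noise — so passing tests demonstrate that the pipeline recovers
structure of this kind when present, not that real OR motion has that
structure.  Simulated raters are also far more consistent (ICC ≈ 0.94 at
the defaults) than the low interrater reliability reported for team-level
NOTSS in practice; the effect-recovery tests require a detectable skill
signal, and a realistic-reliability regime can be explored by raising
`rater_sd`/`rater_bias_sd`.

## Numerical and design choices

- CSV writers use `%.17g` and readers parse with correctly-rounded
  (`round_trip`) floats, so every table round-trips bit-exactly; reruns of
  the deterministic pipeline are byte-identical.
- Quantile bin edges use the default linear interpolation of
  `numpy.quantile`; ties on an edge go to the higher bin.
- Population (ddof = 0) SD for within-team speed variability — the team
  members present *are* the population at that instant.
- Association ties in the greedy tracker break by smaller distance, then
  lower track creation index; assignment is per frame, which equals
  minimum-total-distance matching for well-separated walkers (tested
  against an exhaustive oracle).
- Per-case RNG streams derive from `(seed, case_index)` so any case is
  reproducible in isolation; ratings and covariates use separate streams.
- Replicate studies in the test suite (type-I calibration, sign/coverage
  recovery) use 120-s phases: these questions concern cohort-level
  calibration, and two entropy windows per case retain the full feature
  set at a fraction of the cost.  Cohort sizes match the questions asked
  (30 cases for null calibration, 200 for recovery).

## Known limitations

- The outlier rule's median+MAD threshold is data-dependent, so the
  cleaning pass is not a mathematical fixed point on heavy-tailed motion:
  a second pass can trim more busy-period samples.  It is idempotent in
  the regime it is designed for — regular motion plus clearly separated
  spurious spikes.
- Greedy association cannot survive two members crossing at close range;
  identities may swap.  Team-level features are insensitive to label
  swaps, so this matters only for per-member analyses.
- Features derived from one latent scale (displacement, trajectory,
  speed) are strongly inter-correlated; single-feature regressions on
  cohorts with multiple active effects estimate projections, not partial
  effects.
- With a 17-keypoint skeleton the neck is a shoulder-midpoint surrogate;
  if either shoulder is undetected the position is treated as missing
  rather than fabricated from one side.
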