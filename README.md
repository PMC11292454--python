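# teammotion

Video-based motion analytics for operating-room teams.  The package turns
multi-person 2-D pose keypoints (OpenPose-style output from fixed OR
cameras) into per-case **team motion features** and evaluates their
association with team **nontechnical-skills (NOTSS) ratings** — the
behavioural assessment used for surgical teams (12 items in 4 categories:
situational awareness, decision-making, communication & teamwork,
leadership, each scored 1–4).

It is written for surgical-data-science researchers who have keypoint
detections and expert ratings per case and want a reproducible pipeline
from raw detections to the statistical report, plus a synthetic cohort
generator with known ground truth to validate every stage.

## What it computes

Per team member *i*, with neck position $p_i(t)$ in pixels at frame *t*
(the neck keypoint summarises whole-body position; for 17-keypoint
skeletons it is synthesised as the shoulder midpoint):

- **displacement** $d_i(t) = \lVert p_i(t{+}1) - p_i(t) \rVert$ (px/frame),
- **trajectory** $T_i = \sum_t d_i(t)$ (px, total distance travelled),
- **speed** $v_i(t) = d_i(t) \cdot \mathrm{fps}$ (px/s),
- **acceleration** $a_i(t) = v_i(t{+}1) - v_i(t)$ (signed first difference).

At the team level: the **team displacement** series is the per-transition
mean of member displacements; **speed variability** is the time-average of
the within-team SD of member speeds; and **displacement entropy** is the
Shannon entropy (bits) of the team displacement series after quantile
symbolisation, computed in nonoverlapping 60-s windows and averaged —
low entropy means uniform, predictable team motion, high entropy erratic
motion.

The statistics stage averages NOTSS items across raters, estimates
interrater reliability as the mean-measures consistency ICC from a two-way
mixed model (Shrout–Fleiss ICC(3,k), exact F-based 95% CI), screens
features for normality (Lilliefors KS), correlates each feature with the
total NOTSS score (Spearman by default), and fits ordinary least squares
adjusted for bypass duration and 30-day morbidity risk, reporting adjusted
R².

## Worked example

No intraoperative keypoint dataset with paired ratings is public, so the
repository ships a cohort simulator.  The numbered scripts under
`analysis/` run the whole study on a simulated 30-case cohort:

```bash
python analysis/01_simulate_cohort.py    # keypoints + ratings + ground truth
python analysis/02_extract_features.py   # tracks -> features.csv
python analysis/03_team_statistics.py    # ICC, correlations, regressions
python analysis/04_simulator_checks.py   # ground-truth monotone links
```

The statistics script prints (seed 0 cohort):

```
n = 30 cases; mean total NOTSS = 3.25
ICC(3,k) over 3 raters: 0.939 (95% CI 0.888 to 0.969, p = 1.1e-18)
feature associations with total NOTSS (Spearman):
  mean_trajectory_px           rho = +0.709  p = 0.0000 *
  mean_abs_accel               rho = +0.470  p = 0.0087 *
  displacement_entropy_bits    rho = -0.645  p = 0.0001 *
  ...
adjusted regressions (bypass minutes + 30-day morbidity):
  mean_trajectory_px           coef = +2.846e-05  adj R^2 = 0.433
  displacement_entropy_bits    coef = -1.288      adj R^2 = 0.524
```

The cohort was generated with a positive trajectory effect and a negative
entropy effect on latent team skill, and the analysis recovers exactly that
pattern: teams that travel more and move less erratically are rated higher,
and the effects survive adjustment for the clinical covariates.

The same pipeline runs from the shell on real data:

```bash
teammotion run --keypoints-dir KP_DIR --ratings-csv ratings.csv \
    --covariates-csv covariates.csv --out-dir results/
```

with subcommands `simulate`, `extract`, `features`, `stats` for individual
stages and a YAML/JSON config file mirroring every flag.

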