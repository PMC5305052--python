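# Methods

`rollvection` simulates and analyses roll-plane vection experiments of the
inertial-nulling (IN) / certainty-estimation (CE) type: a rotating
star-field fills the visual field for 1, 4 or 8 s; during the final second
a real roll rotation of the platform is delivered, and the subject reports
the perceived direction of self-motion (clockwise/counterclockwise).
Adaptive staircases drive the inertial velocity toward the point of
subjective equality (PSE) — the inertial velocity at which both reports
are equally likely — so that the visually induced self-motion percept is
measured in physical units (deg/s) rather than on a subjective rating
scale. CE blocks present the same visual stimuli without platform motion
and collect 0–100 certainty-of-self-motion ratings.

## Inertial stimulus

The platform command is a single sine cycle in angular acceleration,

    accel(t) = (π v_peak / T) · sin(2πt/T),
    vel(t)   = (v_peak/2) · (1 − cos(2πt/T)),
    pos(t)   = (v_peak/2) · (t − T sin(2πt/T)/(2π)),

so velocity and acceleration are exactly zero at both endpoints (no
discontinuity in acceleration, velocity or position), peak velocity is
`v_peak` (8 deg/s by default) at mid-stimulus, and the total displacement
is `v_peak·T/2` (4 deg for the default 1-s stimulus). One full cycle is
the minimal profile satisfying all of these constraints simultaneously.
Profiles are sampled (1 kHz default, ≥100 Hz accepted — typical
motion-platform command rates) with velocity/position evaluated from the
analytic integrals, not numerically. Positive = clockwise roll from the
subject's viewpoint, for the inertial and visual stimulus alike. The star
field itself (0.05 cm dots, 0.002 per cm³, 98° horizontal field at 25 cm,
55 deg/s rotation) is carried as metadata only; it is never rendered.

## Observer model

A subject's direction judgment follows a two-parameter cumulative
Gaussian,

    P(CW | v) = λ/2 + (1 − λ) Φ((v − μ_cond)/σ),

with v the signed inertial peak velocity. μ_cond equals the subject's
baseline bias in the three visual-control conditions (darkness, static
stars, zero-coherence stars) and baseline bias + vection shift in the
IN conditions. The lapse rate λ exists in the generative model (default
0) but is deliberately absent from the fitted model, which is the plain
two-parameter fit used in the analysis; this lets tests probe fit
robustness without changing the analysis itself.

Certainty ratings follow a saturating exponential of duration,
`A·max(0, 1 − exp(−(d − t₀)/τ))` plus Gaussian trial noise truncated to
[0, 100]. The functional form is the minimal monotone saturating choice —
the underlying observation being emulated is only that certainty rises
with duration; the onset latency t₀ = 0.5 s is consistent with roll
vection latencies of order 1 s for fast-onset stimuli.

## Cohort calibration

The synthetic cohort (9 controls, 10 migraineurs by default) is
calibrated so that group-level statistics land on the study's reported
values:

- **Mean combined shift** ((PSE_CW − PSE_CCW)/2): migraine 0.045 deg/s at
  1 s and 0.52 deg/s at 8 s (half the reported CW−CCW differences of 0.09
  and 1.04 deg/s), log-duration interpolation at 4 s (a stand-in — no 4-s
  group value is reported); control 0 at all durations.
- **Migraine group baseline** +0.03 deg/s, so the 8-s group PSEs are
  0.03 ± 0.52 = (0.55, −0.49) deg/s, the reported pair. (The reported 1-s
  pair implies a different midpoint; a single duration-independent
  baseline cannot reproduce both, and the 8-s pair is the calibration
  surface.)
- **Between-subject structure**: each subject draws one pair of
  per-direction PSE deviations (u, w) from a bivariate normal with
  correlation ρ = 0.44 (the reported 8-s IN CW/CCW correlation) and
  per-direction variance τ² = 2·Var_combined/(1 − ρ), which makes the
  combined-shift variance at 8 s equal the reported 2.32 deg²/s²
  (migraine) and 0.35 (control) *and* puts the pooled CW-vs-CCW PSE
  correlation near 0.44 at the same time. Deviations scale with duration
  by log₂(d)/3 (0 at 1 s, 1 at 8 s).
- **Thresholds** σ ~ U(0.7, 1.3) deg/s: a realistic roll-velocity
  discrimination scale for healthy adults and consistent with staircases
  that resolve a ~0.5 deg/s shift within 36 trials per condition.
- **Certainty**: subject asymptotes ~ N(60, 20²) clipped to [0, 100],
  with CW/CCW asymptotes coupled at latent r = 0.97 (the reported CE
  correlation); trial noise sd 6 attenuates the *measured* subject-mean
  correlation to ≈ 0.94 with 4 trials per direction.

What the generator does **not** emulate: motion-sickness dropout,
fatigue/adaptation across blocks, lapses (default 0), the single reported
subject with inverted vection direction (representable only as a negative
per-subject shift, not a distinct mechanism), and any duration dependence
of the baseline bias. Passing tests therefore validate the pipeline's
statistical machinery under a faithful, stationary rendering of the
design — not the full richness of human data.

## Staircases

Each IN block interleaves four one-up/one-down tracks — two per VFM
direction, starting at +8 and −8 deg/s (the largest magnitudes
presented) — of 18 trials each (72 total), in a seeded uniformly random
presentation order. A CW report lowers the signed level by the current
step, a CCW report raises it; at each response reversal the step is
multiplied by 0.5, floored at `min_step`. Control blocks reuse the same
machinery with two tracks of 18 (36 trials). Tracks may cross zero.

The schedule itself is an assumption (no published value exists): initial
step 2 deg/s, halving on reversal, floor 1 deg/s. The floor sits at the
population threshold scale deliberately. With a much smaller floor
(e.g. 0.25 deg/s) every post-convergence trial lands within a fraction of
σ of the PSE, where P(CW) ≈ 50% *regardless of σ*: the threshold becomes
unidentifiable, σ̂ collapses in a quarter of simulated blocks, and
resampling confidence intervals become strongly anticonservative
(measured 95% CI coverage of 81–84%). A floor near σ keeps converged
trials near the 16%/84% response levels — the classical optimum for slope
information in up-down procedures — and restores ≈91–92% coverage for
block-level fits.

## Fitting and inference

The proportion of CW reports is fit by maximum likelihood under the
cumulative Gaussian; μ is the PSE and σ the threshold. Probabilities are
clipped to [1e-6, 1 − 1e-6]; σ is constrained to [0.05, 20] deg/s.
Because the model is a probit regression, the likelihood is convex in the
regression coefficients, and iteratively-reweighted least squares reaches
the unique interior optimum; datasets with no interior optimum
(one-category or separated responses) are handled by a deterministic
five-start bounded quasi-Newton search (tolerance 1e-6), flagged
degenerate and never dropped. Perfect separation is detected exactly and
reported as the separation midpoint with σ pinned at its floor.

Uncertainty comes from the case bootstrap: trials resampled with
replacement (pooled over the two same-direction staircases), refit 2,000
times by default, CIs from the 2.5/97.5 percentiles. The CW-vs-CCW
difference is tested by the paired-resample two-sided tail fraction,
p = 2·min(frac(Δ ≤ 0), frac(Δ ≥ 0)), floored at 2/n_resamples, so
non-overlapping resample histograms give the floor p-value; an
independent cross-pair variant is available by flag.

**Known limitation — small-sample calibration.** With 36 adaptive trials
per condition, the PSE estimator's sampling distribution has heavier
tails than either its bootstrap spread or its asymptotic standard error
captures. In simulation the null CW-vs-CCW test rejects at ≈9–11% at
nominal 5%, and an asymptotic Wald test on the same data behaves the same
way — the miscalibration is a property of the design at this trial
count, not of the resampling scheme. Block-level (72-trial) fits are
better behaved (≈91–92% CI coverage at nominal 95%). Per-subject
significance calls from single 36-trial conditions should be read
accordingly.

## Group analysis

Per-subject condition fits are combined into one row per
subject × duration (PSE_CW, PSE_CCW, combined shift, mean CE ratings).
Group statistics mirror the study's: a two-way mixed-design ANOVA
(population between subjects, duration within, subjects nested in
population) computed from sequential nested-projection sums of squares —
the partition SS_total = SS_pop + SS_subj + SS_dur + SS_inter + SS_err is
exact by construction, population is tested against
subject-within-population and the rest against the within-subject
residual; paired t-tests across durations (unpaired by flag); Pearson
correlations; n−1 sample variances. No sphericity correction is applied
by default (a Greenhouse–Geisser correction is behind a flag) and no
multiple-testing correction anywhere, matching the original analysis —
both documented limitations. CE is analysed separately for CW and CCW
rather than combined.

Note that under the default calibration the duration main effect has low
power (≈23% at n = 19): the between-subject combined-shift spread at 8 s
(sd ≈ 1.5 deg/s) dwarfs the ≈0.25 deg/s pooled mean slope. This is a
direct consequence of taking the reported 8-s variances at face value as
combined-shift variances; the subject main effect, by contrast, is
detected essentially always.

## Reproducibility and problem sizes

Every stochastic component takes an explicit seed; identical
(spec, design, seed) yields byte-identical trial tables, and the pipeline
embeds a hash of its canonical config in every results bundle. The
simulation studies shipped with the package use 500 blocks for CI
coverage, 200 replicates for null-rejection and parameter-recovery
studies, and 150–300 replicate cohorts for the group-statistic
calibration checks — sizes at which the Monte-Carlo error of each check
is comfortably below its tolerance.
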