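# Methods

## The task model

The package simulates and analyses a passive Pavlovian reward-learning task
with two interleaved trial types: a *juice* cue predicting an oral juice
bolus and a *visual* cue predicting a neutral visual outcome. On normal
trials the outcome follows the 1 s cue after a 2–4 s delay (juice outcomes
are shifted a further 0.5 s for delivery-hardware latency, and the same
shift is applied to the modeled unexpected-absence window on juice catch
trials). Run 1 contains 54 such trials (27 per type). Run 2 contains 72
trials: 26 normal and 10 *catch* trials per type, in which the cue–outcome
delay is unexpectedly extended to 8–10 s. Catch trials are confined to the
latter 75 % of run-2 trial positions, and a catch trial of a given type is
always followed by at least one normal trial of that type before the next
catch of that type, re-instating the temporal expectation. A catch trial
therefore produces a *negative temporal prediction error* (outcome absent at
the expected time) followed by a *positive temporal prediction error*
(outcome delivered at an unexpected time).

Five event classes are modeled per condition, each 1 s long: cue,
expected outcome (normal-trial delivery), expected absence (2 s after
outcome delivery), unexpected absence (4 s after cue offset on catch
trials, i.e. the end of the typical delivery window, plus the 0.5 s juice
shift), and unexpected outcome (catch-trial delivery).

Choices the task description leaves open, fixed here: delays are drawn
uniformly on a 0.5 s grid within their ranges; inter-trial intervals are
uniform on 4–8 s (same grid, so all onsets align with the TD time bins);
condition order is randomized with at most 4 consecutive same-type trials;
10 s of rest pad each run. The "latter 75 %" rule is implemented as 0-based
trial position >= floor(0.25 × n). The catch-spacing rule is applied within
stimulus type by default (`spacing_across_types=True` gives a strict variant
that also separates catches of different types).

## TD learning model

Each condition is learned by an independent TD(0) learner over a
discretized timeline (bin width `dt` = 0.5 s) with a complete serial
compound (tapped delay line) representation: one indicator feature per
post-cue bin up to a `horizon` of 12 s, enough to span the longest
cue-to-reward interval (1 + 10 + 0.5 s). Outcome onsets of the modeled
condition deliver `reward_magnitude` = 1. With value V(t) = w·x(t), the TD
error of the transition into bin t,

    delta(t) = r(t) + gamma·V(t) − V(t−1),

updates the predictor state's weight, w[x(t−1)] += alpha·delta(t). Defaults
alpha = 0.2, gamma = 0.95 per bin; all parameters are configuration-exposed
and echoed in output metadata. Value carries across the run boundary by
default (run-1 learning establishes the expectations that run-2 catch
trials violate); `carry_across_runs=False` resets it.

Two conventions deserve note. First, the PE trace assigns each transition's
error to its *arrival* bin, so the sample "at cue onset" is the positive
cue-arrival surprise gamma·w0 (the cue itself is unpredictable given
jittered inter-trial intervals); outcome-locked samples are unaffected by
this labeling. Second, each cue onset opens a new episode: the transition
into a cue bin produces the sampled cue PE but does not update the pre-cue
state's weight. Without this cut, inter-trial intervals short enough that
the previous delay line is still active at the next cue let value bootstrap
across trials, and V(cue) overshoots the total future reward — violating
the no-surprise property a converged, perfectly predicted sequence must
have (post-cue |delta| < 1e-3 in the convergence tests; the check excludes
the cue-arrival bin, whose PE never vanishes by design).

Because delays are jittered on normal trials, delivery-time PEs remain
positive even late in learning (delivery time is genuinely uncertain
within the 2–4 s window); unexpected (8–10 s) deliveries land on taps with
near-zero value and produce large positive PEs, while traversal of the
expected window without reward produces negative PEs. PEs are sampled at
cue onsets, expected/unexpected deliveries and unexpected absences — the
points used as parametric modulators.

## First-level GLMs

Designs are built at an oversampled resolution (TR/8) and convolved with a
canonical double-gamma HRF (peak 6 s, undershoot 16 s, dispersions 1,
ratio 1/6) whose kernel is peak-normalized to 1, so that with data scaled
to run mean 100 a unit 1 s event yields a beta in percent signal change.
The *traditional* design has up to 10 task regressors (5 event classes × 2
conditions). The *model-based* design has, per condition, an unmodulated
cue and pooled-outcome main effect plus two parametric regressors — cue
events scaled by cue-onset PEs, and outcome events (expected delivery,
unexpected delivery, unexpected absence) scaled by their PEs — 4 parametric
regressors in total. Modulators are mean-centered within run before
convolution and are *not* orthogonalized against the main effects
(centering keeps |r| < 0.3 on default schedules; an explicit design choice
favouring interpretability). Zero-variance modulators are dropped with a
warning. Per-run intercepts and a discrete-cosine drift basis (128 s
cutoff) complete the design; runs are concatenated with shared task
columns.

Fitting is voxelwise OLS with optional (default-on) Cochrane–Orcutt AR(1)
prewhitening: a single global lag-1 autocorrelation is estimated from
pooled first-pass residuals (a deterministic voxel subsample suffices for
this one number), both sides are quasi-differenced, and the model is refit.
Residual df = n_volumes − rank(X). Rank-deficient designs raise an error
naming the most collinear column pair.

The registry of six group-difference contrasts: (1) juice vs visual cue;
(2) juice vs visual expected outcome; (3) juice vs visual positive temporal
PE (difference of within-condition unexpected − expected delivery
contrasts); (4) juice vs visual negative temporal PE (same for absences);
(5) TD-PE modulation of the juice cue; (6) TD-PE modulation of juice
delivery. The model-based effects are examined per condition on their own
(weights sum to 1), matching how model-based PE encoding is conventionally
tested; the four traditional contrasts are differential (weights sum to 0).
Within-condition component contrasts are exposed as helpers.

## Group inference

One-sample (df = n−1) and pooled-variance two-sample (df = n1+n2−2;
Welch optional) t maps are converted to Z preserving sign and two-sided p.
Cluster-free correction uses classical TFCE (E = 0.5, H = 2, dh = 0.1,
6-connectivity, negative values enhanced on the negated map and re-signed)
with max-statistic permutation FWE within the ROI mask: sign-flipping for
one-sample designs, group-label permutation for two-sample designs, exact
enumeration whenever the number of distinct permutations does not exceed
`n_perm`. The identity permutation is always a member of the null set, so
corrected p >= 1/n_perm and the test is exact-level. This is a deliberate
methodological substitution for parametric probabilistic cluster
enhancement: permutation gives exact FWE control at this problem scale and
needs no smoothness estimation from residual maps. Two significance
conventions are carried through: contrast-wise alpha 0.05 and
experiment-wise alpha 0.05/6 = 0.008333 for the six examined contrasts.

For extreme t values the Z conversion switches to the asymptotic normal
tail inverse when the tail probability underflows; infinite t (zero
variance) maps to Z = ±39 with a flag.

## Brain–symptom association

Per-subject mean percent signal change over an ROI or suprathreshold set is
correlated with symptom scores (SHAPS-C, CAPS emotional-numbing items, TEPS
anticipatory and consummatory scales) by Spearman rank correlation (average
ranks for ties; two-sided p via the t approximation, df = n−2), within the
clinical group. Bonferroni correction across 4 measures × 5 regions gives
the 0.0025 threshold. A voxelwise analog regresses contrast on score and
corrects the slope-t map by score-shuffling TFCE permutation.

## Synthetic cohort

Geometry is a 20×24×20 grid at 3 mm with nine disjoint spherical "ROIs"
(left amygdala, left/right putamen, left pallidum, midbrain, caudate,
pgACC, left/right insula; 20–115 voxels each). BOLD is synthesised only
inside the analysis mask (ROI union dilated by 2 voxels, ~2 700 voxels) —
the same mask all group inference is restricted to; voxel noise is
independent, so this is a marginal of a full-grid simulation. Signal is the
subject's generating design (traditional event classes plus the four
parametric PE regressors, built from the subject's own schedule and TD
traces) times ground-truth betas, on a baseline of 100, plus random cosine
drift (amplitude sd 0.3) and AR(1) noise (marginal sd 1 % signal,
rho = 0.3).

Group-mean betas encode the qualitative pattern the analysis targets:
positive temporal-PE responses (unexpected > expected juice delivery) in
putamen/pallidum/midbrain/caudate/insula/amygdala, negative temporal-PE
deactivation (unexpected absence) in amygdala/putamen/pallidum/midbrain/
caudate/pgACC, positive cue-PE modulation in caudate and insula (negative
in pgACC) and positive delivery-PE modulation across the reward ROIs. The
PTP group is attenuated on the positive temporal PE (putamen_L, pallidum_L,
midbrain, amygdala_L), attenuated on the negative temporal PE (amygdala_L,
putamen_L, pallidum_L), attenuated on delivery-PE modulation (amygdala_L,
putamen_L) and exaggerated on cue-PE modulation (insula_L/R, putamen_L/R).
The between-group shifts (0.20 / 0.30 / 0.16 / 0.15 % respectively) were
calibrated once so the *observed* per-voxel effect size under the default
noise and between-subject variability (sd 0.2 on the varying betas) is
Cohen's d ≈ 0.7 in the affected regions.

Symptom scores are integers on plausible clinical ranges obtained by
monotone binning of Gaussian latents. Within the PTP group the SHAPS-C
latent and the subject's amygdala unexpected-absence beta share a Gaussian
copula whose latent Pearson correlation 2·sin(pi·rho_s/6) makes the
population Spearman correlation between the true amygdala negative
temporal-PE contrast and SHAPS-C equal the configured target (−0.50).
So that the *estimated* contrast keeps this rank correlation, the
generator is constructed to keep extraneous subject-level variance in the
estimated amygdala contrast small: expected-absence betas do not vary
across subjects anywhere, and in the amygdala the other varying betas'
subject sd is shrunk to 0.05 (their unmodeled modulation otherwise leaks
into the traditional unexpected-absence estimate). Remaining attenuation
(measurement noise averaged over ~60 ROI voxels) is a few percent;
pipeline-recovered mean rho is about −0.48 to −0.50.

What the generator does *not* emulate: anatomy, spatial autocorrelation of
noise, motion, physiological noise, slice timing, registration error, and
any behavioural output (the task is passive). Passing recovery tests
therefore demonstrate the correctness and calibration of the analysis
chain under its own assumptions, not robustness to real-data artefacts.

## Problem sizes and numerical choices

Default problem sizes used by the test suite and the acceptance script:
two runs of ~740 s and ~1030 s at TR 1 s (~1 770 volumes), ~2 700 mask
voxels, 45 subjects per group, 500 permutations for group inference, 20
replicate cohorts for the coupling and power checks, and 200 replicates
(12 subjects, single-ROI mask) for the FWE calibration check. Heavy
matmuls run in float32 (float64 available via `dtype=`, used by the
noiseless-recovery tests); normal-equation solves accumulate in float64.
Events map to time bins by the floor convention; intervals are half-open.
The percent-signal scaling convention carries a small known multiplicative
factor (run mean includes task signal, ~1–2 %), which is why recovery is
asserted voxelwise against 2 standard errors rather than to machine
precision.

## Known limitations

- The TD parameter defaults (alpha, gamma, dt, horizon) are explicit
  stand-ins where the task description defers to supplementary material;
  they are echoed in all output metadata.
- pTFCE is intentionally replaced by classical TFCE + permutation; numeric
  Z/p values are not comparable to probabilistic-enhancement outputs, only
  the decision structure (corrected alpha levels) is.
- The traditional design omits the PE-parametric components present in the
  synthetic BOLD, as in the analysis it mirrors; estimated event betas
  absorb a small constant leakage term. Group differences are unaffected
  (the term is common to both groups up to the modeled attenuations), but
  absolute traditional betas are not unbiased estimates of the generating
  betas — the combined design is, and is what the recovery tests fit.
- `run_pipeline` at full default scale (90 subjects × 2 designs × 6
  contrasts × 500 permutations) is a multi-hour desk job; the CLI is meant
  to be driven with scaled configurations, and the tests do so.
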