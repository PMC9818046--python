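# Methods

`tremorlab` implements the computational chain of a between-groups upper-limb
tremor study: psychophysical threshold estimation, tremor signal analysis,
robust group comparison, and causal mediation analysis, together with
synthetic-data generators that give every stage an input with known ground
truth. This note records the models, the parameters that matter, the
numerical choices, and the places where the design was genuinely open.

## Adaptive staircase (module `staircase`)

**Procedure.** Discrimination thresholds are estimated with a transformed
up-down staircase driving a two-alternative forced-choice (2AFC) task. Two
staircases run interleaved: one presents test stimuli below the reference,
one above, each starting at its range bound (the easiest comparison). The
rule is 1-up/2-down with a 2:1 step-size ratio: after two consecutive correct
responses the test stimulus moves one down-step toward the reference; after
any error it moves one up-step (twice the down-step) away. Each staircase
stops at its 6th reversal. The threshold is the mean |test − reference| over
the reversals retained after dropping the first reversal of each staircase —
10 magnitudes for the standard stop rule. Standard configurations: width
(reference 40 mm, test set 25–55 mm on a 1 mm grid, steps 1/2 mm) and weight
(reference 200 g, test set 100–300 g on a 5 g grid, steps 5/10 g).

**Clamping and bookkeeping.** The printed stimulus sets are finite and
exclude the reference, so a down-step that would reach or cross the
reference clamps to one grid increment, and an up-step beyond a range bound
clamps to the bound. A clamp that produces no movement counts as no step:
it can neither create nor break a reversal. The correct-response counter
resets after every step, up or down. The reversal magnitude recorded is the
|test − reference| of the stimulus presented on the reversal trial. Trial
selection between unfinished staircases and reference/test presentation
order are driven by one session-level seeded generator, so a session is
fully reproducible; an independent log-replay function re-derives every step
and reversal from the raw trial log to audit session bookkeeping. A
`max_trials` guard (default 1000) bounds pathological sessions.

**What the procedure tracks.** With equal step sizes a 1-up/2-down staircase
equilibrates where the probability of two consecutive correct responses
equals one half, i.e. at p = √0.5 ≈ 0.707. With the 2:1 up:down step ratio
used here, zero expected drift instead requires p² · s_down =
(1 − p²) · s_up, i.e. p² = 2/3 (p ≈ 0.816). For a psychometric function
rising steeply through threshold the two levels are close in stimulus units
and the reversal-mean estimator lands within one down-step of the 70.7%
point; for shallow functions the estimator sits systematically above it.
Simulation confirms both regimes: with the default steep observer (below)
the mean width estimate over 200 sessions is ≈ 4.66 mm for a 4 mm observer,
while an observer with spread comparable to its threshold yields ≈ 8.6 mm.
The convergence tests therefore use the steep default and the spread
parameter exposes the shallow regime deliberately.

## Simulated observer (module `synth`)

The observer's probability of a correct response is

    P(correct | d) = guess + (1 − guess − lapse) · G(d),    guess = 0.5,

where d = |test − reference| and G is a cumulative Gaussian (location µ,
scale `spread`) truncated at d = 0, so G(0) = 0 (chance at zero difference)
and G → 1. Given `threshold_707` and `spread`, µ is solved numerically so
that P(correct) = 0.707 exactly at `threshold_707` when lapse = 0 — the
level named by the classic equal-step rule. The default spread is
`threshold_707 / 8`, a steep, high-consistency observer for the reasons
above; `lapse` (default 0, capped at 0.1) stress-tests estimator bias.

## Tremor and EMG signals (module `signals`)

**Filtering.** Acceleration and angle signals are band-passed 0.5–40 Hz with
a 4th-order Butterworth applied forward and backward (`sosfiltfilt`):
zero-phase, 8th-order effective magnitude. "Dual-pass" is read as this
forward-backward application. Filtering requires ≥ 5 s of signal and
fs > 80 Hz. One second is trimmed from each end before RMS metrics (the
forward-backward filter rings at the edges with ~2 s time constants from
the 0.5 Hz corner); spectra are computed on the untrimmed series.

**Amplitude metrics.** Postural tremor amplitude is the RMS of the filtered
acceleration (m·s⁻²). Kinetic tremor amplitude is the RMS of the filtered
angle (degrees) within the middle 40° of each 50° wrist ramp (first and last
5° excluded), averaged across the extension/flexion windows. Movement phases
are found on a 1 Hz low-passed copy of the angle (robust to superimposed
tremor): monotone half-cycles spanning at least 45° are windowed between the
±20° crossings; trajectories falling short are segmented best-effort and
flagged. EMG processing: mean removal, 20–450 Hz band-pass (4th order,
zero-phase), full-wave rectification, 40 Hz low-pass, division by the
maximal processed MVC activity.

**Spectra.** Power spectral density by the method of disjoint segments:
non-overlapping rectangular windows of 5 s (trailing partial window
discarded), per-window one-sided periodograms averaged arithmetically; no
tapering or detrending. Resolution is 1/segment-length — 0.2 Hz for the
standard 60 s, 200 Hz postural recording (12 segments). A single full-length
segment reduces to the plain periodogram. Kinetic trials (~40 s of ramps)
cannot supply 12 × 5 s stationary segments, so spectral screening applies to
postural recordings only.

**Screening.** The tremor-band peak is the largest bin in 3–12 Hz, accepted
only if it exceeds 3× the median band power (otherwise "no-peak"). A
weighted-condition peak lower than the unweighted peak by more than one
frequency bin (0.2 Hz) classifies the tremor as "shifted-noncentral"
(mechanical-reflex, e.g. enhanced physiological tremor); otherwise
"central-consistent". Amplitude outliers are values more than k = 3 sample
SDs from their own group mean, with mean and SD computed including the
candidate (no leave-one-out; an all-equal group flags nothing). Note that
including the candidates means two or more comparably extreme values can
mask each other — a known property of the plain k-SD rule, kept because the
rule is applied as stated.

## Robust group comparison (module `cohort`)

Each outcome is modelled as outcome ~ group + grip strength + tactile
acuity; the group coefficient is the adjusted ET-minus-control mean
difference in natural units. The robust fit is two-stage iteratively
reweighted least squares via statsmodels RLM: Huber weights (tuning 1.345)
to convergence, then Tukey biweight (tuning 4.685) warm-started from the
Huber solution, residual scale by normalized MAD, convergence at 1e−8 or 50
iterations. The 95% CI uses the asymptotic standard error at the final
weights with a normal quantile (flagged in the output metadata; a t quantile
is the alternative). An ordinary least-squares difference is returned
alongside. If the OLS fit is perfect (e.g. a constant outcome) the robust
stage is undefined — zero residual scale — and the comparison falls back to
OLS. Inference: a 95% CI strictly containing zero reads "no-difference"
(the degenerate zero-width interval at zero also does). No multiplicity
correction across outcomes; missing rows are dropped listwise.

The two-stage biweight estimator has ~95% efficiency at the Gaussian model,
so on clean data its difference from OLS is random at the ~0.2 standard
error scale at any n (both estimates and their gap shrink as n^(−1/2));
agreement with OLS is therefore assessed as absence of *systematic*
disagreement across replicates, while contaminated-data behaviour is
assessed head-to-head per replicate.

## Causal mediation (module `mediation`)

**Model.** Group status T (control 0, ET 1) affects a primary mediator M
(proprioceptive discrimination threshold), a secondary mediator W (tremor
amplitude under load, causally upstream of M), and the functional outcome Y
directly; grip strength and tactile acuity X confound the mediator-outcome
relations. The estimator is a parametric linear structural-equation system

    W = i_w + c_w T + g_w'X + e_w
    M = i_m + a T + d W + g_m'X + e_m
    Y = i_y + c T + b M + h (T×M) + g W + g_y'X + e_y

with W entered in both the M- and Y-models (the causally dependent mediator
is a post-treatment confounder of M → Y). The average causally mediated
effect at treatment level t is ACME(t) = a(b + ht); the total effect TE is
the T coefficient of Y ~ T + X; ADE(t) = TE − ACME(t); "average" quantities
are the unweighted mean of the two arms (the population-weighted mean is the
noted alternative). With h = 0, ACME + ADE = TE is an algebraic identity of
the linear system, which the tests verify to 1e−10. Fits are ordinary least
squares via an internal solver (validated against statsmodels OLS to 1e−8)
because the bootstrap refits ~10⁵ small regressions.

**Uncertainty.** Nonparametric bootstrap over participants, stratified by
group to preserve the two-arm design; all three structural models plus the
total-effect model are refit per resample; percentile 95% intervals; 1000
resamples by default (min 200); an error is raised if more than 5% of
refits are singular.

**Sensitivity.** The homogeneous treatment assumption — the mediator-outcome
relation differs between arms only through the single coefficient h — is
probed by perturbing the arm-specific M → Y slope per bootstrap draw:
ACME_σ(t) = a(b + ht + ε), ε ~ N(0, σ), over a grid of σ (default 21 points
from 0 to twice the fitted SE of h). Perturbing h alone would leave the
control arm's curve degenerate at t = 0, so the perturbation applies to both
arms' slopes. At σ = 0 the band equals the baseline bootstrap CI. The
breakdown σ per group is the smallest grid value whose band includes zero:
0 when the baseline CI already does, `inf` when no grid value does.

**The model grid.** `run_all_models` runs every combination of the four
functional outcomes × two primary mediators (width, weight threshold) × two
secondary mediators (postural, kinetic weighted amplitude) — 16 models —
with per-model seeds spawned deterministically from one master seed.

## Synthetic cohorts

`generate_cohort` draws X, then W, M, Y in causal order from the structural
equations, with configurable coefficients for every causal arrow, Gaussian
noise per equation, and covariate scales matching typical grip strength
(33 ± 10 kg) and monofilament force (0.25 ± 0.2 g) values. The causal paths
run through `width_threshold` (M) and `postural_rms_weighted` (W);
`weight_threshold` and `kinetic_rms_weighted` are independent redraws of the
same equations — identical marginal structure, not outcome ancestors — and
each outcome column is an affine remap of an independent structural-Y draw,
with signs following the usual clinical directions (ET worse: higher FTM and
peg-test time, lower ABILHAND and block count). Defaults encode a
pure-direct-effect world — no group effect on proprioception (a = 0), strong
group effects on tremor amplitude and function — with 22 control and 20 ET
participants, a realistic size for a two-arm tremor cohort. The
generating coefficients are returned alongside the table so recovery tests
assert against known truth.

Tremor signals are a fixed-frequency sinusoid plus white Gaussian noise with
a seeded random phase; the weighted twin of a pair oscillates lower by
`freq_shift_weighted` (0 emulates centrally driven tremor). Kinetic
trajectories superimpose tremor on an ideal ±25° triangular ramp at 5°/s.
These generators emulate narrowband oscillation over broadband noise but not
1/f sensor noise, amplitude drift, bursting EMG, or movement artefacts —
passing recovery tests therefore demonstrates correctness of the analysis
chain, not robustness to every feature of real recordings.

## Problem sizes and runtime choices

The statistical suites use: 200 staircase sessions for convergence; 300
replicate cohorts of 200 per group with 300 bootstrap resamples for ACME
bias and CI coverage; 500–1000 resamples elsewhere; 200 replicates of
50-per-group cohorts with 10% gross contamination for the robust-vs-OLS
comparison; 30 replicates at 10,000 for the clean-agreement check. These
sizes keep Monte-Carlo error well inside the asserted tolerances.

## Known limitations

- The reversal-mean estimator inherits the 2:1 step-ratio bias described
  above; it is a property of the procedure, reproduced deliberately.
- The mediation estimator is fully parametric and linear; no nonparametric
  or multiply-robust variants, binary/survival outcomes, or >2 mediators.
- The >3 SD screening rule can mask multiple extreme values in small groups.
- Percentile bootstrap intervals for a product of two near-null paths are
  conservative (the classic double-null behaviour of mediation tests).
- Calibration of raw voltages to physical units is supplied, not estimated.
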