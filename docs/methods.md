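# Methods

## The measurement being simulated

`saccs` models an objective, automated test of peripheral contrast
sensitivity (CS).  A Gabor patch (1.4° diameter) appears at one of four
cardinal meridians (0°, 90°, 180°, 270° in the screen frame, mapping to the
nasal, temporal, superior and inferior visual field of a right eye) at one of
three eccentricities (2.0°, 6.5°, 11.0°), with a spatial frequency drawn from
the eccentricity's tested set (0.8, 1.4, 2.2, 4.3 cpd everywhere; 7.2 cpd
added at 6.5°; 7.2 and 10.7 cpd added at 2.0°).  The participant's "seen"
response is the reflexive saccade toward the target, read from a 1 kHz gaze
stream; a keyboard 4AFC judgement of grating orientation provides a parallel
subjective channel, and a separate fixation-maintained session provides a
purely subjective reference.  Contrast placement is adaptive (QUEST+), one
independent instance per meridian.

Because no human or eye tracker is present, a generative observer model
closes the loop.  Everything downstream — gaze classification, adaptive
placement, psychometric fitting, CSF fitting, method agreement — operates
only on the data the observer emits, exactly as it would on recorded data.

## Psychometric model

Detection follows a cumulative Weibull in natural-log contrast,

Ψ(x; m, w, γ, λ) = γ + (1 − λ − γ)·(1 − exp(log 0.5 · exp(c (log x − m)/w))),

with c = log(−log 0.05) − log(−log 0.95) ≈ 4.067, so that `w` is exactly the
5%→95% width of the γ = λ = 0 curve and `m` its 50% point.  The slope is
s = c/w (slope and width are inversely proportional; the product form would
grow with shallower curves and is dimensionally not a slope).  The threshold
contrast is CT = e^m, sensitivity CS = 1/CT, and all reporting uses
log10 CS.  The guess rate is fixed by response mode — 0 for the yes/no
saccade channel, 0.25 for 4AFC keyboard — and the lapse rate defaults to a
conventional 2%.

## QUEST+ engine

Each meridian's engine keeps a posterior over a 15 × 11 grid: thresholds at
the natural logs of 15 contrasts geometrically spaced from 0.024% to 66%
(the same 15 contrasts are the stimulus domain) and slopes 0.5–5.5 in steps
of 0.5.  The prior is uniform; asymptotes are fixed, not gridded.  After each
binary outcome the posterior is multiplied by the Weibull likelihood and
renormalised.  The next stimulus minimises the expected Shannon entropy of
the posterior, with the two outcome branches weighted by their probability
under the current posterior; ties break deterministically to the lowest
contrast.  Stopping is a fixed budget of 30 trials per meridian (120 per
session), never an entropy criterion, so every simulated participant yields
the same amount of data.

## Gaze classification

Fixation must stay within 1° of the screen centre (40 px/° in the default
62 cm geometry).  The first valid sample strictly beyond that radius defines
the saccade; its direction is β_g = atan2(y − y_c, x − x_c) in the raw
screen-pixel frame.  Target meridians are expressed in the same frame, so
the y-down convention cancels.  A response is correct when the circular
distance between β_g and the target meridian is ≤ 22.5° (inclusive
boundary), giving four disjoint 45° acceptance cones.  Landing points,
velocities and amplitudes are deliberately not used.  The response window is
the 500 ms presentation limit plus a configurable 500 ms post-stimulus
grace (answers were allowed after stimulus expiry; whether late saccades
counted in the original procedure is unrecorded, so the grace is a
parameter).  An invalid-sample run (blink) anywhere in the window voids the
trial: its parameters are re-queued and the remaining order reshuffled.

## Trial scheduling

A session holds 120 target trials with exact margins — 30 per meridian and
30 per orientation (45°, 90°, 135°, 180°).  Joint balance is impossible
(120/16 = 7.5), so a random 4×4 integer table with all margins 30 is built
from the near-uniform 7/8 table plus random margin-preserving 2×2 transfers,
then fully shuffled.  Saccadic sessions interleave 12 catch trials (no
target) at uniformly random positions, for 132 trials; catch trials follow
the full workflow but never update QUEST+.  Non-saccadic sessions have no
catch trials.  Fixation durations are uniform on [500, 650] ms (the source
range is stated without a distribution; uniform is the minimal choice).
The keyboard mapping fixes orientation 45°→keys 1/9, 90°→2/8, 135°→3/7,
180°→4/6.

## The simulated observer

Ground truth is a log-parabola CSF per (meridian, eccentricity):

CS(f) = log10 γmax − log10 2 · ((log10 f − log10 SFmax)/(β/2))².

Defaults place peak log10 sensitivity between 1.28 (inferior, 11°) and 1.69
(nasal, 2°), ordered nasal ≈ temporal > superior > inferior and decaying
with eccentricity — the qualitative anisotropy of the parafoveal field;
peak frequency falls from 2.4 to 1.1 cpd across eccentricities and the
bandwidth is 2.2 log10 units.  The detection threshold at frequency f is
m = −ln 10 · CS(f); detection is Bernoulli with the Weibull above
(slope 3.0, lapse 2%).

Saccade latency is base + gain·exp(−contrast/scale) + N(0, σ), defaults
200 ms + 400 ms·exp(−c/0.1) ± 50 ms, floored at 80 ms.  These values make
high-contrast saccades fast (~200 ms) and near-threshold saccades slow
enough to straddle the 500 ms presentation limit; a detected stimulus whose
latency exceeds the limit launches no saccade (the stimulus is already
gone), while the keyboard answer still benefits from the percept.  This is
the mechanism by which the saccade channel reads systematically lower CS
than the keyboard channels, and the latency parameters are calibrated for
that qualitative behaviour only — no quantitative latency data underlie
them.

Fixational jitter is white Gaussian (σ = 0.12°), far inside the 1° radius.
On catch trials a large fixational excursion (amplitude 1.5–3°, uniform
direction, per-trial probability 0.043) escapes fixation and registers as a
false positive.  Blinks (per-trial probability 0.02) appear as ~120 ms runs
of invalid samples.  Saccade direction noise is Gaussian with σ = 5°, so
nearly all true detections land inside the ±22.5° cone.

`cohort_observer` draws participants around this template: a shared
peak-sensitivity shift N(0, 0.15 log10 units), per-location deviations
N(0, 0.05), ±10% peak-frequency jitter and an individual slope
(N(3.0, 0.5), clipped to [1.5, 5.5]).  Without between-participant variance
a simulated cohort of identical clones would understate the cross-cell
spread that drives method correlations in any real group.

`ObserverModel.on_grid` is the idealised configuration for estimator
checks: a fixed threshold and slope sitting exactly on the QUEST+ grid,
near-instant contrast-independent latencies, and no blinks or false
positives, so that any recovery failure is attributable to the estimation
machinery rather than the response periphery.

What the simulator does **not** emulate: saccade main-sequence dynamics,
curvature and landing-point scatter, microsaccades, pupil effects, drift in
tracker calibration, learning or fatigue across a session, and attention
differences between modes.  Passing tests therefore demonstrate the
correctness and statistical behaviour of the measurement machinery under
the stated generative assumptions, not the clinical performance of the test
on real eyes.

## Fitting

Per cell (participant × channel × meridian × eccentricity × frequency) the
contrast-wise response rates are fitted by binomial maximum likelihood over
(m, w, λ): γ fixed by mode, λ bounded in [0, 0.1], L-BFGS-B from a 5 × 4
multistart over threshold and width, probabilities clipped at 1e−9.
All-correct or at-chance tables are unidentifiable; the threshold is clamped
to the sampled contrast range and flagged, and flagged cells are excluded
from downstream summaries.  CSF fitting is bounded least squares on
(log10 γmax, log10 SFmax, β) with deterministic multistarts; SFmax is
constrained to [min f/2, 2·max f], β to (0, 4], γmax to [1, 10⁴].  No
low-frequency truncation is applied to the log-parabola.  Mean CSFs average
log10 CS across participants per frequency before fitting.

## Agreement analysis

Cells with all three channel estimates form the triplet table.  Pearson
correlations use the standard product-moment statistic; Bland–Altman bias is
the mean paired difference with limits of agreement at ±1.96 sample SD (the
conventional multiplier).  Omnibus cohort tests (Friedman, ANOVA) are out of
scope as bespoke code; the tidy triplet table is the interface to standard
routines.

## Problem sizes and determinism

The acceptance script and test suite size their simulations for a single
CPU: threshold recovery uses 200 independent 30-trial runs; closed-loop
recovery uses 100 full 132-trial sessions; the false-positive check uses
10,000 catch trials; the agreement cohort is 4 participants × 15 conditions
× both modes (120 sessions).  Threshold-recovery checks sample the
observer's default slope (3.0) and interior grid thresholds: a slope of 0.5
corresponds to a width of 8.1 natural-log units — wider than the whole
7.9-unit threshold grid — and is not identifiable within a 30-trial budget,
and thresholds at the extreme grid cells saturate against the stimulus
range; neither reflects the estimator.  Every stochastic stage takes an
explicit seed and all artifacts record it.
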