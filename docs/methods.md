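# Methods

`runload` estimates the external load of running from a waist-worn
tri-axial accelerometer, validates that estimate against force-plate
vertical ground reaction force (vGRF), and quantifies how much of a
session's cumulative load GPS-style spatiotemporal parameters can explain.
This note documents the models, the parameters that matter, the synthetic
data the analyses run on, and the numerical choices made where the design
was open.

## Signal model and extraction pipeline

**Filtering.** Force-plate data (1000 Hz) are low-pass filtered with a
third-order Butterworth at 45 Hz — high enough to keep impact transients.
Marker kinematics (200 Hz) use a 20 Hz cutoff, applied to displacement and
again to velocity before each differentiation. Filtering is zero-phase
(forward-backward) by default: the protocol names order and cutoff but not
phase handling, and zero-phase preserves peak timing, which the step
matching depends on. The price is that the effective magnitude response is
the square of the one-pass response — gain 1/2 instead of 1/√2 at the
cutoff — which is documented in `FilterSpec` and switchable off.
Forward-backward filtering pads by odd reflection over 3·(order+1)
samples; traces shorter than three such spans are rejected rather than
padded silently.

**Differentiation** uses central differences (second-order accurate,
delay-free) with second-order one-sided stencils at the ends. The
truncation error for a sine of angular frequency ω sampled at step h is
ω·(1 − sinc(ωh)) ≈ ω³h²/6 in the interior and roughly three times that at
the boundary samples; tests assert at exactly these closed-form levels.

**Stance segmentation.** The reference detector marks a foot contact
wherever vGRF exceeds 50 N, emitting maximal supra-threshold runs as
stance intervals. Runs shorter than 0.08 s or longer than 0.6 s are
rejected (treadmill-start artifacts, walking); contacts truncated by the
recording boundary are dropped because their peaks are biased. The
accelerometer-only detector — the only one available outdoors — finds
local maxima of the 10 Hz-low-passed vertical channel above 1.4 g,
separated by a 0.25 s refractory period (caps cadence at 240 steps/min),
and emits a fixed 0.30 s window centered on each impact peak. All three
constants are configuration parameters; the fixed-window stance proxy is a
design choice, since an event-based contact/toe-off detector cannot be
reconstructed from the available description.

**Alignment.** The IMU clock is aligned to the force/marker clock by
cross-correlating the IMU vertical channel against marker-derived
acceleration (filter → differentiate → filter → differentiate). The lag
estimate is normalized and mean-removed, hence invariant to units (g vs
m/s²) and offsets; ties break toward the smallest |lag|, then negative, so
the result is deterministic.

**Per-step features.** vGRF is normalized to body weight (standard gravity
fixed at 9.81 m/s²). The *active* vGRF peak is the maximum over the 40–60%
stance window — floor on the lower index, ceil on the upper, both
inclusive, so the window is never empty — which excludes the early impact
transient; this exclusion is the point of the window and is tested with a
constructed bimodal stance. Trunk peaks are taken over the full stance:
the vertical channel as the signed maximum (impact peaks are large and
positive; typical running values 2.7–3 g with gravity included), ap/ml as
maximum absolute value (small, sign depends on footedness and lean). Both
conventions are switchable (`signed_vertical`, `remove_gravity_offset`);
the defaults are an interpretation, since "peak positive" and "maximum
absolute" conventions conflict in parts of the literature. An alternative
reading that restricts the vertical peak to an early-stance impact window
is available by passing a narrower stance to `peak_accelerations`.

## Load statistics

Cumulative load of a session is the sum over steps of the vertical peak
acceleration, in g — a volume × magnitude statistic: identically
n_steps × mean peak. Session SD uses the n−1 denominator. Runner pooling
averages session statistics unweighted; "more than two sessions" is read
literally as ≥ 3 (the `min_sessions` parameter exposes ≥ 2). The pooled SD
is deliberately the *mean of per-session SDs* — a within-session
variability summary — not the variance-weighted combination; the
conventional pooled SD is provided separately as
`conventional_pooled_sd` to avoid ambiguity. The 9th-power-weighted load
variant used elsewhere in the literature is out of scope.

## Statistical layer

The model grid regresses session cumulative load on the eleven predictor
subsets of {duration (min), distance (km), speed (m/s), steps} that the
cohort analysis tables use, by OLS with intercept; R² is unit-invariant
but coefficients are not, so the km/min unit convention matters only for
coefficient readouts. LOSO-CV holds out one runner at a time, fits on all
other runners' sessions unweighted, and predicts the held-out sessions.
Errors aggregate in two steps — mean |error| within runner, then
unweighted mean across runners — so runners with many sessions are not
overweighted; the mean true load in the relative-error denominator uses
the same two-step procedure (a pooled-mean alternative exists but is
non-default). The LOSO implementation is verified against a brute-force
per-fold refit with an independent minimal least-squares oracle to 1e-8.
No multiple-testing correction is applied anywhere; none is called for by
the descriptive design.

## Synthetic data: what it emulates and what it does not

**Treadmill trials.** Each step is a half-sine vGRF stance (apex at 50%
stance, so it sits inside the 40–60% window) with an optional
exponential-decay impact transient at 15% stance; flight phases separate
steps at a fixed cadence (170 steps/min default, stance 0.25 s). Per-step
peak amplitudes are Gaussian with speed-interpolated means/SDs
(2.44/2.71/2.85 BW at 2.22/3.33/4.44 m/s). The vertical IMU burst peak is
an affine map of the step's true vGRF peak (slope 0.794 g/BW, intercept
0.800 g — least-squares calibration to the per-speed magnitude table)
plus Gaussian mapping noise. The mapping-noise SD is derived in closed
form from a *target population r²* (default 0.797) and the pooled
three-speed vGRF variance, which makes r²-recovery tests non-circular: the
pipeline must re-estimate a parameter the generator set analytically. One
consequence of pinning slope, intercept and r² is that the per-speed ACC_v
SDs are implied (~0.22–0.28 g) rather than independently calibrated.
Marker displacement is a train of Gaussian bumps whose second derivative
peaks at the burst apexes; a constant 11-sample lag is inserted into the
IMU timebase and must be recovered by the alignment step. Envelope maxima
are rescaled to hit the drawn peak values exactly on a sample, so with
noise off the extraction pipeline must reproduce truth identically.

The waveform family is the simplest shape that makes the windowed-peak
semantics meaningful; it is not a claim about real GRF morphology. Real
signals add baseline drift, asymmetry between feet, soft-tissue artifact
and nonstationary cadence, none of which are modelled — passing tests
demonstrate correctness of the extraction and statistics, not field
validity of the sensor.

**Outdoor cohort.** 96 runners; session counts are a mixture (40% log 1–2
sessions, the rest 3 + Poisson(5)), giving ~500 sessions with roughly 60%
of runners qualifying for pooling. Each runner has a persistent loading
style: a log-normal mean vertical peak (median 5.54 g, log-SD 0.25,
calibrated to a plausible 3–10.5 g cohort range), with a designated 3/96
fraction of heavy styles drawn above 10 g — emulating the observation that
a few runners consistently load very high, which is what gives step count
alone limited explanatory power. Durations are log-normal (median 42 min),
speeds normal around 3.0 m/s clipped to [2.0, 4.65]; distance =
speed·duration exactly and steps = round(cadence·duration) exactly, so the
bookkeeping is self-consistent by construction. Cadence is linear in speed
(150 + 10·speed) plus a persistent runner offset (SD 15 steps/min) and a
small session jitter (SD 3): between-runner cadence variation is what
separates the steps-only model from the duration-only model in the grid,
mirroring real cohorts where cadence differs across runners at equal
speed. Per-step peaks are i.i.d. normal around the (slightly jittered)
runner mean, truncated at zero; the truncation bias is negligible at the
configured scales and is measured in a test. Because the runner mean is
independent of speed, the speed-only model's R² is near zero by design.

The synthetic cohort reproduces the qualitative structure — singleton R²
ordering steps > duration > distance > speed, full model at the grid
maximum — but its absolute R² (~0.8 full model) runs higher and its LOSO
relative error (~21%) lower than in field data, where surface, fatigue and
day-to-day variation add unexplained variance the generator does not
model.

## Problem sizes and determinism

The analyses run the indoor validation at 3 × 1,386 = 4,158 steps (the
full protocol scale) and the outdoor analysis at the full default cohort;
both complete in seconds. All randomness flows through
`numpy.random.default_rng` seeds carried in the parameter objects;
regenerating with the same seed is byte-identical, and every report embeds
its resolved configuration and seed.

## Known limitations

- No tilt correction or sensor-fusion orientation estimation; accelerations
  are used in the sensor frame, gravity included.
- No left/right attribution, no walking/running classification, no
  gap-filling of marker dropouts.
- Sessions must carry a step stream; metadata-only sessions (sensor
  dropout) are not represented.
- The accelerometer stance is a fixed window around the impact peak, not
  an initial-contact/toe-off segmentation.
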