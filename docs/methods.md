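# Methods

## Signal model of the synthetic sessions

Each session is a continuous multichannel record at 250 Hz (1000 Hz is
supported; 250 Hz keeps desk-scale runs fast with the 8–26 Hz control band
far below Nyquist). Two rhythm sources sit at the canonical C3/C4 positions
on the unit-head disc. Source *i* emits

    s_i(t) = e_i(t) · [ sin(2π f_mu t + φ1) + 0.5 · sin(2π f_beta t + φ2) ],

with f_mu = 10 Hz, f_beta = 20 Hz, and a log-normal envelope e_i(t):
a random walk on log-amplitude (diffusion 0.3 per √s) reflected into
amplitude bounds [0.5, 2]. The envelope is what gives band power realistic
trial-to-trial variance; without it the r² and CV analyses would see a
degenerate, near-deterministic feature distribution.

Event-related desynchronization: during cue + feedback of a right-hand trial
the C3 source amplitude is multiplied by (1 − `erd_depth`), and symmetrically
for left-hand trials at C4. The gate spans cue onset through the feedback
deadline because subjects begin imagery at the cue, before the cursor
appears. `erd_depth` is the single effect-size dial: 0 produces label-free
recordings, 1 silences the contralateral source completely. No published
estimate pins the physiological value, so the package's default (0.5) is a
moderate depth at which decoding is good but imperfect; the calibration
suite exercises the two anchor conditions 0 (chance) and 0.8 (near-ceiling).

Channel signal = Σ_sources gain × source + noise, with Gaussian
volume-conduction gains exp(−d²/2σ²), σ = 0.25 in layout units (next-nearest
electrodes receive ~73% gain, the vertex ~28%, the opposite hemisphere
essentially none). Noise is per-channel 1/f (power exponent 1, the canonical
EEG background slope), spatially smoothed across channels with a Gaussian
kernel (σ = 0.15) row-normalized to preserve per-channel variance. The
noise amplitude is calibrated per session so that the 8–26 Hz rhythm-to-noise
power ratio at C3 equals `snr` (default 1; the "high SNR" condition used for
parameter recovery is 5). An occipital 10-Hz distractor source (on by
default) emulates non-sensorimotor activity that data-driven spatial filters
can latch onto.

What the generator does **not** emulate: eye-blink/EMG waveform morphology
(artifacts are broadband bursts defined only by their dB deviation contract),
electrode drift and impedance changes, inter-subject anatomical variability,
and — by default — within-subject learning (an optional knob drifts
`erd_depth` upward across sessions). Passing tests therefore demonstrate
correctness of the decoding and evaluation machinery under the assumed
signal model, not robustness to every pathology of real EEG.

## Electrode geometry

The 64-channel 10-10 layout is idealized: azimuthal-equidistant projection
with Cz at the origin, head rim at radius 1, the standard 10% circumference
ring at 0.8, midline electrodes at 0.2-radius steps, and lateral electrodes
linearly interpolated between midline and rim along their row. Only relative
distances enter the model (mixing gains, Laplacian stencils, noise
smoothing), so digitized head coordinates would add nothing. The 40-channel
interior montage (full F/FC/C/CP rows plus P3/Pz/P4/POz) and the 9-channel
montage (union of the C3/C4 large-Laplacian stencils) are explicit,
overridable constants; published montage figures are not machine-readable,
so these sets are faithful stand-ins documented here.

## Decoding pipelines

**CSP.** Class covariances are averages of per-trial trace-normalized
covariances with diagonal loading (1−λ)Σ + λ(tr Σ/n)I, λ = 0.05 — needed to
condition 40×40 covariances estimated from 50 trials of 2-s segments. The
generalized eigenproblem Σ_L w = λ(Σ_L+Σ_R) w is solved directly
(`scipy.linalg.eigh`); three filter pairs are kept from the two ends of the
eigenvalue spectrum. Features are log variances (the log makes the feature
distribution near-Gaussian for LDA). Filters are sign-fixed (largest-|w|
element positive) so repeated fits are bit-reproducible; eigenvalue ties are
broken by stable sort. Training epochs are the 2-s segment right after
cursor onset — also for the calibration run, where no feedback is shown, so
that online training and offline CV use the same segment definition.

**LDA.** Pooled-covariance closed form w ∝ Σ⁻¹(μ_R − μ_L) with the same
shrinkage style, bias at the class-mean midpoint (equal priors), and output
scaled to unit variance on training decisions so the CSP pipelines'
velocity scale is commensurate with the Laplacian pipeline's z-scored
control signal.

**LAP/S.** The "linear classifier" is the fixed equal-weight log-power
difference log P(C4) − log P(C3) (positive ⇒ rightward, since right-hand
imagery suppresses C3); the weights are configurable. AR band power uses the
Burg method, order 16, over a 0.5-s trailing window — the common mu-rhythm
convention — integrated over 8–26 Hz on a 0.25-Hz grid. A constant window
returns zero power by convention; log arguments are floored at 1e−12. The
adaptive normalizer keeps a trailing 30-s buffer of raw control values
(one per 0.1-s block) and z-scores each new value with the buffer statistics
*before* absorbing it; with fewer than two values, or variance below 1e−12,
it returns 0.

## Closed loop

Control blocks are 0.1 s. The cursor integrates position += gain · control
· dt with gain = 1/3 s⁻¹, chosen so a sustained unit control value crosses
the center-to-target distance in 3 s — half the 6-s budget, keeping typical
trials comfortably inside the cap. The screen is 1-D with targets at ±1 and
the full boundary acts as the target. A boundary test tolerance of 1e−9
prevents float accumulation from deferring an exact crossing by one block.
Online filtering is causal (the offline analyses use the zero-phase variant
of the same 4th-order Butterworth filter); decode windows trail the current
block boundary and may reach back into the cue period, exactly as a
streaming implementation would see.

Calibration: CSP pipelines freeze the whole first run and batch-retrain
after every run on the trailing two runs; LAP/S freezes only the first trial
of each run for normalizer calibration. Everything downstream of the
generator is deterministic, so (config, seed, decoder kind) fixes the trial
log bit for bit.

## Offline evaluation

Trial rejection compares the feedback-period Welch spectrum (1-Hz bins,
Hann, 50% overlap) per channel-frequency bin in 7–35 Hz against a baseline
and rejects beyond ±35 dB, or when feedback lasted under 2 s. The baseline
is the median across trials of the rest-period (0–3 s) spectrum, median
because the estimator must resist the very artifacts being detected. The
per-bin (rather than band-aggregate) test is the stricter reading and is the
default; both choices are exposed.

r² maps large-Laplacian-reference every channel (canonical stencils at
C3/C4; elsewhere up to four neighbors nearest the 0.4-unit next-nearest ring,
rim channels left unreferenced), take trial-wise log band power over the
feedback period, and square the point-biserial correlation with the class
label. Log power is variance-stabilizing and makes the map invariant to any
global gain. Cross-validation is stratified 5-fold, 5 repeats with
explicitly seeded partitions; CSP and LDA are fit on training folds only,
and a deliberate leakage oracle (fit on everything) is kept in the tests as
the contrast that validates fold honesty. Weight traces follow the
top-eigenvalue filter (documented choice; the ranking makes it the most
interpretable), sign-aligned to the first run because CSP filters are
sign-ambiguous, unit-normalized, with run-to-run standard deviation as the
dispersion statistic.

## Problem sizes and determinism

Default sessions are 10 runs × 25 trials. The calibration suites use:
chance-level closed-loop PVC pooled over seven null sessions (>500 valid
outcomes) against exact binomial bounds; null CV on 200 trials; parameter
recovery over five seeds; the monotonicity sweep over erd_depth ∈
{0, 0.2, 0.4, 0.6, 0.8} with five seeds per level (three in the acceptance
script). A single global seed fans out to named sub-seeds (schedule,
envelopes, phases, noise, artifacts, CV partitions), so each component is
independently reproducible and two runs with the same configuration produce
byte-identical exports.

## Known limitations

The simulated subject has no volition: control quality is fully determined
by `erd_depth`/`snr`, so behavioral phenomena that arise from human learning,
motivation or fatigue are outside the model (the per-session `erd_depth`
drift knob can mimic a learning trend but not explain it). EDF export is
16-bit, so round-trips quantize at ~1e−5 of the signal range. The 40-channel
set is a documented stand-in for cap-specific montages. Group-level
statistics (mixed models, ANOVA) are deliberately out of scope — the
exported per-trial logs are designed to feed standard statistics packages.
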