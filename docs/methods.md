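# Methods

`sonokin` implements a desk-scale replica of a multimodal feasibility
study: can joint kinematics be decoded from B-mode muscle ultrasound
(sonomyography, SMG) and from surface EMG, under volitional and
FES-driven movement, with all data streams synchronized after the fact by
shared reference pulses? Because such studies' recordings are rarely
shareable, the package ships a synthetic-data generator that plays the
role of the recordings; every downstream stage is exercised and tested
against it, and real data in the same formats can be substituted
trial-for-trial.

## The synthetic study conditions

A trial is 90 s of alternating full range-of-motion movement of one joint
(wrist or ankle), paced at 60 bpm: one end-state-to-end-state movement per
beat. The normalized motion-completion level θ(t) ∈ [0, 1] (θ = 1 ≡ full
extension, the stimulated/decoded direction) is a sequence of raised-cosine
transitions between holds. The transition takes 0.6 s by default: a paced
human full-ROM movement occupies roughly half the interbeat interval, and
the trajectory's slope is what couples synchronization error into tracking
error (see *Error budget* below). Per-cycle end-state scatter (σ = 0.05)
and onset jitter (σ = 30 ms) emulate human pacing variability; the trace
is min-max normalized per trial so motion completion is defined over the
trial's own range of motion, as it is when motion capture defines it.

Four modalities record simultaneously, each on its own clock (offset
uniform within ±50 ms, optional linear drift, default 0):

- **Motion capture**, 100 Hz: θ plus Gaussian marker noise (σ = 0.005).
- **Surface EMG**, 2000 Hz, extensor and flexor: activation × band-limited
  (20–450 Hz) Gaussian carrier + baseline noise. Activation is a burst
  spanning each movement (extensor on extensions, flexor on flexions), so
  EMG amplitude encodes movement *effort*, not position — the premise that
  separates the modalities. Under FES-ON, a biphasic rectangular pulse
  train (250 µs phases, 30–35 Hz, 1 s ON / 1 s OFF aligned to the
  stimulated extensions) is added at an amplitude far above the ADC full
  scale and the sum is hard-clipped, emulating amplifier saturation.
- **EEG-surrogate**, 1000 Hz: noise; exists only to carry the pulses, as
  the study's EEG channel does for synchronization purposes.
- **Ultrasound**, 5 fps: a speckle phantom (Rayleigh texture smoothed by a
  Gaussian point-spread kernel — B-mode-like statistics, not an acoustic
  simulation) warped by θ through an affine model (vertical compression up
  to 20% at θ = 1 plus lateral shear up to 8%; identity at θ = 0,
  injective in θ), plus per-frame probe jitter (σ = 1 px translation) and
  additive noise (σ = 0.15 of the intensity range), quantized to 8 bits.
  Two 1-s end-state training stacks (θ = 0 and θ = 1) accompany each
  trial. The bottom 8 rows of every frame are a reserved ROI where the
  synchronization pulse is rendered, emulating the ECG-channel trace
  overlay; the ROI is masked out of all decoding.

The frame-noise and probe-jitter defaults were set so that the default
conditions reproduce the error scale reported for SMG tracking in
clinical-system studies (mean normalized RMSE ≈ 0.10–0.25); they are study
conditions, not tuning knobs, and the noise-free configuration
(`TrialConfig.noise_free()`) zeroes all of them.

Two reference pulses (default emission at 2 s and 12 s) reach every
device; each 1-D stream records them on a dedicated trigger channel at the
first sample at or after arrival, and the ultrasound stream lights its ROI
from the first frame time-stamped at or after arrival. Recording error is
therefore bounded by one sampling period per stream by construction.

What the generator does **not** emulate: acoustic wave physics,
out-of-plane probe motion, electromechanical delay between EMG and
movement, spasticity or altered recruitment, FES-frequency wander
(the stimulation train is strictly periodic, so comb filtering works
better here than on hardware stimulators without closed-loop control),
and EEG content. Passing tests therefore show the pipeline's correctness
and its behaviour under the stated conditions — not performance on any
particular clinical recording.

## Synchronization

All streams are shifted so the first detected pulse lands at t = 0; the
extensor EMG stream is the reference, so its residual is identically 0.
Pulse detection is half-amplitude threshold crossing (the pulses are
high-SNR square edges; detections within 0.5 s merge into one episode).
The second pulse verifies timekeeping: the residual Δ = P₂(stream) −
P₂(EMG) must satisfy |Δ| ≤ stream period + EMG period (the reference
term, 0.5 ms, accounts for the reference's own quantization). A failed
bound flags clock drift — a warning, not an exception. Streams keep their
native rates after alignment; the pairing rules make global resampling
unnecessary.

### Error budget

The ultrasound stream's pulse quantization (up to one frame period,
0.2 s at 5 fps) is the dominant, irreducible synchronization error; it
shifts the ultrasound time base relative to motion capture by a per-trial
constant δ ∈ [0, 0.2] s. For a trajectory with transition width w, the
induced mean-squared tracking error is ≈ δ²·π²/(8w) per movement second,
so pipeline RMSE against motion capture includes a floor of ~0.1–0.2 even
for a perfect decoder. This is why the evaluation distinguishes *pipeline*
scores (prediction vs motion capture after alignment and pairing — what a
real study can measure) from *parameter-recovery* scores
(`pipeline.score_against_truth`, prediction vs the generator's θ on the
true clock — pure decoder quality). It also affects the cross-validated
LDA asymmetrically: its training labels come from the shifted motion
capture, so rising and falling transitions are labeled contradictorily
and mid-transition posteriors flatten; the decoder is trained and scored
on the same shifted reference, so the comparison across methods stays
fair.

## Ultrasound decoders

All three use only the current frame — no temporal context — matching the
responsiveness-first design the proportional-control literature uses.

- **Correlation (proportional signal).** `corr2` is the plain 2-D
  Pearson coefficient between equally shaped matrices; it is undefined
  for constant inputs (raised as a degenerate-input error) and the
  proportional ratio is marked invalid when |C_F + C_E| < 10⁻⁶. The
  classical ratio US = C_F/(C_F + C_E) is *flexion*-completion; the
  decoder emits C_E/(C_F + C_E) = 1 − US so that all decoders share the
  θ = 1 ≡ extension orientation. Output is not clamped; per-trial min-max
  normalization happens at evaluation.
- **End-state LDA.** With one (averaged) training frame per class the
  within-class scatter vanishes and the discriminant direction is the
  class-mean difference d = μ_ext − μ_flex; the continuous output is the
  projection ⟨f − μ_flex, d⟩/⟨d, d⟩ (flexion anchor → 0, extension
  anchor → 1, not clamped). A posterior probability would be an equally
  defensible continuous read-out; the projection is the unique
  nondegenerate discriminant and is exactly testable against its closed
  form.
- **Cross-validated LDA.** Reference angles paired to frames by nearest
  timestamp are quantized into K = 10 equal-width bins; folds are
  contiguous 80/20 blocks (random shuffling would leak between adjacent,
  nearly identical frames); pixels are PCA-reduced to the components
  explaining 95% of training variance, capped at n_train − n_classes and
  at 40 components — under speckle noise the raw variance criterion
  mostly counts isotropic noise directions (~330 of 360 on default
  trials), which dilutes the discriminant; 40 keeps the tracking error at
  the correlation decoder's level. LDA uses a shrinkage-regularized
  (Ledoit–Wolf) covariance; the prediction is the posterior-weighted mean
  of bin centers, hence always inside [0.05, 0.95].

## EMG envelopes and artifact suppression

The three chains (Teager-Kaiser: band-pass 15–380 Hz → Ψ → half-wave
rectify → low-pass 7 Hz; Hilbert: band-pass 20–450 Hz → analytic-signal
magnitude → low-pass 7 Hz; moving RMS: 200-sample centered window, full
overlap, shrinking edges) share 4th-order Butterworth filters applied
forward-backward, so all envelopes are zero-phase and mutually
comparable; the Hilbert chain's 7-Hz smoothing and the TKEO rectification
(Ψ goes transiently negative on noise) are package choices made for that
comparability. Each envelope is min-max normalized over the trial; a
constant input yields all zeros plus a degenerate flag rather than a
division by zero. The even RMS window is centered with 99 samples behind
and 100 ahead; an odd window makes it exactly symmetric.

Stimulation-frequency estimation scores candidate fundamentals
(20–60 Hz, 0.25 Hz grid) by summed background-subtracted line power over
*all* harmonics up to 450 Hz (±1 Hz bands, local-median background,
clipped at zero per line). Low fixed harmonic counts fail here: a
biphasic train's even harmonics dominate (octave errors) and the 1-s
ON/OFF gating spreads each line into ±0.5-Hz sidebands. The estimate is
accepted only when its score exceeds 5× the median candidate score;
volitional recordings return "none". Suppression is a cascade of
second-order IIR notches (default bandwidth 2 Hz) at every harmonic
below Nyquist, zero-phase, applied before all three chains under FES-ON.
The gating sidebands fall partly outside the notches, so residual
sideband artifact remains after filtering — consistent with what
practitioners report for comb filtering of real FES artifacts.

## Evaluation

Ultrasound predictions (below the motion-capture rate) pair by nearest
timestamp; EMG envelopes (above it) pair each motion-capture sample with
the most recent envelope value. Both series are min-max normalized per
trial before RMSE, so errors are fractions of the range of motion, and
the extensor envelope is compared against θ directly (no sign or gain
fitting). Statistical pooling uses one RMSE per trial × method:
Mann–Whitney U across modalities (rank-biserial r = 2U_a/(n_a·n_b) − 1,
negative when the first group — SMG — has lower errors), Wilcoxon
signed-rank for FES-ON vs FES-OFF within a modality (r =
(W₊ − W₋)/(W₊ + W₋)), α = 0.01 throughout, no multiple-testing
correction. Exact p-values are used for n ≤ 15 untied pairs
(Wilcoxon) and n_a·n_b ≤ 400 without ties (Mann–Whitney), asymptotic
with tie correction otherwise. Report SDs are across trials; with a
single trial per cell the SD is reported as undefined rather than
imputed.

## Reproducibility and problem sizes

Per-trial seeds derive from the experiment's global seed via
`SeedSequence([global_seed, counter])`, folded below 2³¹, so any trial is
regenerable in isolation; a rerun with the same global seed is
byte-identical. The default experiment is 2 joints × 2 FES conditions ×
10 trials of 90 s with 128×128-pixel frames at 5 fps — about a minute of
compute on one CPU — and the synchronization-bound simulation uses 1000
short (14-s, 32×32-frame) trials with clock offsets wider than one frame
period so pulse phases wrap every sampling grid uniformly. Trial failures
inside an experiment are isolated, logged and summarized, never fatal.

## Known limitations

- The deformation model is affine; real muscle deformation is locally
  nonlinear and partly out-of-plane, which degrades frame correlation in
  ways the phantom cannot show.
- The strictly periodic stimulation artifact makes comb filtering an
  upper bound on real-world suppression; no de-clipping of saturated EMG
  is attempted (none is established practice).
- The flexor EMG channel is generated for completeness but no decoder
  consumes it (the decoded direction is extension).
- LDA1's continuous output convention and the LDA2 feature pipeline are
  package design choices among several defensible readings of "LDA with
  a continuous output"; both are configurable.
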