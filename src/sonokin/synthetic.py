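"""Synthetic multimodal trial generator.

Emulates the study conditions the pipeline was designed for: 90-s trials of
alternating full range-of-motion wrist or ankle movement paced at 60 bpm,
recorded simultaneously by motion capture (100 Hz), surface EMG (2000 Hz),
an EEG-surrogate channel (1000 Hz, synchronization only) and a B-mode
ultrasound stream (~5 fps), each on its own clock and each carrying two
reference synchronization pulses.  An FES-ON condition adds a 1-s ON / 1-s
OFF biphasic stimulation-artifact train (30-35 Hz) to the EMG, hard-clipped
at the ADC full scale to emulate amplifier saturation.

The ultrasound "anatomy" is a speckle phantom deformed by a parametric warp
driven by the normalized motion-completion level θ ∈ [0, 1] (θ = 1 ≡ full
extension).  EMG amplitude follows muscle-activation bursts during movement
episodes, not joint position, so the qualitative accuracy gap between
envelope-based and image-based decoding emerges by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, signal

from .streams import FrameStack, MultimodalTrial, TimedStream

__all__ = [
    "TrialConfig",
    "GroundTruth",
    "SpecklePhantom",
    "generate_angle_trajectory",
    "generate_phantom",
    "generate_frame_stack",
    "generate_emg",
    "generate_trial",
]


class ConfigurationError(ValueError):
    """Raised for invalid trial configurations."""


@dataclass(frozen=True)
class TrialConfig:
    """Parameters of one synthetic trial.

    Stimulation defaults follow the protocol's starting values (250 us pulse
    width, 30 Hz, drive amplitude well above the ADC range so the recorded
    EMG saturates).  Noise defaults emulate clinical-recording imperfections:
    speckle/electronic frame noise, probe wobble, baseline EMG noise, marker
    noise, cycle-to-cycle range-of-motion and timing variability.
    """

    joint: str = "wrist"                 # {"wrist", "ankle"}
    fes_condition: str = "OFF"           # {"ON", "OFF"}
    duration_s: float = 90.0
    cadence_bpm: float = 60.0
    mocap_rate: float = 100.0
    emg_rate: float = 2000.0
    eeg_rate: float = 1000.0
    us_fps: float = 5.0
    frame_shape: Tuple[int, int] = (128, 128)
    stim_frequency: float = 30.0         # Hz, 30-35 across participants
    stim_pulse_width_us: float = 250.0
    stim_amplitude: float = 5.0          # drive units, >> ADC full scale
    stim_interval_s: Tuple[float, float] = (1.0, 1.0)   # ON / OFF
    adc_full_scale: float = 1.0
    transition_s: float = 0.6            # raised-cosine end-to-end move time
    pulse_times: Tuple[float, float] = (2.0, 12.0)      # P1, P2 emission
    sync_pulse_width_s: float = 0.05
    sync_pulse_amplitude: float = 5.0
    pulse_roi_rows: int = 8
    # deformation model
    max_compression: float = 0.2         # vertical compression at θ=1
    max_shear: float = 0.08              # lateral shear at θ=1
    # noise / variability (all zero → noise-free trial)
    frame_noise_std: float = 0.15        # additive, image scale [0, 1]
    probe_jitter_px: float = 1.0         # per-frame translation std
    emg_baseline_std: float = 0.02       # ADC units
    emg_burst_amplitude: float = 0.45    # ADC units at full activation
    mocap_noise_std: float = 0.005       # normalized angle units
    eeg_noise_std: float = 1.0
    rom_variability: float = 0.05        # per-cycle end-state scatter
    timing_jitter_s: float = 0.03        # per-beat onset jitter
    clock_offset_range_s: float = 0.05   # per-stream |offset| bound
    clock_drift: float = 0.0             # fractional rate error, all streams
    seed: int = 0

    def __post_init__(self):
        if self.joint not in ("wrist", "ankle"):
            raise ConfigurationError(f"unknown joint {self.joint!r}")
        if self.fes_condition not in ("ON", "OFF"):
            raise ConfigurationError("fes_condition must be 'ON' or 'OFF'")
        for name in ("mocap_rate", "emg_rate", "eeg_rate", "us_fps"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.cadence_bpm <= 0:
            raise ConfigurationError("cadence_bpm must be positive")
        if self.stim_frequency >= self.emg_rate / 2:
            raise ConfigurationError("stim_frequency must be below Nyquist")
        if self.frame_shape[0] < 32 or self.frame_shape[1] < 32:
            raise ConfigurationError("frame_shape must be at least 32x32")
        if not self.pulse_times[1] - self.pulse_times[0] > 1.0:
            raise ConfigurationError("pulses must be > 1 s apart")

    def noise_free(self) -> "TrialConfig":
        """Copy of this config with every noise/variability source zeroed."""
        return replace(
            self,
            frame_noise_std=0.0,
            probe_jitter_px=0.0,
            emg_baseline_std=0.0,
            mocap_noise_std=0.0,
            eeg_noise_std=0.0,
            rom_variability=0.0,
            timing_jitter_s=0.0,
        )


@dataclass
class GroundTruth:
    """True kinematics and muscle drive of a synthetic trial.

    ``angle`` is the normalized motion-completion level θ(t) ∈ [0, 1]
    sampled at ``mocap_rate`` on the true (lab) clock; θ = 1 is full
    extension.  Activations are muscle drive ∈ [0, 1] at ``emg_rate``;
    nonzero only during movement episodes.
    """

    angle: np.ndarray
    mocap_rate: float
    activation_extensor: np.ndarray
    activation_flexor: np.ndarray
    emg_rate: float
    pulse_times: Tuple[float, float]
    stim_intervals: list = field(default_factory=list)  # (start, end) true-clock

    def angle_at(self, t) -> np.ndarray:
        grid = np.arange(self.angle.size) / self.mocap_rate
        return np.interp(t, grid, self.angle)

    def activation_at(self, t, muscle: str = "extensor") -> np.ndarray:
        a = self.activation_extensor if muscle == "extensor" else self.activation_flexor
        grid = np.arange(a.size) / self.emg_rate
        return np.interp(t, grid, a)


# ---------------------------------------------------------------------------
# kinematics


def _raised_cosine_step(t, onset, width):
    """Smooth 0→1 step over [onset, onset+width] (vectorized)."""
    u = np.clip((t - onset) / width, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * u))


def generate_angle_trajectory(config: TrialConfig, seed=None) -> GroundTruth:
    """Generate the ground-truth motion-completion trace θ(t).

    θ alternates between the flexion (0) and extension (1) end states once
    per metronome beat, with raised-cosine transitions.  For FES-ON trials
    the extension movements are stimulation-driven and their spans are
    recorded as ``stim_intervals`` (the 1-s ON windows).  The trace is
    min-max normalized so the trial attains both 0 and 1, mirroring how
    motion completion is defined over each trial's recorded range of motion.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    beat = 60.0 / config.cadence_bpm
    n = int(round(config.duration_s * config.mocap_rate))
    t = np.arange(n) / config.mocap_rate

    theta = np.zeros(n)
    stim_intervals = []
    level = 0.0
    onsets = []
    k = 1
    while True:
        onset = k * beat
        if config.timing_jitter_s > 0:
            onset += rng.normal(0.0, config.timing_jitter_s)
        if onset + config.transition_s >= config.duration_s:
            break
        onsets.append(onset)
        k += 1
    segments = []  # (onset, from_level, to_level)
    for i, onset in enumerate(onsets):
        going_up = i % 2 == 0
        if config.rom_variability > 0:
            target = (1.0 - abs(rng.normal(0.0, config.rom_variability))
                      if going_up else abs(rng.normal(0.0, config.rom_variability)))
        else:
            target = 1.0 if going_up else 0.0
        segments.append((onset, level, target))
        step = _raised_cosine_step(t, onset, config.transition_s)
        theta = theta + (target - level) * step
        if going_up and config.fes_condition == "ON":
            stim_intervals.append((onset, onset + config.stim_interval_s[0]))
        level = target

    lo, hi = theta.min(), theta.max()
    if hi - lo <= 0:
        raise ConfigurationError("trajectory never moves; check cadence/duration")
    theta = (theta - lo) / (hi - lo)

    act_ext, act_flex = _activations(segments, config, rng)
    return GroundTruth(
        angle=theta,
        mocap_rate=config.mocap_rate,
        activation_extensor=act_ext,
        activation_flexor=act_flex,
        emg_rate=config.emg_rate,
        pulse_times=tuple(config.pulse_times),
        stim_intervals=stim_intervals,
    )


def _activations(segments, config: TrialConfig, rng) -> Tuple[np.ndarray, np.ndarray]:
    """Muscle-drive bursts: extensor fires on upward moves, flexor on downward.

    Each burst is a raised-cosine bump spanning the movement transition plus
    a short hold (contraction outlasts the motion slightly).  Amplitude
    varies cycle to cycle when rom_variability > 0.
    """
    n = int(round(config.duration_s * config.emg_rate))
    t = np.arange(n) / config.emg_rate
    ext = np.zeros(n)
    flex = np.zeros(n)
    burst_len = config.transition_s + 0.15
    for i, (onset, frm, to) in enumerate(segments):
        going_up = to > frm
        amp = 1.0
        if config.rom_variability > 0:
            amp = float(np.clip(rng.normal(0.9, 0.1), 0.5, 1.0))
        u = np.clip((t - onset) / burst_len, 0.0, 1.0)
        bump = amp * np.sin(np.pi * u) ** 2
        bump[(t < onset) | (t > onset + burst_len)] = 0.0
        if going_up:
            ext += bump
        else:
            flex += bump
    return np.clip(ext, 0.0, 1.0), np.clip(flex, 0.0, 1.0)


# ---------------------------------------------------------------------------
# ultrasound phantom


@dataclass
class SpecklePhantom:
    """Speckle texture plus a parametric deformation model.

    The base image is Rayleigh-distributed speckle smoothed by a Gaussian
    point-spread kernel — a stand-in texture with B-mode-like statistics,
    not an acoustic simulation.  The warp maps θ to an affine transform
    (vertical compression up to ``max_compression``, lateral shear up to
    ``max_shear``); it is the identity at θ=0 and injective in θ.
    """

    base_image: np.ndarray             # (H, W) float in [0, 1]
    max_compression: float = 0.2
    max_shear: float = 0.08

    def warp(self, theta: float, jitter=(0.0, 0.0)) -> np.ndarray:
        if not (0.0 <= theta <= 1.0):
            raise ValueError(f"theta={theta} outside [0, 1]")
        h, w = self.base_image.shape
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        s = 1.0 - self.max_compression * theta     # vertical content scale
        shear = self.max_shear * theta
        # output -> input mapping: inverse of (scale about center + shear)
        m = np.array([[1.0 / s, 0.0], [-shear / s, 1.0]])
        offset = np.array([cy, cx]) - m @ np.array([cy - jitter[0], cx - jitter[1]])
        return ndimage.affine_transform(
            self.base_image, m, offset=offset, order=1, mode="nearest"
        )


def generate_phantom(config: TrialConfig, seed=None) -> SpecklePhantom:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    raw = rng.rayleigh(scale=1.0, size=config.frame_shape)
    img = ndimage.gaussian_filter(raw, sigma=1.2)
    img = (img - img.min()) / (img.max() - img.min())
    return SpecklePhantom(
        base_image=0.05 + 0.9 * img,
        max_compression=config.max_compression,
        max_shear=config.max_shear,
    )


def _own_to_true(t_own, offset, drift):
    return t_own / (1.0 + drift) - offset


def _true_to_own(t_true, offset, drift):
    return (t_true + offset) * (1.0 + drift)


def generate_frame_stack(
    phantom: SpecklePhantom,
    truth: GroundTruth,
    config: TrialConfig,
    seed=None,
    clock_offset: float = 0.0,
    clock_drift: float = 0.0,
) -> FrameStack:
    """Render the trial's ultrasound stream on the imaging system's clock.

    One frame per 1/us_fps seconds: the phantom warped by θ at the frame's
    true acquisition time, plus additive Gaussian noise, quantized to 8 bits.
    The synchronization pulse lights the reserved bottom ROI rows from the
    first frame time-stamped at or after the pulse's arrival, for the pulse
    duration.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(round(config.duration_s * config.us_fps))
    t_own = np.arange(n) / config.us_fps
    t_true = _own_to_true(t_own, clock_offset, clock_drift)
    theta = np.clip(truth.angle_at(t_true), 0.0, 1.0)

    h, w = phantom.base_image.shape
    roi = config.pulse_roi_rows
    frames = np.empty((n, h + roi, w), dtype=np.uint8)
    for i in range(n):
        jitter = (
            rng.normal(0.0, config.probe_jitter_px, size=2)
            if config.probe_jitter_px > 0
            else (0.0, 0.0)
        )
        img = phantom.warp(float(theta[i]), jitter=jitter)
        if config.frame_noise_std > 0:
            img = img + rng.normal(0.0, config.frame_noise_std, size=img.shape)
        full = np.zeros((h + roi, w))
        full[:h] = img
        frames[i] = np.clip(np.round(full * 255.0), 0, 255).astype(np.uint8)

    # pulse-trace overlay in the ROI rows
    for p in truth.pulse_times:
        c = _true_to_own(p, clock_offset, clock_drift)
        first = int(np.ceil(c * config.us_fps - 1e-9))
        last = int(np.ceil((c + config.sync_pulse_width_s) * config.us_fps - 1e-9))
        for k in range(first, max(last, first + 1)):
            if 0 <= k < n:
                frames[k, h:, :] = 255
    return FrameStack(frames=frames, times=t_own, pulse_roi_rows=roi)


def generate_endstate_stack(
    phantom: SpecklePhantom, theta: float, config: TrialConfig, seed=None
) -> FrameStack:
    """1-s end-state training stack held at a fixed θ (no pulse overlay)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = max(int(round(config.us_fps)), 1)
    h, w = phantom.base_image.shape
    roi = config.pulse_roi_rows
    frames = np.empty((n, h + roi, w), dtype=np.uint8)
    for i in range(n):
        jitter = (
            rng.normal(0.0, config.probe_jitter_px, size=2)
            if config.probe_jitter_px > 0
            else (0.0, 0.0)
        )
        img = phantom.warp(theta, jitter=jitter)
        if config.frame_noise_std > 0:
            img = img + rng.normal(0.0, config.frame_noise_std, size=img.shape)
        full = np.zeros((h + roi, w))
        full[:h] = img
        frames[i] = np.clip(np.round(full * 255.0), 0, 255).astype(np.uint8)
    return FrameStack(
        frames=frames, times=np.arange(n) / config.us_fps, pulse_roi_rows=roi
    )


# ---------------------------------------------------------------------------
# electrophysiology


def _trigger_channel(n, rate, pulse_times, config, clock_offset, clock_drift):
    trig = np.zeros(n)
    for p in pulse_times:
        c = _true_to_own(p, clock_offset, clock_drift)
        first = int(np.ceil(c * rate - 1e-9))
        last = int(np.ceil((c + config.sync_pulse_width_s) * rate - 1e-9))
        first = max(first, 0)
        trig[first : max(last, first + 1)] = config.sync_pulse_amplitude
    return trig


def generate_emg(
    truth: GroundTruth,
    config: TrialConfig,
    seed=None,
    clock_offset: float = 0.0,
    clock_drift: float = 0.0,
) -> Tuple[TimedStream, TimedStream]:
    """Synthesize extensor and flexor surface EMG on the EMG system's clock.

    EMG = activation x band-limited (20-450 Hz) Gaussian carrier + baseline
    noise.  For FES-ON, a biphasic rectangular pulse train at the stimulation
    frequency is added during the ON intervals and the result is hard-clipped
    at the ADC full scale, emulating amplifier saturation.  Amplitude tracks
    muscle activation (movement effort), not joint position.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.emg_rate
    n = int(round(config.duration_s * fs))
    t_own = np.arange(n) / fs
    t_true = _own_to_true(t_own, clock_offset, clock_drift)

    sos = signal.butter(4, [20.0, min(450.0, 0.45 * fs)], btype="bandpass",
                        fs=fs, output="sos")

    def carrier():
        white = rng.standard_normal(n)
        c = signal.sosfiltfilt(sos, white)
        return c / max(np.std(c), 1e-12)

    streams = []
    for muscle in ("extensor", "flexor"):
        act = truth.activation_at(t_true, muscle)
        x = config.emg_burst_amplitude * act * carrier()
        if config.emg_baseline_std > 0:
            x = x + rng.normal(0.0, config.emg_baseline_std, n)
        if config.fes_condition == "ON" and muscle == "extensor":
            x = x + _stim_artifact(t_true, truth.stim_intervals, config)
            x = np.clip(x, -config.adc_full_scale, config.adc_full_scale)
        trig = _trigger_channel(n, fs, truth.pulse_times, config,
                                clock_offset, clock_drift)
        streams.append(
            TimedStream(values=x, rate=fs, stream_id=f"emg_{muscle}",
                        pulse_channel=trig)
        )
    return streams[0], streams[1]


def _stim_artifact(t_true, stim_intervals, config: TrialConfig) -> np.ndarray:
    """Biphasic rectangular stimulation pulses during the ON intervals."""
    fs = config.emg_rate
    x = np.zeros(t_true.size)
    width_s = config.stim_pulse_width_us * 1e-6
    phase_samp = max(int(round(width_s * fs)), 1)
    t0, t1 = t_true[0], t_true[-1]
    for start, end in stim_intervals:
        k0 = int(np.ceil(start * config.stim_frequency))
        k1 = int(np.floor(end * config.stim_frequency))
        for k in range(k0, k1 + 1):
            tp = k / config.stim_frequency
            if tp < t0 or tp > t1:
                continue
            i = int(round((tp - t0) * fs))
            x[i : i + phase_samp] += config.stim_amplitude
            x[i + phase_samp : i + 2 * phase_samp] -= config.stim_amplitude
    return x


def generate_mocap(
    truth, config, seed=None, clock_offset=0.0, clock_drift=0.0
) -> TimedStream:
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.mocap_rate
    n = int(round(config.duration_s * fs))
    t_own = np.arange(n) / fs
    theta = truth.angle_at(_own_to_true(t_own, clock_offset, clock_drift))
    if config.mocap_noise_std > 0:
        theta = theta + rng.normal(0.0, config.mocap_noise_std, n)
    trig = _trigger_channel(n, fs, truth.pulse_times, config,
                            clock_offset, clock_drift)
    return TimedStream(values=theta, rate=fs, stream_id="mocap",
                       pulse_channel=trig)


def generate_eeg_surrogate(
    truth, config, seed=None, clock_offset=0.0, clock_drift=0.0
) -> TimedStream:
    """Noise channel at the EEG rate; carries the pulses, nothing else."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.eeg_rate
    n = int(round(config.duration_s * fs))
    x = rng.normal(0.0, config.eeg_noise_std, n) if config.eeg_noise_std > 0 else np.zeros(n)
    trig = _trigger_channel(n, fs, truth.pulse_times, config,
                            clock_offset, clock_drift)
    return TimedStream(values=x, rate=fs, stream_id="eeg",
                       pulse_channel=trig)


# ---------------------------------------------------------------------------
# full trial


def generate_trial(config: TrialConfig) -> MultimodalTrial:
    """Generate all four modality streams plus the end-state training stacks.

    Each stream records on its own clock with an independent random offset
    (uniform within ±clock_offset_range_s) and the configured drift; the
    same seed reproduces the trial bit-identically.  Ground truth is retained
    on the trial for evaluation only.
    """
    rng = np.random.default_rng(config.seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=8)
    truth = generate_angle_trajectory(config, seed=int(child_seeds[0]))
    phantom = generate_phantom(config, seed=int(child_seeds[1]))

    # one clock per acquisition device; both EMG channels share theirs
    device_names = ["emg_extensor", "mocap", "eeg", "us"]
    if config.clock_offset_range_s > 0:
        offs = rng.uniform(-config.clock_offset_range_s,
                           config.clock_offset_range_s, size=len(device_names))
        offsets = {nm: float(o) for nm, o in zip(device_names, offs)}
    else:
        offsets = {nm: 0.0 for nm in device_names}
    drift = config.clock_drift
    drifts = dict(drift) if isinstance(drift, dict) else {
        nm: float(drift) for nm in device_names
    }
    for nm in device_names:
        drifts.setdefault(nm, 0.0)
    offsets["emg_flexor"] = offsets["emg_extensor"]
    drifts["emg_flexor"] = drifts["emg_extensor"]

    emg_ext, emg_flex = generate_emg(
        truth, config, seed=int(child_seeds[2]),
        clock_offset=offsets["emg_extensor"], clock_drift=drifts["emg_extensor"],
    )
    mocap = generate_mocap(
        truth, config, seed=int(child_seeds[3]),
        clock_offset=offsets["mocap"], clock_drift=drifts["mocap"],
    )
    eeg = generate_eeg_surrogate(
        truth, config, seed=int(child_seeds[4]),
        clock_offset=offsets["eeg"], clock_drift=drifts["eeg"],
    )
    frames = generate_frame_stack(
        phantom, truth, config, seed=int(child_seeds[5]),
        clock_offset=offsets["us"], clock_drift=drifts["us"],
    )
    flexion_stack = generate_endstate_stack(
        phantom, 0.0, config, seed=int(child_seeds[6])
    )
    extension_stack = generate_endstate_stack(
        phantom, 1.0, config, seed=int(child_seeds[7])
    )
    return MultimodalTrial(
        streams={
            "emg_extensor": emg_ext,
            "emg_flexor": emg_flex,
            "mocap": mocap,
            "eeg": eeg,
        },
        frames=frames,
        flexion_stack=flexion_stack,
        extension_stack=extension_stack,
        config=config,
        ground_truth=truth,
        clock_offsets=offsets,
        clock_drifts=drifts,
    )
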