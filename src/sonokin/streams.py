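"""Core in-memory containers for multimodal trials.

A trial bundles four simultaneously recorded modalities: surface EMG
(2000 Hz), motion capture joint angles (100 Hz), an EEG-surrogate channel
used only for synchronization (1000 Hz), and a B-mode ultrasound frame
sequence (~5 fps).  Each modality records on its own clock; two reference
pulses shared by all devices allow post-hoc alignment.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "TimedStream",
    "FrameStack",
    "MethodPrediction",
    "MultimodalTrial",
]


@dataclass
class TimedStream:
    """Uniformly sampled 1-D signal on its own device clock.

    Parameters
    ----------
    values : ndarray
        Signal samples.
    rate : float
        Nominal sampling rate in Hz.
    t0 : float
        Time of the first sample on the stream's own clock, in seconds.
    stream_id : str
        Label used in error messages and alignment reports.
    pulse_channel : ndarray, optional
        Dedicated trigger channel (the recorded 5 V reference pulse) on the
        same sampling grid.  When absent, pulse detection falls back to the
        signal itself.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    stream_id: str = "stream"
    pulse_channel: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimedStream values must be 1-D")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.pulse_channel is not None:
            self.pulse_channel = np.asarray(self.pulse_channel, dtype=float)
            if self.pulse_channel.shape != self.values.shape:
                raise ValueError("pulse_channel must match values in length")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times on the stream's own (possibly offset) clock."""
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def period(self) -> float:
        return 1.0 / self.rate

    def shifted(self, dt: float) -> "TimedStream":
        """Return a copy with the time axis shifted by ``dt`` seconds."""
        return replace(self, t0=self.t0 + dt)


@dataclass
class FrameStack:
    """Ordered grayscale ultrasound frames with per-frame timestamps.

    The bottom ``pulse_roi_rows`` rows are reserved for the rendered
    synchronization-pulse trace (the ECG-channel overlay) and are excluded
    from all decoding computations.
    """

    frames: np.ndarray          # (n, H, W), grayscale
    times: np.ndarray           # (n,) seconds on the stack's own clock
    pulse_roi_rows: int = 8
    stream_id: str = "us"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if self.times.shape != (self.frames.shape[0],):
            raise ValueError("one timestamp per frame required")

    def __len__(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple:
        return self.frames.shape[1:]

    @property
    def rate(self) -> float:
        if len(self.times) < 2:
            raise ValueError("need >= 2 frames to infer a frame rate")
        return 1.0 / float(np.median(np.diff(self.times)))

    @property
    def period(self) -> float:
        return 1.0 / self.rate

    def anatomy(self) -> np.ndarray:
        """Frames with the pulse-trace ROI rows removed."""
        if self.pulse_roi_rows <= 0:
            return self.frames
        return self.frames[:, : -self.pulse_roi_rows, :]

    def roi(self) -> np.ndarray:
        """The pulse-trace ROI rows of every frame."""
        if self.pulse_roi_rows <= 0:
            raise ValueError("stack has no pulse ROI")
        return self.frames[:, -self.pulse_roi_rows :, :]

    def shifted(self, dt: float) -> "FrameStack":
        return replace(self, times=self.times + dt)


@dataclass
class MethodPrediction:
    """Time-stamped normalized joint-angle estimates from one decoder."""

    times: np.ndarray
    values: np.ndarray
    method: str
    valid: Optional[np.ndarray] = None  # False entries carry NaN values

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return self.times.size

    def finite(self) -> "MethodPrediction":
        """Drop invalid (missing-value) samples."""
        m = self.valid
        return MethodPrediction(self.times[m], self.values[m], self.method)


@dataclass
class MultimodalTrial:
    """All streams of one recorded trial plus (for synthetic data) the truth."""

    streams: dict                      # stream_id -> TimedStream
    frames: FrameStack
    flexion_stack: FrameStack          # 1-s end-state training stack, θ=0
    extension_stack: FrameStack        # 1-s end-state training stack, θ=1
    config: object = None              # TrialConfig echo
    ground_truth: object = None        # GroundTruth (evaluation only)
    clock_offsets: dict = field(default_factory=dict)
    clock_drifts: dict = field(default_factory=dict)

    REFERENCE_STREAM = "emg_extensor"

    @property
    def mocap(self) -> TimedStream:
        return self.streams["mocap"]

    @property
    def emg_extensor(self) -> TimedStream:
        return self.streams["emg_extensor"]
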