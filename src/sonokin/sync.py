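"""Pulse detection, stream alignment and cross-stream sample pairing.

All devices receive two shared reference pulses.  Streams are aligned by
shifting their time axes so the first recorded pulse coincides across
streams (the extensor EMG stream is the reference, so its delay is 0 by
definition).  The second pulse then verifies timekeeping: per stream, the
residual delay relative to the EMG reference must stay within one sampling
period (plus the reference stream's own quantization) or the stream is
flagged as drifting.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Union

import numpy as np

from .streams import FrameStack, MethodPrediction, MultimodalTrial, TimedStream

__all__ = [
    "PulseEvent",
    "AlignmentReport",
    "SyncError",
    "detect_pulses",
    "align_streams",
    "pair_predictions",
]

# detections closer than this merge into one pulse episode
EPISODE_GAP_S = 0.5


class SyncError(RuntimeError):
    """Raised when synchronization pulses cannot be found."""


class PairingError(RuntimeError):
    """Raised when two streams share no overlapping support."""


@dataclass(frozen=True)
class PulseEvent:
    stream_id: str
    sample_index: int
    recorded_time_s: float


@dataclass
class AlignmentReport:
    """Per-stream alignment offsets and second-pulse residual check."""

    offsets: dict        # stream_id -> applied time shift (s)
    residuals: dict      # stream_id -> Δ = P2_stream − P2_ref (s, aligned)
    bounds: dict         # stream_id -> sampling period (s)
    passed: dict         # stream_id -> |residual| within bound + ref period
    reference: str

    def all_passed(self) -> bool:
        return all(self.passed.values())

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "offsets_s": self.offsets,
            "residuals_s": self.residuals,
            "bounds_s": self.bounds,
            "pass": self.passed,
        }


def _episodes_from_mask(mask: np.ndarray, rate: float) -> List[int]:
    """First index of each above-threshold episode, merging nearby runs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    gap = max(int(round(EPISODE_GAP_S * rate)), 1)
    starts = [int(idx[0])]
    last = idx[0]
    for i in idx[1:]:
        if i - last > gap:
            starts.append(int(i))
        last = i
    return starts


def detect_pulses(
    source: Union[TimedStream, FrameStack],
    threshold: float = None,
    expected: int = 2,
) -> List[PulseEvent]:
    """Locate reference-pulse onsets in a stream or frame stack.

    For a 1-D stream the dedicated trigger channel is searched when present
    (otherwise the signal itself); an event is the first sample of each
    episode exceeding the threshold (default: half the peak amplitude, the
    pulses being high-SNR square edges).  For a frame stack an event is the
    first frame whose pulse-ROI mean intensity exceeds the threshold.
    Raises :class:`SyncError` when fewer than ``expected`` pulses are found.
    """
    if isinstance(source, FrameStack):
        trace = source.roi().mean(axis=(1, 2)).astype(float)
        times = source.times
        rate = source.rate
        stream_id = source.stream_id
    else:
        trace = source.pulse_channel if source.pulse_channel is not None else source.values
        trace = np.abs(np.asarray(trace, dtype=float))
        times = source.times
        rate = source.rate
        stream_id = source.stream_id

    if threshold is None:
        threshold = 0.5 * float(np.max(trace)) if trace.size else 0.0
    starts = _episodes_from_mask(trace > threshold, rate)
    events = [
        PulseEvent(stream_id=stream_id, sample_index=i,
                   recorded_time_s=float(times[i]))
        for i in starts
    ]
    if len(events) < expected:
        raise SyncError(
            f"stream {stream_id!r}: found {len(events)} pulse(s), "
            f"expected {expected}"
        )
    return events


def align_streams(trial: MultimodalTrial) -> tuple:
    """Align every stream of a trial on the first reference pulse.

    Returns ``(aligned_trial, report)``.  Time axes are shifted so that the
    first pulse lands at t=0 in every stream; the extensor EMG stream is the
    reference, so its second-pulse residual is exactly 0.  Streams whose
    residual exceeds their sampling period (plus the reference period, the
    reference's own quantization) are flagged ``passed=False`` — a clock-
    drift warning, not an exception.
    """
    ref_id = MultimodalTrial.REFERENCE_STREAM
    sources = dict(trial.streams)
    sources["us"] = trial.frames

    events = {sid: detect_pulses(src)[:2] for sid, src in sources.items()}
    p1_ref = events[ref_id][0].recorded_time_s
    p2_ref_aligned = events[ref_id][1].recorded_time_s - p1_ref

    offsets, residuals, bounds, passed = {}, {}, {}, {}
    aligned_streams = {}
    aligned_frames = None
    ref_period = sources[ref_id].period
    for sid, src in sources.items():
        p1, p2 = (e.recorded_time_s for e in events[sid])
        shift = -p1
        offsets[sid] = shift
        residual = (p2 + shift) - p2_ref_aligned
        residuals[sid] = residual
        bounds[sid] = src.period
        tol = src.period + (ref_period if sid != ref_id else 0.0)
        passed[sid] = bool(abs(residual) <= tol + 1e-12)
        if sid == "us":
            aligned_frames = src.shifted(shift)
        else:
            aligned_streams[sid] = src.shifted(shift)

    report = AlignmentReport(
        offsets=offsets, residuals=residuals, bounds=bounds, passed=passed,
        reference=ref_id,
    )
    aligned = replace(
        trial, streams=aligned_streams, frames=aligned_frames
    )
    return aligned, report


def pair_predictions(
    pred: MethodPrediction,
    reference: TimedStream,
    mode: str = "nearest",
) -> tuple:
    """Pair decoder outputs with reference (motion-capture) samples.

    ``nearest``: each prediction is paired with the reference sample closest
    in time — used for low-rate predictions (ultrasound at ~5 fps vs 100 Hz
    motion capture).  ``preceding_window``: each reference sample is paired
    with the most recent prediction at or before it — used for high-rate
    predictions (EMG envelopes).  Samples outside the overlap of both
    supports are dropped.  Returns ``(measured, predicted)`` arrays of equal
    length.
    """
    pred = pred.finite()
    pt, pv = pred.times, pred.values
    rt, rv = reference.times, np.asarray(reference.values, dtype=float)
    if pt.size == 0 or rt.size == 0:
        raise PairingError("empty prediction or reference series")

    if mode == "nearest":
        keep = (pt >= rt[0]) & (pt <= rt[-1])
        pt, pv = pt[keep], pv[keep]
        if pt.size == 0:
            raise PairingError("no temporal overlap between streams")
        right = np.searchsorted(rt, pt)
        right = np.clip(right, 1, rt.size - 1)
        left = right - 1
        choose_right = (rt[right] - pt) < (pt - rt[left])
        idx = np.where(choose_right, right, left)
        return rv[idx], pv
    elif mode == "preceding_window":
        idx = np.searchsorted(pt, rt, side="right") - 1
        keep = (idx >= 0) & (rt <= pt[-1] + 1.0 / reference.rate)
        if not np.any(keep):
            raise PairingError("no temporal overlap between streams")
        return rv[keep], pv[idx[keep]]
    raise ValueError(f"unknown pairing mode {mode!r}")
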