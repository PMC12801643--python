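"""On-disk trial format: multi-frame TIFF stacks, per-stream CSVs and a
JSON manifest.

A written trial directory contains one grayscale multi-frame TIFF per frame
stack (trial plus the two 1-s end-state training stacks) with a frame-
timestamp sidecar CSV, one CSV per 1-D stream with columns
``time_s,value,trigger``, and a ``manifest.json`` naming every file and
echoing rates, pulse times, clock parameters and the generating
configuration.  Round-trips are bit-exact for the integer pixel data and
full-precision for floating-point samples.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .streams import FrameStack, MultimodalTrial, TimedStream
from .synthetic import GroundTruth, TrialConfig

__all__ = ["write_trial", "read_trial"]

MANIFEST_VERSION = 1


class TrialIOError(RuntimeError):
    pass


def _write_stack(stack: FrameStack, directory: Path, name: str) -> dict:
    tif = directory / f"{name}.tif"
    tifffile.imwrite(tif, stack.frames, photometric="minisblack")
    sidecar = directory / f"{name}_timestamps.csv"
    pd.DataFrame(
        {"frame_index": np.arange(len(stack)), "time_s": stack.times}
    ).to_csv(sidecar, index=False)
    return {
        "tiff": tif.name,
        "timestamps": sidecar.name,
        "pulse_roi_rows": stack.pulse_roi_rows,
        "stream_id": stack.stream_id,
    }


def _read_stack(directory: Path, entry: dict) -> FrameStack:
    tif = directory / entry["tiff"]
    if not tif.exists():
        raise TrialIOError(f"missing frame file: {tif}")
    frames = tifffile.imread(tif)
    if frames.ndim == 2:                       # single-frame stack
        frames = frames[None]
    sidecar = directory / entry["timestamps"]
    if not sidecar.exists():
        raise TrialIOError(f"missing timestamp sidecar: {sidecar}")
    times = pd.read_csv(sidecar, float_precision="round_trip")["time_s"].to_numpy(dtype=float)
    return FrameStack(
        frames=frames, times=times,
        pulse_roi_rows=int(entry["pulse_roi_rows"]),
        stream_id=entry.get("stream_id", "us"),
    )


def _write_stream(stream: TimedStream, directory: Path, name: str) -> dict:
    path = directory / f"{name}.csv"
    cols = {"time_s": stream.times, "value": stream.values}
    if stream.pulse_channel is not None:
        cols["trigger"] = stream.pulse_channel
    pd.DataFrame(cols).to_csv(path, index=False)
    return {"csv": path.name, "rate_hz": stream.rate, "t0_s": stream.t0,
            "stream_id": stream.stream_id}


def _read_stream(directory: Path, entry: dict) -> TimedStream:
    path = directory / entry["csv"]
    if not path.exists():
        raise TrialIOError(f"missing stream file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    return TimedStream(
        values=df["value"].to_numpy(dtype=float),
        rate=float(entry["rate_hz"]),
        t0=float(entry["t0_s"]),
        stream_id=entry["stream_id"],
        pulse_channel=df["trigger"].to_numpy(dtype=float)
        if "trigger" in df else None,
    )


def write_trial(trial: MultimodalTrial, directory) -> Path:
    """Write a trial to ``directory``; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": MANIFEST_VERSION,
        "streams": {
            sid: _write_stream(s, directory, sid)
            for sid, s in trial.streams.items()
        },
        "stacks": {
            "trial": _write_stack(trial.frames, directory, "us_trial"),
            "flexion": _write_stack(trial.flexion_stack, directory, "us_flexion"),
            "extension": _write_stack(trial.extension_stack, directory,
                                      "us_extension"),
        },
        "clock_offsets_s": trial.clock_offsets,
        "clock_drifts": trial.clock_drifts,
    }
    if trial.config is not None:
        manifest["config"] = dataclasses.asdict(trial.config)
    if trial.ground_truth is not None:
        gt = trial.ground_truth
        gt_path = directory / "ground_truth.csv"
        pd.DataFrame({"angle": gt.angle}).to_csv(gt_path, index=False)
        act_path = directory / "activations.csv"
        pd.DataFrame({
            "extensor": gt.activation_extensor,
            "flexor": gt.activation_flexor,
        }).to_csv(act_path, index=False)
        manifest["ground_truth"] = {
            "angle_csv": gt_path.name,
            "mocap_rate_hz": gt.mocap_rate,
            "activations_csv": act_path.name,
            "emg_rate_hz": gt.emg_rate,
            "pulse_times_s": list(gt.pulse_times),
            "stim_intervals_s": [list(iv) for iv in gt.stim_intervals],
        }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def read_trial(manifest_path) -> MultimodalTrial:
    """Load a trial from its manifest; raises on missing/corrupt files."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise TrialIOError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    if manifest.get("schema_version") != MANIFEST_VERSION:
        raise TrialIOError(
            f"unsupported manifest schema: {manifest.get('schema_version')}"
        )
    directory = manifest_path.parent
    streams = {
        sid: _read_stream(directory, entry)
        for sid, entry in manifest["streams"].items()
    }
    stacks = manifest["stacks"]
    config = None
    if "config" in manifest:
        cfg = dict(manifest["config"])
        for key in ("frame_shape", "stim_interval_s", "pulse_times"):
            cfg[key] = tuple(cfg[key])
        if isinstance(cfg.get("clock_drift"), dict):
            cfg["clock_drift"] = dict(cfg["clock_drift"])
        config = TrialConfig(**cfg)
    truth = None
    if "ground_truth" in manifest:
        g = manifest["ground_truth"]
        angle = pd.read_csv(directory / g["angle_csv"],
                            float_precision="round_trip")["angle"].to_numpy()
        acts = pd.read_csv(directory / g["activations_csv"],
                           float_precision="round_trip")
        truth = GroundTruth(
            angle=angle,
            mocap_rate=float(g["mocap_rate_hz"]),
            activation_extensor=acts["extensor"].to_numpy(),
            activation_flexor=acts["flexor"].to_numpy(),
            emg_rate=float(g["emg_rate_hz"]),
            pulse_times=tuple(g["pulse_times_s"]),
            stim_intervals=[tuple(iv) for iv in g["stim_intervals_s"]],
        )
    return MultimodalTrial(
        streams=streams,
        frames=_read_stack(directory, stacks["trial"]),
        flexion_stack=_read_stack(directory, stacks["flexion"]),
        extension_stack=_read_stack(directory, stacks["extension"]),
        config=config,
        ground_truth=truth,
        clock_offsets=manifest.get("clock_offsets_s", {}),
        clock_drifts=manifest.get("clock_drifts", {}),
    )
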