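"""Experiment orchestration: generate → synchronize → decode → evaluate.

``run_experiment`` executes the full trial matrix (joints × FES conditions
× repetitions), decoding every trial with all six methods (three SMG, three
EMG envelope chains) and compiling the study-style evaluation report.
Per-trial seeds are derived from the global seed with a documented counter
scheme, so any single trial is independently reproducible; failures are
isolated per trial and summarized, never fatal to the run.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional

import numpy as np

from . import emg as emg_mod
from . import io as trial_io
from . import smg as smg_mod
from .evaluation import EvalPair, TrialScore, compile_report, linear_fit, rmse
from .streams import MethodPrediction, MultimodalTrial
from .sync import align_streams, pair_predictions
from .synthetic import TrialConfig, generate_trial

__all__ = [
    "ExperimentConfig",
    "trial_seed",
    "decode_trial",
    "score_trial",
    "run_experiment",
    "run_noise_sweep",
]

log = logging.getLogger("sonokin")

ALL_METHODS = (
    "smg_correlation", "smg_lda_endstate", "smg_lda_cv",
    "emg_tkeo", "emg_hilbert", "emg_rms",
)


@dataclass(frozen=True)
class ExperimentConfig:
    """Trial matrix and execution parameters of one experiment."""

    trials_per_cell: int = 10
    joints: tuple = ("wrist", "ankle")
    conditions: tuple = ("OFF", "ON")
    methods: tuple = ALL_METHODS
    base: TrialConfig = field(default_factory=TrialConfig)
    noise_grid: Optional[tuple] = None
    output_dir: Optional[str] = None
    global_seed: int = 0

    def __post_init__(self):
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")
        unknown = set(self.methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")


def trial_seed(global_seed: int, counter: int) -> int:
    """Per-trial seed: SeedSequence([global_seed, counter]), folded < 2³¹."""
    ss = np.random.SeedSequence([int(global_seed), int(counter)])
    return int(ss.generate_state(1)[0] % (2**31))


def _nearest_reference(times: np.ndarray, reference) -> np.ndarray:
    """Reference value nearest in time to each query timestamp."""
    rt, rv = reference.times, np.asarray(reference.values, dtype=float)
    right = np.clip(np.searchsorted(rt, times), 1, rt.size - 1)
    left = right - 1
    choose_right = (rt[right] - times) < (times - rt[left])
    return rv[np.where(choose_right, right, left)]


def decode_trial(trial: MultimodalTrial, methods=ALL_METHODS) -> dict:
    """Align a trial and decode it with the requested methods.

    Returns ``{"aligned": ..., "report": AlignmentReport,
    "predictions": {method: MethodPrediction}}``.
    """
    aligned, report = align_streams(trial)
    mocap = aligned.streams["mocap"]
    predictions = {}

    smg_requested = [m for m in methods if m.startswith("smg")]
    if smg_requested:
        refs = smg_mod.build_reference_frames(
            aligned.flexion_stack, aligned.extension_stack
        )
        if "smg_correlation" in smg_requested:
            predictions["smg_correlation"] = smg_mod.decode_correlation(
                aligned.frames, refs
            )
        if "smg_lda_endstate" in smg_requested:
            predictions["smg_lda_endstate"] = smg_mod.decode_lda_endstate(
                aligned.frames, aligned.flexion_stack, aligned.extension_stack
            )
        if "smg_lda_cv" in smg_requested:
            labels = np.clip(
                _nearest_reference(aligned.frames.times, mocap), 0.0, 1.0
            )
            predictions["smg_lda_cv"], _ = smg_mod.decode_lda_cv(
                aligned.frames, labels
            )

    emg_requested = [m for m in methods if m.startswith("emg")]
    if emg_requested:
        raw = aligned.streams["emg_extensor"]
        fes_spec = None
        cfg = trial.config
        if cfg is not None and cfg.fes_condition == "ON":
            f0 = emg_mod.estimate_stim_frequency(raw)
            if f0 is not None:
                fes_spec = emg_mod.CombFilterSpec(fundamental=f0, rate=raw.rate)
        for m in emg_requested:
            predictions[m] = emg_mod.decode_envelope(
                raw, m.removeprefix("emg_"), fes_spec
            )

    return {"aligned": aligned, "report": report, "predictions": predictions}


def score_trial(decoded: dict, joint: str, condition: str,
                trial_index: int) -> List[TrialScore]:
    """Pair every prediction with motion capture and score it.

    SMG predictions (below the motion-capture rate) use nearest-timestamp
    pairing; EMG envelopes (above it) use preceding-window pairing.  Both
    series are min-max normalized per trial before RMSE, so errors are
    fractions of the range of motion.
    """
    mocap = decoded["aligned"].streams["mocap"]
    scores = []
    for method, pred in decoded["predictions"].items():
        mode = "nearest" if method.startswith("smg") else "preceding_window"
        measured, predicted = pair_predictions(pred, mocap, mode=mode)
        pair = EvalPair(measured, predicted, pairing_mode=mode)
        fit = linear_fit(pair)
        scores.append(TrialScore(
            joint=joint, condition=condition, method=method,
            trial_index=trial_index, rmse=rmse(pair),
            r=fit["r"], R2=fit["R2"], n_pairs=pair.n,
        ))
    return scores


def score_against_truth(trial: MultimodalTrial,
                        methods=("smg_correlation", "smg_lda_endstate",
                                 "smg_lda_cv")) -> dict:
    """Parameter recovery: score decoders against the generator's true θ.

    Only meaningful for synthetic trials.  Decoding runs on the raw stacks
    and streams; each prediction timestamp is mapped back to the true (lab)
    clock through the stream's known offset/drift, and the prediction is
    compared with ground-truth θ there — isolating decoder quality from
    synchronization quantization.  Returns ``{method: {"rmse", "r", "R2"}}``
    on min-max normalized series.
    """
    truth = trial.ground_truth
    if truth is None:
        raise ValueError("trial carries no ground truth")

    def true_times(own_times, sid):
        off = trial.clock_offsets.get(sid, 0.0)
        drift = trial.clock_drifts.get(sid, 0.0)
        return own_times / (1.0 + drift) - off

    refs = smg_mod.build_reference_frames(trial.flexion_stack,
                                          trial.extension_stack)
    preds = {}
    if "smg_correlation" in methods:
        preds["smg_correlation"] = smg_mod.decode_correlation(
            trial.frames, refs)
    if "smg_lda_endstate" in methods:
        preds["smg_lda_endstate"] = smg_mod.decode_lda_endstate(
            trial.frames, trial.flexion_stack, trial.extension_stack)
    if "smg_lda_cv" in methods:
        labels = np.clip(
            truth.angle_at(true_times(trial.frames.times, "us")), 0.0, 1.0)
        preds["smg_lda_cv"], _ = smg_mod.decode_lda_cv(trial.frames, labels)
    for m in methods:
        if m.startswith("emg"):
            raw = trial.streams["emg_extensor"]
            fes_spec = None
            if trial.config is not None and trial.config.fes_condition == "ON":
                f0 = emg_mod.estimate_stim_frequency(raw)
                if f0 is not None:
                    fes_spec = emg_mod.CombFilterSpec(fundamental=f0,
                                                      rate=raw.rate)
            preds[m] = emg_mod.decode_envelope(
                raw, m.removeprefix("emg_"), fes_spec)

    out = {}
    for method, pred in preds.items():
        sid = "us" if method.startswith("smg") else "emg_extensor"
        pred = pred.finite()
        theta = truth.angle_at(true_times(pred.times, sid))
        pair = EvalPair(theta, pred.values, pairing_mode="ground_truth")
        fit = linear_fit(pair)
        out[method] = {"rmse": rmse(pair), "r": fit["r"], "R2": fit["R2"]}
    return out


def run_experiment(config: ExperimentConfig):
    """Run the full trial matrix and compile the evaluation report.

    Deterministic given ``global_seed``.  When ``output_dir`` is set, every
    trial is written to disk alongside the report CSV/JSON and a run
    manifest.  Per-trial failures are recorded and skipped.
    """
    out = Path(config.output_dir) if config.output_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    scores, failures, manifest_entries = [], [], []
    counter = 0
    for joint in config.joints:
        for condition in config.conditions:
            for rep in range(config.trials_per_cell):
                seed = trial_seed(config.global_seed, counter)
                counter += 1
                cfg = replace(config.base, joint=joint,
                              fes_condition=condition, seed=seed)
                label = f"{joint}/{condition}/trial{rep}"
                t_start = time.perf_counter()
                try:
                    trial = generate_trial(cfg)
                    decoded = decode_trial(trial, config.methods)
                    scores.extend(score_trial(decoded, joint, condition, rep))
                except Exception as exc:   # noqa: BLE001 — isolate per trial
                    log.warning("trial %s failed: %s", label, exc)
                    failures.append({"trial": label, "error": str(exc)})
                    continue
                log.info("trial %s done in %.1fs (sync ok=%s)", label,
                         time.perf_counter() - t_start,
                         decoded["report"].all_passed())
                if out is not None:
                    tdir = out / f"{joint}_{condition}_{rep:03d}"
                    manifest_entries.append(str(trial_io.write_trial(trial, tdir)))

    report = compile_report(scores) if scores else None
    if out is not None and report is not None:
        report.rmse_table.to_csv(out / "rmse_table.csv")
        (out / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
        run_manifest = {
            "config": dataclasses.asdict(config) | {
                "base": dataclasses.asdict(config.base)
            },
            "trials": manifest_entries,
            "failures": failures,
        }
        (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2))
    return report, failures


def simulate_pulse_errors(n_seeds: int = 1000, global_seed: int = 0,
                          base: Optional[TrialConfig] = None) -> dict:
    """Second-pulse recording error across many drift-free trials.

    For each seed a short trial is generated (all streams at their standard
    acquisition rates, with
    random clock offsets, hence random pulse phases relative to every
    sampling grid), pulses are detected, and the recording error — detected
    time minus the pulse's true arrival on that stream's clock — is
    measured for the second pulse.  Returns the per-stream maximum absolute
    error in seconds; by construction it cannot exceed one sampling period.
    """
    from .sync import detect_pulses

    if base is None:
        # offsets wider than one ultrasound frame period so the pulse phase
        # wraps every stream's sampling grid uniformly
        base = TrialConfig(duration_s=14.0, frame_shape=(32, 32),
                           pulse_times=(1.0, 11.5),
                           clock_offset_range_s=0.25)
    errors: dict = {}
    for i in range(n_seeds):
        trial = generate_trial(replace(base, seed=trial_seed(global_seed, i)))
        truth = trial.ground_truth
        sources = dict(trial.streams)
        sources["us"] = trial.frames
        for sid, src in sources.items():
            event = detect_pulses(src)[1]
            arrival = truth.pulse_times[1] + trial.clock_offsets[sid]
            err = abs(event.recorded_time_s - arrival)
            errors[sid] = max(errors.get(sid, 0.0), err)
    return errors


def run_noise_sweep(base: TrialConfig, noise_levels, n_trials: int = 3,
                    global_seed: int = 0) -> dict:
    """Mean correlation-decoder RMSE at each frame-noise level (fixed seeds)."""
    results = {}
    for level in noise_levels:
        cell = []
        for rep in range(n_trials):
            seed = trial_seed(global_seed, rep)    # same seeds at every level
            cfg = replace(base, frame_noise_std=float(level), seed=seed)
            trial = generate_trial(cfg)
            decoded = decode_trial(trial, methods=("smg_correlation",))
            sc = score_trial(decoded, cfg.joint, cfg.fes_condition, rep)
            cell.append(sc[0].rmse)
        results[float(level)] = float(np.mean(cell))
    return results
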