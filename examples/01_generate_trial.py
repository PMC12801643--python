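"""Generate one synthetic multimodal trial and write it to disk.

A trial emulates 90 s of paced full range-of-motion wrist movement recorded
simultaneously by surface EMG (2000 Hz), motion capture (100 Hz), an
EEG-surrogate channel (1000 Hz) and B-mode ultrasound (5 fps), each on its
own clock and each carrying two synchronization pulses.  Here we use a
short 20-s trial so the example runs in seconds.
"""
from pathlib import Path

from sonokin import TrialConfig, generate_trial, write_trial

cfg = TrialConfig(joint="wrist", fes_condition="OFF", duration_s=20.0,
                  frame_shape=(64, 64), pulse_times=(2.0, 12.0), seed=42)
trial = generate_trial(cfg)

print(f"trial: {cfg.joint}, FES-{cfg.fes_condition}, {cfg.duration_s:.0f} s")
print(f"ultrasound frames: {len(trial.frames)} at {cfg.us_fps:.0f} fps, "
      f"{trial.frames.frame_shape[1]}x{trial.frames.frame_shape[0]} px "
      f"(bottom {trial.frames.pulse_roi_rows} rows = pulse-trace ROI)")
for sid, s in trial.streams.items():
    print(f"{sid:>13}: {len(s)} samples at {s.rate:.0f} Hz, "
          f"clock offset {trial.clock_offsets[sid]*1e3:+.1f} ms")
print(f"true pulse emission times: {trial.ground_truth.pulse_times} s")

out = Path("scratch/example_trial")
manifest = write_trial(trial, out)
print(f"\nwritten to {manifest}")
print("the directory holds one multi-frame TIFF per frame stack, one CSV "
      "per stream (time_s,value,trigger) and a JSON manifest")
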