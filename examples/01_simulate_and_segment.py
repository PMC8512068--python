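"""Simulate an annotated accelerometer recording and window it.

Generates a recording with six freezing-of-gait episodes, fuses the ankle
sensor's three axes into a magnitude stream, cuts it into non-overlapping
2-second windows, labels them, and marks the window before each freeze
onset as PreFOG.  The printed counts show the class imbalance the pipeline
must correct: one PreFOG window per episode versus many walking windows.
"""

from fogsense.io import combine_magnitude
from fogsense.segmentation import class_counts, relabel_prefog, segment_recording
from fogsense.synthetic import SimulationConfig, simulate_recording

cfg = SimulationConfig(n_fog_events=6, seed=42)
recording, truth = simulate_recording(cfg)
print(f"recording: {len(recording)} samples at {recording.fs:.0f} Hz "
      f"({len(recording) / recording.fs:.0f} s), "
      f"{len(truth.fog_events)} FOG episodes")

magnitude = combine_magnitude(recording)
windows = relabel_prefog(segment_recording(magnitude, w=2.0, sensor="A"))
counts = class_counts(windows)
print(f"windows (w=2 s): {len(windows)} total -> "
      f"NonFOG={counts[0]}, FOG={counts[1]}, PreFOG={counts[2]}")
print("PreFOG equals the episode count: exactly one transition window "
      "precedes each freeze onset.")
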