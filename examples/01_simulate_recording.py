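"""Generate a synthetic 20-min resting-state EEG with known ground truth.

Builds the default 27-channel recording (25 EEG + EOG + ECG at 200 Hz),
writes it as EDF with a TSV stage sidecar, and prints the latent stage
composition — the "truth" every downstream step is judged against.
"""

from collections import Counter
from pathlib import Path

import vigileeg as vg

config = vg.SimulationConfig(seed=1)
trajectory = vg.sample_stage_trajectory(config)
recording, truth = vg.synthesize_recording(trajectory, config)

out = Path("scratch/example_recording")
out.parent.mkdir(exist_ok=True)
paths = vg.write_recording(recording, truth, out)

print(f"channels: {recording.n_channels}, samples/channel: {recording.n_samples}")
print(f"wrote {paths['edf'].name} and {paths['stages'].name}")
counts = Counter(truth.stage_labels)
for stage in ("0", "A1", "A2", "A3", "B1", "B2/3"):
    print(f"  true {stage:<5} {counts.get(stage, 0):4d} s")
print(f"  artifact seconds: {len(truth.artifact_seconds)}, "
      f"SEM events: {len(truth.sem_events)}, blinks: {len(truth.blink_times)}")
# Stage seconds are the latent vigilance states; the classifier must
# recover them from the rendered signals alone.
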