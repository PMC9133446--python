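"""Per-recording vigilance outcomes from a stage sequence.

Computes the three outcome measures — relative stage occurrence, mean
vigilance level (7 = active wakefulness ... 1 = sleep onset) and the
arousal stability index (8 = stable arousal ... 1 = early deep decline).
"""

import vigileeg as vg

config = vg.SimulationConfig(seed=4)
labels = vg.sample_stage_trajectory(config)

summary = vg.summarize(labels)
print("relative occurrence (artifact-free segments):")
for stage, frac in summary.occurrence.items():
    if frac:
        print(f"  {stage:<5} {frac:.3f}")
print(f"mean vigilance level: {summary.mean_vigilance:.3f}  (range 1-7)")
print(f"arousal stability index: {summary.stability_index}  (range 1-8)")

declining = ["A1"] * 800 + ["B2/3"] * 400  # arousal collapses late
print("late decline example ->",
      vg.arousal_stability_index(declining))
# Lower stability scores mean the arousal decline starts earlier in the
# recording; a sequence that only turns drowsy in the last third keeps a
# mid-range score.
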