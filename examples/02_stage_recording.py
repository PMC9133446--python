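"""Stage a synthetic recording and compare against its ground truth.

Runs the full chain — zero-phase filtering, ICA artifact removal, 1-s
segmentation, artifact/graphoelement screening, vigilance staging — and
prints the per-stage agreement with the generator's latent labels.
"""

from collections import Counter

import vigileeg as vg

config = vg.SimulationConfig(duration=600.0, seed=1)
recording, truth = vg.simulate(config)

cleaned, segments = vg.preprocess(recording, run_ica=True, ica_seed=1)
staged = vg.classify_recording(cleaned, segments)

pred = staged["stage"].tolist()
hits = Counter()
totals = Counter()
for true_lab, pred_lab in zip(truth.stage_labels, pred):
    if pred_lab == "ARTIFACT":
        continue
    totals[true_lab] += 1
    hits[true_lab] += true_lab == pred_lab

overall = sum(hits.values()) / sum(totals.values())
print(f"agreement on artifact-free seconds: {overall:.1%}")
for stage in ("0", "A1", "A2", "A3", "B1", "B2/3"):
    if totals[stage]:
        print(f"  {stage:<5} {hits[stage]:4d}/{totals[stage]:<4d} "
              f"({hits[stage] / totals[stage]:.0%})")
# A2/A3 sit on a noisy anterior/posterior alpha ratio and are the usual
# confusions; B1 misses occur when no slow eye movement falls nearby.
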