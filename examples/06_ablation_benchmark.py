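"""Ablation of the two model components on the synthetic noisy benchmark.

Runs the full recognizer and the two ablations over a few paired seeds:
'no-interaction' keeps every intermediate inside the chosen boundaries,
'no-position' drops the boundary model and groups components purely by
pairwise interaction.  The ordering full >= no-interaction >> no-position
mirrors, at desk scale, the contribution of each module.
"""

import numpy as np

from comd.benchmark import ablation_f1

seeds = range(5)
results = ablation_f1(seeds, epsilon=0.6)

print(f"micro-F1 at IoU threshold 0.6, {len(list(seeds))} paired seeds")
for mode, values in results.items():
    print(f"  {mode:15s} mean {np.mean(values):6.2f}   per-seed "
          + " ".join(f"{v:6.2f}" for v in values))

print("\nPosition modelling contributes the boundaries (its removal is")
print("catastrophic); interaction scoring cleans fillers out of spans.")
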