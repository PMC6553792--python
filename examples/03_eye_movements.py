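"""Simulate fixational eye movements and quantize them to cone shifts.

Prints the typical within-trial retinal displacement (a few cone spacings)
and the rarity of microsaccades in a 54-ms trial.
"""

import numpy as np

from coneobserver import sample_microsaccades, simulate_drift, simulate_em_path

PITCH = 2.0 / 79 * 60.0  # arcmin between cones at 1,560 cones/deg^2

disp = []
for seed in range(200):
    path = simulate_drift(216.0 + 54.0, 2.0, seed=seed)
    trial = path[108:]
    disp.append(np.max(np.linalg.norm(trial - trial[0], axis=1)) / PITCH)
print(f"within-trial drift displacement over 200 trials:")
print(f"  median {np.median(disp):.1f} cones, 90th percentile {np.percentile(disp, 90):.1f} cones")
print("(small relative to the ~6-cone period of the 4 cpd stimulus)")

n_events = sum(bool(sample_microsaccades(54.0, seed=s)) for s in range(1000))
print(f"\ntrials with a microsaccade in 54 ms: {n_events / 10:.1f}%")
print("(the 450-ms mean interval makes microsaccades rare within a trial)")

path = simulate_em_path(54.0, PITCH, seed=0)
print(f"\nexample quantized path (dx, dy in cone units):\n{path.shifts[:10].T}")
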