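"""Sweep a biological factor and summarize threshold sensitivity.

Runs scaled experiments across added defocus, fits threshold versus
diopters linearly, and inverts the fit: how much defocus raises the
threshold by 1.5 percentage points? (At full scale the answer is ~7 D —
far beyond any plausible optical variation around the visual field.)
Swap `factor` to 'density' or 'lmratio' for the other sweeps.
"""

import numpy as np

from coneobserver import ExperimentConfig, sweep

cfg = ExperimentConfig(
    contrast_levels=list(np.geomspace(0.005, 0.10, 5)),
    trials_per_contrast=80,
    n_repeats=1,
    master_seed=11,
)
res = sweep(cfg, "defocus", [0.0, 1.0, 2.0], progress=True)

print("\nthreshold vs added defocus:")
for d, t in zip(res.grid, res.thresholds_percent):
    print(f"  {d:5.2f} D: {t:5.2f}%")
fit = res.factor_fit
print(f"linear fit: slope {fit.slope:.3f} pp/D, r^2 = {fit.r_squared:.2f}")
print(f"defocus for a +1.5-pp threshold increase: {res.required_change(1.5):.1f} D")
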