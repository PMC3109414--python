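"""Detect a change in the slope of the biomarker-CAMCOG relation.

CAMCOG scores are integers, so ties are split at random to form an equally
spaced rank series; piecewise-linear segmentation escalates its window and
tolerance until a single change-point emerges, and the whole procedure is
repeated (here 1000 times) with fresh tie-splitting seeds. The reported
slope change-point is the median over repetitions.
"""

import numpy as np

from cogpoint import default_scenarios, generate_cohort, slope_changepoint

cfg = default_scenarios()["tau"]
table = generate_cohort({"tau": cfg}, 95, 97, seed=21)

res = slope_changepoint(
    table.camcog.to_numpy(float),
    table.tau.to_numpy(float),
    repetitions=1000,
    master_seed=5,
)
vals = res.changepoints[~np.isnan(res.changepoints)]
q1, q3 = np.percentile(vals, [25, 75])
print(f"true change-point       : CAMCOG {cfg.theta:.0f}")
print(f"median over repetitions : CAMCOG {res.median:.1f}")
print(f"IQR over repetitions    : [{q1:.1f}, {q3:.1f}]")
print(f"failed repetitions      : {res.n_failed} of {res.repetitions}")
print(
    "\nTie-splitting is the only randomness between repetitions, so a tight"
    "\nIQR means the detected slope change is stable against the arbitrary"
    "\nordering of participants sharing a CAMCOG score."
)
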