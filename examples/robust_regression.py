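"""MM-robust regression versus ordinary least squares under contamination.

Fits a line to data whose upper-leverage tranche has been grossly shifted:
the MM estimate (50% breakdown S-scale + 95%-efficiency bisquare M-step)
recovers the true slope while least squares is dragged away.
"""

import numpy as np

from cogpoint import mm_regression

rng = np.random.default_rng(3)
x = rng.normal(0, 1, 200)
y = 2.0 + 1.0 * x + rng.normal(0, 1, 200)
y[np.argsort(x)[-60:]] += 20.0  # 30% gross outliers at +20 SD, high leverage

fit = mm_regression(x, y)
ols = np.polyfit(x, y, 1)
print(f"true slope        : 1.00")
print(f"MM slope          : {fit.slope:.3f}  (t = {fit.t_slope:.2f}, {fit.df} df)")
print(f"OLS slope         : {ols[0]:.3f}")
print(f"min outlier weight: {fit.weights[np.argsort(x)[-60:]].max():.3f}")
print(
    "\nThe MM slope stays within a few hundredths of the truth because the"
    "\nbisquare weights (last line) drive the contaminated points to ~0,"
    "\nwhile least squares is pulled far off by the same 30% contamination."
)
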