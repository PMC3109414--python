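"""Detect a change in a biomarker's overall level along the CAMCOG axis.

Generates an Abeta42-like cohort (change-point at CAMCOG 90), scans the
structural-change F statistic over candidate splits, and reports the
RSS-minimizing breakpoint with a permutation p-value.
"""

from cogpoint import default_scenarios, fstat_scan, generate_cohort, rss_breakpoint

cfg = default_scenarios()["abeta42"]
table = generate_cohort({"abeta42": cfg}, 95, 97, seed=11)
camcog = table.camcog.to_numpy(float)
y = table.abeta42.to_numpy(float)

scan = fstat_scan(camcog, y, trim=0.15, n_permutations=999, seed=0)
bp = rss_breakpoint(camcog, y)

print(f"true change-point      : CAMCOG {cfg.theta:.0f}")
print(f"sup-F                  : {scan.sup_f:.1f} at CAMCOG {scan.changepoint_camcog:.0f}")
print(f"permutation p          : {scan.p_value:.3f} ({scan.n_permutations} permutations)")
print(f"RSS breakpoint         : CAMCOG {bp.changepoint_camcog:.0f} "
      f"(left regime n = {bp.split_size})")
print(
    "\nThe sup-F position and the RSS-minimizing split coincide for the"
    "\nconstant-per-regime level model; the permutation p (smallest possible"
    "\nvalue 1/1000 here) confirms the level shift is not a sorting artefact."
)
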