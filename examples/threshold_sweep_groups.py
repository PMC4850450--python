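"""Threshold sweep with two-sample group statistics on a reduced cohort.

Simulates both behavioral groups, runs the per-subject sweep (binarize at
each grid threshold, compute C/L/K_mean/sigma with a degree-preserving null)
and prints the group contrast with Welch t-tests per threshold.  Sizes are
reduced (8 subjects per group, 20 null networks, coarse grid) so the script
finishes in well under a minute.
"""

import numpy as np

from nirsnet import SimulationConfig, run_pipeline

result = run_pipeline(
    config=SimulationConfig(n_subjects=8, seed=42),
    case="win-win",
    grid=np.array([0.275, 0.35, 0.425, 0.5]),
    null_n=20,
    seed=42,
)

print(f"{result.group_a} (a) vs {result.group_b} (b), case {result.case!r}\n")
for metric in ("C", "L", "K_mean", "sigma"):
    print(metric)
    sub = result.metric_stats(metric)
    for _, row in sub.iterrows():
        star = "*" if row["significant"] else " "
        print(
            f"  T={row['threshold']:5.3f}  a={row['mean_a']:6.3f}±{row['sd_a']:5.3f}"
            f"  b={row['mean_b']:6.3f}±{row['sd_b']:5.3f}"
            f"  t={row['t']:+6.2f}  p={row['p']:6.4f} {star}"
        )

print(
    "\nExpected pattern: the spontaneous group shows higher C, lower L and "
    "higher K_mean, and both groups keep sigma > 1 (small-world regime); "
    "* marks p < 0.05.  At this reduced size (8 subjects per group) the "
    "contrasts are visible but rarely significant; the full 24-subject "
    "cohort is what powers the t-tests."
)
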