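"""Generate a small synthetic fNIRS cohort and inspect its structure.

Builds recordings for both behavioral groups (spontaneous vs control
deception), then prints the trial layout and the mean inter-channel
correlation per group.  Higher coupling in the spontaneous group should show
up directly as a larger mean |r|.
"""

import numpy as np

from nirsnet import SimulationConfig, simulate_cohort

config = SimulationConfig(n_subjects=4, seed=42)
cohort = simulate_cohort(config)

rec = cohort[0]
print(f"{len(cohort)} recordings ({config.n_subjects} subjects x 2 groups)")
print(
    f"each: {len(rec.channels)} channels x {rec.n_samples} samples "
    f"at {rec.fs:g} Hz ({rec.n_samples / rec.fs:.0f} s), "
    f"{len(rec.markers)} trial markers"
)

for group in ("spontaneous", "control"):
    values = []
    for r in (r for r in cohort if r.group == group):
        corr = np.abs(np.corrcoef(r.data))
        values.append(corr[np.triu_indices(len(r.channels), k=1)].mean())
    print(f"mean inter-channel |r|, {group:11s}: {np.mean(values):.3f}")

print(
    "\nThe spontaneous group's stronger latent coupling produces the denser "
    "correlation structure that the network pipeline should recover."
)
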