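"""From one subject's recording to a binary brain network and its indices.

Runs the single-subject pipeline — band-pass filter, epoch on one trial
case, Pearson correlation matrix, binarization — and prints the clustering
coefficient C, average path length L, average node degree K_mean, the
degree-preserving null means, and the small-worldness sigma at two
thresholds.  sigma > 1 indicates above-random clustering at near-random path
length (a small-world network).
"""

from nirsnet import (
    SimulationConfig,
    bandpass,
    binarize,
    normalize_and_average,
    pearson_matrix,
    segment,
    simulate_recording,
    small_world_metrics,
)

config = SimulationConfig(seed=42)
recording = simulate_recording(config, "S01", "spontaneous")

epochs = normalize_and_average(segment(bandpass(recording), "win-win"))
matrix = pearson_matrix(epochs)
print(f"correlation matrix: {matrix.n_channels} channels, "
      f"{matrix.n_samples_used} samples per channel")

for threshold in (0.275, 0.5):
    net = binarize(matrix, threshold)
    m = small_world_metrics(net, n_random=100, seed=7)
    print(
        f"T={threshold:5.3f}  edges={net.n_edges:3d}  C={m.C:.3f}  "
        f"L={m.L:.3f}  K_mean={m.K_mean:.2f}  "
        f"C_rand={m.C_rand:.3f}  L_rand={m.L_rand:.3f}  sigma={m.sigma:.3f}"
    )

print("\nRaising T prunes weak edges: degree falls, paths lengthen, and the "
      "clustering that survives relative to the null drives sigma up.")
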