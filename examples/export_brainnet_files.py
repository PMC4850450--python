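"""Export a thresholded group-average network as BrainNet Viewer files.

Builds the group-average correlation matrix of a small spontaneous-group
cohort, binarizes it at T = 0.5, and writes the standard ``.node`` and
``.edge`` text files (plus the matrix itself as TSV) that BrainNet Viewer
renders as a 3D brain network.  The packaged channel layout is a synthetic
bilateral frontal grid, a stand-in for digitizer-registered MNI coordinates.
"""

from pathlib import Path

from nirsnet import (
    SimulationConfig,
    bandpass,
    binarize,
    group_average,
    normalize_and_average,
    pearson_matrix,
    segment,
    simulate_cohort,
)
from nirsnet.io import example_channel_coords, export_brainnet, write_matrix

out = Path("brainnet_out")
config = SimulationConfig(n_subjects=4, seed=42)
matrices = [
    pearson_matrix(normalize_and_average(segment(bandpass(rec), "win-win")))
    for rec in simulate_cohort(config)
    if rec.group == "spontaneous"
]
avg = group_average(matrices)
net = binarize(avg, 0.5)

write_matrix(avg, out / "group_average_corr.tsv")
node_path, edge_path = export_brainnet(net, example_channel_coords(24), out / "network")
print(f"group-average matrix over {len(matrices)} subjects -> {out}/group_average_corr.tsv")
print(f"{net.n_edges} edges at T=0.5 -> {node_path} and {edge_path}")
print("Load the .node/.edge pair in BrainNet Viewer for the 3D rendering.")
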