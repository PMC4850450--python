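# nirsnet

Small-world functional brain-network analysis of multichannel fNIRS
recordings, built for group comparisons of task conditions — for example,
spontaneous versus instructed ("control") deception measured over the
prefrontal cortex.

fNIRS measures cortical oxygenated-hemoglobin (HbO2) changes through
source–detector channel pairs.  Treating each channel as a network node and
the Pearson correlation between two channels' HbO2 time series as the edge
weight, the pipeline binarizes each subject's correlation matrix over a grid
of thresholds and characterizes the resulting undirected graphs with the
standard small-world indices:

- **Clustering coefficient** `C = mean_i [ E_i / (k_i (k_i − 1)/2) ]` — the
  fraction of each node's neighbor pairs that are themselves connected
  (`E_i` edges among the `k_i` neighbors of node *i*); local information
  transfer density.
- **Average path length** `L = mean over node pairs of the geodesic
  distance` — global transfer efficiency (reachable pairs only when a graph
  disconnects, flagged as such).
- **Average node degree** `K_mean = 2E/N` — network density.
- **Small-worldness** `σ = (C/C_rand) / (L/L_rand)`, where `C_rand`, `L_rand`
  are means over 100 degree-preserving random reference networks generated
  with the Markov-chain double-edge-swap algorithm.  `σ > 1` marks a
  small-world network: more clustered than random at near-random path length.

The pipeline covers preprocessing (0.01–0.3 Hz zero-phase band-pass, 13-s
trial epochs with 2 s of pre-stimulus baseline, per-epoch normalization and
run averaging), per-subject and group-average connectivity matrices, the
threshold sweep (default grid 0.275–0.625 in steps of 0.025, with
binarization rule |r| ≥ T), per-threshold Welch t-tests between groups, and
BrainNet Viewer exports.  Because no public dataset accompanies the study
design it emulates, a first-class synthetic-data module generates realistic
cohorts (24 subjects × 24 channels at 10 Hz, HRF-shaped evoked responses,
physiological oscillations, community-structured inter-channel correlations
with a group-dependent coupling strength), so every stage is testable end to
end.

## Worked example

From one subject's synthetic recording to its brain-network indices
(`examples/network_metrics_demo.py`):

```text
correlation matrix: 24 channels, 1300 samples per channel
T=0.275  edges=240  C=0.911  L=1.130  K_mean=20.00  C_rand=0.902  L_rand=1.130  sigma=1.010
T=0.500  edges=114  C=0.711  L=1.717  K_mean=9.50  C_rand=0.534  L_rand=1.619  sigma=1.255
```

At the loose threshold nearly all channel pairs count as connected, so the
network is close to complete and barely distinguishable from its
degree-preserving null (`σ ≈ 1`).  At T = 0.5 only the strong correlations
survive; the clustering that remains (C = 0.711 against C_rand = 0.534) at a
near-null path length pushes `σ` to 1.255 — a small-world topology.

The group-level entry point runs the whole design in one call:

```python
from nirsnet import run_pipeline

result = run_pipeline(case="win-win", null_n=100, seed=0)   # 24 + 24 subjects
print(result.metric_stats("K_mean"))   # means, SDs, t and p per threshold
```

On the default synthetic cohort the spontaneous group shows higher C, lower
L and higher K_mean than the control group at every grid threshold, both
groups stay in the small-world regime (`σ > 1` throughout), and the degree
difference is significant (p < 0.05) at the majority of thresholds —
the qualitative pattern expected when one condition couples the recorded
cortex more strongly than the other.  `examples/threshold_sweep_groups.py`
prints a reduced-size version of this table in under a minute.

A thin CLI mirrors the stages (`nirsnet simulate | preprocess | connectivity
| metrics | sweep | run | export-brainnet`); `nirsnet run --config cfg.yaml
--out out/ --seed 1` executes the end-to-end pipeline and records the exact
configuration and seed next to the results.

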