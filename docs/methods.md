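# Methods

## Pipeline overview

Per subject and trial case the analysis chain is

1. zero-phase band-pass filter of the HbO2 time series (0.01–0.3 Hz),
2. epoching on trial markers: 13-s windows, 2 s pre-stimulus + 11 s
   post-stimulus and recovery,
3. per-epoch normalization and run averaging,
4. Pearson correlation matrix across channels (nodes = channels),
5. binarization at a threshold T (edge iff |r| ≥ T; the absolute value means
   strong anticorrelations also form edges),
6. graph indices C, L, K_mean plus a 100-network degree-preserving null and
   the small-worldness σ,
7. repeated over the threshold grid 0.275–0.625 (step 0.025) and compared
   between the two behavioral groups with per-threshold Welch t-tests.

## Preprocessing choices

**Filter.**  The band edges are analysis constants of the emulated design;
the family and order are not, so the package uses a 4th-order Butterworth
band-pass applied forward–backward (`scipy.signal.sosfiltfilt`).  Zero-phase
filtering preserves epoch timing; the effective magnitude response is the
squared design response, which still leaves the 0.1 Hz passband gain within
[0.9, 1.1] and suppresses DC by > 99 % and 1 Hz (cardiac) by > 90 %.
Recordings shorter than the filter warm-up are rejected.

**Normalization.**  Each epoch is baseline-corrected by subtracting its
per-channel pre-stimulus mean.  An optional variant additionally scales each
epoch to unit pre-stimulus SD, but it is off by default: a 2-s baseline of a
0.01–0.3 Hz band-limited signal contains roughly 3–5 effective degrees of
freedom, so the SD estimate is mostly noise, and dividing by it measurably
attenuates inter-channel correlations (~25–30 % on synthetic cohorts) and
dilutes the group contrast.  Correlations are computed on the per-trial
normalized epochs concatenated per case (10 trials × 130 samples by
default); using the run-averaged epoch instead is supported
(`use_average=True`).

## Graph conventions

- Nodes with degree < 2 contribute C_i = 0 (the neighbor-pair fraction is
  undefined there); the network C averages over **all** N nodes.
- L averages geodesics over reachable unordered pairs.  A disconnected graph
  does not produce infinities: the unreachable-pair count and a `connected`
  flag are recorded instead, and the sweep tables carry per-group
  disconnection counts so that the high-threshold regime — which the grid's
  upper bound is meant to avoid — remains visible.  `check_bounds` reports
  the two standard grid diagnostics: the smallest grid value whose
  correlation magnitude is statistically significant (two-sided test of
  r = 0 via t = r√((n−2)/(1−r²))) and the largest grid value at which every
  network keeps mean degree ≥ ln N.
- The diagonal is never an edge, and binarization includes the boundary
  (|r| = T is an edge).

## Null model

Degree-preserving randomization uses the Markov-chain double-edge swap:
pick two current edges (a,b), (c,d) (with a random orientation), and replace
them by (a,d), (c,b) unless a self-loop or duplicate edge would result.
Each random network attempts 10·E swaps — a conventional mixing heuristic —
and rejected attempts count toward the total, so a run is a pure function of
the seed.  Ensemble members get independent sub-seeds spawned from one
`numpy.random.SeedSequence`; C_rand and L_rand are ensemble means, with
disconnected members handled exactly as above and counted.
σ = (C/C_rand)/(L/L_rand) requires positive null means; graphs too sparse
for the comparison yield an error (or NaN inside the sweep, where high
thresholds can legitimately produce them).

## Group statistics

Welch's unequal-variance t-test is the default (a pooled-variance and a
paired variant exist); two-sided p values are reported per threshold and
metric with a significance flag at α = 0.05 and no correction across the 15
thresholds, matching the per-threshold convention of the emulated design.
An optional Benjamini–Hochberg flag adjusts within each metric's curve.
Group-level networks can also be built by averaging correlation matrices
first and thresholding the average (the figure-reproduction path); the sweep
itself always works per subject, which is what the t-tests require.
Fisher-z averaging is deliberately not applied when averaging matrices
(plain coefficient means match the emulated analysis); callers can arctanh
the inputs themselves if they want it.

## Synthetic cohorts

The generator emulates the study conditions: 24 subjects per group, 24
channels at 10 Hz, 10 trials per case for each of three trial cases
(win-win, lose-win, lose-lose), 13-s epochs, recordings of ~7.6 min.  Each
channel is a sum of

- a **community latent** (two 12-channel communities, mimicking bilateral
  frontal patches), entering with weight = the group coupling `a`
  (default 0.92 spontaneous, 0.60 control, ±5 % per-subject jitter);
  communities are mixed with weight `cross_community_mix = 0.5`, so
  between-community correlations are present but weaker than within;
- a **sub-cluster latent** shared by blocks of 4 channels (weight 0.75·a),
  modelling small optode patches with extra local coherence — this is the
  source of the networks' above-random clustering and hence of σ > 1;
- an **evoked response**: a peak-normalized double-gamma HRF (response gamma
  shape 6 peaking at 5 s, undershoot gamma shape 16 scaled by 1/6) convolved
  with the trial onset train, identical across channels;
- **systemic oscillations** (Mayer ~0.1 Hz, respiratory ~0.3 Hz, cardiac
  ~1.1 Hz) shared across channels, and
- **independent white channel noise** with per-channel log-uniform scale in
  [0.35, 2.0] × 0.6.

Latents and channel noise share a flat spectrum, so the analysis band-pass
attenuates them equally and the designed correlation contrast survives
preprocessing.  The heterogeneous noise scales spread the pairwise
correlations over the whole threshold grid instead of collapsing them onto
one value, which is what makes the sweep informative; the coupling defaults
were calibrated once (scratch-scale scan) so that the cohort reproduces the
regime the method is meant to detect — both groups' networks retain edges
and σ > 1 across the full grid, with the spontaneous group denser
throughout — and then frozen.  Seeding is hierarchical: a master seed plus a
CRC-32 of "subject|group" feeds a `SeedSequence`, so cohorts are bit-stable
and subjects independent.

**What the generator does not emulate:** raw optical densities and the
modified Beer-Lambert inversion (signals are generated directly as HbO2),
motion artifacts, HbR channels, spatially continuous correlation decay,
scalp/systemic physiology differences across channels beyond a scale factor,
and subject-specific trial counts for freely chosen behavior (the trial
count per case is a parameter instead).  Passing tests therefore demonstrate
that the pipeline recovers known, structured group differences from
HRF-shaped, band-limited, noisy signals — not that any particular real
cohort would show them.

## Numerical notes

- The HRF kernel is normalized by its sampled maximum; its analytic peak
  sits within 2 ms of t = 5 s, which lies on every sampling grid used, so
  kernels at different rates agree after subsampling.
- Thresholds are compared with ≥ on the raw floating-point values; the grid
  is generated as `t_min + k·step` to keep the printed grid values exact to
  representation.
- Pearson matrices clip to [−1, 1], force an exact unit diagonal and exact
  symmetry; zero-variance channels produce zero correlations plus a warning
  rather than NaN.
- Path lengths come from unweighted BFS distances
  (`scipy.sparse.csgraph.shortest_path`); clustering from the triangle count
  `diag(A³)/2` (exact for N ≤ a few thousand, since counts are integers well
  below 2⁵³).
- The rewiring chain consumes its random numbers in a fixed order
  (edge-pair indices and orientations drawn up front), so results are
  reproducible across platforms for a given seed.

## Known limitations

- With only two latent communities, very high thresholds fragment subject
  networks; reachable-pair L then mixes within-component distances, which is
  why disconnection counts are reported alongside.  The default grid ceiling
  (0.625) together with the calibrated generator keeps group-mean degree
  above ~4 at the top of the grid.
- σ inherits the usual caveat of density: near-complete graphs give σ ≈ 1
  regardless of structure, so the bottom of the grid is the least
  discriminative region.
- The two behavioral groups are simulated as independent cohorts, matching
  the unpaired two-sample tests; the paired option in `compare_groups` is
  provided for designs where the same subjects perform both tasks.
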