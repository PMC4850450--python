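"""Degree-preserving random reference networks and small-worldness.

The null model is the Markov-chain double-edge swap: repeatedly pick two
edges (a,b) and (c,d) and replace them with (a,d) and (c,b) unless that would
create a self-loop or a duplicate edge.  Every accepted swap preserves each
node's degree exactly, so the ensemble randomizes topology while holding the
degree sequence fixed.  Small-worldness compares the observed network with
the ensemble means:

    sigma = (C / C_rand) / (L / L_rand),

with sigma > 1 the usual small-world criterion (more clustered than random at
near-random path length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_metrics import BinaryNetwork, NetworkMetrics, network_metrics

__all__ = [
    "NullEnsembleResult",
    "rewire",
    "null_ensemble",
    "small_worldness",
    "small_world_metrics",
]

#: attempted swaps per random network, as a multiple of the edge count
SWAPS_PER_EDGE = 10


def rewire(
    net: BinaryNetwork,
    n_swaps: int | None = None,
    seed: int | np.random.Generator | np.random.SeedSequence | None = None,
) -> BinaryNetwork:
    """One degree-preserving randomization of ``net``.

    Attempts ``n_swaps`` double-edge swaps (default ``SWAPS_PER_EDGE * E``);
    attempts that would create a self-loop or multi-edge are rejected but
    still count toward the total, so a run is fully determined by the seed.
    """
    rng = np.random.default_rng(seed)
    adjacency = net.adjacency.astype(bool).copy()
    edges = np.argwhere(np.triu(adjacency, k=1))
    n_edges = edges.shape[0]
    if n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    if n_swaps is None:
        n_swaps = SWAPS_PER_EDGE * n_edges
    pick = rng.integers(0, n_edges, size=(int(n_swaps), 2))
    orient = rng.integers(0, 2, size=int(n_swaps))
    for i in range(int(n_swaps)):
        e1, e2 = pick[i]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if orient[i]:
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adjacency[a, d] or adjacency[c, b]:
            continue
        adjacency[a, b] = adjacency[b, a] = False
        adjacency[c, d] = adjacency[d, c] = False
        adjacency[a, d] = adjacency[d, a] = True
        adjacency[c, b] = adjacency[b, c] = True
        edges[e1, 0], edges[e1, 1] = a, d
        edges[e2, 0], edges[e2, 1] = c, b
    return BinaryNetwork(
        labels=list(net.labels),
        adjacency=adjacency.astype(np.int8),
        threshold=net.threshold,
    )


@dataclass
class NullEnsembleResult:
    """Metrics of an ensemble of degree-preserving randomizations."""

    n_random: int
    C_rand: float
    L_rand: float
    per_network_metrics: list[NetworkMetrics]
    n_disconnected: int
    seed: object = None


def null_ensemble(
    net: BinaryNetwork,
    n_random: int = 100,
    n_swaps: int | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> NullEnsembleResult:
    """Ensemble of independently rewired copies of ``net``.

    ``C_rand`` and ``L_rand`` are the ensemble means (L over reachable pairs
    for any disconnected member; the count of such members is reported).
    Sub-seeds are spawned from ``seed``, so the ensemble is reproducible.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    metrics = []
    for child in ss.spawn(n_random):
        random_net = rewire(net, n_swaps=n_swaps, seed=np.random.default_rng(child))
        metrics.append(network_metrics(random_net))
    return NullEnsembleResult(
        n_random=n_random,
        C_rand=float(np.mean([m.C for m in metrics])),
        L_rand=float(np.mean([m.L for m in metrics])),
        per_network_metrics=metrics,
        n_disconnected=sum(not m.connected for m in metrics),
        seed=seed,
    )


def small_worldness(C: float, L: float, C_rand: float, L_rand: float) -> float:
    """sigma = (C/C_rand) / (L/L_rand)."""
    if not (C_rand > 0 and L_rand > 0):
        raise ValueError(
            "null means must be positive (graph too sparse for a null model): "
            f"C_rand={C_rand}, L_rand={L_rand}"
        )
    if not L > 0:
        raise ValueError("observed path length must be positive")
    return (C / C_rand) / (L / L_rand)


def small_world_metrics(
    net: BinaryNetwork,
    n_random: int = 100,
    n_swaps: int | None = None,
    seed: int | np.random.SeedSequence | None = None,
    strict: bool = True,
) -> NetworkMetrics:
    """Observed metrics plus null means and sigma for one network.

    With ``strict=False`` a network too sparse for the null comparison (no
    edges, zero null clustering) yields NaN sigma instead of raising — used
    by the threshold sweep where high thresholds can produce such networks.
    """
    m = network_metrics(net)
    try:
        ens = null_ensemble(net, n_random=n_random, n_swaps=n_swaps, seed=seed)
        m.C_rand, m.L_rand = ens.C_rand, ens.L_rand
        m.sigma = small_worldness(m.C, m.L, ens.C_rand, ens.L_rand)
    except ValueError:
        if strict:
            raise
        m.sigma = float("nan")
    return m
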