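"""Functional-network construction and graph statistics.

Networks are pairwise Pearson correlations between activity traces —
neuron-level (all responsive pairs) or region-level (per-region mean
traces).  On these weighted graphs the pipeline computes the mean
connectivity, the strong-connection ratio (fraction of correlations above
0.8), a spectral partition into k communities, Newman modularity with a
resolution parameter

    Q = (1/2m) Σ_ij [A_ij − γ k_i k_j / 2m] δ(c_i, c_j),

with m = ½ Σ_ij A_ij the total edge weight and k_i the weighted degree,
and weighted degree centrality (row sums of A).

Correlation weights can be negative; modularity and centrality are only
well defined on nonnegative graphs, so a negative-weight policy ("clip"
to zero, "abs", or "error") is applied first.  Raw signed weights are kept
for the mean connectivity and weight distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import SpectralClustering

from .data import CalciumDataset, RegionMap
from .respond import ResponsiveSet

__all__ = [
    "FunctionalNetwork",
    "Partition",
    "ModularityParams",
    "connectivity_matrix",
    "mean_connectivity",
    "strong_ratio",
    "region_network",
    "spectral_partition",
    "modularity",
    "degree_centrality",
    "greedy_partition",
]


@dataclass(frozen=True)
class FunctionalNetwork:
    """Symmetric weighted graph over neurons or regions.

    Weights lie in [−1, 1] with a zero diagonal.  ``meta`` carries
    provenance such as regions dropped for having no neurons.
    """

    weights: np.ndarray
    nodes: tuple
    level: str = "neuron"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "nodes", tuple(self.nodes))
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weight matrix must be square")
        if len(self.nodes) != W.shape[0]:
            raise ValueError("one node label per row required")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.abs(W) > 1.0 + 1e-12):
            raise ValueError("weights must lie in [-1, 1]")
        if np.any(np.diag(W) != 0):
            raise ValueError("diagonal must be zero (no self-edges)")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.weights[iu]

    def to_edge_list(self) -> pd.DataFrame:
        iu = np.triu_indices(self.n_nodes, k=1)
        return pd.DataFrame(
            {"i": [self.nodes[a] for a in iu[0]],
             "j": [self.nodes[b] for b in iu[1]],
             "w": self.weights[iu]})

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.weights, index=list(self.nodes),
                     columns=list(self.nodes)).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, level: str = "neuron") -> "FunctionalNetwork":
        frame = pd.read_csv(path, index_col=0)
        return cls(weights=frame.to_numpy(dtype=float),
                   nodes=tuple(frame.index), level=level)


@dataclass(frozen=True)
class Partition:
    """Node → community assignment with contiguous ids from 0."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(labels)
        if not np.array_equal(uniq, np.arange(len(uniq))):
            # relabel by first occurrence for contiguity
            order = {c: i for i, c in enumerate(pd.unique(labels))}
            labels = np.array([order[c] for c in labels])
        object.__setattr__(self, "labels", labels)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def to_frame(self, nodes=None) -> pd.DataFrame:
        nodes = nodes if nodes is not None else np.arange(len(self.labels))
        return pd.DataFrame({"node": list(nodes), "community": self.labels})


@dataclass(frozen=True)
class ModularityParams:
    """Resolution γ and the policy for negative correlation weights."""

    gamma: float = 1.0
    negative_policy: str = "clip"

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.negative_policy not in ("clip", "abs", "error"):
            raise ValueError("negative_policy must be clip, abs or error")

    def transform(self, W: np.ndarray) -> np.ndarray:
        if self.negative_policy == "clip":
            return np.clip(W, 0.0, None)
        if self.negative_policy == "abs":
            return np.abs(W)
        if np.any(W < 0):
            raise ValueError("negative weights present and policy is 'error'")
        return W


def connectivity_matrix(traces, nodes=None, level: str = "neuron") -> FunctionalNetwork:
    """Pairwise Pearson correlations between equal-length traces.

    ``traces`` is (n_series, n_samples).  Zero-variance series are an
    error (the offending node is named); the diagonal is forced to zero.
    """
    X = np.asarray(traces, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 equal-length series")
    if X.shape[1] < 3:
        raise ValueError("series must have length >= 3")
    if nodes is None:
        nodes = tuple(range(X.shape[0]))
    sd = X.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if len(bad):
        raise ValueError(f"zero-variance series for node(s): "
                         f"{[nodes[b] for b in bad]}")
    W = np.corrcoef(X)
    W = np.clip((W + W.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(W, 0.0)
    return FunctionalNetwork(weights=W, nodes=nodes, level=level)


def mean_connectivity(net: FunctionalNetwork) -> float:
    """Mean signed weight over the strict upper triangle."""
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    return float(net.upper_triangle().mean())


def strong_ratio(net: FunctionalNetwork, threshold: float = 0.8) -> float:
    """Fraction of pairs with correlation strictly above ``threshold``.

    The denominator is all off-diagonal pairs of the matrix ("all existing
    connections"); the inequality is strict, so ties at the threshold do
    not count as strong.
    """
    if net.n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    tri = net.upper_triangle()
    return float(np.count_nonzero(tri > threshold) / len(tri))


def region_network(
    dataset: CalciumDataset,
    regions: RegionMap,
    responsive_only: bool = False,
    rset: ResponsiveSet | None = None,
) -> FunctionalNetwork:
    """Region-level network: Pearson correlation of per-region mean traces.

    Neuron traces are averaged within each region first; regions without
    any included neuron are dropped and listed in ``meta['dropped']``.
    With ``responsive_only`` the average runs over the union-responsive
    neurons (requires ``rset``).
    """
    include = np.ones(dataset.n_neurons, dtype=bool)
    if responsive_only:
        if rset is None:
            raise ValueError("responsive_only requires a ResponsiveSet")
        include = rset.union.copy()
    labels = dataset.regions
    mean_traces, kept, dropped = [], [], []
    for rid, name in enumerate(regions.names):
        sel = include & (labels == rid)
        if sel.any():
            mean_traces.append(dataset.traces[sel].mean(axis=0))
            kept.append(name)
        else:
            dropped.append(name)
    if len(kept) < 2:
        raise ValueError("fewer than 2 populated regions")
    net = connectivity_matrix(np.vstack(mean_traces), nodes=tuple(kept),
                              level="region")
    net.meta["dropped"] = dropped
    return net


def spectral_partition(
    net: FunctionalNetwork, k: int = 3, seed: int | None = 0, max_retries: int = 5
) -> Partition:
    """Spectral clustering of the network into ``k`` communities.

    Correlation weights are mapped to affinities via (w + 1)/2 (so
    [−1, 1] → [0, 1]) with unit self-affinity.  An empty community triggers
    a bounded retry with a fresh k-means seed.
    """
    if k > net.n_nodes:
        raise ValueError("k cannot exceed the node count")
    if k == net.n_nodes:
        return Partition(labels=np.arange(net.n_nodes))
    affinity = (net.weights + 1.0) / 2.0
    np.fill_diagonal(affinity, 1.0)
    base = 0 if seed is None else seed
    for attempt in range(max_retries):
        sc = SpectralClustering(
            n_clusters=k, affinity="precomputed", random_state=base + attempt)
        labels = sc.fit_predict(affinity)
        if len(np.unique(labels)) == k:
            return Partition(labels=labels)
    raise RuntimeError(f"spectral clustering produced an empty community "
                       f"in {max_retries} attempts")


def modularity(
    net: FunctionalNetwork,
    partition: Partition,
    params: ModularityParams | None = None,
) -> float:
    """Newman modularity Q with resolution γ over ordered node pairs.

    Q = (1/2m) Σ_ij [A_ij − γ k_i k_j / 2m] δ(c_i, c_j), where A is the
    policy-transformed weight matrix, k_i = Σ_j A_ij and m = ½ Σ_ij A_ij.
    Every edge is counted in both orientations, matching the 2m
    normalization.  For the single-community partition at γ = 1, Q = 0
    identically.
    """
    params = params or ModularityParams()
    if len(partition.labels) != net.n_nodes:
        raise ValueError("partition must cover all nodes")
    A = params.transform(net.weights)
    two_m = A.sum()
    if two_m <= 0:
        raise ValueError("no edge weight remains after the negative-weight policy")
    k = A.sum(axis=1)
    same = partition.labels[:, None] == partition.labels[None, :]
    B = A - params.gamma * np.outer(k, k) / two_m
    return float(B[same].sum() / two_m)


def degree_centrality(
    net: FunctionalNetwork,
    params: ModularityParams | None = None,
    binary: bool = False,
    threshold: float = 0.8,
) -> pd.Series:
    """Weighted degree per node: sum of incident (policy-transformed)
    weights; ``binary`` counts edges with weight strictly above
    ``threshold`` instead."""
    params = params or ModularityParams()
    A = params.transform(net.weights)
    if binary:
        values = (A > threshold).sum(axis=1).astype(float)
    else:
        values = A.sum(axis=1)
    return pd.Series(values, index=list(net.nodes), name="degree_centrality")


def greedy_partition(
    net: FunctionalNetwork, params: ModularityParams | None = None
) -> Partition:
    """Greedy modularity maximization (CNM) on the policy-transformed graph.

    The per-day re-optimization alternative to carrying a fixed day-1
    partition forward.
    """
    params = params or ModularityParams()
    A = params.transform(net.weights)
    G = nx.Graph()
    G.add_nodes_from(range(net.n_nodes))
    ii, jj = np.triu_indices(net.n_nodes, k=1)
    for a, b in zip(ii, jj):
        if A[a, b] > 0:
            G.add_edge(int(a), int(b), weight=float(A[a, b]))
    communities = nx.community.greedy_modularity_communities(
        G, weight="weight", resolution=params.gamma)
    labels = np.empty(net.n_nodes, dtype=int)
    for c, members in enumerate(communities):
        for m in members:
            labels[m] = c
    return Partition(labels=labels)
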