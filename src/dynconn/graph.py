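"""Weighted-graph centrality measures for connectivity matrices.

Degree centrality (DC) on a directed graph is the sum of in-degree and
out-degree strengths (column plus row sums of the weight matrix); on an
undirected graph it is the column sum. Betweenness centrality (BC) is
computed over weighted shortest paths with edge length ``1/weight`` —
the standard convention for connectome matrices, where a strong edge is
a short path. Hub nodes are those whose mean-normalized BC exceeds 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "WeightedGraphMatrix",
    "CentralityResult",
    "degree_centrality",
    "betweenness_centrality",
    "normalize_centrality",
    "identify_hubs",
]


@dataclass
class WeightedGraphMatrix:
    """Square matrix of nonnegative edge weights.

    The diagonal is ignored by every metric: self-connections are
    artifacts of correlation (r = 1 with itself) and of tractography
    seeding conventions, and carry no information.
    """

    weights: np.ndarray
    directed: bool = False
    node_labels: list[str] | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidArgumentError(f"weight matrix must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise InvalidArgumentError("weight matrix contains non-finite entries")
        if np.any(w < 0):
            raise InvalidArgumentError("edge weights must be nonnegative")
        if not self.directed:
            off = w - np.diag(np.diag(w))
            if not np.allclose(off, off.T, atol=1e-10):
                raise InvalidArgumentError("undirected graph requires a symmetric weight matrix")
        self.weights = w
        if self.node_labels is None:
            self.node_labels = [f"node_{i}" for i in range(w.shape[0])]
        elif len(self.node_labels) != w.shape[0]:
            raise InvalidArgumentError("node_labels length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class CentralityResult:
    values: np.ndarray
    metric: str  # "dc" or "bc"
    normalized: bool = False
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not self.node_labels:
            self.node_labels = [f"node_{i}" for i in range(len(self.values))]


def degree_centrality(g: WeightedGraphMatrix) -> CentralityResult:
    """Weighted degree centrality, diagonal excluded.

    Directed graphs: ``DC_i = sum_j w_ij + sum_j w_ji`` (out-strength
    plus in-strength). Undirected graphs: the column sum ``sum_j w_ji``.
    """
    w = g.weights - np.diag(np.diag(g.weights))
    if g.directed:
        values = w.sum(axis=1) + w.sum(axis=0)
    else:
        values = w.sum(axis=0)
    return CentralityResult(values=values, metric="dc", node_labels=list(g.node_labels))


def betweenness_centrality(g: WeightedGraphMatrix) -> CentralityResult:
    """Weighted betweenness centrality with edge length 1/weight.

    Zero-weight edges are treated as absent (a zero fiber probability
    means no connection, and 1/0 is undefined). Counts fractional
    contributions over all equal-length shortest paths; unreachable
    pairs contribute nothing. Unnormalized node counts are returned.
    """
    w = g.weights - np.diag(np.diag(g.weights))
    n = g.n_nodes
    graph = nx.DiGraph() if g.directed else nx.Graph()
    graph.add_nodes_from(range(n))
    rows, cols = np.nonzero(w)
    for i, j in zip(rows, cols):
        if not g.directed and i > j:
            continue
        graph.add_edge(int(i), int(j), length=1.0 / w[i, j])
    bc = nx.betweenness_centrality(graph, weight="length", normalized=False)
    values = np.array([bc[i] for i in range(n)])
    return CentralityResult(values=values, metric="bc", node_labels=list(g.node_labels))


def normalize_centrality(c: CentralityResult) -> CentralityResult:
    """Divide centrality values by their mean so the output mean is 1."""
    mean = float(np.mean(c.values))
    if mean <= 0:
        raise DegenerateInputError(
            f"cannot normalize centrality with non-positive mean ({mean:g})"
        )
    return CentralityResult(
        values=c.values / mean,
        metric=c.metric,
        normalized=True,
        node_labels=list(c.node_labels),
    )


def identify_hubs(c: CentralityResult, threshold: float = 1.5) -> set[int]:
    """Node indices whose normalized centrality strictly exceeds ``threshold``.

    Requires a mean-normalized input; boundary values (exactly equal to
    the threshold) are not hubs.
    """
    if not c.normalized:
        raise InvalidArgumentError("identify_hubs requires a normalized CentralityResult")
    return {int(i) for i in np.nonzero(c.values > threshold)[0]}
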