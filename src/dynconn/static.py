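"""Static functional connectivity chain.

Per subject: node-by-time series -> full-length Pearson correlation
matrix -> soft threshold ``w = ((r + 1)/2)**beta`` (beta = 6 for an
unsigned network) -> Fisher r-to-z transform -> undirected weighted
degree centrality. The soft threshold avoids a hard edge cutoff and
maps [-1, 1] monotonically onto [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError
from .graph import CentralityResult, WeightedGraphMatrix, degree_centrality

__all__ = [
    "NodeTimeSeries",
    "ConnectivityMatrix",
    "SoftThresholdConfig",
    "pearson_connectivity",
    "soft_threshold",
    "fisher_z",
    "static_dc",
]

_STAGES = ("correlation", "soft", "fisher_z", "partial")


@dataclass
class NodeTimeSeries:
    """Node-by-time real matrix sampled every ``tr`` seconds."""

    subject_id: str
    data: np.ndarray
    tr: float
    node_labels: list[str] | None = None

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 2:
            raise InvalidArgumentError("time series must be a 2-D node-by-time matrix")
        if d.shape[0] < 2:
            raise InvalidArgumentError("need at least 2 nodes")
        if not np.all(np.isfinite(d)):
            raise InvalidArgumentError("time series contains non-finite values")
        if self.tr <= 0:
            raise InvalidArgumentError(f"tr must be positive, got {self.tr}")
        self.data = d
        if self.node_labels is None:
            self.node_labels = [f"node_{i}" for i in range(d.shape[0])]
        elif len(self.node_labels) != d.shape[0]:
            raise InvalidArgumentError("node_labels length does not match node count")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class ConnectivityMatrix:
    """Square symmetric connectivity matrix with a declared transform stage."""

    values: np.ndarray
    stage: str
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidArgumentError(f"connectivity matrix must be square, got {v.shape}")
        if self.stage not in _STAGES:
            raise InvalidArgumentError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")
        if not np.allclose(v, v.T, atol=1e-10):
            raise InvalidArgumentError("connectivity matrix must be symmetric")
        self.values = v
        if not self.node_labels:
            self.node_labels = [f"node_{i}" for i in range(v.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


@dataclass
class SoftThresholdConfig:
    """Exponent of the unsigned soft-threshold map; 6 keeps the network unsigned."""

    beta: float = 6.0

    def __post_init__(self):
        if self.beta <= 0:
            raise InvalidArgumentError(f"beta must be positive, got {self.beta}")


def pearson_connectivity(ts: NodeTimeSeries) -> ConnectivityMatrix:
    """Pearson correlation of the entire time series between every node pair."""
    if ts.n_timepoints < 3:
        raise InvalidArgumentError(
            f"need at least 3 time points for a correlation, got {ts.n_timepoints}"
        )
    sd = ts.data.std(axis=1)
    dead = np.nonzero(sd == 0)[0]
    if dead.size:
        raise DegenerateInputError(
            f"zero-variance node(s) {dead.tolist()} ({[ts.node_labels[i] for i in dead]})"
        )
    r = np.corrcoef(ts.data)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return ConnectivityMatrix(values=r, stage="correlation", node_labels=list(ts.node_labels))


def soft_threshold(m: ConnectivityMatrix, cfg: SoftThresholdConfig | None = None) -> ConnectivityMatrix:
    """Map correlations to edge weights via ``w = ((r + 1)/2)**beta``.

    Strictly monotone in r; r = -1 maps to 0 and r = 1 maps to 1.
    """
    cfg = cfg or SoftThresholdConfig()
    r = m.values
    if np.any(r < -1) or np.any(r > 1):
        raise InvalidArgumentError("soft_threshold input entries must lie in [-1, 1]")
    w = ((r + 1.0) / 2.0) ** cfg.beta
    return ConnectivityMatrix(values=w, stage="soft", node_labels=list(m.node_labels))


def fisher_z(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Element-wise Fisher r-to-z (atanh) with the diagonal zeroed.

    The diagonal is zeroed before the transform: a self-edge weight of 1
    would map to atanh(1) = inf and the degree sum excludes it anyway.
    """
    w = m.values.copy()
    np.fill_diagonal(w, 0.0)
    if np.any(w < 0) or np.any(w >= 1):
        bad = np.argwhere((w < 0) | (w >= 1))[0]
        raise DegenerateInputError(
            f"fisher_z requires off-diagonal entries in [0, 1); "
            f"entry ({bad[0]}, {bad[1]}) = {m.values[bad[0], bad[1]]:g}"
        )
    z = np.arctanh(w)
    return ConnectivityMatrix(values=z, stage="fisher_z", node_labels=list(m.node_labels))


def static_dc(ts: NodeTimeSeries, cfg: SoftThresholdConfig | None = None) -> CentralityResult:
    """Static degree centrality: pearson -> soft threshold -> Fisher z -> DC."""
    z = fisher_z(soft_threshold(pearson_connectivity(ts), cfg))
    g = WeightedGraphMatrix(weights=z.values, directed=False, node_labels=list(z.node_labels))
    return degree_centrality(g)
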