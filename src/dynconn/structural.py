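"""Structural connectivity from directed fiber-probability matrices.

Each subject contributes a square matrix whose (i, j) entry is the
probability that probabilistic tractography streamlines seeded in
region i reach region j. The matrix is directed (seed-to-target and
target-to-seed probabilities differ) and its entries lie in [0, 1].
Degree centrality on this weighted directed network is the sum of
in-degree and out-degree strengths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import FormatError, InvalidArgumentError
from .graph import CentralityResult, WeightedGraphMatrix, degree_centrality
from .io import read_matrix_tsv

logger = logging.getLogger(__name__)

__all__ = ["FiberProbabilityMatrix", "load_fiber_matrix", "structural_dc"]


@dataclass
class FiberProbabilityMatrix:
    values: np.ndarray
    subject_id: str = ""
    node_labels: list[str] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise InvalidArgumentError(f"fiber matrix must be square, got {v.shape}")
        bad = np.argwhere((v < 0) | (v > 1))
        if bad.size:
            r, c = bad[0]
            raise FormatError(
                f"fiber probability out of [0, 1] at row {r + 1} col {c + 1}: {v[r, c]:g}"
            )
        if np.any(np.diag(v) != 0):
            logger.info("zeroing nonzero diagonal of fiber matrix %s", self.subject_id)
            v = v.copy()
            np.fill_diagonal(v, 0.0)
        self.values = v
        if self.node_labels is None:
            self.node_labels = [f"node_{i}" for i in range(v.shape[0])]
        elif len(self.node_labels) != v.shape[0]:
            raise InvalidArgumentError("node_labels length does not match matrix size")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def load_fiber_matrix(path: str | Path, node_labels: list[str] | None = None,
                      subject_id: str = "") -> FiberProbabilityMatrix:
    """Read a headerless p-by-p TSV of fiber probabilities and validate it."""
    values = read_matrix_tsv(path, expect_square=True)
    return FiberProbabilityMatrix(
        values=values,
        subject_id=subject_id or Path(path).stem,
        node_labels=node_labels,
    )


def structural_dc(m: FiberProbabilityMatrix) -> CentralityResult:
    """Directed weighted degree centrality of the fiber-probability network."""
    g = WeightedGraphMatrix(weights=m.values, directed=True, node_labels=list(m.node_labels))
    return degree_centrality(g)
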