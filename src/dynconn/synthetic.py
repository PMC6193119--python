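"""Synthetic multi-subject cohorts with planted ground truth.

The generator emulates the statistical structure the analysis chain
assumes, so every stage can be verified against a known answer:

* latent brain states are sparse, diagonally dominant (hence SPD)
  precision matrices — the literal estimand of the graphical-lasso
  stage;
* each subject's node time series is drawn from the zero-mean Gaussian
  of the currently active state, with states switching as a Markov
  chain with geometric dwell (exit probability 1/dwell_mean);
* one group ("abdominal") carries a planted connectivity effect: edges
  touching chosen nodes are scaled both in the state precisions and in
  a shared directed fiber-probability matrix;
* eating-disorder scores are generated linearly from the planted
  structural degree centrality plus an age effect and Gaussian noise;
* WHR values are drawn from non-overlapping per-sex bands so the WHR
  classifier reproduces the intended group labels exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError
from .graph import WeightedGraphMatrix, degree_centrality
from .static import NodeTimeSeries
from .stats import ABDOMINAL, NON_ABDOMINAL, EDEQ_SCALES, SubjectRecord, classify_whr
from .structural import FiberProbabilityMatrix, structural_dc

__all__ = [
    "SyntheticCohortConfig",
    "GroundTruth",
    "Cohort",
    "generate_state_precisions",
    "generate_state_sequence",
    "generate_cohort",
    "write_cohort",
]

# WHR bands per (sex, group); disjoint from the classifier thresholds
# (0.9 male / 0.85 female) so labels round-trip deterministically.
_WHR_BANDS = {
    ("male", ABDOMINAL): (0.92, 1.05),
    ("male", NON_ABDOMINAL): (0.75, 0.88),
    ("female", ABDOMINAL): (0.87, 1.00),
    ("female", NON_ABDOMINAL): (0.70, 0.83),
}


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a modest resting-state-like cohort: two groups of
    20 subjects, 10 nodes, 600 time points at TR = 0.645 s, three
    latent states with a mean dwell of 40 time points, and a 1.5-fold
    connectivity effect on two nodes in the abdominal group.
    """

    n_per_group: int = 20
    p: int = 10
    t: int = 600
    tr: float = 0.645
    k_states: int = 3
    dwell_mean: float = 40.0
    precision_sparsity: float = 0.2
    group_effect_nodes: list[int] = field(default_factory=lambda: [0, 1])
    group_effect_size: float = 1.5
    edeq_beta: float = 0.5
    edeq_age_beta: float = 0.01
    edeq_noise_sd: float = 0.5
    edeq_const: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise InvalidArgumentError("n_per_group must be >= 2")
        if self.p < 3:
            raise InvalidArgumentError("p must be >= 3")
        if self.t < 2:
            raise InvalidArgumentError("t must be >= 2")
        if self.tr <= 0:
            raise InvalidArgumentError("tr must be positive")
        if self.k_states < 1:
            raise InvalidArgumentError("k_states must be >= 1")
        if self.dwell_mean < 1:
            raise InvalidArgumentError("dwell_mean must be >= 1")
        if not 0 <= self.precision_sparsity <= 1:
            raise InvalidArgumentError("precision_sparsity must lie in [0, 1]")
        if self.group_effect_size <= 0:
            raise InvalidArgumentError("group_effect_size must be positive")
        if self.edeq_noise_sd < 0:
            raise InvalidArgumentError("edeq_noise_sd must be >= 0")
        bad = [i for i in self.group_effect_nodes if not 0 <= i < self.p]
        if bad:
            raise InvalidArgumentError(f"group_effect_nodes out of range [0, {self.p}): {bad}")


@dataclass
class GroundTruth:
    """Planted quantities the downstream stages should recover."""

    state_sequences: dict[str, np.ndarray]  # per-subject labels in [1..k]
    state_precisions: list[np.ndarray]  # base (non-abdominal) SPD precisions
    state_precisions_effect: list[np.ndarray]  # abdominal-group precisions
    true_dc_effects: np.ndarray  # per-node structural DC difference (abd - non)
    true_edeq_betas: dict[str, float]


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    time_series: dict[str, NodeTimeSeries]
    fiber_matrices: dict[str, FiberProbabilityMatrix]
    ground_truth: GroundTruth


def _sparse_components(p: int, k: int, sparsity: float, rng: np.random.Generator):
    """Off-diagonal parts (unit-diagonal scale) and diagonal scales for k states.

    Off-diagonal entries are drawn so the planted partial correlations
    are strong (|rho| ~ 0.35-0.55) on a random sparse support; the
    support differs between states, which is what makes them
    distinguishable by clustering.
    """
    n_pairs = p * (p - 1) // 2
    n_active = int(round(sparsity * n_pairs))
    iu = np.triu_indices(p, k=1)
    offdiags, scales = [], []
    for _ in range(k):
        off = np.zeros((p, p))
        if n_active:
            chosen = rng.choice(n_pairs, size=n_active, replace=False)
            # theta_ij = -rho_ij on unit-diagonal scale
            vals = -rng.uniform(0.35, 0.55, size=n_active) * rng.choice(
                [-1.0, 1.0], size=n_active
            )
            off[iu[0][chosen], iu[1][chosen]] = vals
            off += off.T
        offdiags.append(off)
        scales.append(rng.uniform(0.8, 1.5, size=p))
    return offdiags, scales


def _dominate(off: np.ndarray, scale: np.ndarray, min_eig: float = 0.1) -> np.ndarray:
    """SPD precision with planted partial correlations.

    Starts from a unit-diagonal matrix I + off (whose off-diagonal is
    minus the target partial correlations), shrinks the off-diagonal
    until the minimum eigenvalue clears ``min_eig``, then applies
    per-node diagonal scales (theta = D^1/2 R D^1/2), which leaves the
    partial correlations unchanged.
    """
    base = off.copy()
    np.fill_diagonal(base, 1.0)
    while np.linalg.eigvalsh(base)[0] < min_eig:
        base[~np.eye(base.shape[0], dtype=bool)] *= 0.9
    d = np.sqrt(scale)
    return base * np.outer(d, d)


def generate_state_precisions(
    p: int, k: int, sparsity: float, seed: int = 0
) -> list[np.ndarray]:
    """k sparse symmetric positive-definite precision matrices.

    Approximately ``sparsity * p * (p - 1) / 2`` off-diagonal pairs are
    nonzero per state; positive definiteness is enforced by strict
    diagonal dominance (diagonal = off-diagonal row L1 norm plus a
    positive margin).
    """
    if p < 3 or k < 1:
        raise InvalidArgumentError(f"need p >= 3 and k >= 1, got p={p}, k={k}")
    if not 0 <= sparsity <= 1:
        raise InvalidArgumentError(f"sparsity must lie in [0, 1], got {sparsity}")
    rng = np.random.default_rng(seed)
    offdiags, margins = _sparse_components(p, k, sparsity, rng)
    return [_dominate(o, m) for o, m in zip(offdiags, margins)]


def generate_state_sequence(
    t: int, k: int, dwell_mean: float, seed: int = 0
) -> np.ndarray:
    """Markov label sequence over [1..k] with geometric dwell.

    At each step the chain leaves its current state with probability
    ``1/dwell_mean`` and jumps to one of the other states uniformly, so
    the mean run length equals ``dwell_mean``.
    """
    if t < 1 or k < 1:
        raise InvalidArgumentError(f"need t >= 1 and k >= 1, got t={t}, k={k}")
    if dwell_mean < 1:
        raise InvalidArgumentError(f"dwell_mean must be >= 1, got {dwell_mean}")
    rng = np.random.default_rng(seed)
    labels = np.empty(t, dtype=int)
    labels[0] = rng.integers(1, k + 1)
    if k == 1:
        return np.ones(t, dtype=int)
    p_exit = 1.0 / dwell_mean
    exits = rng.random(t - 1) < p_exit
    for i in range(1, t):
        if exits[i - 1]:
            others = [s for s in range(1, k + 1) if s != labels[i - 1]]
            labels[i] = others[rng.integers(0, k - 1)]
        else:
            labels[i] = labels[i - 1]
    return labels


def _scale_effect_edges(off: np.ndarray, nodes: list[int], factor: float) -> np.ndarray:
    scaled = off.copy()
    scaled[nodes, :] *= factor
    scaled[:, nodes] *= factor
    # edges between two effect nodes were scaled twice; undo one factor
    for i in nodes:
        for j in nodes:
            if i != j:
                scaled[i, j] /= factor
    return scaled


def generate_cohort(config: SyntheticCohortConfig) -> Cohort:
    """Generate a full two-group cohort with planted ground truth.

    Group layout: the first ``n_per_group`` subjects are abdominal
    (carrying the planted effect), the rest non-abdominal; sexes are
    balanced within each group.
    """
    rng = np.random.default_rng(config.seed)
    p, k = config.p, config.k_states
    offdiags, margins = _sparse_components(p, k, config.precision_sparsity, rng)
    base_precisions = [_dominate(o, m) for o, m in zip(offdiags, margins)]
    effect_offdiags = [
        _scale_effect_edges(o, config.group_effect_nodes, config.group_effect_size)
        for o in offdiags
    ]
    effect_precisions = [_dominate(o, m) for o, m in zip(effect_offdiags, margins)]

    chol = {
        ABDOMINAL: [np.linalg.cholesky(np.linalg.inv(t)) for t in effect_precisions],
        NON_ABDOMINAL: [np.linalg.cholesky(np.linalg.inv(t)) for t in base_precisions],
    }

    base_fiber = rng.uniform(0.0, 0.3, size=(p, p))
    np.fill_diagonal(base_fiber, 0.0)
    effect_fiber = base_fiber.copy()
    effect_fiber[config.group_effect_nodes, :] *= config.group_effect_size
    effect_fiber[:, config.group_effect_nodes] *= config.group_effect_size
    for i in config.group_effect_nodes:
        for j in config.group_effect_nodes:
            if i != j:
                effect_fiber[i, j] /= config.group_effect_size
    effect_fiber = np.clip(effect_fiber, 0.0, 1.0)
    dc_base = structural_dc(FiberProbabilityMatrix(values=base_fiber)).values
    dc_effect = structural_dc(FiberProbabilityMatrix(values=effect_fiber)).values

    subjects: list[SubjectRecord] = []
    time_series: dict[str, NodeTimeSeries] = {}
    fibers: dict[str, FiberProbabilityMatrix] = {}
    sequences: dict[str, np.ndarray] = {}
    n_total = 2 * config.n_per_group
    for idx in range(n_total):
        group = ABDOMINAL if idx < config.n_per_group else NON_ABDOMINAL
        sid = f"s{idx:03d}"
        sex = "male" if idx % 2 == 0 else "female"
        lo, hi = _WHR_BANDS[(sex, group)]
        whr = float(rng.uniform(lo, hi))
        age = float(rng.uniform(20.0, 70.0))
        bmi = float(rng.uniform(25.0, 40.0))
        assert classify_whr(sex, whr) == group

        seq = generate_state_sequence(
            config.t, k, config.dwell_mean, seed=int(rng.integers(2**31))
        )
        sequences[sid] = seq
        z = rng.standard_normal((config.t, p))
        data = np.empty((p, config.t))
        factors = chol[group]
        for state in range(1, k + 1):
            mask = seq == state
            if mask.any():
                data[:, mask] = (z[mask] @ factors[state - 1].T).T
        time_series[sid] = NodeTimeSeries(subject_id=sid, data=data, tr=config.tr)

        fiber = effect_fiber if group == ABDOMINAL else base_fiber
        fibers[sid] = FiberProbabilityMatrix(values=fiber.copy(), subject_id=sid)
        dc_nodes = (dc_effect if group == ABDOMINAL else dc_base)[config.group_effect_nodes]
        dc_signal = float(np.mean(dc_nodes))
        scores = {}
        for scale in EDEQ_SCALES:
            val = (
                config.edeq_beta * dc_signal
                + config.edeq_age_beta * age
                + config.edeq_const
                + rng.normal(0.0, config.edeq_noise_sd)
            )
            scores[scale] = max(0.0, float(val))
        subjects.append(
            SubjectRecord(
                id=sid, sex=sex, age=age, bmi=bmi, whr=whr, group=group, **scores
            )
        )

    truth = GroundTruth(
        state_sequences=sequences,
        state_precisions=base_precisions,
        state_precisions_effect=effect_precisions,
        true_dc_effects=dc_effect - dc_base,
        true_edeq_betas={
            "dc": config.edeq_beta,
            "age": config.edeq_age_beta,
            "const": config.edeq_const,
        },
    )
    return Cohort(subjects=subjects, time_series=time_series,
                  fiber_matrices=fibers, ground_truth=truth)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write subjects.tsv, ts_<id>.tsv, fiber_<id>.tsv and ground_truth/."""
    from .io import write_matrix_tsv, write_subject_table

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_subject_table(out / "subjects.tsv", cohort.subjects)
    for sid, ts in cohort.time_series.items():
        write_matrix_tsv(out / f"ts_{sid}.tsv", ts.data)
    for sid, fib in cohort.fiber_matrices.items():
        write_matrix_tsv(out / f"fiber_{sid}.tsv", fib.values)
    gt = out / "ground_truth"
    gt.mkdir(exist_ok=True)
    labels = np.column_stack(
        [cohort.ground_truth.state_sequences[s.id] for s in cohort.subjects]
    )
    header = "\t".join(s.id for s in cohort.subjects)
    np.savetxt(gt / "state_labels.tsv", labels, delimiter="\t", fmt="%d",
               header=header, comments="")
    for i, theta in enumerate(cohort.ground_truth.state_precisions, start=1):
        write_matrix_tsv(gt / f"precision_state_{i}.tsv", theta)
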