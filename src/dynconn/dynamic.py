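"""Sliding-window dynamic connectivity and brain-state discovery.

The chain per subject: Gaussian-tapered sliding windows over the node
time series -> weighted empirical covariance per window -> L1-penalized
precision (graphical lasso, penalty selected by contiguous-block
cross-validation) -> partial-correlation matrix per window. Windows
from all subjects are pooled and clustered with K-means into recurring
brain states; participant-level states are greedily matched to group
states by Pearson correlation of their mean matrices; per-state degree
centrality is extracted through the same soft-threshold + Fisher-z path
as the static analysis.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.cluster import KMeans
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics import silhouette_score

from .errors import ConvergenceError, DegenerateInputError, InvalidArgumentError
from .graph import CentralityResult, WeightedGraphMatrix, degree_centrality
from .static import ConnectivityMatrix, NodeTimeSeries, SoftThresholdConfig, fisher_z, soft_threshold

__all__ = [
    "WindowConfig",
    "WindowedCovariance",
    "PrecisionEstimate",
    "RegularizationGrid",
    "BrainState",
    "StateAssignment",
    "window_length_from_frequency",
    "build_taper",
    "windowed_covariances",
    "graphical_lasso_fit",
    "glasso_objective",
    "select_lambda_cv",
    "precision_to_partial_corr",
    "subject_partial_windows",
    "select_num_states",
    "cluster_group_states",
    "cluster_subject_states",
    "match_states",
    "per_state_dc",
    "default_lambda_grid",
]


@dataclass
class WindowConfig:
    """Sliding-window geometry.

    window_len: window length in time points (172 TRs at TR = 0.645 s
    captures one full cycle of the 0.009 Hz band edge).
    stride: hop between consecutive window starts, in time points.
    taper_sigma: SD (time points) of the Gaussian the rectangular window
    is convolved with; tapering down-weights the window edges.
    min_freq: lowest retained frequency (Hz), used to derive window_len
    from the TR when it is not given explicitly.
    """

    window_len: int = 172
    stride: int = 1
    taper_sigma: float = 3.0
    min_freq: float = 0.009

    def __post_init__(self):
        if self.window_len < 2:
            raise InvalidArgumentError(f"window_len must be >= 2, got {self.window_len}")
        if self.stride < 1:
            raise InvalidArgumentError(f"stride must be >= 1, got {self.stride}")
        if self.taper_sigma <= 0:
            raise InvalidArgumentError(f"taper_sigma must be > 0, got {self.taper_sigma}")


@dataclass
class WindowedCovariance:
    """Taper-weighted empirical covariance of one window."""

    s: np.ndarray
    window_index: int
    center_time: float

    def __post_init__(self):
        s = np.asarray(self.s, dtype=float)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise InvalidArgumentError("covariance must be square")
        if not np.allclose(s, s.T, atol=1e-8):
            raise InvalidArgumentError("covariance must be symmetric")
        if np.any(np.diag(s) <= 0):
            raise DegenerateInputError(
                f"zero-variance node(s) in window {self.window_index}: "
                f"{np.nonzero(np.diag(s) <= 0)[0].tolist()}"
            )
        self.s = s


@dataclass
class PrecisionEstimate:
    theta: np.ndarray
    lam: float
    objective: float
    converged: bool = True


@dataclass
class RegularizationGrid:
    lambdas: list[float]
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if not self.lambdas:
            raise InvalidArgumentError("empty regularization grid")
        if any(l < 0 for l in self.lambdas):
            raise InvalidArgumentError("all lambdas must be >= 0")
        if self.n_folds < 2:
            raise InvalidArgumentError("n_folds must be >= 2")
        self.lambdas = sorted(float(l) for l in self.lambdas)


@dataclass
class BrainState:
    """A K-means cluster of windowed connectivity matrices."""

    index: int
    mean_matrix: ConnectivityMatrix
    occupancy: float


@dataclass
class StateAssignment:
    """Window labels plus the participant-to-group state mapping."""

    window_labels: dict[str, np.ndarray]
    subject_to_group: dict[str, dict[int, int]]
    variance_explained: dict[str, np.ndarray] = field(default_factory=dict)


def window_length_from_frequency(tr: float, min_freq: float = 0.009) -> int:
    """Window length (time points) covering one period of ``min_freq``.

    round((1/min_freq)/tr) with a floor of 2; (0.645 s, 0.009 Hz) -> 172.
    """
    if tr <= 0:
        raise InvalidArgumentError(f"tr must be positive, got {tr}")
    nyquist = 1.0 / (2.0 * tr)
    if not 0 < min_freq < nyquist:
        raise InvalidArgumentError(
            f"min_freq must lie in (0, Nyquist={nyquist:g} Hz), got {min_freq}"
        )
    return max(2, round((1.0 / min_freq) / tr))


def build_taper(cfg: WindowConfig) -> np.ndarray:
    """Rectangular window convolved with a truncated Gaussian kernel.

    The kernel has SD ``taper_sigma`` time points and support +-3 sigma;
    the same-length result is normalized to sum to 1 and is symmetric
    about the window center. As sigma -> 0 the taper tends to uniform
    weights 1/window_len.
    """
    half = max(1, int(np.ceil(3.0 * cfg.taper_sigma)))
    x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / cfg.taper_sigma) ** 2)
    kernel /= kernel.sum()
    rect = np.ones(cfg.window_len)
    taper = signal.convolve(rect, kernel, mode="same")
    taper /= taper.sum()
    return taper


def windowed_covariances(ts: NodeTimeSeries, cfg: WindowConfig) -> list[WindowedCovariance]:
    """Tapered covariance for each sliding window.

    Window count is ``floor((t - window_len)/stride) + 1``. Each window
    uses the taper weights u: S = sum_k u_k (x_k - xbar_u)(x_k - xbar_u)^T
    with xbar_u the u-weighted mean.
    """
    t = ts.n_timepoints
    if t < cfg.window_len:
        raise InvalidArgumentError(
            f"time series has {t} points but the window needs {cfg.window_len}"
        )
    u = build_taper(cfg)
    out = []
    n_windows = (t - cfg.window_len) // cfg.stride + 1
    for w in range(n_windows):
        start = w * cfg.stride
        x = ts.data[:, start : start + cfg.window_len]
        mean = x @ u
        xc = x - mean[:, None]
        s = (xc * u) @ xc.T
        s = (s + s.T) / 2.0
        out.append(WindowedCovariance(s=s, window_index=w, center_time=start + (cfg.window_len - 1) / 2.0))
    return out


def glasso_objective(theta: np.ndarray, s: np.ndarray, lam: float) -> float:
    """Penalized Gaussian log-likelihood: logdet(theta) - tr(S theta) - lam*||offdiag(theta)||_1."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        return -np.inf
    off = theta - np.diag(np.diag(theta))
    return logdet - float(np.trace(s @ theta)) - lam * float(np.abs(off).sum())


def graphical_lasso_fit(s: WindowedCovariance | np.ndarray, lam: float,
                        max_iter: int = 200, tol: float = 1e-5) -> PrecisionEstimate:
    """L1-penalized precision estimate for one windowed covariance.

    Maximizes logdet(theta) - tr(S theta) - lam*||offdiag(theta)||_1.
    lam = 0 returns the unpenalized Gaussian MLE, the inverse of S.
    """
    mat = s.s if isinstance(s, WindowedCovariance) else np.asarray(s, dtype=float)
    if lam < 0:
        raise InvalidArgumentError(f"lambda must be >= 0, got {lam}")
    if lam == 0:
        try:
            theta = np.linalg.inv(mat)
        except np.linalg.LinAlgError as exc:
            raise DegenerateInputError(f"singular covariance at lambda=0: {exc}") from exc
        theta = (theta + theta.T) / 2.0
        return PrecisionEstimate(theta=theta, lam=0.0, objective=glasso_objective(theta, mat, 0.0))
    # LARS gives the exact path on tiny problems where coordinate
    # descent stalls near the soft-threshold kink; cd scales better.
    mode = "lars" if mat.shape[0] <= 3 else "cd"
    # ill-conditioned windowed covariances (short, tapered windows) can
    # break the solver; retry with light diagonal loading
    last_exc: Exception | None = None
    theta = None
    converged = True
    for eps in (0.0, 1e-6, 1e-4, 1e-2):
        loaded = mat + eps * float(np.mean(np.diag(mat))) * np.eye(mat.shape[0])
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                _, theta = _sk_graphical_lasso(
                    loaded, alpha=lam, mode=mode, max_iter=max_iter, tol=tol
                )
            # a near-zero dual gap past the iteration cap is a solver
            # stall, not a bad solution; record it on the estimate
            converged = not any(
                issubclass(w.category, ConvergenceWarning) for w in caught
            )
            break
        except FloatingPointError as exc:
            last_exc = exc
    if theta is None:
        raise ConvergenceError(
            f"graphical lasso failed to converge: {last_exc}"
        ) from last_exc
    theta = (theta + theta.T) / 2.0
    return PrecisionEstimate(
        theta=theta,
        lam=float(lam),
        objective=glasso_objective(theta, mat, lam),
        converged=converged,
    )


def default_lambda_grid(n: int = 8, lo: float = 0.01, hi: float = 1.0) -> list[float]:
    """Log-spaced penalty grid used when the caller does not supply one."""
    return list(np.geomspace(lo, hi, n))


def select_lambda_cv(
    windows: list[WindowedCovariance],
    grid: RegularizationGrid,
    fit_tol: float = 1e-5,
    fit_max_iter: int = 200,
) -> float:
    """Cross-validated penalty over contiguous window blocks.

    The windows are split into ``n_folds`` contiguous blocks (contiguity
    respects the temporal dependence of overlapping windows). For each
    candidate lambda, a precision is fit on the average training-block
    covariance and scored with the unpenalized log-likelihood
    logdet(theta) - tr(S_test theta) on the held-out block's average
    covariance. Returns the lambda with the best mean held-out score;
    ties go to the smaller lambda.
    """
    if len(windows) < grid.n_folds:
        raise InvalidArgumentError(
            f"need at least n_folds={grid.n_folds} windows, got {len(windows)}"
        )
    covs = np.stack([w.s for w in windows])
    blocks = np.array_split(np.arange(len(windows)), grid.n_folds)
    scores = np.zeros(len(grid.lambdas))
    for fold, test_idx in enumerate(blocks):
        train_idx = np.concatenate([b for j, b in enumerate(blocks) if j != fold])
        s_train = covs[train_idx].mean(axis=0)
        s_test = covs[test_idx].mean(axis=0)
        for i, lam in enumerate(grid.lambdas):
            theta = graphical_lasso_fit(s_train, lam, max_iter=fit_max_iter, tol=fit_tol).theta
            scores[i] += glasso_objective(theta, s_test, 0.0)
    scores /= grid.n_folds
    best = int(np.argmax(scores))  # argmax takes the first (smallest lambda) on ties
    return grid.lambdas[best]


def precision_to_partial_corr(theta: PrecisionEstimate | np.ndarray) -> ConnectivityMatrix:
    """Partial correlations: rho_ij = -theta_ij / sqrt(theta_ii theta_jj), unit diagonal."""
    t = theta.theta if isinstance(theta, PrecisionEstimate) else np.asarray(theta, dtype=float)
    d = np.diag(t)
    if np.any(d <= 0):
        raise InvalidArgumentError("precision matrix must have a positive diagonal")
    scale = 1.0 / np.sqrt(d)
    rho = -t * np.outer(scale, scale)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    return ConnectivityMatrix(values=rho, stage="partial")


def subject_partial_windows(
    ts: NodeTimeSeries,
    cfg: WindowConfig,
    grid: RegularizationGrid | None = None,
    lam: float | None = None,
    fit_tol: float = 1e-3,
    fit_max_iter: int = 50,
) -> tuple[list[ConnectivityMatrix], float, list[WindowedCovariance]]:
    """Windowed partial-correlation matrices for one subject.

    A single penalty is used for all of a subject's windows: either the
    supplied ``lam`` or the cross-validated optimum on that subject's
    own windows. Per-window fits use a looser solver tolerance than the
    standalone estimator: the matrices feed K-means clustering, which
    is insensitive to fourth-decimal precision, and a subject
    contributes hundreds of windows.
    """
    covs = windowed_covariances(ts, cfg)
    if lam is None:
        grid = grid or RegularizationGrid(lambdas=default_lambda_grid())
        lam = select_lambda_cv(covs, grid, fit_tol=fit_tol, fit_max_iter=fit_max_iter)
    mats = [
        precision_to_partial_corr(
            graphical_lasso_fit(c, lam, max_iter=fit_max_iter, tol=fit_tol)
        )
        for c in covs
    ]
    return mats, float(lam), covs


def _vectorize(mats: list[ConnectivityMatrix] | list[np.ndarray]) -> np.ndarray:
    arrs = [m.values if isinstance(m, ConnectivityMatrix) else np.asarray(m) for m in mats]
    p = arrs[0].shape[0]
    iu = np.triu_indices(p, k=1)
    return np.stack([a[iu] for a in arrs])


def _unvectorize(vec: np.ndarray, p: int) -> np.ndarray:
    m = np.zeros((p, p))
    iu = np.triu_indices(p, k=1)
    m[iu] = vec
    m += m.T
    np.fill_diagonal(m, 1.0)
    return m


def _kmeans(x: np.ndarray, k: int, seed: int) -> KMeans:
    return KMeans(n_clusters=k, n_init=10, max_iter=300, random_state=seed).fit(x)


def select_num_states(
    subject_windows: dict[str, list[ConnectivityMatrix]],
    k_range: range | list[int],
    seed: int = 0,
) -> int:
    """Choose the state count by per-subject silhouette voting.

    Each subject's vectorized windows are clustered for every k in
    ``k_range``; the subject votes for its silhouette-maximizing k. The
    mode over subjects wins; mode ties are broken by the elbow criterion
    (largest second difference of the mean within-cluster dispersion
    curve) and then by the smaller k.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise InvalidArgumentError("k_range is empty")
    votes = []
    inertia_curves = []
    for sid in sorted(subject_windows):
        x = _vectorize(subject_windows[sid])
        if x.shape[0] <= max(ks):
            raise InvalidArgumentError(
                f"subject {sid} has {x.shape[0]} windows, need more than max k = {max(ks)}"
            )
        sil, inert = [], []
        for k in ks:
            km = _kmeans(x, k, seed)
            inert.append(km.inertia_ / x.shape[0])
            if k == 1 or len(set(km.labels_)) < 2:
                sil.append(-1.0)
            else:
                sil.append(silhouette_score(x, km.labels_))
        votes.append(ks[int(np.argmax(sil))])
        inertia_curves.append(inert)
    counts = Counter(votes)
    top = max(counts.values())
    tied = sorted(k for k, c in counts.items() if c == top)
    if len(tied) == 1:
        return tied[0]
    # elbow tie-break: largest second difference of mean dispersion
    mean_inertia = np.mean(inertia_curves, axis=0)
    elbow = {}
    for k in tied:
        i = ks.index(k)
        if 0 < i < len(ks) - 1:
            elbow[k] = mean_inertia[i - 1] - 2 * mean_inertia[i] + mean_inertia[i + 1]
        else:
            elbow[k] = -np.inf
    best = max(elbow.values())
    return min(k for k in tied if elbow[k] == best)


def cluster_group_states(
    all_windows: list[ConnectivityMatrix],
    k: int,
    seed: int = 0,
) -> tuple[list[BrainState], np.ndarray]:
    """K-means over pooled windows; states indexed in descending occupancy.

    Clusters the vectorized upper triangles with squared-Euclidean
    distance, 10 seeded restarts. Each state's mean matrix is the
    element-wise mean of its member matrices.
    """
    if len(all_windows) < k:
        raise InvalidArgumentError(f"{len(all_windows)} windows < k = {k}")
    x = _vectorize(all_windows)
    km = _kmeans(x, k, seed)
    labels = km.labels_.copy()
    occ = np.bincount(labels, minlength=k) / len(labels)
    order = np.argsort(-occ, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    p = all_windows[0].n_nodes
    states = []
    for i in range(k):
        members = x[labels == i]
        mean = _unvectorize(members.mean(axis=0), p)
        states.append(
            BrainState(
                index=i,
                mean_matrix=ConnectivityMatrix(values=mean, stage="partial",
                                               node_labels=list(all_windows[0].node_labels)),
                occupancy=float((labels == i).mean()),
            )
        )
    return states, labels


def cluster_subject_states(
    windows: list[ConnectivityMatrix], k: int, seed: int = 0
) -> tuple[list[ConnectivityMatrix], np.ndarray, np.ndarray]:
    """Participant-level K-means: returns cluster means, labels and the
    variance explained by each cluster (its share of total dispersion
    accounted for, used to order the greedy matching)."""
    if len(windows) < k:
        raise InvalidArgumentError(f"{len(windows)} windows < k = {k}")
    x = _vectorize(windows)
    km = _kmeans(x, k, seed)
    labels = km.labels_
    p = windows[0].n_nodes
    total = float(((x - x.mean(axis=0)) ** 2).sum())
    var_exp = np.zeros(k)
    means = []
    for i in range(k):
        members = x[labels == i]
        means.append(ConnectivityMatrix(values=_unvectorize(members.mean(axis=0), p),
                                        stage="partial", node_labels=list(windows[0].node_labels)))
        # between-cluster contribution of cluster i relative to total dispersion
        if total > 0:
            var_exp[i] = members.shape[0] * float(
                ((members.mean(axis=0) - x.mean(axis=0)) ** 2).sum()
            ) / total
        else:
            var_exp[i] = members.shape[0] / x.shape[0]
    return means, labels, var_exp


def match_states(
    subject_states: list[ConnectivityMatrix],
    variance_explained: np.ndarray,
    group_states: list[BrainState],
) -> dict[int, int]:
    """Greedy participant-to-group state matching without replacement.

    Subject clusters are processed in descending variance-explained
    order; each is assigned the still-unassigned group state whose mean
    matrix has the maximum Pearson correlation with it (ties to the
    lower group-state index).
    """
    if len(subject_states) > len(group_states):
        raise InvalidArgumentError(
            f"{len(subject_states)} subject states exceed {len(group_states)} group states"
        )
    sub_vecs = _vectorize(subject_states)
    grp_vecs = _vectorize([g.mean_matrix for g in group_states])
    free = list(range(len(group_states)))
    mapping: dict[int, int] = {}
    for si in np.argsort(-np.asarray(variance_explained), kind="stable"):
        best_j, best_r = free[0], -np.inf
        for j in free:
            a, b = sub_vecs[si], grp_vecs[j]
            sa, sb = a.std(), b.std()
            r = float(np.corrcoef(a, b)[0, 1]) if sa > 0 and sb > 0 else -np.inf
            if r > best_r:
                best_r, best_j = r, j
        mapping[int(si)] = group_states[best_j].index
        free.remove(best_j)
    return mapping


def per_state_dc(
    subject_windows: dict[str, list[ConnectivityMatrix]],
    assignment: StateAssignment,
    soft_cfg: SoftThresholdConfig | None = None,
) -> dict[str, dict[int, CentralityResult]]:
    """Per-subject, per-group-state degree centrality.

    For each subject and each group state its windows map to: average
    the member matrices element-wise, soft-threshold, Fisher-z, then
    undirected DC. States a subject never visits are simply absent from
    that subject's dict (downstream group tests drop them).
    """
    soft_cfg = soft_cfg or SoftThresholdConfig()
    out: dict[str, dict[int, CentralityResult]] = {}
    for sid, windows in subject_windows.items():
        labels = assignment.window_labels[sid]
        if len(labels) != len(windows):
            raise InvalidArgumentError(
                f"subject {sid}: {len(labels)} labels for {len(windows)} windows"
            )
        mapping = assignment.subject_to_group[sid]
        per_state: dict[int, CentralityResult] = {}
        for local_state, group_state in mapping.items():
            member = [w.values for w, l in zip(windows, labels) if l == local_state]
            if not member:
                continue
            mean = np.mean(member, axis=0)
            m = ConnectivityMatrix(values=mean, stage="partial",
                                   node_labels=list(windows[0].node_labels))
            z = fisher_z(soft_threshold(m, soft_cfg))
            g = WeightedGraphMatrix(weights=z.values, directed=False,
                                    node_labels=list(z.node_labels))
            per_state[int(group_state)] = degree_centrality(g)
        out[sid] = per_state
    return out
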