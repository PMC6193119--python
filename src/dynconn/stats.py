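"""Group statistics: WHR classification, permutation tests with FDR,
demographic-table tests, and centrality-to-behavior regressions.

Subjects are split into abdominal / non-abdominal obesity groups by the
waist-hip ratio (WHR > 0.9 for males, > 0.85 for females). Group
differences in degree centrality are tested node-wise with a label-
permutation null of the difference in group means, two-sided, followed
by Benjamini-Hochberg FDR. Eating-disorder scores (EDE-Q subscales) are
regressed on one or more DC predictors with age as a covariate, and the
resulting p-values are FDR-corrected jointly over regions x scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import DegenerateInputError, InvalidArgumentError

__all__ = [
    "SubjectRecord",
    "PermutationConfig",
    "PermutationResult",
    "RegressionResult",
    "ABDOMINAL",
    "NON_ABDOMINAL",
    "EDEQ_SCALES",
    "classify_whr",
    "permutation_test_dc",
    "bh_fdr",
    "chi_square_independence",
    "t_test_from_summaries",
    "fit_edeq_regression",
    "correct_regression_family",
]

ABDOMINAL = "abdominal"
NON_ABDOMINAL = "non_abdominal"
EDEQ_SCALES = ("edeq_r", "edeq_e", "edeq_s", "edeq_w")

_SEX_ALIASES = {"m": "male", "male": "male", "f": "female", "female": "female"}


@dataclass
class SubjectRecord:
    """One row of the subject table; the obesity group is derived from WHR."""

    id: str
    sex: str
    age: float
    bmi: float
    whr: float
    edeq_r: float
    edeq_e: float
    edeq_s: float
    edeq_w: float
    group: str = ""

    def __post_init__(self):
        sex = _SEX_ALIASES.get(str(self.sex).strip().lower())
        if sex is None:
            raise InvalidArgumentError(f"unknown sex token {self.sex!r} for subject {self.id}")
        self.sex = sex
        if self.whr <= 0:
            raise InvalidArgumentError(f"whr must be positive, got {self.whr}")
        if self.age <= 0:
            raise InvalidArgumentError(f"age must be positive, got {self.age}")
        for scale in EDEQ_SCALES:
            if getattr(self, scale) < 0:
                raise InvalidArgumentError(f"{scale} must be >= 0 for subject {self.id}")
        if not self.group:
            self.group = classify_whr(self.sex, self.whr)
        elif self.group not in (ABDOMINAL, NON_ABDOMINAL):
            raise InvalidArgumentError(f"unknown group {self.group!r}")


@dataclass
class PermutationConfig:
    n_perm: int = 5000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_perm < 1:
            raise InvalidArgumentError("n_perm must be >= 1")
        if not 0 < self.alpha < 1:
            raise InvalidArgumentError("alpha must be in (0, 1)")


@dataclass
class PermutationResult:
    """Node-wise permutation test output (observed mean difference,
    permutation p, BH q, and the q < alpha flag)."""

    table: pd.DataFrame  # columns: node, observed_diff, p, q, significant
    n_perm: int
    alpha: float


@dataclass
class RegressionResult:
    coefficients: dict[str, float]
    coefficient_p: dict[str, float]
    r_squared: float
    model_p: float
    n: int
    q: float | None = None


def classify_whr(sex: str, whr: float) -> str:
    """Abdominal obesity if WHR strictly exceeds 0.9 (males) / 0.85 (females)."""
    sex_norm = _SEX_ALIASES.get(str(sex).strip().lower())
    if sex_norm is None:
        raise InvalidArgumentError(f"unknown sex token {sex!r}")
    threshold = 0.9 if sex_norm == "male" else 0.85
    return ABDOMINAL if whr > threshold else NON_ABDOMINAL


def bh_fdr(pvalues, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q_i = min_{j >= i} m p_(j)/j, capped at 1.

    Returns (qvalues, reject flags) in the input order; rejection is
    q < alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidArgumentError("pvalues must be a non-empty 1-D array")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidArgumentError("all p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q, q < alpha


def permutation_test_dc(
    dc: pd.DataFrame,
    labels,
    cfg: PermutationConfig | None = None,
) -> PermutationResult:
    """Node-wise permutation test of group differences in DC.

    ``dc`` is a subjects x nodes table (index = subject id); ``labels``
    is the per-subject group vector aligned with the rows. The observed
    statistic per node is mean(group 1) - mean(group 2); the null is
    built by reshuffling labels (group sizes preserved) ``n_perm``
    times, with two-sided add-one p-values
    p = (1 + #{|null| >= |obs|}) / (1 + n_perm), then BH-FDR across
    nodes.
    """
    cfg = cfg or PermutationConfig()
    labels = np.asarray(labels)
    if labels.shape[0] != dc.shape[0]:
        raise InvalidArgumentError("labels length must match the number of DC rows")
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise InvalidArgumentError(f"need exactly 2 groups, got {list(groups)}")
    values = dc.to_numpy(dtype=float)
    keep = ~np.any(np.isnan(values), axis=0)
    if not keep.all():
        import warnings

        warnings.warn(
            f"dropping {int((~keep).sum())} node(s) with missing DC values", stacklevel=2
        )
        values = values[:, keep]
    node_names = [c for c, k in zip(dc.columns, keep) if k]
    mask1 = labels == groups[0]
    n1, n2 = int(mask1.sum()), int((~mask1).sum())
    if n1 < 2 or n2 < 2:
        raise InvalidArgumentError("need at least 2 subjects per group")
    observed = values[mask1].mean(axis=0) - values[~mask1].mean(axis=0)

    rng = np.random.default_rng(cfg.seed)
    n = values.shape[0]
    total = values.sum(axis=0)
    exceed = np.zeros(values.shape[1], dtype=int)
    for _ in range(cfg.n_perm):
        perm = rng.permutation(n)
        sum1 = values[perm[:n1]].sum(axis=0)
        null = sum1 / n1 - (total - sum1) / n2
        exceed += np.abs(null) >= np.abs(observed)
    p = (1 + exceed) / (1 + cfg.n_perm)
    q, reject = bh_fdr(p, cfg.alpha)
    table = pd.DataFrame(
        {
            "node": node_names,
            "observed_diff": observed,
            "p": p,
            "q": q,
            "significant": reject,
        }
    )
    return PermutationResult(table=table, n_perm=cfg.n_perm, alpha=cfg.alpha)


def chi_square_independence(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, no continuity correction, 1 df."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise InvalidArgumentError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise InvalidArgumentError("counts must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateInputError("chi-square table has a zero margin")
    stat, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def t_test_from_summaries(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variant: str = "pooled",
) -> tuple[float, float, float]:
    """Two-sample t test from summary statistics; returns (t, df, p)."""
    if sd1 <= 0 or sd2 <= 0:
        raise InvalidArgumentError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise InvalidArgumentError("each group needs n >= 2")
    if variant not in ("pooled", "welch"):
        raise InvalidArgumentError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    res = sps.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=(variant == "pooled")
    )
    if variant == "pooled":
        df = n1 + n2 - 2.0
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def fit_edeq_regression(
    edeq,
    dc_predictors: dict[str, np.ndarray] | pd.DataFrame,
    age,
) -> RegressionResult:
    """OLS of an EDE-Q score on one or more DC predictors plus age.

    Model: EDEQ = sum_k beta_k DC_k + beta_age * age + C. Reports the
    model R-squared, per-coefficient two-sided p, and the model F-test
    p. Rows with missing values are dropped listwise.
    """
    if isinstance(dc_predictors, pd.DataFrame):
        dc = {str(c): dc_predictors[c].to_numpy(dtype=float) for c in dc_predictors.columns}
    else:
        dc = {str(k): np.asarray(v, dtype=float) for k, v in dc_predictors.items()}
    y = np.asarray(edeq, dtype=float)
    age = np.asarray(age, dtype=float)
    names = list(dc)
    x = np.column_stack([dc[k] for k in names] + [age])
    if x.shape[0] != y.shape[0]:
        raise InvalidArgumentError("predictor and response lengths differ")
    ok = np.isfinite(y) & np.all(np.isfinite(x), axis=1)
    y, x = y[ok], x[ok]
    if y.shape[0] < x.shape[1] + 2:
        raise InvalidArgumentError(
            f"need at least {x.shape[1] + 2} complete rows, got {y.shape[0]}"
        )
    design = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        for j, name in enumerate(names + ["age"]):
            reduced = np.delete(design, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise InvalidArgumentError(f"collinear predictor: {name}")
        raise InvalidArgumentError("rank-deficient design matrix")
    fit = sm.OLS(y, design).fit()
    coef_names = ["const"] + names + ["age"]
    return RegressionResult(
        coefficients=dict(zip(coef_names, fit.params)),
        coefficient_p=dict(zip(coef_names, fit.pvalues)),
        r_squared=float(fit.rsquared),
        model_p=float(fit.f_pvalue),
        n=int(fit.nobs),
    )


def correct_regression_family(
    results: dict[tuple[str, str], RegressionResult],
    alpha: float = 0.05,
    use: str = "model",
) -> dict[tuple[str, str], RegressionResult]:
    """BH-FDR jointly across the (region/network, EDE-Q scale) family.

    ``use`` picks the p-value entering the correction: the model F-test
    p ("model") or the first DC coefficient's p ("coef"). Attaches a q
    to every result; rejections at alpha are always a subset of raw
    rejections.
    """
    if use not in ("model", "coef"):
        raise InvalidArgumentError("use must be 'model' or 'coef'")
    keys = list(results)
    if not keys:
        raise InvalidArgumentError("empty results table")
    ps = []
    for key in keys:
        res = results[key]
        if use == "model":
            ps.append(res.model_p)
        else:
            dc_names = [k for k in res.coefficient_p if k not in ("const", "age")]
            ps.append(res.coefficient_p[dc_names[0]])
    q, _ = bh_fdr(np.clip(ps, np.finfo(float).tiny, 1.0), alpha)
    for key, qi in zip(keys, q):
        results[key].q = float(qi)
    return results
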