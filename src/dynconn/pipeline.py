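"""End-to-end orchestration: structural -> static -> dynamic -> stats -> regressions.

Mirrors the analysis flow of a multimodal connectivity study: directed
degree centrality from fiber-probability matrices, static functional DC
from full-length correlations, dynamic brain states from windowed
graphical-lasso partial correlations, node-wise permutation tests of
group differences with BH-FDR, and OLS regressions of the four EDE-Q
subscales on the identified DC values with age as covariate (single-
modality and combined models). A JSON run manifest records the config,
stage timings and output checksums.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dynamic import (
    RegularizationGrid,
    StateAssignment,
    WindowConfig,
    cluster_group_states,
    cluster_subject_states,
    default_lambda_grid,
    match_states,
    per_state_dc,
    select_num_states,
    subject_partial_windows,
    window_length_from_frequency,
)
from .errors import InvalidArgumentError
from .io import file_checksum, read_matrix_tsv, read_subject_table, read_time_series, write_matrix_tsv
from .static import SoftThresholdConfig, static_dc
from .stats import (
    ABDOMINAL,
    EDEQ_SCALES,
    PermutationConfig,
    correct_regression_family,
    fit_edeq_regression,
    permutation_test_dc,
)
from .structural import load_fiber_matrix, structural_dc

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    ts_dir: str
    fiber_dir: str
    subjects: str
    out_dir: str
    tr: float = 0.645
    window: WindowConfig | None = None
    soft: SoftThresholdConfig = field(default_factory=SoftThresholdConfig)
    lambda_grid: list[float] = field(default_factory=default_lambda_grid)
    n_folds: int = 5
    k_range: tuple[int, int] = (2, 6)
    permutation: PermutationConfig = field(default_factory=PermutationConfig)
    seed: int = 0

    def __post_init__(self):
        for name in ("ts_dir", "fiber_dir", "subjects"):
            if not Path(getattr(self, name)).exists():
                raise InvalidArgumentError(f"{name} does not exist: {getattr(self, name)}")
        if self.window is None:
            self.window = WindowConfig(
                window_len=window_length_from_frequency(self.tr, 0.009)
            )


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict[str, float]
    outputs: dict[str, str]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(
            {"config": self.config, "version": self.version,
             "stages": self.stages, "outputs": self.outputs},
            indent=2, default=str))
        os.replace(tmp, path)


def _mean_dc_predictor(dc_table: pd.DataFrame, significant: list[str]) -> pd.Series:
    """Mean DC over the identified nodes (falls back to the full mean)."""
    cols = significant or list(dc_table.columns)
    return dc_table[cols].mean(axis=1)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run every stage on a cohort directory and write all result tables."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, float] = {}
    outputs: dict[str, Path] = {}
    t_start = time.perf_counter()

    subjects = read_subject_table(config.subjects)
    ids = [s.id for s in subjects]
    labels = np.array([s.group for s in subjects])
    subj_df = pd.DataFrame(
        {"age": [s.age for s in subjects],
         **{sc: [getattr(s, sc) for s in subjects] for sc in EDEQ_SCALES}},
        index=ids,
    )

    # --- structural DC -------------------------------------------------
    t0 = time.perf_counter()
    rows = {}
    for sid in ids:
        m = load_fiber_matrix(Path(config.fiber_dir) / f"fiber_{sid}.tsv", subject_id=sid)
        rows[sid] = structural_dc(m).values
    dc_struct = pd.DataFrame.from_dict(rows, orient="index")
    dc_struct.columns = [f"node_{i}" for i in range(dc_struct.shape[1])]
    outputs["dc_structural"] = out / "dc_structural.tsv"
    dc_struct.to_csv(outputs["dc_structural"], sep="\t", index_label="subject_id")
    stages["structural"] = time.perf_counter() - t0

    # --- static DC -----------------------------------------------------
    t0 = time.perf_counter()
    ts_by_id = {
        sid: read_time_series(Path(config.ts_dir) / f"ts_{sid}.tsv", tr=config.tr, subject_id=sid)
        for sid in ids
    }
    dc_stat = pd.DataFrame.from_dict(
        {sid: static_dc(ts_by_id[sid], config.soft).values for sid in ids}, orient="index"
    )
    dc_stat.columns = [f"node_{i}" for i in range(dc_stat.shape[1])]
    outputs["dc_static"] = out / "dc_static.tsv"
    dc_stat.to_csv(outputs["dc_static"], sep="\t", index_label="subject_id")
    stages["static"] = time.perf_counter() - t0

    # --- dynamic states + per-state DC ---------------------------------
    t0 = time.perf_counter()
    grid = RegularizationGrid(lambdas=list(config.lambda_grid), n_folds=config.n_folds,
                              seed=config.seed)
    windows_by_id, lambdas = {}, {}
    for sid in ids:
        mats, lam, _ = subject_partial_windows(ts_by_id[sid], config.window, grid)
        windows_by_id[sid] = mats
        lambdas[sid] = lam
    pd.Series(lambdas, name="lambda").to_csv(out / "lambdas.tsv", sep="\t",
                                             index_label="subject_id")
    outputs["lambdas"] = out / "lambdas.tsv"

    k_lo, k_hi = config.k_range
    k = select_num_states(windows_by_id, range(k_lo, k_hi + 1), seed=config.seed)
    all_windows = [w for sid in ids for w in windows_by_id[sid]]
    group_states, group_labels = cluster_group_states(all_windows, k, seed=config.seed)
    for st in group_states:
        path = out / f"state_{st.index}.tsv"
        write_matrix_tsv(path, st.mean_matrix.values)
        outputs[f"state_{st.index}"] = path

    window_labels, mapping, var_exp = {}, {}, {}
    for sid in ids:
        means, lab, ve = cluster_subject_states(windows_by_id[sid], k, seed=config.seed)
        m = match_states(means, ve, group_states)
        window_labels[sid], mapping[sid], var_exp[sid] = lab, m, ve
    assignment = StateAssignment(window_labels=window_labels, subject_to_group=mapping,
                                 variance_explained=var_exp)
    assign_rows = [
        {"subject_id": sid, "window": w,
         "group_state": mapping[sid][int(l)]}
        for sid in ids for w, l in enumerate(window_labels[sid])
    ]
    outputs["assignments"] = out / "assignments.tsv"
    pd.DataFrame(assign_rows).to_csv(outputs["assignments"], sep="\t", index=False)

    dc_dyn = per_state_dc(windows_by_id, assignment, config.soft)
    dyn_rows = []
    for sid in ids:
        for state, cr in dc_dyn[sid].items():
            for node, v in enumerate(cr.values):
                dyn_rows.append({"subject_id": sid, "state": state,
                                 "node": f"node_{node}", "dc": v})
    dyn_table = pd.DataFrame(dyn_rows)
    outputs["dc_dynamic"] = out / "dc_dynamic.tsv"
    dyn_table.to_csv(outputs["dc_dynamic"], sep="\t", index=False)
    stages["dynamic"] = time.perf_counter() - t0

    # --- permutation group statistics ----------------------------------
    t0 = time.perf_counter()
    perm_results = {}
    for name, table in (("structural", dc_struct), ("static", dc_stat)):
        res = permutation_test_dc(table, labels, config.permutation)
        perm_results[name] = res
        path = out / f"perm_{name}.tsv"
        res.table.to_csv(path, sep="\t", index=False)
        outputs[f"perm_{name}"] = path

    # dynamic: per-state node tests over subjects that visited the state
    dyn_sig: list[tuple[int, str]] = []
    dyn_tables = []
    for state in sorted(dyn_table["state"].unique()):
        sub = dyn_table[dyn_table["state"] == state].pivot(
            index="subject_id", columns="node", values="dc")
        sub = sub.dropna(axis=0)
        state_labels = np.array([labels[ids.index(s)] for s in sub.index])
        if len(set(state_labels)) < 2 or min(
            (state_labels == g).sum() for g in set(state_labels)
        ) < 2:
            continue
        res = permutation_test_dc(sub, state_labels, config.permutation)
        res.table.insert(0, "state", state)
        dyn_tables.append(res.table)
        dyn_sig += [(state, n) for n in res.table.loc[res.table.significant, "node"]]
    if dyn_tables:
        perm_dyn = pd.concat(dyn_tables, ignore_index=True)
        outputs["perm_dynamic"] = out / "perm_dynamic.tsv"
        perm_dyn.to_csv(outputs["perm_dynamic"], sep="\t", index=False)
    stages["stats"] = time.perf_counter() - t0

    # --- EDE-Q regressions ---------------------------------------------
    t0 = time.perf_counter()
    sig_struct = list(perm_results["structural"].table.loc[
        perm_results["structural"].table.significant, "node"])
    sig_stat = list(perm_results["static"].table.loc[
        perm_results["static"].table.significant, "node"])
    predictors = {
        "dc_structural": _mean_dc_predictor(dc_struct, sig_struct),
        "dc_static": _mean_dc_predictor(dc_stat, sig_stat),
    }
    if dyn_sig:
        vals = []
        for sid in ids:
            per = [dc_dyn[sid][st].values[int(node.split("_")[1])]
                   for st, node in dyn_sig if st in dc_dyn[sid]]
            vals.append(np.mean(per) if per else np.nan)
        predictors["dc_dynamic"] = pd.Series(vals, index=ids)

    family = {}
    combos = [("structural", ["dc_structural"]), ("static", ["dc_static"])]
    if "dc_dynamic" in predictors:
        combos += [("dynamic", ["dc_dynamic"]),
                   ("combined", list(predictors))]
    else:
        combos += [("combined", ["dc_structural", "dc_static"])]
    for combo_name, cols in combos:
        x = pd.DataFrame({c: predictors[c] for c in cols}, index=ids)
        for scale in EDEQ_SCALES:
            family[(combo_name, scale)] = fit_edeq_regression(
                subj_df[scale], x, subj_df["age"])
    family = correct_regression_family(family, alpha=config.permutation.alpha)
    reg_rows = [
        {"model": name, "scale": scale, "n": r.n, "r2": r.r_squared,
         "p_model": r.model_p, "q": r.q,
         **{f"beta_{k}": v for k, v in r.coefficients.items()}}
        for (name, scale), r in family.items()
    ]
    outputs["regressions"] = out / "regressions.tsv"
    pd.DataFrame(reg_rows).to_csv(outputs["regressions"], sep="\t", index=False)
    stages["regress"] = time.perf_counter() - t0
    stages["total"] = time.perf_counter() - t_start

    cfg_dict = asdict(config)
    manifest = RunManifest(
        config=cfg_dict,
        version=__version__,
        stages=stages,
        outputs={k: file_checksum(v) for k, v in outputs.items()},
    )
    manifest.write(out / "manifest.json")
    for stage, secs in stages.items():
        logger.info("stage %-12s %.2fs", stage, secs)
    return manifest
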