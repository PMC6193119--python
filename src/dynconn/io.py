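"""Plain-TSV readers and writers shared by every pipeline stage.

All on-disk artifacts are tab-separated text: matrices are headerless
p-row files, tables carry a header row, decimals use '.'. No imaging
formats are read — the pipeline's inputs begin after node extraction.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .stats import SubjectRecord

__all__ = [
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_subject_table",
    "write_subject_table",
    "read_time_series",
    "file_checksum",
]

_SUBJECT_COLUMNS = ["id", "sex", "age", "bmi", "whr", "edeq_r", "edeq_e", "edeq_s", "edeq_w"]


def read_matrix_tsv(path: str | Path, expect_square: bool = False) -> np.ndarray:
    """Read a headerless numeric TSV; rejects ragged rows, NaN and Inf."""
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cells = line.split("\t")
            if rows and len(cells) != len(rows[0]):
                raise FormatError(
                    f"{path.name}: row {lineno} has {len(cells)} columns, expected {len(rows[0])}"
                )
            try:
                row = [float(c) for c in cells]
            except ValueError as exc:
                raise FormatError(f"{path.name}: non-numeric cell in row {lineno}: {exc}") from exc
            if not all(np.isfinite(row)):
                raise FormatError(f"{path.name}: non-finite value in row {lineno}")
            rows.append(row)
    if not rows:
        raise FormatError(f"{path.name}: empty matrix file")
    mat = np.asarray(rows, dtype=float)
    if expect_square and mat.shape[0] != mat.shape[1]:
        raise FormatError(f"{path.name}: expected a square matrix, got {mat.shape}")
    return mat


def write_matrix_tsv(path: str | Path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter="\t", fmt="%.10g")


def read_subject_table(path: str | Path) -> list[SubjectRecord]:
    """Read the subject TSV into typed records.

    Requires the columns id, sex, age, bmi, whr and the four EDE-Q
    subscales; sex tokens M/F/male/female (any case) are accepted. The
    obesity group is taken from a 'group' column if present, otherwise
    derived from sex and WHR.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"id": str})
    except Exception as exc:
        raise FormatError(f"{path.name}: cannot parse subject table: {exc}") from exc
    missing = [c for c in _SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SubjectRecord(
                    id=str(row["id"]),
                    sex=str(row["sex"]),
                    age=float(row["age"]),
                    bmi=float(row["bmi"]),
                    whr=float(row["whr"]),
                    edeq_r=float(row["edeq_r"]),
                    edeq_e=float(row["edeq_e"]),
                    edeq_s=float(row["edeq_s"]),
                    edeq_w=float(row["edeq_w"]),
                    group=str(row["group"]) if "group" in df.columns else "",
                )
            )
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path.name}: row {i + 2}: {exc}") from exc
    return records


def write_subject_table(path: str | Path, records: list[SubjectRecord]) -> None:
    df = pd.DataFrame(
        [
            {
                "id": r.id, "sex": r.sex, "age": r.age, "bmi": r.bmi, "whr": r.whr,
                "group": r.group, "edeq_r": r.edeq_r, "edeq_e": r.edeq_e,
                "edeq_s": r.edeq_s, "edeq_w": r.edeq_w,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def read_time_series(path: str | Path, tr: float, subject_id: str | None = None):
    """Read a p-by-t headerless TSV as a NodeTimeSeries."""
    from .static import NodeTimeSeries

    data = read_matrix_tsv(path)
    return NodeTimeSeries(
        subject_id=subject_id or Path(path).stem.removeprefix("ts_"),
        data=data,
        tr=tr,
    )


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
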