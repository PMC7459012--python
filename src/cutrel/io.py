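"""Readers and writers for the pipeline's plain-text formats.

Responses travel as CSV (first column examinee id, one column per item);
exam metadata as JSON or YAML (chosen by file extension); curves as CSV;
per-exam report tables as TSV.  Reading validates everything the
pipeline assumes and points at the offending cell on failure.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .synthetic import ExamSpec, ItemSpec, ResponseMatrix


def write_responses(matrix: ResponseMatrix, path: str | Path) -> None:
    matrix.scores.to_csv(path, index_label="examinee")


def read_responses(
    path: str | Path,
    exam: ExamSpec | None = None,
    item_kinds: Sequence[str] | None = None,
) -> ResponseMatrix:
    """Load and validate a scored response CSV.

    Item kinds come from ``exam`` or ``item_kinds``; without either they
    are inferred from the scores (a column containing 0.5 must be MTF,
    anything else is treated as Type A).  Illegal values, missing cells
    and single-examinee files are rejected with coordinates.
    """
    frame = pd.read_csv(path, index_col=0)
    if frame.shape[0] < 2:
        raise ValueError(
            f"{path}: only {frame.shape[0]} examinee(s); score variance "
            "and everything built on it need at least 2"
        )
    if exam is not None:
        if list(frame.columns) != exam.item_ids:
            raise ValueError(f"{path}: item columns do not match exam spec")
        kinds = list(exam.item_kinds)
    elif item_kinds is not None:
        if len(item_kinds) != frame.shape[1]:
            raise ValueError(f"{path}: item_kinds length mismatch")
        kinds = list(item_kinds)
    else:
        values = frame.to_numpy(dtype=float)
        kinds = [
            "mtf" if np.any(values[:, j] == 0.5) else "typeA"
            for j in range(values.shape[1])
        ]
    matrix = ResponseMatrix(frame.astype(float), kinds)
    matrix.validate()
    return matrix


# --------------------------------------------------------------------------
# exam metadata

def exam_to_dict(exam: ExamSpec) -> dict:
    return {
        "exam_id": exam.exam_id,
        "cut_percent": float(exam.cut_percent),
        "school": exam.school,
        "year": int(exam.year_of_study),
        "items": [
            {
                "item_id": it.item_id,
                "kind": it.kind,
                "n_options": int(it.n_options),
                "step_params": [float(s) for s in it.step_params],
            }
            for it in exam.items
        ],
    }


def exam_from_dict(data: dict) -> ExamSpec:
    items = tuple(
        ItemSpec(
            item_id=d["item_id"],
            kind=d["kind"],
            n_options=d.get("n_options", 5 if d["kind"] == "typeA" else 4),
            step_params=tuple(
                d.get("step_params", [0.0] * (1 if d["kind"] == "typeA" else 2))
            ),
        )
        for d in data["items"]
    )
    return ExamSpec(
        exam_id=data["exam_id"],
        items=items,
        cut_percent=float(data["cut_percent"]),
        school=str(data.get("school", "A")),
        year_of_study=int(data.get("year", 1)),
    )


def write_exam_spec(exam: ExamSpec, path: str | Path) -> None:
    path = Path(path)
    data = exam_to_dict(exam)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=1))


def read_exam_spec(path: str | Path) -> ExamSpec:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return exam_from_dict(data)


# --------------------------------------------------------------------------
# tables

def write_curve_csv(curve, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_reports_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
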