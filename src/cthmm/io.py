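"""Reading and writing the long-format dataset table and run artifacts.

The canonical on-disk dataset is a delimited long-format table with header
``subject,time,outcome,z1,...,zD`` (z1 is the all-ones intercept column);
one row per observation, times in any consistent unit, first time per
subject equal to 0.  Ground truth from the simulator goes to a JSON sidecar
that the fitters never read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model import Subject
from .simulate import GroundTruth

__all__ = ["write_dataset", "read_dataset", "write_ground_truth",
           "write_jsonl", "read_jsonl"]


def write_dataset(subjects: list[Subject], path) -> None:
    rows = []
    for s in subjects:
        sid = s.subject_id
        for t in range(s.T):
            row = {"subject": sid, "time": s.times[t], "outcome": s.outcomes[t]}
            for d in range(s.Z.shape[1]):
                row[f"z{d + 1}"] = s.Z[t, d]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dataset(path) -> list[Subject]:
    df = pd.read_csv(path)
    base = ["subject", "time", "outcome"]
    zcols = [c for c in df.columns if c.startswith("z")]
    expected = base + [f"z{i + 1}" for i in range(len(zcols))]
    if list(df.columns) != expected:
        raise ValueError(
            f"dataset must have columns subject,time,outcome,z1..zD; "
            f"got {list(df.columns)}"
        )
    if df[base + zcols].isna().any().any():
        raise ValueError("dataset contains missing values")
    subjects = []
    for sid, g in df.groupby("subject", sort=True):
        g = g.sort_values("time")
        subj = Subject(g["time"].to_numpy(dtype=float),
                       g["outcome"].to_numpy(dtype=float),
                       g[zcols].to_numpy(dtype=float), subject_id=sid)
        subj.validate()
        subjects.append(subj)
    return subjects


def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict()))


def write_jsonl(records: list[dict], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, default=_json_default) + "\n")


def read_jsonl(path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
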