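"""CSV / YAML / Newick input-output.

Long datasets travel as a plain CSV (id columns then variables) plus a YAML
sidecar recording design, scale, variables and centering state.  Values
tables are exported in long form (dataset_id, group_id, pair_id,
measure_id, value, is_missing).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .preprocessing import ID_COLUMNS, CenteringSpec, LongDataset

__all__ = [
    "write_long_dataset",
    "read_long_dataset",
    "values_table_to_long",
    "write_values_table",
    "read_values_table",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.yaml")


def write_long_dataset(dataset: LongDataset, path: str | Path) -> None:
    path = Path(path)
    dataset.frame.to_csv(path, index=False)
    meta = {
        "dataset_id": dataset.dataset_id,
        "design": dataset.design,
        "variables": list(dataset.variables),
        "scale": [float(dataset.scale[0]), float(dataset.scale[1])],
        "centered": dataset.centered,
        "default_centering": (dataset.default_centering.mode
                              if dataset.default_centering else None),
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=False))


def read_long_dataset(path: str | Path) -> LongDataset:
    path = Path(path)
    meta = yaml.safe_load(_sidecar(path).read_text())
    frame = pd.read_csv(path)
    for col in ID_COLUMNS:
        if col in frame.columns and col != "occasion_id":
            frame[col] = frame[col].astype(str)
    default = (CenteringSpec(meta["default_centering"])
               if meta.get("default_centering") else None)
    return LongDataset(
        dataset_id=meta["dataset_id"], design=meta["design"], frame=frame,
        variables=list(meta["variables"]),
        scale=(float(meta["scale"][0]), float(meta["scale"][1])),
        centered=meta.get("centered"), default_centering=default)


def values_table_to_long(values: pd.DataFrame) -> pd.DataFrame:
    long = values.stack(future_stack=True).rename("value").reset_index()
    long = long.rename(columns={long.columns[-2]: "measure_id"})
    long["is_missing"] = long["value"].isna()
    return long


def write_values_table(values: pd.DataFrame, path: str | Path) -> None:
    values_table_to_long(values).to_csv(path, index=False)


def read_values_table(path: str | Path) -> pd.DataFrame:
    long = pd.read_csv(path)
    wide = long.pivot(index=["dataset_id", "group_id", "pair_id"],
                      columns="measure_id", values="value")
    wide.columns.name = None
    return wide
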