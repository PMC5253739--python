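"""File interfaces: model YAML/JSON, tidy time-course CSV, FC tables.

The model file layout mirrors the in-memory types (keys ``species``,
``reactions``, ``enzymes``); a read -> write -> read round trip is exact,
and two successive writes of the same model are byte-identical.

Time courses travel as tidy CSV with columns
``time, species, value, units[, replicate]``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .model import ModelSpec, model_from_dict, model_to_dict
from .simulate import TimeCourse

__all__ = [
    "read_model",
    "write_model",
    "timecourse_to_frame",
    "timecourse_from_frame",
    "write_timecourse",
    "read_timecourse",
    "write_fc_table",
    "read_fc_table",
    "write_ratio_table",
]


def read_model(path: str | Path) -> ModelSpec:
    path = Path(path)
    text = path.read_text()
    spec = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return model_from_dict(spec)


def write_model(model: ModelSpec, path: str | Path) -> None:
    path = Path(path)
    spec = model_to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(spec, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(spec, sort_keys=False))


def timecourse_to_frame(tc: TimeCourse, replicate: int | None = None) -> pd.DataFrame:
    rows = {
        "time": np.repeat(tc.times, len(tc.species)),
        "species": list(tc.species) * len(tc.times),
        "value": tc.values.ravel(),
        "units": tc.units,
    }
    frame = pd.DataFrame(rows)
    if replicate is None and "replicate" in tc.meta:
        replicate = tc.meta["replicate"]
    if replicate is not None:
        frame["replicate"] = replicate
    return frame


def timecourse_from_frame(frame: pd.DataFrame) -> TimeCourse:
    units = frame["units"].iloc[0]
    wide = frame.pivot_table(index="time", columns="species", values="value", sort=True)
    # preserve first-appearance species order from the tidy frame
    order = list(dict.fromkeys(frame["species"]))
    wide = wide[order]
    meta = {}
    if "replicate" in frame.columns:
        meta["replicate"] = int(frame["replicate"].iloc[0])
    return TimeCourse(
        wide.index.to_numpy(float), wide.to_numpy(), tuple(order), units, meta
    )


def write_timecourse(tc_or_list, path: str | Path) -> None:
    """One TimeCourse, or a list of replicates, to a tidy CSV."""
    if isinstance(tc_or_list, TimeCourse):
        frame = timecourse_to_frame(tc_or_list)
    else:
        frame = pd.concat(
            [timecourse_to_frame(tc, rep) for rep, tc in enumerate(tc_or_list)],
            ignore_index=True,
        )
    frame.to_csv(path, index=False)


def read_timecourse(path: str | Path):
    """Inverse of :func:`write_timecourse`; a list when replicates exist."""
    frame = pd.read_csv(path)
    if "replicate" in frame.columns and frame["replicate"].nunique() > 1:
        return [
            timecourse_from_frame(g) for _, g in frame.groupby("replicate", sort=True)
        ]
    return timecourse_from_frame(frame)


def write_fc_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_fc_table(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"enzyme", "direction"} - set(frame.columns)
    if missing:
        raise ValueError(f"FC table is missing columns {sorted(missing)}")
    return frame


def write_ratio_table(table: pd.DataFrame, path: str | Path) -> None:
    """AUC-ratio table in heatmap-ready long format."""
    long = table.reset_index().melt(
        id_vars=table.index.names if table.index.names[0] else ["index"],
        var_name="species",
        value_name="log2_auc_ratio",
    )
    long.to_csv(path, index=False)
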