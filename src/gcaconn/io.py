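"""File I/O: phenotype CSV, feature/time-series HDF5, atlas TSV, JSON reports."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, is_dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .connectome import RunTimeSeries
from .dataset import SES_COLUMNS, StudyData

logger = logging.getLogger(__name__)

__all__ = [
    "load_phenotypes",
    "save_phenotypes",
    "save_features",
    "load_features",
    "save_timeseries",
    "load_timeseries",
    "save_atlas",
    "load_atlas",
    "save_json",
]

REQUIRED_COLUMNS = ["subject_id", "site", "family_id", "twin",
                    "age", "sex", "race", "mean_fd"] + SES_COLUMNS


def load_phenotypes(path) -> pd.DataFrame:
    """Read and validate the phenotype table.

    Subjects missing any required field (including any task score) are
    excluded with a logged count; a missing required *column* or duplicated
    subject id is an error.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks required column(s): {missing}")
    task_cols = [c for c in df.columns if c.startswith("task_")]
    if not task_cols:
        raise ValueError("phenotype file has no task_* score columns")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject id(s): {dups[:5]}")
    needed = REQUIRED_COLUMNS + task_cols
    complete = df[needed].notna().all(axis=1)
    if (~complete).any():
        logger.info(
            "excluding %d subject(s) with missing required fields", int((~complete).sum())
        )
    return df.loc[complete].reset_index(drop=True)


def save_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def save_features(path, features: np.ndarray, subject_ids, metric: str = "pearson") -> None:
    """Subjects x edges matrix to HDF5 plus a CSV manifest next to it."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=np.asarray(features))
        f.attrs["metric"] = metric
    pd.DataFrame({"subject_id": list(subject_ids)}).to_csv(
        path.with_suffix(".manifest.csv"), index=False
    )


def load_features(path) -> tuple[np.ndarray, list, str]:
    path = Path(path)
    with h5py.File(path, "r") as f:
        features = f["features"][...]
        metric = f.attrs.get("metric", "pearson")
    manifest = pd.read_csv(path.with_suffix(".manifest.csv"))
    return features, manifest["subject_id"].tolist(), str(metric)


def save_timeseries(path, runs: dict[str, list[RunTimeSeries]]) -> None:
    """One HDF5 group per subject, one dataset pair (frames, fd) per run."""
    with h5py.File(path, "w") as f:
        for sid, subject_runs in runs.items():
            grp = f.create_group(sid)
            for run in subject_runs:
                g = grp.create_group(f"run{run.run_id}")
                g.create_dataset("frames", data=run.frames)
                g.create_dataset("fd", data=run.fd)


def load_timeseries(path) -> dict[str, list[RunTimeSeries]]:
    out: dict[str, list[RunTimeSeries]] = {}
    with h5py.File(path, "r") as f:
        for sid in f:
            runs = []
            for rname in sorted(f[sid]):
                g = f[sid][rname]
                runs.append(
                    RunTimeSeries(
                        g["frames"][...], g["fd"][...],
                        run_id=int(rname.removeprefix("run")), subject_id=sid,
                    )
                )
            out[sid] = runs
    return out


def save_atlas(path, atlas: pd.DataFrame) -> None:
    atlas.to_csv(path, sep="\t", index=False)


def load_atlas(path) -> pd.DataFrame:
    atlas = pd.read_csv(path, sep="\t")
    if not {"parcel_id", "network"} <= set(atlas.columns):
        raise ValueError("atlas TSV needs parcel_id and network columns")
    return atlas


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def save_json(path, payload) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, allow_nan=True))
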