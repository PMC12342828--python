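"""Reading and writing the package's standard on-disk formats: snapshot and
time-course CSV, 16-bit TIFF images and label masks, and YAML/JSON configs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .model import ModelParams
from .synthetic import SNAPSHOT_COLUMNS, TimeCourse


def write_snapshot(snapshot: pd.DataFrame, path) -> None:
    snapshot.to_csv(path, index=False)


def read_snapshot(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SNAPSHOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"snapshot file {path} is missing columns {missing}")
    return df


def write_timecourse(tc: TimeCourse, path) -> None:
    tc.to_frame().to_csv(path, index=False)


def read_timecourse(path) -> TimeCourse:
    df = pd.read_csv(path)
    return TimeCourse(
        times=df["time_min"].to_numpy(dtype=float),
        mean_counts=df["mean_count"].to_numpy(dtype=float),
        n_cells_per_timepoint=df["n_cells"].to_numpy(dtype=np.int64),
    )


def write_image(image: np.ndarray, path) -> None:
    """Save as 16-bit grayscale TIFF (values clipped to the uint16 range)."""
    tifffile.imwrite(path, np.clip(np.round(image), 0, 65535).astype(np.uint16))


def read_image(path) -> np.ndarray:
    return tifffile.imread(path)


def write_mask(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, mask.astype(np.uint16))


read_mask = read_image


def load_params(path) -> ModelParams:
    """Model parameters from a YAML or JSON mapping with keys
    k_m, b, gamma_m, k_p, gamma_p."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return ModelParams(**{k: float(data[k]) for k in ("k_m", "b", "gamma_m", "k_p", "gamma_p")})


def dump_params(params: ModelParams, path) -> None:
    data = asdict(params)
    if str(path).endswith(".json"):
        Path(path).write_text(json.dumps(data, indent=2))
    else:
        Path(path).write_text(yaml.safe_dump(data))
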