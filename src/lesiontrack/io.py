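"""File I/O: TIFF volumes with JSON sidecars, CSV/TSV tables, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import VoxelVolume

__all__ = [
    "save_volume",
    "load_volume",
    "write_trajectories",
    "read_trajectories",
    "write_components",
    "read_components",
    "write_behavior_sequences",
    "read_behavior_sequences",
    "write_dsp",
    "read_dsp",
    "load_config_dict",
]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def save_volume(volume: VoxelVolume, path) -> Path:
    """Write a volume as multi-page TIFF plus a JSON sidecar with metadata."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(volume.values, dtype=np.float32))
    meta = {
        "voxel_size_um": list(volume.voxel_size),
        "channel": volume.channel,
        "week": volume.week,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def load_volume(path) -> VoxelVolume:
    """Read a multi-page TIFF and its JSON sidecar back into a VoxelVolume."""
    path = Path(path)
    values = tifffile.imread(path)
    meta = json.loads(_sidecar_path(path).read_text())
    return VoxelVolume(
        values=np.asarray(values, dtype=float),
        voxel_size=tuple(meta["voxel_size_um"]),
        channel=meta.get("channel", ""),
        week=meta.get("week"),
    )


def write_trajectories(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_trajectories(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"mouse_id", "lesion_id", "week", "volume_um3"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    if "censored" not in df:
        df["censored"] = False
    return df


def write_components(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_components(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_behavior_sequences(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_behavior_sequences(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"lesion_id", "session", "state"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"behavior CSV missing columns: {sorted(missing)}")
    return df


def write_dsp(counts: pd.DataFrame, annotation: pd.DataFrame, counts_path, annot_path) -> None:
    """Write genes x AOIs counts and the AOI annotation as TSV."""
    counts.to_csv(counts_path, sep="\t")
    annotation.to_csv(annot_path, sep="\t")


def read_dsp(counts_path, annot_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    annotation = pd.read_csv(annot_path, sep="\t", index_col=0)
    counts.columns.name = annotation.index.name
    missing = {"class", "lesion_id", "group"} - set(annotation.columns)
    if missing:
        raise ValueError(f"AOI annotation missing columns: {sorted(missing)}")
    return counts, annotation


def load_config_dict(path) -> dict:
    """Load a YAML or JSON config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        return yaml.safe_load(text)
    return json.loads(text)
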