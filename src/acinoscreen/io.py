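"""File-format glue: TIFF stacks, CSV tables, YAML configs."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


def write_plate_tiffs(plate, out_dir) -> list[Path]:
    """One channel-interleaved multi-page TIFF per field.

    Page order is frame-major: (frame0 c0, frame0 c1, frame1 c0, ...).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for (condition, replicate, well, fld), stack in plate.frames.items():
        name = f"{condition}_r{replicate}_w{well}_f{fld}.tif"
        path = out_dir / name
        n_frames, n_channels, h, w = stack.shape
        pages = stack.reshape(n_frames * n_channels, h, w)
        tifffile.imwrite(path, pages, metadata={
            "condition": condition, "replicate": replicate,
            "well": well, "field": fld, "n_channels": n_channels,
        })
        paths.append(path)
    return paths


def read_field_tiff(path, n_channels: int = 2) -> np.ndarray:
    """Read a channel-interleaved stack back to (n_frames, C, H, W)."""
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_pages, h, w = pages.shape
    if n_pages % n_channels:
        raise ValueError(f"{path}: page count not divisible by {n_channels}")
    return pages.reshape(n_pages // n_channels, n_channels, h, w)


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path, config_cls):
    """Instantiate a simulator config dataclass from a YAML mapping."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    names = {f.name for f in dataclasses.fields(config_cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return config_cls(**data)
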