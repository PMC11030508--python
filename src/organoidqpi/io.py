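"""File I/O helpers: TIFF images, YAML configs, CSV tables."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile
import yaml


def write_tiff(path, image: np.ndarray, float32: bool = True) -> None:
    arr = np.asarray(image)
    if float32 and arr.dtype.kind == "f":
        arr = arr.astype(np.float32)
    tifffile.imwrite(str(path), arr)


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_label_tiff(path, labels: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(labels, dtype=np.uint8))


def write_frames_tiff(path, frames: np.ndarray) -> None:
    """Multi-page TIFF, one page per illumination frame."""
    tifffile.imwrite(str(path), np.asarray(frames, dtype=np.float32))


def dataclass_to_dict(obj) -> dict:
    d = dataclasses.asdict(obj)

    def clean(v):
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    return clean(d)


def write_yaml(path, obj) -> None:
    data = dataclass_to_dict(obj) if dataclasses.is_dataclass(obj) else obj
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_yaml(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
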