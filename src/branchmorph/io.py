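"""Readers and writers for the on-disk formats the toolkit exchanges.

Class masks are stored as palettized (indexed) PNGs whose palette
*index* is the class id — 0 background, 1 trunk, 2 branch — following
the VOC annotation convention.  The attached palette colors are a
visualization aid only and are never parsed.  Measurements travel as
CSV with a fixed header; metric reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

__all__ = [
    "CLASS_PALETTE",
    "save_class_mask",
    "load_class_mask",
    "save_image",
    "load_image",
    "measurements_to_frame",
    "write_measurements",
    "write_json",
    "load_run_config",
]

#: display colors for class ids 0..2 (background, trunk, branch)
CLASS_PALETTE = [(0, 0, 0), (153, 102, 51), (122, 199, 76)]


def save_class_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a class mask as an indexed PNG (palette index = class id)."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("class mask must be 2-D")
    if arr.min(initial=0) < 0 or arr.max(initial=0) > 255:
        raise ValueError("class ids must fit in a palette index (0..255)")
    img = Image.fromarray(arr.astype(np.uint8), mode="P")
    palette = list(sum(CLASS_PALETTE, ()))
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(Path(path))


def load_class_mask(path: str | Path) -> np.ndarray:
    """Read an indexed-PNG class mask back to an integer label array."""
    with Image.open(Path(path)) as img:
        if img.mode != "P":
            raise ValueError(
                f"{path}: expected an indexed (palette) PNG mask, got mode {img.mode!r}"
            )
        return np.asarray(img, dtype=np.int64)


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write an RGB uint8 image as PNG/JPEG (by extension)."""
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(Path(path))


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file as an RGB uint8 array."""
    with Image.open(Path(path)) as img:
        return np.asarray(img.convert("RGB"), dtype=np.uint8)


_MEASUREMENT_COLUMNS = ["instance_id", "class", "length_px", "inclination_deg"]


def measurements_to_frame(records) -> pd.DataFrame:
    """Convert BranchMeasurement records to a tidy DataFrame."""
    rows = [
        {
            "instance_id": r.instance_id,
            "class": r.class_name,
            "length_px": r.length_px,
            "inclination_deg": round(r.inclination_deg, 4),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_MEASUREMENT_COLUMNS)


def write_measurements(records, path: str | Path) -> None:
    measurements_to_frame(records).to_csv(Path(path), index=False)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run configuration as a plain dict."""
    with open(Path(path)) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a YAML mapping")
    return cfg
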