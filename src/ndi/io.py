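"""File I/O: TIFF stacks, ROI definitions, YAML config with validation."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

from ndi.polarimetry import DEFAULT_PIXEL_SIZE_UM, PolarizedImageSet, Region

#: every configurable default, inspectable via `ndi defaults`
DEFAULTS = {
    "background": 0.0,
    "threshold": 0.0,
    "smoothing_window": 1,
    "pixel_size_um": DEFAULT_PIXEL_SIZE_UM,
    "frame_interval_s": 0.0,
    "registration": {"mode": "similarity", "reference_frame": 0},
    "bleach": {"n_bins": 10, "fit_min": 0.2, "fit_max": 1.0},
    "fcs": {"fix_s": 0.2, "lag_min": 5e-6, "lag_max": 2.0},
    "gp": {"gp_ref": 0.207},
    "blobs": {"sigma": 1.0, "min_size": 4, "use_gradient": True},
}


def read_stack(path: str | Path) -> np.ndarray:
    """Read a single- or multi-page TIFF as a float stack (n, h, w)."""
    arr = tifffile.imread(str(path)).astype(float)
    return arr[None] if arr.ndim == 2 else arr


def write_float_tiff(path: str | Path, data: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(data, dtype=np.float32))


def load_polarized_set(
    pa_path: str | Path,
    pe_path: str | Path,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    frame_interval: float = 0.0,
    background: float | np.ndarray = 0.0,
) -> PolarizedImageSet:
    """Load paired `<stem>_pa.tif` / `<stem>_pe.tif` channel stacks."""
    return PolarizedImageSet(
        ipa=read_stack(pa_path),
        ipe=read_stack(pe_path),
        pixel_size=pixel_size,
        frame_interval=frame_interval,
        background_ipa=background,
        background_ipe=background,
    )


def load_regions(path: str | Path) -> list[Region]:
    """Read regions from a JSON list of {kind, geometry, label, width}."""
    items = json.loads(Path(path).read_text())
    regions = []
    for it in items:
        kind = it["kind"]
        if kind == "rectangle":
            regions.append(Region.rectangle(*it["geometry"], label=it.get("label", "")))
        elif kind == "line":
            regions.append(
                Region.line(*it["geometry"], width=it.get("width", 1), label=it.get("label", ""))
            )
        elif kind == "polygon":
            regions.append(Region.polygon(it["geometry"], label=it.get("label", "")))
        else:
            raise ValueError(f"unsupported region kind in file: {kind!r}")
    return regions


def validate_config(config: dict, schema: dict | None = None, path: str = "") -> dict:
    """Check ``config`` against the defaults schema; unknown keys are
    rejected with their full key path named. Returns defaults merged with
    overrides."""
    schema = DEFAULTS if schema is None else schema
    merged = {}
    for key, default in schema.items():
        if isinstance(default, dict):
            merged[key] = validate_config(config.get(key, {}), default, f"{path}{key}.")
        else:
            merged[key] = config.get(key, default)
    for key in config:
        if key not in schema:
            raise ValueError(f"unknown config key: {path}{key}")
    return merged


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return validate_config({})
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(raw)
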