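"""Reading and writing scenes, ratio images and sidecar metadata.

Scenes are stored as one multi-page TIFF per channel (frame-major) plus a
``scene.json`` sidecar carrying the pixel size (µm/px), frame interval (s)
and channel names; ground truth goes to ``truth.json``. Ratio images are
written as 32-bit float TIFF together with a validity-mask TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .ratio import RatioImage
from .simulate import GroundTruth, SceneStack

SIDECAR_NAME = "scene.json"
TRUTH_NAME = "truth.json"


def write_scene(
    directory, stack: SceneStack, truth: GroundTruth | None = None, extra: dict | None = None
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, data in stack.channels.items():
        tifffile.imwrite(
            directory / f"{name}.tif", data.astype(np.float32),
            photometric="minisblack",
        )
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "channels": list(stack.channels),
    }
    if extra:
        meta.update(extra)
    (directory / SIDECAR_NAME).write_text(json.dumps(meta, indent=2))
    if truth is not None:
        (directory / TRUTH_NAME).write_text(json.dumps(truth.to_dict(), indent=2))
    return directory


def read_scene(directory) -> SceneStack:
    directory = Path(directory)
    meta = json.loads((directory / SIDECAR_NAME).read_text())
    channels = {
        name: tifffile.imread(directory / f"{name}.tif").astype(float)
        for name in meta["channels"]
    }
    for name, data in channels.items():
        if data.ndim == 2:  # single-frame stacks come back squeezed
            channels[name] = data[None]
    return SceneStack(channels, meta["pixel_size_um"], meta["frame_interval_s"])


def read_stack(path, pixel_size: float | None = None) -> np.ndarray:
    """Plain multi-page TIFF reader; returns (frames, rows, cols)."""
    data = tifffile.imread(path).astype(float)
    return data[None] if data.ndim == 2 else data


def write_ratio_image(path, ratio: RatioImage) -> None:
    path = Path(path)
    tifffile.imwrite(path, ratio.values.astype(np.float32))
    mask_path = path.with_name(path.stem + "_valid" + path.suffix)
    tifffile.imwrite(mask_path, ratio.valid_mask.astype(np.uint8))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)
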