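"""Readers and writers: PNG/PGM/TIFF images, masks, manifests, DCA1, checkpoints.

Conventions used throughout: row-major arrays, origin at the top-left,
0-based (row, col) indexing; masks are 0/255 on disk and 0/1 in memory.
"""
from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .preprocess import RawAngiogram

log = logging.getLogger("angioseg")

_LUMA = np.array([0.299, 0.587, 0.114])


def load_image(path) -> RawAngiogram:
    """Load a grayscale 8-bit angiogram (PNG, PGM P5 or TIFF).

    Multi-channel inputs are collapsed by luminance (identical channels
    collapse exactly); 16-bit inputs are rescaled to 8-bit.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            mode = im.mode
            arr = np.asarray(im)
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if np.all(arr[:, :, 0] == arr[:, :, 1]) and np.all(arr[:, :, 1] == arr[:, :, 2]):
            arr = arr[:, :, 0]
        else:
            arr = np.clip(np.rint(arr.astype(np.float64) @ _LUMA), 0, 255).astype(np.uint8)
    if arr.dtype == np.uint16:
        arr = (arr / 257.0).round().astype(np.uint8)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    img = RawAngiogram(arr.astype(np.uint8), source_id=str(path))
    img.original_mode = mode
    return img


def save_image(path, pixels: np.ndarray) -> None:
    pixels = np.asarray(pixels)
    if np.issubdtype(pixels.dtype, np.floating):
        pixels = np.clip(np.rint(pixels * 255), 0, 255).astype(np.uint8)
    Image.fromarray(pixels.astype(np.uint8), mode="L").save(Path(path))


def save_mask(path, mask: np.ndarray) -> None:
    """Binary mask written as 0/255 PNG."""
    m = (np.asarray(mask) > 0).astype(np.uint8) * 255
    Image.fromarray(m, mode="L").save(Path(path))


def load_mask(path) -> np.ndarray:
    """Read a mask image, binarizing at >127 (guards resaved copies)."""
    try:
        with Image.open(Path(path)) as im:
            arr = np.asarray(im.convert("L"))
    except Exception as exc:
        raise IOError(f"cannot read mask {path}: {exc}") from exc
    return (arr > 127).astype(np.uint8)


def save_rgb(path, channels: np.ndarray) -> None:
    """Write a (3,H,W) uint8 stack as an RGB PNG."""
    Image.fromarray(np.moveaxis(channels, 0, 2), mode="RGB").save(Path(path))


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def load_manifest(path) -> pd.DataFrame:
    """Dataset manifest CSV: image_path, mask_path, patient_id, side."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"image_path", "mask_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    root = path.parent
    df["image_path"] = [str(root / p) for p in df["image_path"]]
    df["mask_path"] = [str(root / p) for p in df["mask_path"]]
    return df


# ---------------------------------------------------------------------------
# DCA1 layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dca1Record:
    image_path: str
    gt_path: str
    id: int


def load_dca1(root_dir):
    """Load the paired angiogram / ground-truth layout of the DCA1 dataset.

    Files are ``<id>.pgm`` with ``<id>_gt.pgm`` masks (PNG accepted too).
    Returns records sorted by id; unpaired files are reported in the second
    return value, never silently dropped. The full public set has 134 pairs;
    smaller subsets load with a warning.
    """
    root = Path(root_dir)
    images, gts = {}, {}
    for p in sorted(root.glob("*")):
        m = re.fullmatch(r"(\d+)(_gt)?\.(pgm|png|tif|tiff)", p.name)
        if not m:
            continue
        idx = int(m.group(1))
        (gts if m.group(2) else images)[idx] = p
    records, unpaired = [], []
    for idx in sorted(set(images) | set(gts)):
        if idx in images and idx in gts:
            records.append(Dca1Record(str(images[idx]), str(gts[idx]), idx))
        else:
            unpaired.append(str(images.get(idx, gts.get(idx))))
    if len(records) != 134:
        warnings.warn(f"DCA1 layout at {root} has {len(records)} pairs "
                      "(full public set has 134)")
    if unpaired:
        log.warning("DCA1: %d unpaired files: %s", len(unpaired), unpaired)
    return records, unpaired


# ---------------------------------------------------------------------------
# checkpoints: npz weights + YAML config snapshot
# ---------------------------------------------------------------------------

def save_checkpoint(path, model, config: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **model.state_dict())
    if config is not None:
        with open(path.with_suffix(".yaml"), "w") as fh:
            yaml.safe_dump(config, fh)


def load_checkpoint(path, model) -> dict:
    path = Path(path)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    cfg_path = path.with_suffix(".yaml")
    if cfg_path.exists():
        with open(cfg_path) as fh:
            return yaml.safe_load(fh)
    return {}
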