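"""Dual-phase angiogram enhancement: unsharp masking + two CLAHE filters.

X-ray angiograms are low-contrast: iodinated contrast medium attenuates the
beam, so vessels are slightly darker than a noisy, unevenly illuminated
background. The pipeline sharpens fine vessel edges with an unsharp mask
(USM) and then boosts local contrast with two differently parameterized
CLAHE filters; the three results are stacked into one 3-channel image fed
to both the side classifier and the segmentation network.

All operators work internally on 8-bit intensities (256 histogram bins);
float inputs in [0, 1] are rescaled in and back out.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


class ParameterError(ValueError):
    pass


@dataclass
class RawAngiogram:
    """Single-channel intensity image (uint8 0-255 or float 0-1)."""
    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ParameterError(f"angiogram must be 2-D, got {self.pixels.ndim}-D")
        if self.pixels.shape[0] < 32 or self.pixels.shape[1] < 32:
            raise ParameterError(f"angiogram too small: {self.pixels.shape}")
        if np.issubdtype(self.pixels.dtype, np.floating):
            lo, hi = float(self.pixels.min()), float(self.pixels.max())
            if lo < -1e-6 or hi > 1 + 1e-6:
                raise ParameterError("float angiogram must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ClaheParams:
    clip_limit: float = 2.0
    tile_grid: tuple = (8, 8)

    def __post_init__(self):
        if self.clip_limit <= 0:
            raise ParameterError("clip_limit must be > 0")
        if min(self.tile_grid) < 1:
            raise ParameterError("tile_grid entries must be >= 1")


@dataclass(frozen=True)
class PreprocessParams:
    """Defaults are conventional values for 512x512 X-ray images; the
    contract is the pipeline structure, the constants are tunable."""
    usm_radius: float = 2.0
    usm_amount: float = 1.5
    clahe_a: ClaheParams = field(default_factory=lambda: ClaheParams(2.0, (8, 8)))
    clahe_b: ClaheParams = field(default_factory=lambda: ClaheParams(4.0, (16, 16)))

    def __post_init__(self):
        if self.usm_radius <= 0:
            raise ParameterError("usm_radius must be > 0")
        if self.usm_amount < 0:
            raise ParameterError("usm_amount must be >= 0")
        if self.clahe_a == self.clahe_b:
            raise ParameterError("clahe_a and clahe_b must differ in some field")


@dataclass
class PreprocessedImage:
    """3 stacked channels (usm, clahe_a, clahe_b), each input-shaped."""
    channels: np.ndarray           # (3, H, W) uint8
    channel_roles: tuple = ("usm", "clahe_a", "clahe_b")
    source_id: str = ""

    def __post_init__(self):
        if self.channels.shape[0] != 3 or self.channels.ndim != 3:
            raise ParameterError("preprocessed image must have exactly 3 channels")


def _to_u8(pixels: np.ndarray):
    """Return (uint8 image, was_float flag)."""
    if np.issubdtype(pixels.dtype, np.floating):
        return np.clip(np.rint(pixels * 255.0), 0, 255).astype(np.uint8), True
    return pixels.astype(np.uint8), False


def _from_u8(img: np.ndarray, was_float: bool):
    return img.astype(np.float64) / 255.0 if was_float else img


def unsharp_mask(img: RawAngiogram, radius: float = 2.0,
                 amount: float = 1.5) -> RawAngiogram:
    """Sharpen by adding back the Gaussian high-frequency residual.

    out = clip(img + amount * (img - gaussian_blur(img, radius)))
    """
    if radius <= 0:
        raise ParameterError("usm radius must be > 0")
    if amount < 0:
        raise ParameterError("usm amount must be >= 0")
    u8, was_float = _to_u8(img.pixels)
    x = u8.astype(np.float64)
    blur = ndimage.gaussian_filter(x, sigma=radius, mode="reflect")
    out = np.clip(np.rint(x + amount * (x - blur)), 0, 255).astype(np.uint8)
    return RawAngiogram(_from_u8(out, was_float), img.source_id)


def _tile_lut(tile: np.ndarray, clip_limit: float) -> np.ndarray:
    """Clipped-histogram equalization LUT for one tile (256 bins)."""
    n = tile.size
    hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
    if np.isfinite(clip_limit):
        # OpenCV-style units: clip at clip_limit x the uniform bin height
        clip = max(clip_limit * n / 256.0, 1.0)
        excess = np.maximum(hist - clip, 0.0).sum()
        hist = np.minimum(hist, clip) + excess / 256.0
    cdf = np.cumsum(hist)
    return np.clip(np.rint(cdf * 255.0 / n), 0, 255)


def clahe(img: RawAngiogram, clip_limit: float = 2.0,
          tile_grid: tuple = (8, 8)) -> RawAngiogram:
    """Contrast-limited adaptive histogram equalization.

    Per-tile histograms are clipped at ``clip_limit`` times the uniform bin
    height (excess redistributed uniformly), equalized, and the per-tile
    look-up tables are blended bilinearly between neighbouring tile centres.
    Images not divisible by the grid are mirror-padded and cropped back.
    """
    if clip_limit <= 0:
        raise ParameterError("clip_limit must be > 0")
    rows, cols = int(tile_grid[0]), int(tile_grid[1])
    if rows < 1 or cols < 1:
        raise ParameterError("tile_grid entries must be >= 1")
    u8, was_float = _to_u8(img.pixels)
    h, w = u8.shape
    if rows > h or cols > w:
        raise ParameterError(f"tile_grid {tile_grid} larger than image {u8.shape}")

    th = -(-h // rows)   # ceil tile size
    tw = -(-w // cols)
    ph, pw = th * rows - h, tw * cols - w
    padded = np.pad(u8, ((0, ph), (0, pw)), mode="symmetric")

    luts = np.empty((rows, cols, 256))
    for i in range(rows):
        for j in range(cols):
            tile = padded[i * th:(i + 1) * th, j * tw:(j + 1) * tw]
            luts[i, j] = _tile_lut(tile, clip_limit)

    # bilinear blend between the four surrounding tile-centre LUTs
    yy = np.arange(th * rows)
    xx = np.arange(tw * cols)
    fy = (yy + 0.5) / th - 0.5
    fx = (xx + 0.5) / tw - 0.5
    y0 = np.clip(np.floor(fy).astype(int), 0, rows - 1)
    x0 = np.clip(np.floor(fx).astype(int), 0, cols - 1)
    y1 = np.minimum(y0 + 1, rows - 1)
    x1 = np.minimum(x0 + 1, cols - 1)
    wy = np.clip(fy - y0, 0.0, 1.0)[:, None]
    wx = np.clip(fx - x0, 0.0, 1.0)[None, :]

    img_idx = padded.astype(int)
    g_y0 = y0[:, None]
    g_y1 = y1[:, None]
    g_x0 = x0[None, :]
    g_x1 = x1[None, :]
    v00 = luts[np.broadcast_to(g_y0, padded.shape),
               np.broadcast_to(g_x0, padded.shape), img_idx]
    v01 = luts[np.broadcast_to(g_y0, padded.shape),
               np.broadcast_to(g_x1, padded.shape), img_idx]
    v10 = luts[np.broadcast_to(g_y1, padded.shape),
               np.broadcast_to(g_x0, padded.shape), img_idx]
    v11 = luts[np.broadcast_to(g_y1, padded.shape),
               np.broadcast_to(g_x1, padded.shape), img_idx]
    out = ((1 - wy) * ((1 - wx) * v00 + wx * v01)
           + wy * ((1 - wx) * v10 + wx * v11))
    out = np.clip(np.rint(out[:h, :w]), 0, 255).astype(np.uint8)
    return RawAngiogram(_from_u8(out, was_float), img.source_id)


def preprocess_pipeline(img: RawAngiogram,
                        params: PreprocessParams | None = None) -> PreprocessedImage:
    """USM, then two CLAHE filters applied to the USM output; stack 3 channels."""
    params = params or PreprocessParams()
    sharp = unsharp_mask(img, params.usm_radius, params.usm_amount)
    ca = clahe(sharp, params.clahe_a.clip_limit, params.clahe_a.tile_grid)
    cb = clahe(sharp, params.clahe_b.clip_limit, params.clahe_b.tile_grid)
    chans = [_to_u8(sharp.pixels)[0], _to_u8(ca.pixels)[0], _to_u8(cb.pixels)[0]]
    return PreprocessedImage(np.stack(chans, axis=0), source_id=img.source_id)


def model_input(pre: PreprocessedImage) -> np.ndarray:
    """(3,H,W) float32 in [0,1] — the tensor layout the networks consume."""
    return pre.channels.astype(np.float32) / 255.0
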