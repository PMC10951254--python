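"""SE-RegUNet: RegNet encoder + U-Net decoder with squeeze-and-excitation.

The encoder follows the RegNet design space: per-block widths come from a
quantized linear rule (``w_j = w0 + wa * j`` snapped to powers of ``wm`` and
multiples of 8), blocks are grouped 3x3 bottlenecks with channel attention.
Two block flavours are provided: the Y block (bottleneck ratio 1, residual
throughout) and the Z block (inverted bottleneck, linear projection, residual
only at stride 1). The decoder is a U-Net: bilinear x2 upsampling, skip
concatenation, two conv3x3-BN-ReLU layers, and an SE gate per stage; a
softmax head emits per-pixel class probabilities at input resolution.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .nn import functional as F
from .nn.layers import Module, Conv2d, BatchNorm2d, Linear, SEBlock, ReLU, Sequential


# ---------------------------------------------------------------------------
# RegNet design-space arithmetic
# ---------------------------------------------------------------------------

def generate_regnet_widths(w_a: float, w_0: int, w_m: float, depth: int,
                           q: int = 8, group_width: int = 1):
    """Quantized-linear width schedule of the RegNet design space.

    Returns (stage_widths, stage_depths) after snapping block widths to the
    geometric grid, rounding to multiples of ``q`` and making every width
    divisible by the group width.
    """
    if w_a < 0 or w_0 <= 0 or w_m <= 1:
        raise ValueError("invalid RegNet parameters")
    ks = np.round(np.log((w_0 + w_a * np.arange(depth)) / w_0) / np.log(w_m))
    widths = w_0 * np.power(w_m, ks)
    widths = (np.round(widths / q) * q).astype(int)
    widths = np.array([max(group_width, int(round(w / group_width)) * group_width)
                       for w in widths])
    stage_widths, stage_depths = [], []
    for w in widths:
        if stage_widths and stage_widths[-1] == w:
            stage_depths[-1] += 1
        else:
            stage_widths.append(int(w))
            stage_depths.append(1)
    return stage_widths, stage_depths


@dataclass(frozen=True)
class EncoderSpec:
    """Concrete per-stage encoder layout (strides 4, 8, 16, 32)."""
    name: str
    block: str                   # 'y' | 'z'
    stem_width: int
    widths: tuple
    depths: tuple
    group_width: int
    bottleneck: float            # block width multiplier (Y: 1.0; Z: >1 inverted)
    se_ratio: float = 0.25


def _regnety_16gf_spec() -> EncoderSpec:
    widths, depths = generate_regnet_widths(106.23, 200, 2.48, 18, group_width=112)
    return EncoderSpec("regnety_16gf", "y", 32, tuple(widths), tuple(depths), 112, 1.0)


# The 4-gigaflop Z variant: inverted-bottleneck RegNet calibrated to the
# 4 GFLOP design point (grouped 3x3, SE, linear projection).
_REGNETZ_4GF = EncoderSpec("regnetz_4gf", "z", 32,
                           widths=(56, 112, 272, 576),
                           depths=(2, 6, 12, 2),
                           group_width=8, bottleneck=4.0)

_TINY_Z = EncoderSpec("tiny_z", "z", 16,
                      widths=(16, 32, 48, 64),
                      depths=(1, 1, 2, 1),
                      group_width=8, bottleneck=2.0)

ENCODER_SPECS = {
    "regnetz_4gf": _REGNETZ_4GF,
    "regnety_16gf": _regnety_16gf_spec(),
    "tiny_z": _TINY_Z,
}

# Decoder widths, deepest stage first; the last entry is the width of the
# full-resolution stage after the final upsample. Calibrated per backbone so
# total model complexity sits at the intended design point.
DEFAULT_DECODER_CHANNELS = {
    "regnetz_4gf": (288, 144, 72, 36, 18),
    "regnety_16gf": (1792, 512, 256, 96, 48),
    "tiny_z": (48, 32, 24, 16, 12),
}


@dataclass
class SegModelConfig:
    backbone: str = "regnetz_4gf"
    input_size: int = 512
    in_channels: int = 3
    num_classes: int = 2
    decoder_channels: tuple | None = None
    se_reduction: int = 16
    width_scale: float = 1.0     # divide decoder widths for desk-scale runs
    seed: int = 0

    def resolved_decoder(self) -> tuple:
        if self.decoder_channels is not None:
            ch = tuple(self.decoder_channels)
        else:
            ch = DEFAULT_DECODER_CHANNELS[self.backbone]
        if self.width_scale != 1.0:
            ch = tuple(max(4, int(round(c * self.width_scale))) for c in ch)
        return ch

    def to_dict(self):
        d = asdict(self)
        d["decoder_channels"] = list(self.resolved_decoder())
        return d


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

class ConvBNAct(Module):
    def __init__(self, cin, cout, k=3, stride=1, groups=1, act=True, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride=stride, padding=k // 2,
                           groups=groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def forward(self, x):
        x = self.bn(self.conv(x))
        if self.act and not isinstance(x, F.Probe):
            x = nn.relu(x)
        return x


def _num_groups(width: int, group_width: int) -> int:
    g = max(1, min(group_width, width))
    while width % g:
        g -= 1
    return width // g


class RegNetBlock(Module):
    """Grouped bottleneck block, Y (residual) or Z (inverted, linear) style."""

    def __init__(self, cin, cout, stride, spec: EncoderSpec, rng=None):
        super().__init__()
        wb = int(round(cout * spec.bottleneck))
        groups = _num_groups(wb, spec.group_width)
        self.style = spec.block
        self.expand = ConvBNAct(cin, wb, k=1, rng=rng)
        self.spatial = ConvBNAct(wb, wb, k=3, stride=stride, groups=groups, rng=rng)
        se_hidden = max(1, int(round(spec.se_ratio * (cin if spec.block == "y" else wb))))
        self.se = SEBlock(wb, hidden=se_hidden, rng=rng)
        self.project = ConvBNAct(wb, cout, k=1, act=False, rng=rng)
        self.use_residual = (spec.block == "y") or (stride == 1 and cin == cout)
        self.shortcut = None
        if self.use_residual and (stride != 1 or cin != cout):
            self.shortcut = ConvBNAct(cin, cout, k=1, stride=stride, act=False, rng=rng)

    def forward(self, x):
        out = self.project(self.se(self.spatial(self.expand(x))))
        if self.use_residual:
            idn = self.shortcut(x) if self.shortcut is not None else x
            if isinstance(out, F.Probe):
                return out
            out = out + idn
        if self.style == "y" and not isinstance(out, F.Probe):
            out = nn.relu(out)
        return out


class RegNetEncoder(Module):
    """Stem (stride 2) + four stages (strides 4/8/16/32) returning a pyramid."""

    def __init__(self, spec: EncoderSpec, in_channels=3, rng=None):
        super().__init__()
        self.spec = spec
        self.stem = ConvBNAct(in_channels, spec.stem_width, k=3, stride=2, rng=rng)
        self.stages = []
        cin = spec.stem_width
        for w, d in zip(spec.widths, spec.depths):
            blocks = [RegNetBlock(cin, w, 2, spec, rng=rng)]
            blocks += [RegNetBlock(w, w, 1, spec, rng=rng) for _ in range(d - 1)]
            self.stages.append(Sequential(*blocks))
            cin = w
        self.out_channels = (spec.stem_width,) + tuple(spec.widths)

    def forward(self, x):
        feats = [self.stem(x)]
        for stage in self.stages:
            feats.append(stage(feats[-1]))
        return feats  # strides 2, 4, 8, 16, 32


class DecodeBlock(Module):
    """Upsample x2, concatenate the skip, two conv3x3-BN-ReLU, SE gate."""

    def __init__(self, cin, skip_ch, cout, se_reduction=16, rng=None):
        super().__init__()
        self.conv1 = ConvBNAct(cin + skip_ch, cout, rng=rng)
        self.conv2 = ConvBNAct(cout, cout, rng=rng)
        self.se = SEBlock(cout, reduction=se_reduction, rng=rng)

    def forward(self, x, skip):
        x = F.upsample_bilinear2x(x)
        if not isinstance(x, F.Probe):
            if (x.shape[2], x.shape[3]) != (skip.shape[2], skip.shape[3]):
                raise ValueError(
                    f"decode_block: upsampled {x.shape[2:]} vs skip {skip.shape[2:]}")
            x = nn.concat([x, skip], axis=1)
        else:
            x = x.spawn((x.shape[0], x.shape[1] + skip.shape[1]) + x.shape[2:])
        return self.se(self.conv2(self.conv1(x)))


class SERegUNet(Module):
    """Full segmentation network with per-pixel softmax output."""

    def __init__(self, config: SegModelConfig, rng=None):
        super().__init__()
        if config.backbone not in ENCODER_SPECS:
            raise ConfigError(f"unsupported backbone {config.backbone!r}; "
                              f"choose from {sorted(ENCODER_SPECS)}")
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        spec = ENCODER_SPECS[config.backbone]
        self.encoder = RegNetEncoder(spec, config.in_channels, rng=rng)
        dch = self.config.resolved_decoder()
        enc_ch = self.encoder.out_channels          # stem, s4, s8, s16, s32
        skips = enc_ch[:-1][::-1]                    # s16, s8, s4, stem
        cin = enc_ch[-1]
        self.decoders = []
        for skip_ch, cout in zip(skips, dch[:4]):
            self.decoders.append(DecodeBlock(cin, skip_ch, cout,
                                             config.se_reduction, rng=rng))
            cin = cout
        self.final_conv = ConvBNAct(cin, dch[4], rng=rng)
        self.head = Conv2d(dch[4], config.num_classes, 1, rng=rng)

    def _check_size(self, h, w):
        if h % 32 or w % 32:
            raise ValueError(
                f"input size {h}x{w} must be divisible by 32 (encoder stride)")

    def forward(self, x):
        if not isinstance(x, F.Probe):
            self._check_size(x.shape[2], x.shape[3])
        feats = self.encoder(x)
        y = feats[-1]
        for dec, skip in zip(self.decoders, feats[:-1][::-1]):
            y = dec(y, skip)
        y = F.upsample_bilinear2x(y)
        y = self.final_conv(y)
        y = self.head(y)
        if isinstance(y, F.Probe):
            return y
        return nn.softmax(y, axis=1)


def _quadrant_pool(x):
    """Average-pool each spatial quadrant and concatenate: (N,C,H,W)->(N,4C).

    Plain global pooling is translation-invariant, which erases the one cue
    that separates left- from right-rooted vascular trees — *where* the tree
    enters the frame. Pooling per quadrant keeps that coarse laterality
    while remaining input-size agnostic.
    """
    if isinstance(x, F.Probe):
        return x.spawn((x.shape[0], 4 * x.shape[1]))
    n, c, h, w = x.shape
    halves_y = (slice(0, (h + 1) // 2), slice(h // 2, h))
    halves_x = (slice(0, (w + 1) // 2), slice(w // 2, w))
    quads = [x[:, :, ys, xs].mean(axis=(2, 3))
             for ys in halves_y for xs in halves_x]
    return nn.concat(quads, axis=1)


class SideClassifier(Module):
    """LCA/RCA classifier: encoder + quadrant average pool + linear -> sigmoid."""

    def __init__(self, config: SegModelConfig, rng=None):
        super().__init__()
        if config.backbone not in ENCODER_SPECS:
            raise ConfigError(f"unsupported backbone {config.backbone!r}")
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        self.encoder = RegNetEncoder(ENCODER_SPECS[config.backbone],
                                     config.in_channels, rng=rng)
        self.fc = Linear(4 * self.encoder.out_channels[-1], 1, rng=rng)

    def forward(self, x):
        feats = self.encoder(x)
        g = _quadrant_pool(feats[-1])
        y = self.fc(g)
        if isinstance(y, F.Probe):
            return y
        return nn.sigmoid(y)


# ---------------------------------------------------------------------------
# public builders (spec surface)
# ---------------------------------------------------------------------------

def build_encoder(config: SegModelConfig, rng=None) -> RegNetEncoder:
    if config.backbone not in ENCODER_SPECS:
        raise ConfigError(f"unsupported backbone {config.backbone!r}")
    rng = rng or np.random.default_rng(config.seed)
    return RegNetEncoder(ENCODER_SPECS[config.backbone], config.in_channels, rng=rng)


def se_block(channels: int, reduction: int = 16, rng=None) -> SEBlock:
    return SEBlock(channels, reduction=reduction, rng=rng)


def decode_block(cin: int, skip_ch: int, cout: int, se_reduction: int = 16,
                 rng=None) -> DecodeBlock:
    return DecodeBlock(cin, skip_ch, cout, se_reduction, rng=rng)


def build_se_regunet(config: SegModelConfig | str, rng=None) -> SERegUNet:
    if isinstance(config, str):
        config = SegModelConfig(backbone=config)
    return SERegUNet(config, rng=rng)


def build_classifier(config: SegModelConfig | str, rng=None) -> SideClassifier:
    if isinstance(config, str):
        config = SegModelConfig(backbone=config)
    return SideClassifier(config, rng=rng)
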