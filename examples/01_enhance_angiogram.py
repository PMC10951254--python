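"""Enhance a low-contrast angiogram with USM + dual CLAHE.

Generates one synthetic angiogram, runs the enhancement pipeline and
reports the vessel/background contrast before and after: the vessel tree
should separate far more strongly from its surroundings in the enhanced
channels, which is exactly what the downstream networks consume.
"""
import numpy as np
from scipy import ndimage

import angioseg as ag

sample = ag.generate_tree(ag.SyntheticSpec(), seed=7)
pre = ag.preprocess_pipeline(sample.image)

mask = sample.mask.astype(bool)
ring = ndimage.binary_dilation(mask, iterations=5) & ~mask
raw = sample.image.pixels.astype(float)
enh = pre.channels.mean(axis=0)

print(f"image {sample.image.pixels.shape}, side={sample.side}, "
      f"vessel fraction {mask.mean():.2%}")
print(f"raw contrast (background ring - vessel): "
      f"{raw[ring].mean() - raw[mask].mean():.1f} gray levels")
print(f"enhanced contrast:                       "
      f"{enh[ring].mean() - enh[mask].mean():.1f} gray levels")
print("channels:", pre.channel_roles)
# A higher enhanced contrast means the vessels are easier to segment;
# the three channels give the model one sharpened and two differently
# contrast-equalized views of the same frame.
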