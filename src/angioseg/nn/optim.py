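"""Optimizers: AdamW and a Ranger21-style composite.

The composite optimizer follows the headline recipe of the Ranger21 family:
AdamW at its core, plus linear learning-rate warm-up, gradient
centralization on multi-axis weights, and a cosine "explore-exploit"
decay over the scheduled run length.
"""
from __future__ import annotations

import math

import numpy as np


class AdamW:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=1e-4):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def _step_lr(self) -> float:
        return self.lr

    def _transform_grad(self, p, g):
        return g

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        lr = self._step_lr()
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = self._transform_grad(p, p.grad)
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Ranger21Style(AdamW):
    """AdamW + linear warm-up + gradient centralization + cosine decay."""

    def __init__(self, params, lr=1e-3, total_steps=1000, warmup_frac=0.22,
                 decay_start_frac=0.72, min_lr_frac=1e-2, **kw):
        super().__init__(params, lr=lr, **kw)
        self.total_steps = max(1, int(total_steps))
        self.warmup_steps = max(1, int(warmup_frac * self.total_steps))
        self.decay_start = int(decay_start_frac * self.total_steps)
        self.min_lr_frac = min_lr_frac

    def _step_lr(self) -> float:
        t = self.t
        if t <= self.warmup_steps:
            return self.lr * t / self.warmup_steps
        if t <= self.decay_start:
            return self.lr
        span = max(1, self.total_steps - self.decay_start)
        frac = min(1.0, (t - self.decay_start) / span)
        cos = 0.5 * (1.0 + math.cos(math.pi * frac))
        return self.lr * (self.min_lr_frac + (1 - self.min_lr_frac) * cos)

    def _transform_grad(self, p, g):
        if g.ndim > 1:  # centralize conv/linear weight gradients
            g = g - g.mean(axis=tuple(range(1, g.ndim)), keepdims=True)
        return g


def build_optimizer(name: str, params, lr: float, total_steps: int,
                    weight_decay: float = 1e-4):
    name = name.lower()
    if name == "adamw":
        return AdamW(params, lr=lr, weight_decay=weight_decay)
    if name == "ranger21_style":
        return Ranger21Style(params, lr=lr, total_steps=total_steps,
                             weight_decay=weight_decay)
    raise ValueError(f"unknown optimizer {name!r}")
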