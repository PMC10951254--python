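"""Static complexity profiling: parameter, MAC and model-size accounting.

The profiler pushes a shape-only probe through the model's own forward
code, so the counted layers are exactly the executed ones. One
multiply-accumulate is counted as one FLOP (the convention under which a
"4GF" backbone performs ~4e9 operations on a classification-sized input).
"""
from __future__ import annotations

from dataclasses import dataclass

from .nn.functional import Probe
from .nn.layers import Module


@dataclass
class ComplexityReport:
    trainable_parameters: int
    flops: float                 # multiply-accumulates for one forward pass
    model_size_mb: float
    input_size: int

    @property
    def parameters_millions(self) -> float:
        return self.trainable_parameters / 1e6

    @property
    def gflops(self) -> float:
        return self.flops / 1e9

    def to_dict(self):
        return {
            "trainable_parameters": self.trainable_parameters,
            "parameters_millions": round(self.parameters_millions, 2),
            "gflops": round(self.gflops, 2),
            "model_size_mb": round(self.model_size_mb, 2),
            "input_size": self.input_size,
        }


def profile_complexity(model: Module, input_size: int = 512,
                       in_channels: int = 3) -> ComplexityReport:
    """Count trainable parameters and forward MACs at ``input_size``."""
    n_params = model.num_parameters()
    probe = Probe((1, in_channels, input_size, input_size))
    out = model(probe)
    if isinstance(out, (list, tuple)):
        out = out[-1]
    if not isinstance(out, Probe):
        raise TypeError("model forward must propagate the probe")
    macs = probe.counter["macs"]
    return ComplexityReport(
        trainable_parameters=n_params,
        flops=float(macs),
        model_size_mb=n_params * 4 / 2 ** 20,
        input_size=input_size,
    )
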