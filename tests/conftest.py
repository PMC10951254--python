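import numpy as np
import pytest

import angioseg as ag


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def synthetic_sample():
    """Standard generator fixture: default spec, fixed seed."""
    return ag.generate_tree(ag.SyntheticSpec(), seed=7)


@pytest.fixture(scope="session")
def tiny_seg_config():
    return ag.SegModelConfig(backbone="tiny_z", input_size=64, seed=0)


def make_training_data(n, size, seed0, spec_kwargs=None):
    """Preprocessed (x, y) pairs from the synthetic generator."""
    spec = ag.SyntheticSpec(size=size, **(spec_kwargs or {}))
    out = []
    for i in range(n):
        s = ag.generate_tree(spec, seed=seed0 + i)
        out.append((ag.model_input(ag.preprocess_pipeline(s.image)), s.mask))
    return out
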