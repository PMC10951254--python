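"""The full inference path: preprocess -> classify side -> segment.

Uses untrained tiny models (so the mask is meaningless) to demonstrate the
routing contract: the classifier picks LCA or RCA and the bundle dispatches
to that side's segmentation model.
"""
import angioseg as ag

cfg = ag.SegModelConfig(backbone="tiny_z", input_size=64, seed=0)
bundle = {
    "classifier": ag.build_classifier(cfg),
    "lca_model": ag.build_se_regunet(ag.SegModelConfig(backbone="tiny_z", seed=1)),
    "rca_model": ag.build_se_regunet(ag.SegModelConfig(backbone="tiny_z", seed=2)),
}

sample = ag.generate_tree(ag.SyntheticSpec(size=64, side="LCA"), seed=3)
result = ag.infer(sample.image, bundle, truth=sample.mask)

print(f"true side {sample.side}; predicted {result.side} "
      f"(P(LCA) = {result.side_prob:.3f})")
print(f"mask shape {result.mask.shape}, vessel pixels {result.mask.sum()}")
print(f"metrics vs ground truth: { {k: round(v, 3) for k, v in result.metrics.items() if v is not None} }")
# With trained weights in the bundle (see example 03 and the CLI), the
# routed model produces the actual vasculature mask at input resolution.
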