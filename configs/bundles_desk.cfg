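# Curvature bundles of the two-scale SBM demo graph.
experiment=bundles
seed=0
n_scales=32
method=sinkhorn
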