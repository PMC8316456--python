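# Full-scale sweep (10^4 nodes, 20 samples per ratio): hours of compute;
# use only when the desk-scale answer needs tightening.
experiment=detectability
seed=42
k_bars=3,5,8,12
n=10000
samples=20
n_scales=20
edge_sample=2000
noise_level=0.035
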