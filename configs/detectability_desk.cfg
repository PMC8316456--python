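# Desk-scale detectability sweep: runs in minutes on one CPU.
experiment=detectability
seed=42
k_bars=5,8
n=2000
samples=5
n_scales=5
edge_sample=150
noise_level=auto
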