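# dynor

Dynamical Ollivier–Ricci curvature and geometric-modularity multiscale
community detection for undirected networks.

Many networks — gene co-expression graphs, connectomes, infrastructure —
organise themselves on several scales at once, and embedding them into a
fixed latent space distorts whatever structure does not fit that space.
`dynor` instead describes a graph through the *similarity of diffusion
processes* seeded at neighbouring nodes.  For an edge `ij` of weight
`w_ij` and the diffusion `p_i(τ) = δ_i e^{−τL}` generated by the
random-walk Laplacian `L = K⁻¹(K − A)`, the dynamic Ollivier–Ricci
curvature

    κ_ij(τ) = 1 − W₁(p_i(τ), p_j(τ)) / w_ij

measures, via the 1-Wasserstein distance `W₁` over the geodesic metric,
how much the two diffusions overlap after time τ.  Curvature starts at 0,
ends at 1 when both diffusions reach stationarity, and in between is
positive across well-connected regions and depressed across bottlenecks,
so *gaps* in the edge-curvature distribution reveal community structure —
robustly down to the Kesten–Stigum detectability threshold
`r_KS = (k̄ − √k̄)/(k̄ + √k̄)` where spectral methods fail.  The same field
powers a null-model-free *geometric modularity*

    Q_κ(C, τ) = (1/2m_κ) Σ_ij (κ_ij(τ) − κ₀) δ(C_i, C_j),

optimised by a signed Louvain scheme at every scale; partitions that stay
stable within and across scales are the network's multiscale communities.

The package is aimed at network scientists and computational biologists
who want curvature fields, mixing-time bounds, detectability analyses or
multiscale clusterings of graphs up to a few thousand nodes on a single
machine.

## Worked example

Two planted blocks of 50 nodes (`p_in = 0.5`, `p_out = 0.1`): compute the
curvature field, locate the scale where the within/between separation
peaks, and read off the gap anatomy.

```python
import numpy as np
import dynor as dy
from dynor.gap import separation_scale

graph, part = dy.generate_ssbm(100, p_in=0.5, p_out=0.1, seed=1)
op = dy.build_operator(graph)
grid = dy.ScaleGrid.for_operator(op, num=40)
field = dy.curvature_field(graph, grid, method="sinkhorn")

profile = dy.curvature_gap(field, part.labels)
sep, tau_k = separation_scale(profile)
ti = int(np.argmin(np.abs(grid.taus - tau_k)))
within = part.labels[field.edges[:, 0]] == part.labels[field.edges[:, 1]]

print(f"characteristic scale  tau_k = {tau_k:.2f}")
print(f"1 / lambda_c          = {1 / dy.lambda_c_mean(0.5, 0.1):.2f}")
print(f"within-edge mean kappa at tau_k = {field.kappa[within, ti].mean():.3f}")
print(f"between-edge mean kappa at tau_k = {field.kappa[~within, ti].mean():.3f}")
print(f"normalised gap at tau_k = {profile.delta_kappa[ti]:.2f}")
```

```
characteristic scale  tau_k = 2.23
1 / lambda_c          = 3.00
within-edge mean kappa at tau_k = 0.735
between-edge mean kappa at tau_k = 0.536
normalised gap at tau_k = 6.29
```

The separation peaks near the inverse community eigenvalue
`1/λ_c = (p_in + p_out)/(2 p_out)`, where within-block diffusion pairs
have locally mixed (`κ ≈ 0.75`, the mixing-bound level) while
between-block pairs lag — a six-sigma separation of the two edge
populations.  Scanning `dy.scale_scan` over the grid and calling
`dy.robust_scales` turns the same field into multiscale partitions; see
`dynor --help` for the command-line interface (`generate`, `curvature`,
`gap`, `scan`, `benchmark`) and `docs/methods.md` for the model,
solver and protocol details.

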