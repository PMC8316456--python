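# Methods

## Model

`dynor` studies an undirected graph through pairs of continuous-time
diffusions.  Edge weights `w_ij` carry distance semantics; a similarity
adjacency `A` (unit on edges for unweighted graphs, or a declared
conversion `max_uv w_uv − w_ij` / `exp(−w_ij)` for weighted ones) defines
the random-walk Laplacian

    L = K^{-1}(K − A),      K_ii = Σ_j A_ij,

whose diffusion `p_i(τ) = δ_i e^{−τL}` conserves mass and converges to the
degree-proportional stationary state `π`.  The dynamic Ollivier–Ricci
curvature of an edge compares the two diffusions seeded at its endpoints
by optimal transport over the geodesic (shortest-path) metric `d`:

    κ_ij(τ) = 1 − W1(p_i(τ), p_j(τ)) / w_ij .

`κ → 0` as `τ → 0` (point masses one edge length apart) and `κ → 1` as
both measures reach `π`.  In between, `κ` is positive in clique-like,
near-zero in grid-like and negative in tree-like neighbourhoods, so the
*distribution* of `κ` across edges at a scale τ is a geometric fingerprint
of the structure visible at that scale.

Three derived analyses are built on the field `κ_ij(τ)`:

1. **Mixing bound.**  The first scale with `κ_ij ≥ 0.75` upper-bounds the
   ε-mixing time of the coupled pair (ε′ = d0·ε with ε = 1/4, the middle
   of the range guaranteeing exponential convergence).  `mixing_bound` and
   `empirical_mixing` verify the two sides of this inequality on a grid.
2. **Curvature gap.**  For a two-block partition,
   `Δκ(τ) = |⟨κ⟩_within − ⟨κ⟩_between| / σ` with
   `σ = sqrt((σ²_within + σ²_between)/2)` (population standard
   deviations), a sensitivity index for detecting planted structure; its
   maximum over scales is compared against a background noise level, and
   for the symmetric SBM the resulting critical edge-density ratio tracks
   the Kesten–Stigum threshold `r_KS = (k̄ − √k̄)/(k̄ + √k̄)`.
3. **Geometric modularity.**
   `Q_κ(C, τ) = (1/2m_κ) Σ_edges (κ_ij(τ) − κ0) δ(C_i, C_j)` with
   `2m_κ = Σ|κ_ij|` and `κ0 = max_ij κ_ij(τ_min)`, optimised by a signed
   Louvain scheme; scanning τ and keeping partitions that are stable
   within and across scales yields the multiscale community structure
   without a statistical null model.

## Normalised vs raw gap, and the characteristic scale

In exact arithmetic the normalised gap does **not** vanish as `τ → ∞`:
both the mean within/between difference and the pooled dispersion decay
with the same slowest eigenmode `e^{−λ_c τ}`, so their ratio saturates at
a positive spectral constant.  Two consequences are built into the API:

* `gap.separation_scale` returns the argmax of the *raw* separation
  `|⟨κ⟩_w − ⟨κ⟩_b|`, which does vanish in both limits and peaks near
  `1/λ_c`; this is the characteristic community scale, and the mean
  within-edge curvature there is ≈ 0.75, tying the gap anatomy to the
  mixing bound.  (`⟨λ_c⟩ = 2 p_out/(p_in + p_out)` for the symmetric SBM
  ensemble.)
* `gap.curvature_gap` marks scales whose pooled dispersion falls below
  `sigma_floor` (default 1e-3, the order of the transport solver's
  accuracy) as undefined: once the curvature distribution has collapsed to
  a point at solver resolution the standardised ratio is 0/0 noise.  Pass
  `sigma_floor=0` with exact-LP curvature to keep every scale.

## Transport solvers

* **Exact (`lp`).**  Per edge, the problem is first reduced by
  transporting only the positive part of `p_i − p_j` onto its negative
  part — optimal whenever the cost is a metric, because common mass can
  stay in place — and the rectangular LP is solved with HiGHS.  The
  reduction shrinks supports by orders of magnitude at small scales and
  is exact up to `rel_trim` (fraction of *moved* mass allowed to be
  dropped, error ≤ `rel_trim · μ · d_max`).
* **Entropic (`sinkhorn`).**  Plain matrix scaling reporting the plan cost
  `⟨ζ, d⟩`.  Default regularisation `0.025 · median(d)`: measured curvature
  error against the LP is a few 1e-4 to 1e-3 on the SBM test graphs, well
  below the 0.01 documented accuracy contract.  Iterations stop when the
  worst marginal violation passes `tol` or when no pair's cost moves by
  more than `cost_tol = 1e-5` per check interval — the cost settles long
  before the marginals at small regularisation.  Graphs of ≤ 600 nodes
  run all edges of a scale in one shared-kernel batch warm-started across
  scales (the first scale is annealed from a large regularisation);
  larger graphs fall back to per-edge reduced problems.  Pairs already
  mixed to total variation ≤ 1e-6/d_max are priced by the metric bounds
  `d0·TV ≤ W1 ≤ d_max·TV`.
* **Ensemble budgets.**  Detectability sweeps additionally cap each side's
  reduced support at the `max_support` heaviest entries (default 300 in
  `critical_ratio_sweep`).  This biases individual curvatures but the bias
  is largely shared by within- and between-edges, and every sweep decision
  is made against a noise level calibrated with the identical protocol, so
  the detection contrast is preserved at a fraction of the cost.

## Scale grid

`ScaleGrid.for_operator` places `num` logarithmic points on
`[0.1/λ_max, 10/λ_2]` (estimated from the symmetrised operator), so the
curvature traverses its full dynamical range 0 → 1; `τ = 0` is excluded
(curvature is 0 there by the limit).  Every experiment states its `num`:
40 for the dense-SBM gap anatomy, 48 for the multiscale scan (the
four-block window spans only ~0.2 decades and needs ~14 points per
decade to register as a plateau), 5–7 for the large sparse ensembles.
These are desk-scale protocol choices, declared per experiment and fully
overridable.

## Clustering details

The signed Louvain maximises `Σ B_ij δ(C_i, C_j)` (no null-model term):
shuffled sweep order per run, first-improvement moves, ties kept with the
current community, aggregation summing signed weights, repeated until no
move improves.  `κ0` is computed once at the smallest grid scale, making
all edge gains non-positive there, so the scan starts from singletons and
ends (connected graphs) in one community; both end states are filtered
from the robust-scale report by default.  A robust plateau is a run of at
least `plateau_len = 3` consecutive scales with `vi_tau ≤ 0.05·ln n` and
consecutive-scale VI under the same tolerance, represented by its
highest-Q partition; `vi_tau` compares the best partition against
`n_vi` randomly chosen partitions from the Louvain run pool.

## Synthetic generators and what they do not cover

The generators produce Bernoulli SBM/ER ensembles with independent edges:
the two-block symmetric SBM (dense `p_in = 0.5, p_out = 0.1` and sparse
`p_in + p_out = 2k̄/n` regimes), the four-block two-scale SBM (sizes
30/40/35/50, within 0.7/0.8/0.9/0.6, between 0.1 within a superblock pair
and 0.02 across — the pairing is configurable), ER controls at
`p = (8+0.5)/(2n)`, and deterministic canonical graphs (cycles, cliques,
trees, grids, barbells).  Sparse ensembles at constant mean degree almost
surely contain isolated vertices; ensemble experiments therefore operate
on the largest connected component, keeping the matching planted labels.
Passing tests on these ensembles demonstrate the method's behaviour under
its own model assumptions — independent edges, homogeneous blocks, no
degree correction, no overlapping communities — and say nothing about
weighted real-world graphs beyond the Jaccard-similarity pathway, which
is exercised only structurally.

## Finite-size effects the tests account for

* The ER-control gap statistic grows as the edge count shrinks (its
  per-scale sampling scale is `~sqrt(1/m_w + 1/m_b)`), so the background
  noise level of a sweep is calibrated from matched ER-limit draws rather
  than fixed at the printed 0.035, which corresponds to much larger
  ensembles.
* Estimating the ER gap from a *subsample* of edges breaks the
  cancellation of node-level curvature fluctuations between the two edge
  classes and inflates the statistic roughly tenfold; the ER control is
  therefore always computed on all edges.
* Eigenvector correlations with planted labels at the KS threshold vanish
  only asymptotically; at n = 2000 the transition is smeared (mean |corr|
  ≈ 0.2 at `r = r_KS`), so the collapse is demonstrated at a ratio
  clearly beyond the threshold.

## Numerical conventions

Eigenvectors of `L` are computed through the symmetric similarity
transform `K^{1/2} L K^{-1/2}`, returned in the right-eigenvector
convention, unit norm, sign fixed so the largest-magnitude entry is
positive; `|Δφ_s| = |Σ_{(u,v)∈E, u<v} φ_s(u) − φ_s(v)|` uses the stored
`u < v` edge orientation.  Diffusion steps through the grid use the
action of the operator exponential (`expm_multiply`) with the semigroup
property, never a dense exponential; measures are clipped at zero and
renormalised each step (round-off only).  Degenerate inputs: disconnected
graphs are rejected by every diffusion-dependent operation with a
dedicated error; trimming that would empty a measure raises; a constant
eigenvector has zero label correlation by convention.

## Known limitations

Exact LP curvature on all edges is only practical up to a few hundred
nodes per scale; beyond that the entropic path with the documented
approximations is the default.  The plateau-selection defaults
(`vi_tol`, `plateau_len`) are declared choices, not derived quantities.
Directed graphs, multigraphs, overlapping communities and W_p for p ≠ 1
are out of scope.
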