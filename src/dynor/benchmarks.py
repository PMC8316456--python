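"""Scripted desk-scale experiments built entirely from the generators.

Three experiments are provided:

* ``bundles`` — curvature trajectories of the two-scale four-block SBM,
  grouped by edge class (within-block, strong between, weak between);
* ``detectability`` — ensemble sweep of the maximal curvature gap against
  the edge-density ratio, compared with the Kesten-Stigum limit;
* ``eigenvectors`` — the coherent-difference statistic |Delta phi_s| as an
  eigenvector-quality measure for sparse planted partitions.

Each takes an :class:`ExperimentConfig` and returns plain tables; the CLI
writes them with a manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .cluster import canonical_labels, partition_agreement
from .curvature import curvature_field
from .diffusion import ScaleGrid, build_operator, delta_phi, label_correlation, spectral
from .gap import critical_ratio_sweep, ks_threshold
from .graphs import generate_multiscale_sbm, generate_ssbm

__all__ = [
    "ExperimentConfig",
    "run_bundle_experiment",
    "run_detectability_experiment",
    "run_eigenvector_experiment",
    "EXPERIMENTS",
]


@dataclass
class ExperimentConfig:
    """Flat, fully serialisable experiment description."""

    experiment: str
    seed: int = 0
    params: dict = dfield(default_factory=dict)

    def get(self, key, default=None):
        return self.params.get(key, default)

    def to_text(self) -> str:
        lines = [f"experiment={self.experiment}", f"seed={self.seed}"]
        lines += [f"{k}={v}" for k, v in sorted(self.params.items())]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ExperimentConfig":
        params = {}
        experiment, seed = None, 0
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line (expected key=value): {line!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key == "experiment":
                experiment = val
            elif key == "seed":
                seed = int(val)
            else:
                params[key] = _parse_value(val)
        if experiment is None:
            raise ValueError("config is missing the 'experiment' key")
        return cls(experiment=experiment, seed=seed, params=params)

    def digest(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


def _parse_value(val: str):
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    if "," in val:
        return [_parse_value(v) for v in val.split(",")]
    return val


def _kmeans_1d(x, k=3, n_iter=100):
    """Plain 1-D k-means with quantile initialisation."""
    x = np.asarray(x, dtype=float)
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    for _ in range(n_iter):
        assign = np.abs(x[:, None] - centers[None, :]).argmin(axis=1)
        new = np.array([x[assign == j].mean() if np.any(assign == j) else centers[j]
                        for j in range(k)])
        if np.allclose(new, centers):
            break
        centers = new
    return assign, centers


def multiscale_edge_classes(graph, fine, coarse):
    """0 = within-block, 1 = strong between (same superblock), 2 = weak between."""
    lf = fine.labels
    lc = coarse.labels
    u, v = graph.edges[:, 0], graph.edges[:, 1]
    classes = np.full(graph.n_edges, 2)
    classes[lc[u] == lc[v]] = 1
    classes[lf[u] == lf[v]] = 0
    return classes


def run_bundle_experiment(config: ExperimentConfig):
    """Curvature bundles of the two-scale SBM.

    Returns a dict with the per-class mean trajectories, the scale of
    maximal class spread, and the agreement of an unsupervised 1-D
    3-clustering of edge curvatures with the edge classes at that scale.
    """
    graph, fine, coarse = generate_multiscale_sbm(seed=config.seed)
    grid = _grid_from_config(config, graph, default_num=int(config.get("n_scales", 40)))
    field = curvature_field(graph, grid, method=config.get("method", "sinkhorn"),
                            trim_cutoff=float(config.get("trim_cutoff", 0.0)))
    classes = multiscale_edge_classes(graph, fine, coarse)
    means = np.stack([field.kappa[classes == c].mean(axis=0) for c in range(3)])
    spread = means.max(axis=0) - means.min(axis=0)
    t_star = int(np.argmax(spread))
    assign, _ = _kmeans_1d(field.kappa[:, t_star], k=3)
    agreement = partition_agreement(assign, classes)
    traj = pd.DataFrame({
        "tau": grid.taus,
        "mean_within": means[0],
        "mean_strong_between": means[1],
        "mean_weak_between": means[2],
        "spread": spread,
    })
    return {
        "field": field,
        "edge_classes": classes,
        "trajectories": traj,
        "tau_max_spread": float(grid.taus[t_star]),
        "bundle_agreement": float(agreement),
    }


def run_detectability_experiment(config: ExperimentConfig):
    """Critical-ratio sweep per mean degree; phase table (k_bar, r_star, r_ks)."""
    k_bars = config.get("k_bars", [5, 8])
    if np.isscalar(k_bars):
        k_bars = [k_bars]
    r_grid = config.get("r_grid")
    sweeps, rows = {}, []
    for i, k_bar in enumerate(k_bars):
        rg = np.asarray(r_grid, dtype=float) if r_grid is not None else \
            np.linspace(0.1, min(0.95, ks_threshold(k_bar) + 0.3), 8)
        noise = config.get("noise_level", "auto")
        res = critical_ratio_sweep(
            k_bar, rg,
            n=int(config.get("n", 2000)),
            samples=int(config.get("samples", 5)),
            noise_level=noise if noise == "auto" else float(noise),
            seed=config.seed + i,
            n_scales=int(config.get("n_scales", 20)),
            edge_sample=int(config.get("edge_sample", 400)),
            max_iter=int(config.get("max_iter", 400)),
            max_support=int(config.get("max_support", 300)),
        )
        sweeps[k_bar] = res
        rows.append({"k_bar": k_bar, "r_star": res.r_star, "r_ks": res.r_ks})
    return {"sweeps": sweeps, "phase_table": pd.DataFrame(rows)}


def run_eigenvector_experiment(config: ExperimentConfig):
    """Per-seed correlations with the planted labels of: the max-|Delta phi|
    eigenvector, the Fiedler-style phi_2, and the best of all computed
    eigenvectors."""
    n = int(config.get("n", 2000))
    p_in = float(config.get("p_in", 8.0 / n))
    p_out = float(config.get("p_out", 0.5 / n))
    n_seeds = int(config.get("n_seeds", 20))
    n_modes = int(config.get("n_modes", 50))
    rows = []
    for s in range(n_seeds):
        graph, part = generate_ssbm(n, p_in, p_out, seed=config.seed + s)
        sub, keep = graph.largest_component()
        labels = part.labels[keep]
        op = build_operator(sub)
        basis = spectral(op, k=min(n_modes, sub.n_nodes - 1))
        dphi = delta_phi(basis, sub)
        dphi[0] = 0.0  # constant eigenvector carries no signal
        s_star = int(np.argmax(dphi[1:]) + 1)
        corrs = np.array([label_correlation(basis.phis[:, j], labels)
                          for j in range(1, basis.phis.shape[1])])
        rows.append({
            "seed": s,
            "s_max_delta_phi": s_star,
            "corr_delta_phi": label_correlation(basis.phis[:, s_star], labels),
            "corr_phi2": label_correlation(basis.phis[:, 1], labels),
            "corr_best": float(corrs.max()),
        })
    return {"table": pd.DataFrame(rows)}


def _grid_from_config(config, graph, default_num=40):
    tau_min = config.get("tau_min")
    tau_max = config.get("tau_max")
    num = int(config.get("n_scales", default_num))
    if tau_min is not None and tau_max is not None:
        return ScaleGrid.logspace(float(tau_min), float(tau_max), num)
    return ScaleGrid.for_operator(build_operator(graph), num=num)


EXPERIMENTS = {
    "bundles": run_bundle_experiment,
    "detectability": run_detectability_experiment,
    "eigenvectors": run_eigenvector_experiment,
}


def write_manifest(path, command, config: ExperimentConfig, outputs, inputs=()):
    """Atomically write a JSON manifest sufficient to re-run the command."""
    import datetime
    import os
    import tempfile

    payload = {
        "command": command,
        "config_hash": config.digest(),
        "seed": config.seed,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "inputs": {str(p): _file_digest(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
    }
    fd, tmp = tempfile.mkstemp(dir=os.path.dirname(os.path.abspath(path)))
    with os.fdopen(fd, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
    os.replace(tmp, path)


def _file_digest(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]
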