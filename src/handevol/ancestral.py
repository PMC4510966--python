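"""ML ancestral-state reconstruction under Brownian motion.

Point estimates are the GLS/ML estimates, which for BM coincide with
branch-length-weighted squared-change parsimony (each internal node is
the 1/branch-length weighted average of its neighbours).  Estimate
variances follow the GLS prediction-variance formulation with the
phylogenetic mean estimated, scaled by the ML Brownian rate; 95%
confidence intervals are estimate +/- 1.96 * sqrt(variance).

The phylomorphospace places these reconstructions at the internal nodes
of a PCA morphospace, with tree branches as edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .evo_models import _as_tip_vector
from .tree import PhyloTree

Z95 = 1.959963984540054  # two-sided 95% normal quantile

__all__ = [
    "AncestralReconstruction",
    "Phylomorphospace",
    "ml_ancestral_states",
    "ancestral_ci",
    "build_phylomorphospace",
]


@dataclass
class AncestralReconstruction:
    """Per-node trait estimates with variances and 95% CIs.

    Tips carry their observed values with variance zero; internal nodes
    carry the ML estimate under BM with rate ``sigma2``.
    """

    tree: PhyloTree
    estimates: dict[int, float]
    variances: dict[int, float]
    sigma2: float
    ci_low: dict[int, float] = field(default_factory=dict)
    ci_high: dict[int, float] = field(default_factory=dict)

    def estimate(self, node: int) -> float:
        return self.estimates[node]

    def ci(self, node: int) -> tuple[float, float]:
        return self.ci_low[node], self.ci_high[node]


def _node_tip_shared_depths(tree: PhyloTree, node: int) -> np.ndarray:
    """Shared root-ward path length between ``node`` and every tip.

    Geometry only — cached on the tree so repeated reconstructions
    (e.g. coverage simulations) pay the path walks once.
    """
    cache = tree._cache.setdefault("node_tip_shared", {})
    if node not in cache:
        d = tree.depths()
        anc_node = set(tree.ancestors(node) + [node])
        out = np.empty(tree.n_tips)
        for k, t in enumerate(tree.tips):
            anc_tip = set(tree.ancestors(t) + [t])
            out[k] = max(d[i] for i in anc_node & anc_tip)
        cache[node] = out
    return cache[node]


def ml_ancestral_states(
    tree: PhyloTree, x, sigma2: float | None = None
) -> AncestralReconstruction:
    """ML (= weighted squared-change parsimony) ancestral states under BM.

    If ``sigma2`` is not given, the ML Brownian rate fitted to the tip
    data is plugged into the variances.  Variance at node a:

        var = sigma^2 * [C_aa - c_a' C^-1 c_a
                         + (1 - 1' C^-1 c_a)^2 / (1' C^-1 1)]

    where C is the tip BM covariance and c_a the node-to-tip shared
    path lengths; the trailing term propagates the uncertainty of the
    estimated phylogenetic mean.
    """
    xv = _as_tip_vector(tree, x)
    if tree.n_tips < 2:
        raise ValueError("ancestral reconstruction needs at least 2 tips")
    C = tree.shared_depth_matrix()
    try:
        cho = linalg.cho_factor(C, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular tip covariance (zero-length branch?): {exc}"
        ) from exc
    one = np.ones(tree.n_tips)
    Ci1 = linalg.cho_solve(cho, one, check_finite=False)
    Cix = linalg.cho_solve(cho, xv, check_finite=False)
    denom = float(one @ Ci1)
    mu = float(one @ Cix) / denom
    r = xv - mu
    Cir = linalg.cho_solve(cho, r, check_finite=False)
    if sigma2 is None:  # ML Brownian rate (GLS residual quadratic form / n)
        sigma2 = float(r @ Cir) / tree.n_tips
    d = tree.depths()
    tipset = set(tree.tips)
    estimates: dict[int, float] = {}
    variances: dict[int, float] = {}
    for k, t in enumerate(tree.tips):
        estimates[t] = float(xv[k])
        variances[t] = 0.0
    for node in tree.preorder():
        if node in tipset:
            continue
        c_a = _node_tip_shared_depths(tree, node)
        Cic = linalg.cho_solve(cho, c_a, check_finite=False)
        estimates[node] = mu + float(c_a @ Cir)
        var = d[node] - float(c_a @ Cic) + (1.0 - float(one @ Cic)) ** 2 / denom
        variances[node] = sigma2 * max(var, 0.0)
    recon = AncestralReconstruction(tree, estimates, variances, float(sigma2))
    return ancestral_ci(recon)


def ancestral_ci(recon: AncestralReconstruction) -> AncestralReconstruction:
    """Attach 95% CIs: estimate +/- 1.96 * sqrt(variance)."""
    for node, var in recon.variances.items():
        if var < 0:
            raise ValueError(f"negative variance {var} at node {node}")
        half = Z95 * np.sqrt(var)
        est = recon.estimates[node]
        recon.ci_low[node] = est - half
        recon.ci_high[node] = est + half
    return recon


@dataclass
class Phylomorphospace:
    """Tree projected into the first two PC axes of a morphospace."""

    tree: PhyloTree
    nodes: pd.DataFrame  # node_id, label, is_tip, pc1, pc2, CI columns
    edges: pd.DataFrame  # parent_id, child_id
    reconstructions: dict[str, AncestralReconstruction]

    def lca(self, tip_a: str, tip_b: str) -> pd.Series:
        """Coordinates (with CIs) of the LCA of two tips, e.g. Pan–Homo."""
        node = self.tree.mrca([tip_a, tip_b])
        return self.nodes.set_index("node_id").loc[node]


def build_phylomorphospace(tree: PhyloTree, scores: pd.DataFrame) -> Phylomorphospace:
    """Project a tree through a morphospace given tip PC scores.

    ``scores`` is indexed by tip label with at least two columns (the
    first two are used as PC1/PC2).  Internal-node coordinates are the
    ML ancestral states of each axis; edges mirror the tree's branches.
    """
    missing = [l for l in tree.tip_labels if l not in scores.index]
    if missing:
        raise KeyError(f"PC scores missing for tips: {missing}")
    axes = list(scores.columns[:2])
    if len(axes) < 2:
        raise ValueError("scores must provide at least two PC axes")
    recons = {ax: ml_ancestral_states(tree, scores[ax]) for ax in axes}
    rows = []
    tipset = set(tree.tips)
    for node in tree.preorder():
        row = {
            "node_id": node,
            "label": tree.labels.get(node, ""),
            "is_tip": node in tipset,
        }
        for out_name, ax in zip(("pc1", "pc2"), axes):
            r = recons[ax]
            row[out_name] = r.estimates[node]
            row[f"{out_name}_ci_low"] = r.ci_low[node]
            row[f"{out_name}_ci_high"] = r.ci_high[node]
        rows.append(row)
    nodes = pd.DataFrame(rows)
    edges = pd.DataFrame(
        [(int(tree.parent[b]), b) for b in tree.branches()],
        columns=["parent_id", "child_id"],
    )
    return Phylomorphospace(tree, nodes, edges, recons)
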