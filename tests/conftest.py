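"""Shared fixtures and independent oracle implementations.

The oracles deliberately avoid the package's vectorized code paths:
covariances are built per tip pair by walking node paths, Hansen means
by hand-integrating each path segment, and ancestral states by solving
the squared-change-parsimony linear system node by node.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from handevol.tree import PhyloTree, RegimePainting
from handevol.synthetic import sim_tree


# ---------------------------------------------------------------------------
# tree fixtures


@pytest.fixture
def three_tip():
    from handevol import read_newick

    return read_newick("((A:1,B:1):1,C:2);")


def star_tree(n: int, branch: float = 1.0) -> PhyloTree:
    parent = [-1] + [0] * n
    blen = [np.nan] + [branch] * n
    labels = {i + 1: f"t{i + 1}" for i in range(n)}
    return PhyloTree(parent, blen, labels)


def random_ou_fixture(seed: int, n_tips: int = 8, n_regimes: int = 2):
    """Random tree + painting + parameters + data for oracle checks."""
    rng = np.random.default_rng(seed)
    tree = sim_tree(n_tips, float(rng.uniform(2.0, 8.0)), seed=seed + 1)
    branches = tree.branches()
    shift_branches = rng.choice(
        [b for b in branches if tree.children[b]] or branches,
        size=min(n_regimes - 1, len(branches)),
        replace=False,
    )
    branch_regime = {}
    order = tree.preorder()
    labels = {int(b): f"r{k + 1}" for k, b in enumerate(shift_branches)}
    for node in order:
        if node == tree.root:
            continue
        if node in labels:
            branch_regime[node] = labels[node]
        else:
            branch_regime[node] = branch_regime.get(int(tree.parent[node]), "bg")
    painting = RegimePainting(tree, branch_regime, "bg")
    alpha = float(rng.uniform(0.2, 3.0))
    sigma2 = float(rng.uniform(0.3, 2.0))
    theta = {lab: float(rng.normal(0, 2)) for lab in painting.labels}
    x = rng.normal(0, 1, tree.n_tips)
    return tree, painting, alpha, sigma2, theta, x


# ---------------------------------------------------------------------------
# oracles


def node_path(tree: PhyloTree, node: int) -> list[int]:
    return tree.ancestors(node) + [node]


def pairwise_mrca_depth(tree: PhyloTree, a: int, b: int) -> float:
    """Shared path length of two nodes by explicit path comparison."""
    pa, pb = node_path(tree, a), node_path(tree, b)
    d = tree.depths()
    shared = [n for n in pa if n in pb]
    return max(d[n] for n in shared)


def bm_cov_oracle(tree: PhyloTree) -> np.ndarray:
    tips = tree.tips
    n = len(tips)
    C = np.empty((n, n))
    d = tree.depths()
    for i in range(n):
        for j in range(n):
            C[i, j] = d[tips[i]] if i == j else pairwise_mrca_depth(
                tree, tips[i], tips[j]
            )
    return C


def ou_cov_oracle(tree: PhyloTree, alpha: float, sigma2: float) -> np.ndarray:
    tips = tree.tips
    d = tree.depths()
    n = len(tips)
    V = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            s = d[tips[i]] if i == j else pairwise_mrca_depth(tree, tips[i], tips[j])
            Ti, Tj = d[tips[i]], d[tips[j]]
            V[i, j] = (
                sigma2
                / (2 * alpha)
                * math.exp(-alpha * (Ti + Tj - 2 * s))
                * (1 - math.exp(-2 * alpha * s))
            )
    return V


def hansen_mean_oracle(
    tree: PhyloTree, painting: RegimePainting, alpha: float, theta: dict
) -> np.ndarray:
    """Per-tip expected value by per-segment exponential integration."""
    d = tree.depths()
    means = []
    for t in tree.tips:
        T = d[t]
        total = theta[painting.root_label] * math.exp(-alpha * T)
        path = node_path(tree, t)[1:]  # branches below the root
        for b in path:
            t0, t1 = d[int(tree.parent[b])], d[b]
            w = math.exp(-alpha * (T - t1)) - math.exp(-alpha * (T - t0))
            total += theta[painting.branch_regime[b]] * w
        means.append(total)
    return np.array(means)


def scp_states_oracle(tree: PhyloTree, x: np.ndarray) -> dict[int, float]:
    """Squared-change parsimony: minimize sum (dx)^2 / branch length.

    Solves the harmonic system in which every internal node is the
    1/branch-length weighted average of its neighbours.
    """
    tips = tree.tips
    internal = [n for n in range(tree.n_nodes) if tree.children[n]]
    idx = {n: k for k, n in enumerate(internal)}
    tipval = {t: x[k] for k, t in enumerate(tips)}
    A = np.zeros((len(internal), len(internal)))
    rhs = np.zeros(len(internal))
    for n in internal:
        k = idx[n]
        neighbours = list(tree.children[n])
        if n != tree.root:
            neighbours.append(int(tree.parent[n]))
        for m in neighbours:
            b = tree.blen[m] if m in tree.children[n] else tree.blen[n]
            w = 1.0 / b
            A[k, k] += w
            if m in idx:
                A[k, idx[m]] -= w
            else:
                rhs[k] += w * tipval[m]
    sol = np.linalg.solve(A, rhs)
    return {n: float(sol[idx[n]]) for n in internal}
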