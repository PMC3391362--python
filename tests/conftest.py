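"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own code paths: the
Brownian covariance matrix is built by walking the tree directly, the GLS
estimates come from explicit matrix algebra, and projected areas are
recounted with plain loops.
"""

from __future__ import annotations

import numpy as np
import pytest

from cenarea.phylo_contrasts import PhyloNode, PhyloTree, load_grass_tree
from cenarea.karyo_model import load_table1


@pytest.fixture(scope="session")
def grass_tree() -> PhyloTree:
    return load_grass_tree()


@pytest.fixture(scope="session")
def table1_panel():
    return load_table1()


# ---------------------------------------------------------------------------
# Phylogenetic oracles (matrix route, independent of the pruning recursion)
# ---------------------------------------------------------------------------

def brownian_cov(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """V[i, j] = shared path length from the root for tips i, j."""
    tips = tree.tip_names
    idx = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))

    def walk(node: PhyloNode, depth: float) -> list[int]:
        d = depth + (node.branch_length or 0.0)
        if node.is_leaf:
            V[idx[node.name], idx[node.name]] = d
            return [idx[node.name]]
        groups = [walk(c, d) for c in node.children]
        for gi, g in enumerate(groups):
            for gj in range(gi + 1, len(groups)):
                for i in g:
                    for j in groups[gj]:
                        V[i, j] = V[j, i] = d
        return [i for g in groups for i in g]

    walk(tree.root, 0.0)
    return tips, V


def gls_slope(V: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    """Generalized least-squares slope of y on x under covariance V."""
    Vi = np.linalg.inv(V)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return float(beta[1])


def gls_root_estimate(V: np.ndarray, x: np.ndarray) -> float:
    """Minimum-variance estimate of the root state under covariance V."""
    Vi = np.linalg.inv(V)
    one = np.ones_like(x)
    return float((one @ Vi @ x) / (one @ Vi @ one))


def random_bifurcating_tree(
    n_tips: int, rng: np.random.Generator
) -> PhyloTree:
    """Random topology by successive joins; branch lengths U(0.05, 1)."""
    nodes = [
        PhyloNode(name=f"t{i}", branch_length=float(rng.uniform(0.05, 1.0)))
        for i in range(n_tips)
    ]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = PhyloNode(
            branch_length=float(rng.uniform(0.05, 1.0)), children=[a, b]
        )
        nodes.append(parent)
    nodes[0].branch_length = None
    return PhyloTree(root=nodes[0])


# ---------------------------------------------------------------------------
# Imaging oracle
# ---------------------------------------------------------------------------

def brute_force_projected_area(volume: np.ndarray, background_max: int) -> int:
    """Loop-based recount of projected pixels brighter than the background."""
    nz, ny, nx = volume.shape
    count = 0
    for y in range(ny):
        for x in range(nx):
            m = 0
            for z in range(nz):
                if volume[z, y, x] > m:
                    m = volume[z, y, x]
            if m > background_max:
                count += 1
    return count
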