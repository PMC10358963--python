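"""Shared fixtures and independent oracles for the test suite.

The oracle helpers here deliberately avoid the package's own covariance /
K code paths: they parse Newick with dendropy directly and walk parent
chains, so agreement between oracle and implementation is informative.
"""
from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd
import pytest


def oracle_vcv(newick: str) -> tuple[list[str], np.ndarray]:
    """Phylogenetic covariance by explicit per-pair MRCA path sums."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]

    def ancestors(node):
        chain = []
        depth = {}
        d = 0.0
        cur = node
        while cur is not None:
            chain.append(cur)
            cur = cur.parent_node
        # depth from root, walking the chain backwards
        total = 0.0
        for nd in reversed(chain):
            if nd.parent_node is not None:
                total += nd.edge.length or 0.0
            depth[id(nd)] = total
        return chain, depth

    n = len(leaves)
    C = np.zeros((n, n))
    chains = [ancestors(l) for l in leaves]
    for i in range(n):
        chain_i, depth_i = chains[i]
        C[i, i] = depth_i[id(leaves[i])]
        ids_i = {id(nd) for nd in chain_i}
        for j in range(i + 1, n):
            chain_j, depth_j = chains[j]
            mrca = next(nd for nd in chain_j if id(nd) in ids_i)
            C[i, j] = C[j, i] = depth_j[id(mrca)]
    return labels, C


def oracle_patristic(newick: str) -> pd.DataFrame:
    """All-pairs tip path lengths from the explicit covariance oracle."""
    labels, C = oracle_vcv(newick)
    d = np.diag(C)
    D = d[:, None] + d[None, :] - 2 * C
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=labels, columns=labels)


def oracle_blomberg_k(C: np.ndarray, x: np.ndarray) -> float:
    """Brute-force GLS K: explicit solve, formula applied term by term."""
    n = len(x)
    ones = np.ones(n)
    Cinv = np.linalg.inv(C)
    a = (ones @ Cinv @ x) / (ones @ Cinv @ ones)
    d = x - a * ones
    mse0 = (d @ d) / (n - 1)
    mse = (d @ Cinv @ d) / (n - 1)
    expected = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)
    return (mse0 / mse) / expected


@pytest.fixture
def five_tip_newick() -> str:
    return "((A:1,B:1):1,(C:1,D:1):1,E:2);"


@pytest.fixture
def small_community():
    """A reduced synthetic community reused by pipeline-level tests."""
    from endotraits import CommunitySpec, simulate_community

    return simulate_community(CommunitySpec(
        n_leaves=4, isolates_per_leaf_method=5, n_resources=30,
        slow_width_mean=12.0, slow_width_sd=8.0,
        fast_width_mean=24.0, fast_width_sd=4.0, seed=11,
    ))
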