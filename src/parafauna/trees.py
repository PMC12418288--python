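"""Host phylogeny handling: ultrametrization, polytomy resolution, cophenetic
distances and the phylogenetic covariance matrix.

Trees are :class:`dendropy.Tree` objects throughout; tip labels are taxon
labels and must be unique.
"""
from __future__ import annotations

import random

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "tip_depths",
    "is_ultrametric",
    "ultrametrize_extend",
    "resolve_polytomies",
    "cophenetic_matrix",
    "phylo_vcv",
    "read_newick",
    "write_newick",
]


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def _edge_len(edge) -> float:
    return edge.length if edge.length is not None else 0.0


def tip_depths(tree: dendropy.Tree) -> pd.Series:
    """Root-to-tip path length for every leaf, indexed by taxon label."""
    depths = {}
    for leaf in tree.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += _edge_len(node.edge)
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return pd.Series(depths, name="depth")


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-9) -> bool:
    d = tip_depths(tree)
    return bool(d.max() - d.min() <= tol * max(1.0, d.max()))


def ultrametrize_extend(tree: dendropy.Tree) -> dendropy.Tree:
    """Extend each terminal branch so all tips reach the maximum tip depth.

    Topology and internal branch lengths are untouched; only pendant edges
    grow, each by (max depth - its tip's depth).
    """
    if tree.seed_node is None or len(tree.seed_node.child_nodes()) == 0:
        raise ValueError("tree must be rooted and non-trivial")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("branch lengths must be nonnegative")
    out = tree.clone(depth=1)
    depths = tip_depths(out)
    target = float(depths.max())
    for leaf in out.leaf_node_iter():
        deficit = target - depths[leaf.taxon.label]
        if deficit > 0:
            leaf.edge.length = _edge_len(leaf.edge) + deficit
    return out


def resolve_polytomies(tree: dendropy.Tree, seed: int = 0) -> dendropy.Tree:
    """Randomly resolve multifurcations into bifurcations with zero-length
    inserted edges, leaving all cophenetic distances unchanged."""
    out = tree.clone(depth=1)
    out.resolve_polytomies(limit=2, update_bipartitions=False,
                           rng=random.Random(seed))
    # dendropy inserts edges with length None; pin them to 0 so path sums
    # are well defined.
    for edge in out.preorder_edge_iter():
        if edge.length is None and edge.head_node is not out.seed_node:
            edge.length = 0.0
    return out


def _taxon_labels(tree: dendropy.Tree) -> list[str]:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    return labels


def cophenetic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Patristic (cophenetic) distance between every pair of tips: the sum of
    branch lengths on the tree path connecting them."""
    labels = _taxon_labels(tree)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    idx = pd.Index(labels, name="host_id")
    return pd.DataFrame(d, index=idx, columns=idx)


def phylo_vcv(tree: dendropy.Tree) -> pd.DataFrame:
    """Phylogenetic covariance matrix under Brownian motion.

    ``V[i, j]`` is the shared root-to-MRCA path length of tips i and j,
    computed as ``(depth_i + depth_j - d_ij) / 2`` from root-to-tip depths
    and patristic distances; the diagonal holds each tip's depth.
    """
    coph = cophenetic_matrix(tree)
    depths = tip_depths(tree).reindex(coph.index).to_numpy()
    v = (depths[:, None] + depths[None, :] - coph.to_numpy()) / 2.0
    return pd.DataFrame(v, index=coph.index, columns=coph.columns)
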