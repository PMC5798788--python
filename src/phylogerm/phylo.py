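"""Species phylogeny: cophenetic distances and the relatedness matrix A.

The tree is a rooted, dated phylogeny with branch lengths in millions of
years.  Two matrices feed the downstream analyses:

* the cophenetic distance matrix (total path length between tips), used by
  the Mantel tests, and
* the phylogenetic relatedness matrix **A**, the shared root-to-MRCA branch
  length of each species pair scaled to unit diagonal, which models the
  expected correlation of species-level coefficients under Brownian-like
  evolution and enters the GLMM prior covariance as sigma^2 * A.
"""

from __future__ import annotations

import io
import warnings

import dendropy
import numpy as np
import pandas as pd


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted dendropy tree.

    Requires branch lengths on all non-root edges and unique tip labels.
    """
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"unparseable Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has edges without branch lengths")
        if edge.length < 0:
            raise ValueError("negative branch length")
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    out = io.StringIO()
    tree.write(file=out, schema="newick", suppress_rooting=True)
    return out.getvalue().strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


def _root_distances(tree: dendropy.Tree) -> dict:
    """Distance from the root to every node, keyed by node."""
    dist = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        dist[node] = dist[node.parent_node] + (node.edge.length or 0.0)
    return dist


def cophenetic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Square symmetric matrix of tip-to-tip path lengths (Myr)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = tip_labels(tree)
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    n = len(labels)
    D = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d = pdm.patristic_distance(taxa[a], taxa[b])
                D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=labels, columns=labels)


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = [d for node, d in _root_distances(tree).items() if node.is_leaf()]
    dmax = max(depths)
    if dmax == 0:
        return True
    return (dmax - min(depths)) <= rel_tol * dmax


def relatedness_matrix(tree: dendropy.Tree, scale: bool = True) -> pd.DataFrame:
    """Phylogenetic relatedness matrix A over species.

    ``A[i, j]`` is the branch length shared from the root down to the most
    recent common ancestor of tips *i* and *j*.  With ``scale=True``
    (default) entries are normalized by the root-to-tip depth so that the
    diagonal is 1 and A is a correlation matrix; for a non-ultrametric tree
    each pair is normalized by the geometric mean of the two tip depths,
    with a warning.
    """
    labels = tip_labels(tree)
    depth = _root_distances(tree)
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    tip_depth = {lab: depth[leaves[lab]] for lab in labels}
    if max(tip_depth.values()) <= 0:
        raise ValueError("zero-depth tree: cannot form a relatedness matrix")
    if not is_ultrametric(tree):
        warnings.warn(
            "tree is not ultrametric; relatedness entries normalized per pair "
            "by the geometric mean of tip depths",
            stacklevel=2,
        )

    # shared depth = root distance of the MRCA
    n = len(labels)
    A = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                A[i, i] = tip_depth[a] if not scale else 1.0
                continue
            if i < j:
                mrca = tree.mrca(taxa=[leaves[a].taxon, leaves[b].taxon])
                shared = depth[mrca]
                if scale:
                    shared = shared / np.sqrt(tip_depth[a] * tip_depth[b])
                A[i, j] = A[j, i] = shared
    if not scale:
        for i, a in enumerate(labels):
            A[i, i] = tip_depth[a]
    return pd.DataFrame(A, index=labels, columns=labels)


def shared_depths(tree: dendropy.Tree) -> pd.DataFrame:
    """Unscaled root-to-MRCA shared branch lengths (Myr); diagonal = tip depth."""
    return relatedness_matrix(tree, scale=False)


def check_matches_species(tree: dendropy.Tree, species: set[str]) -> None:
    """Raise unless tip labels exactly cover the given species codes."""
    tips = set(tip_labels(tree))
    if tips != set(species):
        missing = sorted(set(species) - tips)
        extra = sorted(tips - set(species))
        raise ValueError(
            f"tree tips do not match species in data; missing from tree: "
            f"{missing}; extra in tree: {extra}"
        )
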