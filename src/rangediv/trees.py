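"""Tree handling and phylogenetic covariance algebra.

Trees are :class:`dendropy.Tree` objects throughout the package; this module
wraps Newick I/O with stricter validation and provides the covariance
machinery (Brownian variance-covariance matrix, Pagel's lambda transform,
determinant standardization) that the regression and mixed-model stages
consume.  Covariance matrices always carry tip labels and every consumer
aligns data by label, never by row position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

Tree = dendropy.Tree

__all__ = [
    "Tree",
    "NewickError",
    "PhyloCovariance",
    "parse_newick",
    "write_newick",
    "check_ultrametric",
    "tip_labels",
    "tip_depths",
    "tree_depth",
    "rescale_depth",
    "prune_to_tips",
    "phylo_vcv",
    "transform_vcv",
]


class NewickError(ValueError):
    """Malformed Newick input (unbalanced parentheses, duplicate or missing
    labels, absent branch lengths)."""


def parse_newick(text: str) -> Tree:
    """Parse a Newick string with branch lengths into a rooted tree.

    Polytomies are preserved.  Raises :class:`NewickError` naming the
    offending token for duplicate tip labels or edges without lengths
    (a missing length on the root edge is permitted and treated as no
    root edge).
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"invalid newick: {exc}") from exc
    seen: set[str] = set()
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise NewickError("unlabelled tip in newick input")
        if leaf.taxon.label in seen:
            raise NewickError(f"duplicate tip label: {leaf.taxon.label!r}")
        seen.add(leaf.taxon.label)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon else "<internal>"
            raise NewickError(f"edge above {name!r} has no branch length")
        if edge.length < 0:
            raise NewickError("negative branch length")
    return tree


def write_newick(tree: Tree) -> str:
    """Serialize a tree to Newick with branch lengths."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def tip_labels(tree: Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def _node_depths(tree: Tree) -> dict:
    depths = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def tip_depths(tree: Tree) -> pd.Series:
    """Root-to-tip path length for every tip, indexed by label."""
    depths = _node_depths(tree)
    return pd.Series(
        {leaf.taxon.label: depths[leaf] for leaf in tree.leaf_node_iter()}
    )


def tree_depth(tree: Tree) -> float:
    return float(tip_depths(tree).max())


def check_ultrametric(tree: Tree, tol: float = 1e-8) -> bool:
    """True iff the spread of root-to-tip depths is within ``tol``."""
    d = tip_depths(tree)
    return bool(d.max() - d.min() <= tol)


def rescale_depth(tree: Tree, depth: float = 1.0) -> Tree:
    """Rescale all branch lengths in place so total depth equals ``depth``.

    Mirrors the fixed-root calibration in which the root age is set to one;
    returns the tree for chaining.
    """
    current = tree_depth(tree)
    if current <= 0:
        raise ValueError("tree has zero depth")
    factor = depth / current
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


def prune_to_tips(tree: Tree, labels) -> Tree:
    """Return a deep-copied tree retaining only the given tips.

    Branch lengths on retained paths are preserved (unifurcations are
    collapsed by summing edge lengths, as in standard pruning).
    """
    labels = set(labels)
    missing = labels - set(tip_labels(tree))
    if missing:
        raise KeyError(f"labels not in tree: {sorted(missing)}")
    pruned = tree.clone(depth=1)
    keep = [t for t in pruned.taxon_namespace if t.label in labels]
    pruned.retain_taxa(keep)
    return pruned


@dataclass
class PhyloCovariance:
    """Brownian-motion tip covariance of a rooted tree.

    Entry (i, j) is the root-to-MRCA depth of the tip pair; the diagonal
    holds tip depths.  ``lam`` records the Pagel's-lambda multiplier that
    has been applied to the off-diagonal entries and ``standardized``
    whether the matrix was divided by det^(1/n).
    """

    matrix: pd.DataFrame
    lam: float = 1.0
    standardized: bool = False
    labels: list[str] = field(init=False)

    def __post_init__(self):
        self.labels = list(self.matrix.index)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()

    def reindex(self, labels) -> np.ndarray:
        """Covariance aligned to an explicit label order."""
        return self.matrix.loc[list(labels), list(labels)].to_numpy()

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)


def phylo_vcv(tree: Tree) -> PhyloCovariance:
    """Phylogenetic variance-covariance matrix of a rooted tree.

    Computed in one postorder sweep: every internal node at depth *d*
    contributes *d* as the covariance of each tip pair whose most recent
    common ancestor it is.
    """
    if tree.seed_node is None:
        raise ValueError("tree has no root")
    depths = _node_depths(tree)
    labels = tip_labels(tree)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two tips")
    V = np.zeros((n, n))
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            below[node] = [i]
            V[i, i] = depths[node]
        else:
            groups = [below.pop(ch) for ch in node.child_nodes()]
            d = depths[node]
            for a in range(len(groups)):
                for b in range(a + 1, len(groups)):
                    for i in groups[a]:
                        V[i, groups[b]] = d
                        V[groups[b], i] = d
            merged = [i for g in groups for i in g]
            below[node] = merged
    return PhyloCovariance(pd.DataFrame(V, index=labels, columns=labels))


def transform_vcv(
    C: PhyloCovariance, lam: float = 1.0, standardize: bool = False
) -> PhyloCovariance:
    """Apply Pagel's lambda to the off-diagonals and/or det-standardize.

    With ``standardize`` the matrix is divided by det^(1/n) so its
    determinant is 1, the convention used before inverting to a
    phylogenetic precision matrix in the spatiophylogenetic model.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    V = C.values.copy()
    n = V.shape[0]
    d = np.diag(V)
    if lam < 1.0 and d.max() - d.min() > 1e-6 * max(d.max(), 1.0):
        # diagonal-preserving lambda transform is only defined on
        # ultrametric trees (equal tip depths)
        raise ValueError("lambda transform requires an ultrametric tree")
    off = ~np.eye(n, dtype=bool)
    V[off] *= lam
    if standardize:
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            raise ValueError("covariance is singular; cannot standardize")
        V = V / np.exp(logdet / n)
    return PhyloCovariance(
        pd.DataFrame(V, index=C.labels, columns=C.labels),
        lam=lam * C.lam,
        standardized=standardize or C.standardized,
    )
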