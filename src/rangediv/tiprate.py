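"""Tip-level speciation-rate estimation: the DR statistic.

The equal-splits measure ES of a tip sums the edge lengths on its
root-to-tip path, halving the weight at each successive node toward the
root (the pendant edge has weight 1).  Its inverse, DR = 1/ES, is a
nonparametric per-tip proxy for recent speciation rate: tips subtended by
many short edges (recent, nested splits) get small ES and high DR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trees import Tree

__all__ = ["equal_splits_measure", "dr_statistic"]


def equal_splits_measure(tree: Tree) -> pd.Series:
    """Equal-splits value per tip, indexed by tip label.

    One preorder sweep using the recurrence ES(v) = l_v + ES(parent)/2,
    which reproduces the tip-to-root sum sum_j l_j (1/2)^(j-1).  A root
    edge, if present, is excluded.
    """
    acc: dict = {tree.seed_node: 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length
        if length is None:
            raise ValueError("branch without length")
        val = length + acc[node.parent_node] / 2.0
        if node.is_leaf():
            if length <= 0:
                raise ValueError(
                    f"zero-length pendant edge at tip {node.taxon.label!r}"
                )
            out[node.taxon.label] = val
        else:
            acc[node] = val
    return pd.Series(out, name="equal_splits")


def dr_statistic(tree: Tree) -> pd.DataFrame:
    """Per-tip DR table: equal_splits, dr = 1/ES, log_dr = ln(dr).

    The log is natural; recorded in the ``attrs`` metadata of the frame.
    """
    es = equal_splits_measure(tree)
    dr = 1.0 / es
    table = pd.DataFrame(
        {"equal_splits": es, "dr": dr, "log_dr": np.log(dr)}
    )
    table.index.name = "label"
    table.attrs["log_base"] = "e"
    return table
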