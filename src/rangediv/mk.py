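"""Two-state continuous-time Markov (Mk) characters on a tree.

Closed-form 2x2 transition probabilities, tip-state simulation by exact
endpoint sampling, the pruning likelihood of a tip pattern, and 1-D ML
fitting of a symmetric rate.  Everything is vectorized over characters so
the FiSSE null distribution (hundreds of simulated characters on one tree)
is cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .trees import Tree

__all__ = [
    "mk_transition_matrix",
    "simulate_mk_character",
    "mk_loglik",
    "fit_symmetric_mk_rate",
]


def mk_transition_matrix(q01: float, q10: float, t: float) -> np.ndarray:
    """P(t) for rate matrix [[-q01, q01], [q10, -q10]], in closed form."""
    q = q01 + q10
    if q == 0.0:
        return np.eye(2)
    pi1 = q01 / q
    e = np.exp(-q * t)
    return np.array(
        [
            [1.0 - pi1 * (1.0 - e), pi1 * (1.0 - e)],
            [(1.0 - pi1) * (1.0 - e), 1.0 - (1.0 - pi1) * (1.0 - e)],
        ]
    )


def simulate_mk_character(
    tree: Tree,
    q01: float,
    q10: float,
    root_freq: float = 0.5,
    seed: int | None = None,
    size: int = 1,
    rng: np.random.Generator | None = None,
) -> pd.Series | pd.DataFrame:
    """Evolve binary states along the tree; return tip states.

    ``root_freq`` is the probability of root state 1.  Endpoint sampling
    with the exact transition matrix is used (tip states only, no
    per-branch event history).  With ``size`` > 1 a (tips x size)
    DataFrame of independent characters is returned.
    """
    if q01 < 0 or q10 < 0:
        raise ValueError("transition rates must be non-negative")
    if q01 == q10 == 0.0 and not 0.0 <= root_freq <= 1.0:
        raise ValueError("root frequency must be a probability")
    if rng is None:
        rng = np.random.default_rng(seed)
    states: dict = {}
    root_state = (rng.random(size) < root_freq).astype(np.int64)
    states[tree.seed_node] = root_state
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        P = mk_transition_matrix(q01, q10, t)
        parent = states[node.parent_node]
        p1 = P[:, 1][parent]
        states[node] = (rng.random(size) < p1).astype(np.int64)
    tips = {
        leaf.taxon.label: states[leaf] for leaf in tree.leaf_node_iter()
    }
    frame = pd.DataFrame(tips).T
    frame.index.name = "label"
    if size == 1:
        return frame[0].rename("state")
    return frame


def _align_states(tree: Tree, states) -> pd.DataFrame:
    if isinstance(states, dict):
        states = pd.Series(states)
    if isinstance(states, pd.Series):
        states = states.to_frame()
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = set(labels) - set(states.index)
    if missing:
        raise KeyError(f"tips without states: {sorted(missing)[:5]}")
    return states.loc[labels]


def mk_loglik(
    tree: Tree,
    states,
    q01: float,
    q10: float,
    root_freq: float | str = 0.5,
) -> float | np.ndarray:
    """Pruning log-likelihood of observed tip states under the Mk model.

    ``root_freq``: probability of state 1 at the root, or ``"conditional"``
    to weight root states by their own conditional likelihoods.  Accepts a
    Series (one character) or DataFrame (characters in columns); returns a
    scalar or an array accordingly.
    """
    frame = _align_states(tree, states)
    X = frame.to_numpy()
    m = X.shape[1]
    row = {lab: i for i, lab in enumerate(frame.index)}
    partial: dict = {}
    logscale = np.zeros(m)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = row[node.taxon.label]
            D = np.zeros((2, m))
            D[X[i], np.arange(m)] = 1.0
            partial[node] = D
        else:
            D = np.ones((2, m))
            for child in node.child_nodes():
                P = mk_transition_matrix(q01, q10, child.edge.length or 0.0)
                D *= P @ partial.pop(child)
            mx = D.max(axis=0)
            mx[mx == 0] = 1.0
            D /= mx
            logscale += np.log(mx)
            partial[node] = D
    D = partial[tree.seed_node]
    if root_freq == "conditional":
        tot = D.sum(axis=0)
        like = (D**2).sum(axis=0) / np.where(tot > 0, tot, 1.0)
    else:
        like = (1.0 - root_freq) * D[0] + root_freq * D[1]
    out = np.log(np.where(like > 0, like, np.nan)) + logscale
    return float(out[0]) if m == 1 else out


def fit_symmetric_mk_rate(
    tree: Tree, states, bounds: tuple[float, float] = (1e-4, 1e3)
) -> float:
    """ML estimate of a single symmetric transition rate for a tip pattern.

    Scalar bounded optimization on log-rate; used to calibrate the FiSSE
    null-character generator to the observed state pattern.
    """
    states = pd.Series(states) if isinstance(states, dict) else states

    def nll(logq: float) -> float:
        q = float(np.exp(logq))
        val = mk_loglik(tree, states, q, q, root_freq=0.5)
        return -val if np.isfinite(val) else 1e10

    res = minimize_scalar(
        nll,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(np.exp(res.x))
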