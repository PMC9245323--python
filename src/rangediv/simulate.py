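"""Synthetic clade generator.

Produces trees, binary characters, continuous traits and trait tables
with the statistical structure the downstream analyses assume: birth-death
and state-dependent (BiSSE) tree simulation by the Gillespie event
algorithm, Brownian traits with Pagel's lambda, Mk binary characters, and
a honeyeater-like species table (192 tips, 68 island / 124 continental,
right-skewed range sizes with island ranges systematically smaller, and a
linear structural trait simulation following the
position -> body size -> dispersal -> range size/shape arrow diagram).

All simulators are bit-for-bit reproducible under a fixed seed, and all
trees are rescaled to unit root depth, mirroring a root age fixed to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .mk import simulate_mk_character
from .sse import BiSSEParams
from .tiprate import dr_statistic
from .trees import Tree, phylo_vcv, rescale_depth, transform_vcv, tree_depth

__all__ = [
    "SimConfig",
    "TraitModel",
    "MkRates",
    "RangeSizeModel",
    "PathCoefficients",
    "simulate_bd_tree",
    "simulate_sse_tree",
    "simulate_bm_trait",
    "simulate_mk_character",
    "generate_clade_dataset",
]

DATASET_COLUMNS = [
    "range_size",
    "shape_index",
    "lat_midpoint",
    "lon_midpoint",
    "setting",
    "body_mass",
    "hwi",
    "dr_rate",
    "genus",
]


# ---------------------------------------------------------------------------
# tree simulation


def _grow_gillespie(n_tips, lam, mu, Q, root_state, rng):
    """One forward Gillespie run; returns (tree, tip states) or None on
    total extinction.  Stops just before the first event that would follow
    the moment the extant count reaches n_tips, so pendant edges are
    strictly positive."""
    k = len(lam)
    qout = Q.sum(axis=1) - np.diag(Q)
    tree = dendropy.Tree()
    root = tree.seed_node
    c1 = root.new_child(edge_length=0.0)
    c2 = root.new_child(edge_length=0.0)
    birth_time = {c1: 0.0, c2: 0.0}
    state_of = {c1: root_state, c2: root_state}
    by_state = [[] for _ in range(k)]
    by_state[root_state] = [c1, c2]
    t = 0.0
    while True:
        counts = np.array([len(g) for g in by_state], dtype=float)
        n_active = int(counts.sum())
        if n_active == 0:
            return None
        rate_spec = counts * lam
        rate_ext = counts * mu
        rate_tot = rate_spec.sum() + rate_ext.sum() + (counts * qout).sum()
        if rate_tot <= 0:
            return None
        dt = rng.exponential(1.0 / rate_tot)
        t += dt
        if n_active == n_tips:
            break  # cut just before the next event
        u = rng.random() * rate_tot
        s = 0
        kind = None
        for s in range(k):
            if u < rate_spec[s]:
                kind = "spec"
                break
            u -= rate_spec[s]
            if u < rate_ext[s]:
                kind = "ext"
                break
            u -= rate_ext[s]
            if u < counts[s] * qout[s]:
                kind = "trans"
                break
            u -= counts[s] * qout[s]
        if kind is None:  # guard against roundoff at the upper boundary
            s = int(np.argmax(counts))
            kind = "spec" if lam[s] > 0 else "ext"
        group = by_state[s]
        i = rng.integers(len(group))
        node = group[i]
        group[i] = group[-1]
        group.pop()
        if kind == "spec":
            node.edge.length = t - birth_time[node]
            for _ in range(2):
                child = node.new_child(edge_length=0.0)
                birth_time[child] = t
                state_of[child] = s
                by_state[s].append(child)
            del state_of[node]
        elif kind == "ext":
            node.edge.length = t - birth_time[node]
            del state_of[node]  # dead tip: stays unlabelled, pruned later
        else:
            row = Q[s].copy()
            row[s] = 0.0
            s2 = rng.choice(k, p=row / row.sum())
            state_of[node] = s2
            by_state[s2].append(node)
    tip_states = {}
    alive = [n for g in by_state for n in g]
    for i, node in enumerate(alive):
        node.edge.length = t - birth_time[node]
        taxon = tree.taxon_namespace.require_taxon(label=f"t{i + 1}")
        node.taxon = taxon
        tip_states[taxon.label] = state_of[node]
    # prune extinct lineages (leaves without taxa), collapse unifurcations
    changed = True
    while changed:
        changed = False
        for leaf in list(tree.leaf_node_iter()):
            if leaf.taxon is None and leaf.parent_node is not None:
                leaf.parent_node.remove_child(leaf)
                changed = True
    tree.suppress_unifurcations()
    while len(tree.seed_node.child_nodes()) == 1:
        child = tree.seed_node.child_nodes()[0]
        tree.seed_node.remove_child(child)
        child.parent_node = None
        tree.seed_node = child
    tree.seed_node.edge.length = None
    return tree, tip_states


def simulate_bd_tree(
    n_tips: int, birth: float, death: float, seed: int
) -> Tree:
    """Constant-rate birth-death tree with ``n_tips`` extant tips,
    rescaled to unit depth.  Requires birth > death >= 0."""
    if n_tips < 2:
        raise ValueError("n_tips must be at least 2")
    if not birth > death or death < 0:
        raise ValueError("need birth > death >= 0")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        out = _grow_gillespie(
            n_tips,
            np.array([birth]),
            np.array([death]),
            np.zeros((1, 1)),
            0,
            rng,
        )
        if out is not None:
            tree, _ = out
            depth = tree_depth(tree)
            rescale_depth(tree, 1.0)
            tree.depth_scale = depth
            return tree
    raise RuntimeError(
        "birth-death simulation went extinct in 100 consecutive attempts; "
        "parameters may be non-viable"
    )


def simulate_sse_tree(
    params: BiSSEParams,
    n_tips: int,
    seed: int,
    root_state: int = 0,
    max_retries: int = 100,
):
    """Joint Gillespie simulation of tree growth and a binary character
    under BiSSE.  Returns (tree, tip-state Series); the tree is rescaled
    to unit depth with the original depth stored as ``tree.depth_scale``
    (generating rates on the rescaled tree are the input rates times this
    factor).  Retries on total extinction and, when transitions permit,
    on monomorphic tip states, up to ``max_retries`` times."""
    if n_tips < 2:
        raise ValueError("n_tips must be at least 2")
    lam, mu, Q = params.arrays()
    rng = np.random.default_rng(seed)
    can_mix = params.q01 > 0 and params.q10 > 0
    last = None
    for _ in range(max_retries):
        out = _grow_gillespie(n_tips, lam, mu, Q, root_state, rng)
        if out is None:
            continue
        tree, states = out
        last = out
        if can_mix and len(set(states.values())) < 2:
            continue
        break
    else:
        if last is None:
            raise RuntimeError(
                f"all {max_retries} state-dependent simulations went extinct"
            )
        tree, states = last
    depth = tree_depth(tree)
    rescale_depth(tree, 1.0)
    tree.depth_scale = depth
    series = pd.Series(states, name="state")
    series = series.loc[[lf.taxon.label for lf in tree.leaf_node_iter()]]
    return tree, series


def simulate_bm_trait(
    tree: Tree,
    sigma2: float,
    lam: float = 1.0,
    root: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Draw one trait from N(root, sigma2 * C(lambda)) with C the Brownian
    tree covariance and off-diagonals scaled by lambda."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    C = transform_vcv(phylo_vcv(tree), lam=lam)
    L = np.linalg.cholesky(
        sigma2 * C.values + 1e-12 * np.eye(len(C.labels))
    )
    vals = root + L @ rng.standard_normal(len(C.labels))
    return pd.Series(vals, index=C.labels, name="trait")


# ---------------------------------------------------------------------------
# clade dataset


@dataclass
class TraitModel:
    """Brownian residual model for the structural trait simulation."""

    sigma2: float = 1.0
    lam: float = 1.0
    root: float = 0.0

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")


@dataclass
class MkRates:
    q01: float = 1.0
    q10: float = 1.0

    def __post_init__(self):
        if self.q01 < 0 or self.q10 < 0:
            raise ValueError("Mk rates must be non-negative")


@dataclass
class RangeSizeModel:
    """Log-normal range-size parameters (km^2) per geographic setting.

    Defaults emulate the honeyeater distribution: right-skewed sizes
    spanning roughly 4e1 to 7e6 km^2 with island ranges systematically
    smaller (island location well below the continental one)."""

    island_meanlog: float = 9.2
    island_sdlog: float = 1.6
    continental_meanlog: float = 12.2
    continental_sdlog: float = 1.8

    def __post_init__(self):
        if self.island_sdlog <= 0 or self.continental_sdlog <= 0:
            raise ValueError("sdlog must be positive")


@dataclass
class PathCoefficients:
    """Standardized path coefficients of the structural simulation.

    Signs follow the arrow diagram the analyses test: position shapes
    body size and dispersal, body size raises dispersal, dispersal raises
    range size while body size constrains it, and range size drives the
    shape index.  Magnitudes are a design choice (the source analyses
    report signs, not effect sizes)."""

    lat_to_body: float = -0.3
    lon_to_body: float = 0.3
    body_to_hwi: float = 0.3
    lat_to_hwi: float = 0.2
    island_to_hwi: float = 0.2
    lat_to_range: float = 0.3
    lon_to_range: float = -0.3
    hwi_to_range: float = 0.3
    body_to_range: float = -0.2
    hwi_to_shape: float = 0.2

    @classmethod
    def null(cls) -> "PathCoefficients":
        """All path effects zero (for null-recovery experiments)."""
        return cls(**{f: 0.0 for f in cls.__dataclass_fields__})


@dataclass
class SimConfig:
    """Configuration of one synthetic clade.

    Defaults are the study conditions: a 192-tip pure-birth tree of unit
    depth with an island fraction of 68/192, i.i.d. island assignment,
    and log-normal range sizes per setting."""

    n_tips: int = 192
    birth_rate: float = 1.0
    death_rate: float = 0.0
    sse_params: BiSSEParams | None = None
    trait_model: TraitModel = field(default_factory=TraitModel)
    mk_rates: MkRates = field(default_factory=MkRates)
    range_size_model: RangeSizeModel = field(default_factory=RangeSizeModel)
    path_coefficients: PathCoefficients = field(
        default_factory=PathCoefficients
    )
    island_fraction: float = 68.0 / 192.0
    island_flag_mode: str = "iid"  # or "mk"
    missing_hwi_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be at least 2")
        if self.birth_rate < 0 or self.death_rate < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.island_fraction <= 1.0:
            raise ValueError("island_fraction must be in [0, 1]")
        if self.island_flag_mode not in ("iid", "mk"):
            raise ValueError("island_flag_mode must be 'iid' or 'mk'")
        if not 0.0 <= self.missing_hwi_fraction < 0.5:
            raise ValueError("missing_hwi_fraction must be in [0, 0.5)")


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def generate_clade_dataset(config: SimConfig):
    """Simulate a tree plus a honeyeater-like species table.

    Returns (DataFrame indexed by tip label with the fixed column order
    ``DATASET_COLUMNS``, tree).  With ``sse_params`` set, the island flag
    is the state of the jointly simulated binary character (state 1 =
    island), coupling the setting to speciation rate; otherwise the flag
    is i.i.d. Bernoulli(island_fraction) or Mk-evolved, uncoupled from
    the tree."""
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_flag, s_traits, s_missing = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    ]
    if config.sse_params is not None:
        tree, states = simulate_sse_tree(
            config.sse_params, config.n_tips, seed=s_tree
        )
        island = states.astype(bool)
    else:
        tree = simulate_bd_tree(
            config.n_tips, config.birth_rate, config.death_rate, seed=s_tree
        )
        if config.island_flag_mode == "mk":
            states = simulate_mk_character(
                tree,
                config.mk_rates.q01,
                config.mk_rates.q10,
                root_freq=config.island_fraction,
                seed=s_flag,
            )
            island = states.astype(bool)
        else:
            rng_flag = np.random.default_rng(s_flag)
            labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
            island = pd.Series(
                rng_flag.random(config.n_tips) < config.island_fraction,
                index=labels,
            )
    if island.all() or (~island).all():
        raise ValueError(
            "island assignment produced an empty class; adjust "
            "island_fraction or n_tips"
        )
    labels = list(island.index)
    rng = np.random.default_rng(s_traits)
    tm = config.trait_model
    pc = config.path_coefficients

    def bm_noise() -> np.ndarray:
        draw = simulate_bm_trait(tree, tm.sigma2, tm.lam, 0.0, rng=rng)
        return _zscore(draw.loc[labels].to_numpy())

    lat = 15.0 * bm_noise()
    lon = 140.0 + 20.0 * bm_noise()
    z_alat = _zscore(np.abs(lat))
    z_alon = _zscore(np.abs(lon))
    z_isl = _zscore(island.to_numpy().astype(float))
    log_body = (
        np.log(20.0)
        + 0.4 * (pc.lat_to_body * z_alat + pc.lon_to_body * z_alon)
        + 0.4 * bm_noise()
    )
    z_body = _zscore(log_body)
    hwi = 25.0 + 5.0 * (
        pc.body_to_hwi * z_body
        + pc.lat_to_hwi * z_alat
        + pc.island_to_hwi * z_isl
        + bm_noise()
    )
    hwi = np.clip(hwi, 2.0, 60.0)
    z_hwi = _zscore(hwi)
    rs = config.range_size_model
    meanlog = np.where(
        island, rs.island_meanlog, rs.continental_meanlog
    )
    sdlog = np.where(island, rs.island_sdlog, rs.continental_sdlog)
    struct = (
        pc.lat_to_range * z_alat
        + pc.lon_to_range * z_alon
        + pc.hwi_to_range * z_hwi
        + pc.body_to_range * z_body
    )
    log_range = meanlog + sdlog * _zscore(0.5 * struct + bm_noise())
    # shape index of a compact range scales like sqrt(area); dispersal
    # nudges shapes toward compactness, noise toward elongation
    log_shape = (
        0.5 * log_range
        - 1.26
        + 0.2 * pc.hwi_to_shape * z_hwi
        + 0.25 * bm_noise()
    )
    dr = dr_statistic(tree)["dr"].loc[labels]
    genus = _genus_groups(tree, cut=0.4).loc[labels]
    hwi_col = pd.Series(hwi, index=labels)
    if config.missing_hwi_fraction > 0:
        rng_miss = np.random.default_rng(s_missing)
        n_miss = int(round(config.missing_hwi_fraction * config.n_tips))
        drop = rng_miss.choice(config.n_tips, size=n_miss, replace=False)
        hwi_col.iloc[drop] = np.nan
    data = pd.DataFrame(
        {
            "range_size": np.exp(log_range),
            "shape_index": np.exp(log_shape),
            "lat_midpoint": lat,
            "lon_midpoint": lon,
            "setting": np.where(island, "island", "continental"),
            "body_mass": np.exp(log_body),
            "hwi": hwi_col,
            "dr_rate": dr,
            "genus": genus,
        },
        index=pd.Index(labels, name="label"),
    )[DATASET_COLUMNS]
    return data, tree


def _genus_groups(tree: Tree, cut: float = 0.4) -> pd.Series:
    """Clade membership at a depth cut, as a synthetic genus label."""
    depth = {tree.seed_node: 0.0}
    group: dict = {}
    counter = [0]
    out: dict[str, str] = {}

    def assign(node, gid):
        for leaf in node.leaf_iter():
            out[leaf.taxon.label] = gid

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        if depth[node.parent_node] < cut <= depth[node]:
            counter[0] += 1
            assign(node, f"g{counter[0]}")
    ser = pd.Series(out, name="genus")
    return ser


def null_config(**overrides) -> SimConfig:
    """Study-condition config with all structural path effects zeroed."""
    kw = dict(path_coefficients=PathCoefficients.null())
    kw.update(overrides)
    return SimConfig(**kw)
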