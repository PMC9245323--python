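import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm
from scipy.stats import mannwhitneyu

from rangediv.mk import mk_loglik, mk_transition_matrix, simulate_mk_character
from rangediv.simulate import (
    PathCoefficients,
    SimConfig,
    generate_clade_dataset,
    simulate_bd_tree,
    simulate_bm_trait,
    simulate_sse_tree,
)
from rangediv.sse import BiSSEParams
from rangediv.tiprate import dr_statistic
from rangediv.trees import check_ultrametric, parse_newick, tip_depths, write_newick


def gamma_statistic(tree):
    """Closed-form gamma of an ultrametric tree (lineage-through-time
    shape statistic; standard normal under pure birth)."""
    depths = {tree.seed_node: 0.0}
    node_depths = []
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depths[node] = depths[node.parent_node] + node.edge.length
        if not node.is_leaf():
            node_depths.append(depths[node])
    node_depths = np.sort(np.array(node_depths))
    n = len(node_depths) + 1
    tip_depth = max(depths[lf] for lf in tree.leaf_node_iter())
    # g_k = time interval with exactly k lineages, k = 2..n
    boundaries = np.append(node_depths, tip_depth)
    ks = np.arange(2, n + 1)
    g_k = np.diff(boundaries)
    T = float((ks * g_k).sum())
    inner = np.cumsum(ks * g_k)[:-1].sum() / (n - 2)
    return (inner - T / 2.0) / (T * np.sqrt(1.0 / (12.0 * (n - 2))))


class TestBirthDeathTree:
    def test_two_tip_tree_forced_shape(self):
        tree = simulate_bd_tree(2, 1.0, 0.0, seed=0)
        d = tip_depths(tree)
        assert len(d) == 2
        assert np.allclose(d, 1.0)

    def test_tip_count_and_ultrametricity(self):
        tree = simulate_bd_tree(192, 1.0, 0.0, seed=1)
        assert len(tree.leaf_nodes()) == 192
        assert check_ultrametric(tree, 1e-8)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            simulate_bd_tree(10, 0.5, 0.5, seed=0)
        with pytest.raises(ValueError):
            simulate_bd_tree(1, 1.0, 0.0, seed=0)

    def test_reproducible(self):
        t1 = simulate_bd_tree(25, 1.0, 0.3, seed=7)
        t2 = simulate_bd_tree(25, 1.0, 0.3, seed=7)
        assert write_newick(t1) == write_newick(t2)

    def test_pure_birth_gamma_centred_on_zero(self):
        """Under pure birth the gamma statistic is standard normal; its
        mean over replicates must sit at 0 within Monte-Carlo error."""
        vals = [
            gamma_statistic(simulate_bd_tree(50, 1.0, 0.0, seed=s))
            for s in range(400)
        ]
        assert abs(np.mean(vals)) < 3.5 / np.sqrt(len(vals))


class TestSSETree:
    def test_symmetric_rates_give_half_frequency(self):
        p = BiSSEParams(1.0, 1.0, 0.0, 0.0, 1.0, 1.0)
        freqs = [
            simulate_sse_tree(p, 40, seed=s)[1].mean() for s in range(200)
        ]
        assert abs(np.mean(freqs) - 0.5) < 3.5 * np.std(freqs) / np.sqrt(200)

    def test_fast_state_has_higher_tip_rate(self):
        p = BiSSEParams(1.0, 2.0, 0.0, 0.0, 0.3, 0.3)
        wins = 0
        for s in range(100):
            tree, states = simulate_sse_tree(p, 60, seed=s)
            dr = dr_statistic(tree)["dr"]
            mask = states.loc[dr.index].astype(bool)
            if dr[mask].mean() > dr[~mask].mean():
                wins += 1
        assert wins > 60

    def test_no_transitions_keeps_root_state(self):
        p = BiSSEParams(1.0, 1.0, 0.0, 0.0, 0.0, 0.0)
        _, states = simulate_sse_tree(p, 30, seed=3, root_state=0)
        assert (states == 0).all()

    def test_state_independent_matches_bd_plus_mk(self):
        """Tip-state frequencies from the joint simulator with
        state-independent rates are indistinguishable from a neutral
        character evolved on an independent birth-death tree."""
        p = BiSSEParams(1.0, 1.0, 0.0, 0.0, 0.8, 0.8)
        joint, split = [], []
        for s in range(200):
            _, st = simulate_sse_tree(p, 40, seed=s)
            joint.append(st.mean())
            tree = simulate_bd_tree(40, 1.0, 0.0, seed=10_000 + s)
            ch = simulate_mk_character(tree, 0.8, 0.8, root_freq=0.5, seed=s)
            split.append(ch.mean())
        _, pval = mannwhitneyu(joint, split)
        assert pval > 0.01


class TestBMTrait:
    def test_lambda_zero_iid(self, bd_tree_factory):
        tree = bd_tree_factory(100, seed=4)
        draws = np.array([
            simulate_bm_trait(tree, 1.0, 0.0, 0.0, seed=s).to_numpy()
            for s in range(300)
        ])
        cov = np.cov(draws[:, 0], draws[:, 50])[0, 1]
        assert abs(cov) < 0.2

    def test_two_tip_difference_variance(self):
        tree = parse_newick("(A:1,B:1);")
        sigma2 = 0.7
        diffs = [
            np.diff(simulate_bm_trait(tree, sigma2, 1.0, 0.0, seed=s))[0]
            for s in range(1000)
        ]
        assert np.var(diffs) == pytest.approx(2.0 * sigma2, rel=0.15)

    def test_deterministic_under_seed(self, bd_tree_factory):
        tree = bd_tree_factory(20, seed=5)
        a = simulate_bm_trait(tree, 1.0, 0.8, 2.0, seed=11)
        b = simulate_bm_trait(tree, 1.0, 0.8, 2.0, seed=11)
        pd.testing.assert_series_equal(a, b)

    def test_non_ultrametric_rejected(self):
        tree = parse_newick("((A:1,B:2):1,C:2);")
        with pytest.raises(ValueError):
            simulate_bm_trait(tree, 1.0, 0.5, 0.0, seed=0)


class TestMkCharacter:
    def test_no_rates_keeps_root(self, bd_tree_factory):
        tree = bd_tree_factory(20, seed=6)
        states = simulate_mk_character(tree, 0.0, 0.0, root_freq=0.0, seed=0)
        assert (states == 0).all()

    def test_stationary_frequency(self, bd_tree_factory):
        tree = bd_tree_factory(50, seed=7)
        draws = simulate_mk_character(tree, 30.0, 30.0, size=200, seed=1)
        assert abs(draws.to_numpy().mean() - 0.5) < 0.05

    def test_transition_matrix_matches_expm(self):
        for q01, q10, t in [(0.3, 0.8, 0.5), (2.0, 0.1, 1.7), (1.0, 1.0, 0.2)]:
            Q = np.array([[-q01, q01], [q10, -q10]])
            assert np.allclose(
                mk_transition_matrix(q01, q10, t), expm(Q * t), atol=1e-12
            )

    def test_three_tip_likelihood_matches_enumeration(self, three_tip_tree):
        """Brute-force sum over ancestral states with matrix exponentials."""
        q01, q10 = 0.6, 1.1
        Q = np.array([[-q01, q01], [q10, -q10]])
        P1 = expm(Q * 1.0)
        P2 = expm(Q * 2.0)
        states = pd.Series({"A": 1, "B": 0, "C": 1})
        pi = np.array([0.5, 0.5])
        total = 0.0
        for root in (0, 1):
            for anc in (0, 1):
                total += (
                    pi[root]
                    * P1[root, anc]
                    * P1[anc, states["A"]]
                    * P1[anc, states["B"]]
                    * P2[root, states["C"]]
                )
        ll = mk_loglik(three_tip_tree, states, q01, q10, root_freq=0.5)
        assert ll == pytest.approx(np.log(total), abs=1e-10)


class TestCladeDataset:
    def test_study_condition_counts(self):
        data, tree = generate_clade_dataset(SimConfig(seed=5))
        assert len(data) == 192
        n_island = (data["setting"] == "island").sum()
        # binomial draw at p = 68/192: stay within 4 sd of the mean
        assert abs(n_island - 68) < 4 * np.sqrt(192 * (68 / 192) * (124 / 192))
        assert set(data.columns) >= {
            "range_size", "shape_index", "lat_midpoint", "lon_midpoint",
            "setting", "body_mass", "hwi", "dr_rate",
        }
        assert not data.drop(columns="genus").isna().any().any()

    def test_island_ranges_smaller(self):
        data, _ = generate_clade_dataset(SimConfig(seed=6))
        isl = data.loc[data.setting == "island", "range_size"]
        con = data.loc[data.setting == "continental", "range_size"]
        assert np.median(isl) < np.median(con)
        assert (data.range_size > 0).all()

    def test_log_range_moments_match_model(self):
        data, _ = generate_clade_dataset(SimConfig(seed=7))
        cfg = SimConfig()
        con = np.log(data.loc[data.setting == "continental", "range_size"])
        assert abs(con.mean() - cfg.range_size_model.continental_meanlog) < 1.0
        assert abs(con.std() - cfg.range_size_model.continental_sdlog) < 0.8

    def test_missingness_request(self):
        data, _ = generate_clade_dataset(
            SimConfig(n_tips=50, missing_hwi_fraction=0.1, seed=8)
        )
        assert data["hwi"].isna().sum() == 5

    def test_reproducible(self):
        d1, t1 = generate_clade_dataset(SimConfig(n_tips=40, seed=9))
        d2, t2 = generate_clade_dataset(SimConfig(n_tips=40, seed=9))
        pd.testing.assert_frame_equal(d1, d2)
        assert write_newick(t1) == write_newick(t2)

    def test_empty_class_reported(self):
        with pytest.raises(ValueError, match="empty class"):
            generate_clade_dataset(SimConfig(n_tips=10, island_fraction=0.0, seed=1))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(island_fraction=1.5)
        with pytest.raises(ValueError):
            SimConfig(n_tips=1)

    def test_null_coefficients_all_zero(self):
        pc = PathCoefficients.null()
        assert all(v == 0.0 for v in vars(pc).values())
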