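import numpy as np
import pandas as pd
import pytest

from rangediv.mk import mk_loglik, simulate_mk_character
from rangediv.simulate import simulate_bd_tree, simulate_sse_tree
from rangediv.sse import (
    BiSSEParams,
    HiSSEParams,
    ModelSpec,
    akaike_weights,
    bd_loglik,
    binarize_by_threshold,
    bisse_loglik,
    fisse_test,
    fit_sse_model,
    hisse_loglik,
    make_model_set,
)


def _random_case(seed):
    tree = simulate_bd_tree(10, 1.0, 0.3, seed=seed)
    states = simulate_mk_character(tree, 1.0, 1.5, seed=seed + 1)
    if states.nunique() < 2:
        states.iloc[0] = 1 - states.iloc[0]
    return tree, states


def _hisse_tied(lam0, lam1, mu, q01, q10, q_hidden):
    Q = np.zeros((4, 4))
    Q[0, 1] = Q[2, 3] = q01
    Q[1, 0] = Q[3, 2] = q10
    Q[0, 2] = Q[2, 0] = Q[1, 3] = Q[3, 1] = q_hidden
    return HiSSEParams(lam=[lam0, lam1, lam0, lam1], mu=[mu] * 4, Q=Q)


class TestLikelihoodOracles:
    def test_factorization_identity(self):
        """State-independent BiSSE factorizes into birth-death x Mk; both
        factors come from independent closed-form implementations."""
        rng = np.random.default_rng(0)
        for seed in range(10):
            tree, states = _random_case(seed)
            lam, mu = rng.uniform(0.5, 2.0), rng.uniform(0.0, 0.4)
            q01, q10 = rng.uniform(0.2, 1.5, 2)
            p = BiSSEParams(lam, lam, mu, mu, q01, q10)
            for root, mk_root in (("flat", 0.5), ("conditional", "conditional")):
                full = bisse_loglik(tree, states, p, root=root)
                parts = bd_loglik(tree, lam, mu) + mk_loglik(
                    tree, states, q01, q10, root_freq=mk_root
                )
                assert full == pytest.approx(parts, abs=1e-6)

    def test_degenerate_chain_equals_birth_death(self):
        tree = simulate_bd_tree(15, 1.0, 0.2, seed=3)
        states = pd.Series(0, index=[lf.taxon.label for lf in tree.leaf_node_iter()])
        p = BiSSEParams(1.3, 0.7, 0.3, 0.1, 0.0, 0.0)
        ll = bisse_loglik(tree, states, p, root=np.array([1.0, 0.0]))
        assert ll == pytest.approx(bd_loglik(tree, 1.3, 0.3), abs=1e-6)

    def test_hisse_reduces_to_bisse_when_hidden_tied(self):
        for seed in range(5):
            tree, states = _random_case(20 + seed)
            hp = _hisse_tied(1.2, 2.1, 0.3, 0.6, 0.9, 0.7)
            bp = BiSSEParams(1.2, 2.1, 0.3, 0.3, 0.6, 0.9)
            for root in ("flat", "conditional"):
                assert hisse_loglik(tree, states, hp, root=root) == pytest.approx(
                    bisse_loglik(tree, states, bp, root=root), abs=1e-8
                )

    def test_cid_likelihood_invariant_to_observed_permutation(self):
        """Under character-independent diversification the observed states
        carry no rate information beyond the Mk factor's symmetry."""
        tree, states = _random_case(40)
        # CID: lam/mu depend on hidden only; symmetric observed moves
        Q = np.zeros((4, 4))
        Q[0, 1] = Q[1, 0] = Q[2, 3] = Q[3, 2] = 0.8
        Q[0, 2] = Q[2, 0] = Q[1, 3] = Q[3, 1] = 0.5
        cid = HiSSEParams(lam=[1.0, 1.0, 2.5, 2.5], mu=[0.2] * 4, Q=Q)
        base = hisse_loglik(tree, states, cid, root="flat")
        flipped = 1 - states
        assert hisse_loglik(tree, flipped, cid, root="flat") == pytest.approx(
            base, abs=1e-8
        )

    def test_tolerance_convergence(self):
        tree, states = _random_case(50)
        p = BiSSEParams(1.0, 2.0, 0.2, 0.3, 0.5, 0.5)
        a = bisse_loglik(tree, states, p, rtol=1e-8)
        b = bisse_loglik(tree, states, p, rtol=5e-9)
        assert abs(a - b) < 1e-6

    def test_invariant_to_child_rotation(self):
        tree, states = _random_case(60)
        p = BiSSEParams(1.0, 2.0, 0.1, 0.1, 0.4, 0.6)
        base = bisse_loglik(tree, states, p)
        for node in tree.preorder_internal_node_iter():
            node.set_child_nodes(list(reversed(node.child_nodes())))
        assert bisse_loglik(tree, states, p) == pytest.approx(base, abs=1e-9)

    def test_missing_state_rejected(self):
        tree, states = _random_case(70)
        with pytest.raises(KeyError):
            bisse_loglik(tree, states.iloc[:-2], BiSSEParams(1, 1))


class TestModelSet:
    def test_twenty_models(self):
        specs = make_model_set("hisse_binary")
        assert len(specs) == 20
        kinds = pd.Series([s.kind for s in specs]).value_counts()
        assert kinds["hisse"] == 16 and kinds["cid"] == 4
        assert len({s.name for s in specs}) == 20

    def test_cid2_complexity_matches_bisse(self):
        bisse_k = make_model_set("bisse")[0].k
        for spec in make_model_set("hisse_binary"):
            if spec.name.startswith("CID2"):
                assert spec.k == bisse_k == 6

    def test_specs_expand_consistently(self):
        for spec in make_model_set("hisse_binary"):
            theta = np.linspace(0.5, 1.5, spec.k)
            lam, mu, Q = spec.expand(theta)
            assert lam.shape == (spec.n_states,)
            assert (Q >= 0).all() and np.allclose(np.diag(Q), 0.0)

    def test_dual_transition_rejected(self):
        with pytest.raises(ValueError, match="dual"):
            ModelSpec(
                name="bad",
                n_states=4,
                obs_of_state=[0, 1, 0, 1],
                lam_tie=["l"] * 4,
                mu_tie=["m"] * 4,
                q_tie={(0, 3): "q"},
            )

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_model_set("nope")


class TestFitting:
    def test_recovers_rate_asymmetry(self):
        p = BiSSEParams(1.0, 3.0, 0.0, 0.0, 0.3, 0.3)
        tree, states = simulate_sse_tree(p, 200, seed=1)
        fit = fit_sse_model(tree, states, make_model_set("bisse")[0],
                            n_starts=2, seed=2)
        assert fit.params["lam1"] > fit.params["lam0"]

    def test_refit_deterministic(self):
        p = BiSSEParams(1.0, 2.0, 0.0, 0.0, 0.5, 0.5)
        tree, states = simulate_sse_tree(p, 60, seed=3)
        spec = make_model_set("bisse")[0]
        f1 = fit_sse_model(tree, states, spec, n_starts=2, seed=4)
        f2 = fit_sse_model(tree, states, spec, n_starts=2, seed=4)
        assert np.array_equal(f1.theta, f2.theta)

    def test_transition_rate_reliability_flag(self):
        p = BiSSEParams(1.0, 2.0, 0.0, 0.0, 0.5, 0.5)
        tree, states = simulate_sse_tree(p, 60, seed=5)
        fit = fit_sse_model(tree, states, make_model_set("bisse")[0],
                            n_starts=1, seed=6)
        assert not fit.transition_rates_reliable  # 60 < 800 tips


class TestAkaikeWeights:
    def test_equal_aic_splits_evenly(self):
        t = akaike_weights([("a", 3, -10.0, 26.0), ("b", 3, -10.0, 26.0)])
        assert np.allclose(t["weight"], 0.5)

    def test_delta_two_closed_form(self):
        t = akaike_weights([("a", 3, -10.0, 26.0), ("b", 4, -10.0, 28.0)])
        w = 1.0 / (1.0 + np.exp(-1.0))
        assert t.set_index("model")["weight"]["a"] == pytest.approx(w, abs=1e-10)
        assert t.set_index("model")["weight"]["b"] == pytest.approx(1 - w, abs=1e-10)

    def test_shift_invariance_and_normalization(self, rng):
        aics = rng.uniform(100, 120, 8)
        rows = [(f"m{i}", 2, 0.0, a) for i, a in enumerate(aics)]
        shifted = [(f"m{i}", 2, 0.0, a + 57.0) for i, a in enumerate(aics)]
        w1 = akaike_weights(rows)["weight"].to_numpy()
        w2 = akaike_weights(shifted)["weight"].to_numpy()
        assert np.allclose(w1, w2, atol=1e-10)
        assert w1.sum() == pytest.approx(1.0, abs=1e-10)
        assert akaike_weights(rows)["dAIC"].min() == 0.0


class TestBinarize:
    def test_median_rule_tie_convention(self):
        states, info = binarize_by_threshold(
            pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}), "median"
        )
        assert states.tolist() == [0, 0, 1, 1]
        assert info["threshold"] == pytest.approx(2.5)

    def test_fixed_threshold_range_size_extremes(self):
        # the empirical extremes versus the 100,000 km^2 cut
        vals = pd.Series({"smallest": 42.4, "largest": 7306701.0})
        states, _ = binarize_by_threshold(vals, "fixed:100000")
        assert states["smallest"] == 0  # strictly-less-than is "small"
        assert states["largest"] == 1

    def test_quartile_grouping(self):
        vals = pd.Series(np.arange(1.0, 9.0))
        states, info = binarize_by_threshold(vals, "quartile-grouping")
        assert states.iloc[0] == 1 and states.iloc[-1] == 1
        assert states.iloc[3] == 0
        assert info["threshold_low"] < info["threshold_high"]

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            binarize_by_threshold(pd.Series([2.0, 2.0, 2.0]), "median")

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            binarize_by_threshold(pd.Series([1.0, -1.0]), "median")


class TestFiSSE:
    def test_deterministic_under_seed(self):
        p = BiSSEParams(1.0, 2.0, 0.0, 0.0, 0.5, 0.5)
        tree, states = simulate_sse_tree(p, 80, seed=7)
        r1 = fisse_test(tree, states, n_sim=100, seed=8)
        r2 = fisse_test(tree, states, n_sim=100, seed=8)
        assert r1.pvalue == r2.pvalue and r1.statistic == r2.statistic

    def test_single_state_rejected(self):
        tree = simulate_bd_tree(30, 1.0, 0.0, seed=9)
        states = pd.Series(0, index=[lf.taxon.label for lf in tree.leaf_node_iter()])
        with pytest.raises(ValueError, match="both states"):
            fisse_test(tree, states, n_sim=100, seed=0)

    def test_pvalue_in_unit_interval(self):
        p = BiSSEParams(1.0, 1.0, 0.0, 0.0, 1.0, 1.0)
        for seed in range(5):
            tree, states = simulate_sse_tree(p, 50, seed=seed)
            res = fisse_test(tree, states, n_sim=100, seed=seed)
            assert 0.0 < res.pvalue <= 1.0
            assert res.lam0 > 0 and res.lam1 > 0
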