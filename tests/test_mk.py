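import numpy as np
import pytest
from scipy import stats

import stripevol as sv
from stripevol.mk import (MkModel, MorphCoding, aicc_table, build_model_matrix,
                          enumerate_codings, fit_mk, likelihood_ratio_test,
                          marginal_asr, mk_loglik, transition_matrices)
from stripevol.simulate import simulate_bd_tree, simulate_mk
from stripevol.tree import parse_tree

from _oracles import brute_mk_loglik, brute_node_posteriors, expm_series
from conftest import random_q


class TestConstraints:
    def test_model_i_all_free(self):
        spec = build_model_matrix("i", 4)
        assert spec.n_free == 12

    def test_model_ii_symmetric(self):
        spec = build_model_matrix("ii", 4)
        assert spec.n_free == 6
        assert np.array_equal(spec.index, spec.index.T)

    def test_model_iii_zero_set(self):
        # loss/gain of two or more stripes forbidden: q31=q41=q42=q13=q14=q24=0
        spec = build_model_matrix("iii", 4)
        zero_cells = {(2, 0), (3, 0), (3, 1), (0, 2), (0, 3), (1, 3)}
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                assert (spec.index[i, j] == 0) == ((i, j) in zero_cells)
        assert spec.n_free == 6

    def test_model_iv_three_adjacent_classes(self):
        spec = build_model_matrix("iv", 4)
        assert spec.n_free == 3
        assert spec.index[0, 1] == spec.index[1, 0]
        assert spec.index[1, 2] == spec.index[2, 1]
        assert spec.index[2, 3] == spec.index[3, 2]
        assert spec.index[0, 2] == 0 and spec.index[0, 3] == 0

    def test_model_ii_two_states(self):
        assert build_model_matrix("ii", 2).n_free == 1

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            build_model_matrix("v", 4)
        with pytest.raises(ValueError, match="4-state"):
            build_model_matrix("iii", 3)

    def test_build_q_rows_sum_to_zero(self):
        spec = build_model_matrix("i", 4)
        Q = spec.build_q(np.arange(1.0, 13.0))
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)


class TestTransitionMatrices:
    def test_matches_series_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            k = int(rng.integers(2, 5))
            Q = random_q(rng, k, scale=2.0)
            t = float(rng.uniform(0, 10.0 / max(np.abs(Q).max(), 1e-9)))
            P = transition_matrices(Q, np.array([t]))[0]
            assert np.max(np.abs(P - expm_series(Q, t))) < 1e-10

    def test_probability_conservation(self):
        rng = np.random.default_rng(1)
        Q = random_q(rng, 4, scale=0.5)
        for t in (0.0, 0.5, 5.0, 100.0):
            P = transition_matrices(Q, np.array([t]))[0]
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(P >= 0)


class TestLoglik:
    def test_zero_rates_single_state(self):
        t = parse_tree("((A:1,B:1):1,C:2);")
        coding = MorphCoding.from_dict({"A": 1, "B": 1, "C": 1}, k=4)
        ll = mk_loglik(t, coding, np.zeros((4, 4)))
        assert ll == pytest.approx(np.log(0.25))

    def test_impossible_history_zero_length(self):
        t = parse_tree("(A:0,B:0);")
        coding = MorphCoding.from_dict({"A": 0, "B": 1}, k=2)
        Q = np.array([[-0.5, 0.5], [0.5, -0.5]])
        assert mk_loglik(t, coding, Q) == -np.inf

    def test_missing_tip_coding_rejected(self, tree12):
        coding = MorphCoding.from_dict({tree12.tip_labels[0]: 0}, k=2)
        Q = np.array([[-0.1, 0.1], [0.1, -0.1]])
        with pytest.raises(ValueError, match="absent"):
            mk_loglik(tree12, coding, Q)

    def test_invalid_q_rejected(self, tree12):
        coding = MorphCoding.from_dict({lab: 0 for lab in tree12.tip_labels}, k=2)
        with pytest.raises(ValueError):
            mk_loglik(tree12, coding, np.array([[0.1, -0.1], [0.1, -0.1]]))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 6))
        tree = simulate_bd_tree(0.5, 0.1, n, seed=int(rng.integers(2**31)))
        k = int(rng.integers(2, 5))
        Q = random_q(rng, k)
        sim = simulate_mk(tree, Q, seed=int(rng.integers(2**31)))
        prior = np.full(k, 1.0 / k)
        assert mk_loglik(tree, sim.coding, Q) == pytest.approx(
            brute_mk_loglik(tree, sim.coding, Q, prior), abs=1e-10)

    def test_polymorphic_ambiguity_matches_enumeration(self):
        tree = simulate_bd_tree(0.5, 0.0, 4, seed=11)
        rng = np.random.default_rng(2)
        Q = random_q(rng, 3)
        states = {lab: (0,) for lab in tree.tip_labels}
        states[tree.tip_labels[0]] = (0, 2)
        coding = MorphCoding(states=states, k=3)
        prior = np.full(3, 1 / 3)
        got = mk_loglik(tree, coding, Q, polymorphic="ambiguous")
        assert got == pytest.approx(brute_mk_loglik(tree, coding, Q, prior), abs=1e-10)
        with pytest.raises(ValueError, match="polymorphic"):
            mk_loglik(tree, coding, Q)

    def test_state_relabeling_invariance(self, tree12):
        rng = np.random.default_rng(3)
        Q = random_q(rng, 4)
        sim = simulate_mk(tree12, Q, seed=5)
        perm = rng.permutation(4)
        Qp = Q[np.ix_(perm, perm)]
        relabeled = MorphCoding.from_dict(
            {sp: int(np.argwhere(perm == st[0])[0, 0])
             for sp, st in sim.coding.states.items()}, k=4)
        assert mk_loglik(tree12, sim.coding, Q) == pytest.approx(
            mk_loglik(tree12, relabeled, Qp), abs=1e-10)


class TestFit:
    def test_er_rate_recovery(self):
        # symmetric q = 0.1 on 300-tip trees: MLE within 50% in >= 90% of reps
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(200 + rep)
            tree = simulate_bd_tree(0.3, 0.05, 300, seed=int(rng.integers(2**31)))
            Q = np.array([[-0.1, 0.1], [0.1, -0.1]])
            sim = simulate_mk(tree, Q, seed=int(rng.integers(2**31)))
            fit = MkModel(tree, sim.coding, MkModel.er_spec(2)).fit(n_starts=3, seed=0)
            hits += abs(fit.rates[0] - 0.1) / 0.1 <= 0.5
        assert hits >= 18

    def test_single_state_data(self, tree12):
        coding = MorphCoding.from_dict({lab: 2 for lab in tree12.tip_labels}, k=4)
        fit = MkModel(tree12, coding, MkModel.er_spec(4)).fit(seed=0)
        assert np.all(fit.rates <= 1e-8)
        assert fit.llf == pytest.approx(np.log(0.25), abs=1e-4)

    def test_nested_model_never_beats_full(self, tree12):
        rng = np.random.default_rng(7)
        Q = random_q(rng, 3, scale=0.3)
        sim = simulate_mk(tree12, Q, seed=8)
        er = MkModel(tree12, sim.coding, MkModel.er_spec(3)).fit(n_starts=3, seed=0)
        ard = MkModel(tree12, sim.coding, MkModel.ard_spec(3)).fit(n_starts=3, seed=0)
        assert er.llf <= ard.llf + 1e-6

    def test_fit_reproducible_under_seed(self, tree12):
        rng = np.random.default_rng(9)
        Q = random_q(rng, 2, scale=0.2)
        sim = simulate_mk(tree12, Q, seed=10)
        f1 = MkModel(tree12, sim.coding, MkModel.er_spec(2)).fit(n_starts=4, seed=123)
        f2 = MkModel(tree12, sim.coding, MkModel.er_spec(2)).fit(n_starts=4, seed=123)
        assert np.array_equal(f1.rates, f2.rates)
        assert f1.llf == f2.llf


class TestLRT:
    def test_equal_likelihoods(self):
        class F:
            def __init__(self, llf, df):
                self.llf, self.df_model = llf, df

        stat, df, p = likelihood_ratio_test(F(-10.0, 1), F(-10.0, 3))
        assert stat == 0.0 and df == 2 and p == pytest.approx(1.0)

    def test_chi_square_critical_value(self):
        class F:
            def __init__(self, llf, df):
                self.llf, self.df_model = llf, df

        stat, df, p = likelihood_ratio_test(F(0.0, 1), F(3.841 / 2, 2))
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(3.841, 1), abs=1e-12)
        assert p == pytest.approx(0.05, abs=1e-3)

    def test_er_vs_ard_df_is_11(self, tree12):
        rng = np.random.default_rng(11)
        Q = random_q(rng, 4, scale=0.2)
        sim = simulate_mk(tree12, Q, seed=12)
        er = MkModel(tree12, sim.coding, MkModel.er_spec(4)).fit(n_starts=2, seed=0)
        ard = MkModel(tree12, sim.coding, MkModel.ard_spec(4)).fit(n_starts=2, seed=0)
        _, df, _ = likelihood_ratio_test(er, ard)
        assert df == 11

    def test_negative_statistic_flags_optimizer_failure(self):
        class F:
            def __init__(self, llf, df):
                self.llf, self.df_model = llf, df

        with pytest.raises(RuntimeError, match="worse"):
            likelihood_ratio_test(F(-5.0, 1), F(-6.0, 2))


class TestAiccTable:
    class _Fit:
        def __init__(self, llf, k, name, nobs=50):
            self.llf, self.df_model, self.name, self.nobs = llf, k, name, nobs

    def test_single_model_weight_one(self):
        df = aicc_table([self._Fit(-50.0, 2, "only")])
        assert df["weight"].iloc[0] == pytest.approx(1.0)
        assert df["dAICc"].iloc[0] == 0.0

    def test_identical_models_split_weight(self):
        df = aicc_table([self._Fit(-50.0, 2, "a"), self._Fit(-50.0, 2, "b")])
        assert np.allclose(df["weight"], 0.5)

    def test_delta_four_weights(self):
        # AICc {100, 104}: weights exp(0)/(exp(0)+exp(-2)) = .8808, .1192
        fits = [self._Fit(-(100 - 2 * 1 - 2 * 1 * 2 / (50 - 1 - 1)) / 2, 1, "good"),
                self._Fit(-(104 - 2 * 1 - 2 * 1 * 2 / (50 - 1 - 1)) / 2, 1, "bad")]
        df = aicc_table(fits)
        assert df["AICc"].iloc[0] == pytest.approx(100.0)
        assert df["dAICc"].iloc[1] == pytest.approx(4.0)
        assert df["weight"].iloc[0] == pytest.approx(0.8808, abs=1e-4)
        assert df["weight"].iloc[1] == pytest.approx(0.1192, abs=1e-4)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(13)
        fits = [self._Fit(-float(rng.uniform(40, 90)), int(rng.integers(1, 8)), f"m{i}")
                for i in range(6)]
        assert aicc_table(fits)["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="n="):
            aicc_table([self._Fit(-10.0, 5, "m", nobs=6)])

    def test_reports_both_aic_and_aicc(self):
        df = aicc_table([self._Fit(-50.0, 2, "m")])
        assert "AIC" in df.columns and "AICc" in df.columns
        assert df["AICc"].iloc[0] > df["AIC"].iloc[0]


class TestMarginalAsr:
    def test_tips_are_point_masses(self, tree12):
        rng = np.random.default_rng(14)
        Q = random_q(rng, 4, scale=0.2)
        sim = simulate_mk(tree12, Q, seed=15)
        post = marginal_asr(tree12, sim.coding, Q)
        for i, lab in enumerate(tree12.tip_labels):
            assert post[i, sim.coding.states[lab][0]] == pytest.approx(1.0)

    def test_symmetric_cherry_root_is_half_half(self):
        t = parse_tree("(A:1,B:1);")
        coding = MorphCoding.from_dict({"A": 0, "B": 1}, k=2)
        Q = np.array([[-0.3, 0.3], [0.3, -0.3]])
        post = marginal_asr(t, coding, Q)
        assert np.allclose(post[t.root], [0.5, 0.5], atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_joint_enumeration(self, seed):
        rng = np.random.default_rng(30 + seed)
        tree = simulate_bd_tree(0.5, 0.0, 4, seed=int(rng.integers(2**31)))
        k = int(rng.integers(2, 4))
        Q = random_q(rng, k)
        sim = simulate_mk(tree, Q, seed=int(rng.integers(2**31)))
        prior = np.full(k, 1.0 / k)
        got = marginal_asr(tree, sim.coding, Q)
        want = brute_node_posteriors(tree, sim.coding, Q, prior)
        assert np.max(np.abs(got - want)) < 1e-10

    def test_rows_sum_to_one(self, tree12):
        rng = np.random.default_rng(16)
        Q = random_q(rng, 3)
        sim = simulate_mk(tree12, Q, seed=17)
        post = marginal_asr(tree12, sim.coding, Q)
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-12)


class TestCodings:
    def test_three_polymorphic_species_give_eight(self):
        states = {"a": (0,), "b": (0, 1), "c": (1, 2), "d": (2, 3), "e": (3,)}
        coding = MorphCoding(states=states, k=4)
        combos = enumerate_codings(coding)
        assert len(combos) == 8
        assert all(c.is_resolved for c in combos)
        # deterministic order
        again = enumerate_codings(coding)
        assert [c.states for c in again] == [c.states for c in combos]

    def test_monomorphic_gives_one(self):
        coding = MorphCoding.from_dict({"a": 0, "b": 1}, k=4)
        assert len(enumerate_codings(coding)) == 1

    def test_two_polymorphic_give_four(self):
        coding = MorphCoding(states={"a": (0, 1), "b": (2, 3), "c": (1,)}, k=4)
        assert len(enumerate_codings(coding)) == 4

    def test_fixture_has_eight_combinations(self, fixture27):
        assert fixture27.n_coding_combinations == 8
        assert len(enumerate_codings(fixture27.stripes)) == 8
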