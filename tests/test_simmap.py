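import numpy as np
import pytest

from stripevol.mk import MorphCoding, marginal_asr
from stripevol.simmap import (_Bridge, count_trajectory_transitions,
                              sample_histories, summarize)
from stripevol.simulate import simulate_bd_tree, simulate_mk
from stripevol.tree import parse_tree

from _oracles import bridge_expected_transitions
from conftest import random_q


@pytest.fixture(scope="module")
def small_case():
    tree = simulate_bd_tree(0.4, 0.1, 6, seed=11)
    Q = np.array([[-0.2, 0.2], [0.3, -0.3]])
    sim = simulate_mk(tree, Q, seed=3)
    return tree, Q, sim.coding


class TestSampling:
    def test_near_zero_rates_give_constant_histories(self, tree12):
        coding = MorphCoding.from_dict({lab: 1 for lab in tree12.tip_labels}, k=3)
        Q = random_q(np.random.default_rng(0), 3, scale=1e-9)
        ens = sample_histories(tree12, coding, Q, n_maps=50, seed=0)
        for h in ens.histories:
            assert all(bh.n_changes == 0 for bh in h.branches.values())
            assert np.all(h.node_states == 1)

    def test_node_frequencies_match_marginal_asr(self, small_case):
        tree, Q, coding = small_case
        n = 4000
        ens = sample_histories(tree, coding, Q, n_maps=n, seed=0)
        freq = summarize(ens).node_frequencies
        asr = marginal_asr(tree, coding, Q)
        se = np.sqrt(asr * (1 - asr) / n)
        assert np.all(np.abs(freq - asr) <= 3.5 * np.maximum(se, 1e-12) + 1e-12)

    def test_histories_consistent_with_tips_and_endpoints(self, small_case):
        tree, Q, coding = small_case
        ens = sample_histories(tree, coding, Q, n_maps=30, seed=1)
        for h in ens.histories:
            for i, lab in enumerate(tree.tip_labels):
                assert h.node_states[i] == coding.states[lab][0]
            for c, bh in h.branches.items():
                assert bh.segments[0][0] == h.node_states[tree.parent[c]]
                assert bh.segments[-1][0] == h.node_states[c]
                assert bh.length == pytest.approx(tree.branch_lengths[c], abs=1e-9)
                states = [s for s, _ in bh.segments]
                assert all(a != b for a, b in zip(states, states[1:]))

    def test_seed_reproducible(self, small_case):
        tree, Q, coding = small_case
        e1 = sample_histories(tree, coding, Q, n_maps=20, seed=7)
        e2 = sample_histories(tree, coding, Q, n_maps=20, seed=7)
        for h1, h2 in zip(e1.histories, e2.histories):
            assert np.array_equal(h1.node_states, h2.node_states)
            assert h1.branches == h2.branches

    def test_root_state_distribution_within_binomial_bounds(self, small_case):
        # spec'd property: empirical root draws vs analytic posterior, 99% bounds
        tree, Q, coding = small_case
        n = 10_000
        ens = sample_histories(tree, coding, Q, n_maps=n, seed=0)
        freq = summarize(ens).node_frequencies[tree.root]
        post = marginal_asr(tree, coding, Q)[tree.root]
        half = 2.576 * np.sqrt(post * (1 - post) / n)
        assert np.all(np.abs(freq - post) <= half + 1e-12)


class TestBridge:
    def test_expected_transitions_match_numerical_integration(self):
        Q = np.array([[-0.4, 0.4], [0.6, -0.6]])
        t, a, b = 1.5, 0, 1
        from scipy.linalg import expm
        p_ab = expm(Q * t)[a, b]
        br = _Bridge(Q)
        rng = np.random.default_rng(0)
        n = 6000
        counts = [sum(br.sample(a, b, t, p_ab, rng).transition_counts(2).sum()
                      for _ in range(1)) for _ in range(n)]
        want = bridge_expected_transitions(Q, t, a, b)
        got = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(n)
        assert abs(got - want) < 3.5 * se

    def test_bridge_against_rejection_sampler(self):
        # naive forward rejection sampling as the cross-validation oracle
        Q = np.array([[-0.5, 0.5], [0.8, -0.8]])
        t, a, b = 1.0, 0, 0
        rng = np.random.default_rng(1)
        rej = []
        while len(rej) < 3000:
            s, time_left, changes = a, t, 0
            while True:
                w = rng.exponential(1.0 / -Q[s, s])
                if w >= time_left:
                    break
                s = 1 - s
                changes += 1
                time_left -= w
            if s == b:
                rej.append(changes)
        from scipy.linalg import expm
        p_ab = expm(Q * t)[a, b]
        br = _Bridge(Q)
        uni = [br.sample(a, b, t, p_ab, rng).n_changes for _ in range(3000)]
        se = np.sqrt(np.var(rej, ddof=1) / 3000 + np.var(uni, ddof=1) / 3000)
        assert abs(np.mean(rej) - np.mean(uni)) < 3.5 * se
        # even-change parity must hold exactly for matching endpoints
        assert all(c % 2 == 0 for c in uni)

    def test_zero_length_branch_same_state(self):
        Q = np.array([[-0.5, 0.5], [0.5, -0.5]])
        br = _Bridge(Q)
        h = br.sample(1, 1, 0.0, 1.0, np.random.default_rng(0))
        assert h.segments == ((1, 0.0),)


class TestSummaries:
    def test_dwell_time_conservation(self, small_case):
        tree, Q, coding = small_case
        ens = sample_histories(tree, coding, Q, n_maps=50, seed=2)
        for h in ens.histories:
            tot = sum(bh.length for bh in h.branches.values())
            assert tot == pytest.approx(tree.total_length(), rel=1e-9)
        summ = summarize(ens)
        assert summ.dwell_times.sum() == pytest.approx(tree.total_length(), rel=1e-9)

    def test_transition_counts_match_independent_recount(self, small_case):
        tree, Q, coding = small_case
        ens = sample_histories(tree, coding, Q, n_maps=200, seed=3)
        summ = summarize(ens)
        # independent recount: per-history segment-change totals
        totals = [sum(len(bh.segments) - 1 for bh in h.branches.values())
                  for h in ens.histories]
        assert summ.transition_counts.sum() == pytest.approx(np.mean(totals), rel=1e-12)

    def test_seed_invariance_within_mc_error(self, small_case):
        tree, Q, coding = small_case
        f1 = summarize(sample_histories(tree, coding, Q, n_maps=3000, seed=4))
        f2 = summarize(sample_histories(tree, coding, Q, n_maps=3000, seed=5))
        se = np.sqrt(f1.node_frequencies * (1 - f1.node_frequencies) / 3000)
        assert np.all(np.abs(f1.node_frequencies - f2.node_frequencies)
                      <= 5 * np.maximum(se, 1e-3))

    def test_monte_carlo_error_shrinks_with_sqrt_n(self, small_case):
        tree, Q, coding = small_case
        v = tree.root
        ses = []
        for n in (100, 1000):
            vals = [summarize(sample_histories(tree, coding, Q, n_maps=n,
                                               seed=100 + 17 * i + n)
                              ).node_frequencies[v, 0]
                    for i in range(12)]
            ses.append(np.std(vals, ddof=1))
        ratio = ses[0] / ses[1]
        assert 1.6 < ratio < 6.5  # ~sqrt(10), wide Monte-Carlo slack


class TestTrajectoryTransitions:
    def test_uniform_data_no_transitions(self, tree12):
        coding = MorphCoding.from_dict({lab: 0 for lab in tree12.tip_labels}, k=2)
        Q = np.array([[-1e-6, 1e-6], [1e-6, -1e-6]])
        summ = summarize(sample_histories(tree12, coding, Q, n_maps=200, seed=0))
        assert count_trajectory_transitions(summ) == set()

    def test_recovers_single_clade_stem_branch(self):
        # one derived clade nested in an ancestral background: the stem branch
        # of the clade is the unique majority-state change at threshold 0.5
        t = parse_tree("(((A:1,B:1):3,(C:1,D:1):3):2,(E:3,F:3):3);")
        coding = MorphCoding.from_dict(
            {"A": 1, "B": 1, "C": 0, "D": 0, "E": 0, "F": 0}, k=2)
        Q = np.array([[-0.05, 0.05], [0.05, -0.05]])
        summ = summarize(sample_histories(t, coding, Q, n_maps=3000, seed=0))
        changed = count_trajectory_transitions(summ, threshold=0.5)
        # the changed branches must include the stem of (A,B) and only
        # branches on the path into that clade
        ab_tips = {t.tip_index()["A"], t.tip_index()["B"]}
        stem = [v for v in range(t.n_nodes)
                if not t.is_tip(v) and
                {c for c in t.children[v]} == ab_tips][0]
        assert stem in changed
        assert len(changed) == 1

    def test_strict_threshold_is_subset(self, small_case):
        tree, Q, coding = small_case
        summ = summarize(sample_histories(tree, coding, Q, n_maps=2000, seed=1))
        assert count_trajectory_transitions(summ, 1.0) <= \
            count_trajectory_transitions(summ, 0.5)
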