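"""Stochastic character mapping: sampled full histories of a discrete trait.

A stochastic map is one complete realization of the character everywhere on
the tree — a state at every node and a piecewise-constant path along every
branch — drawn from the distribution of histories conditional on the tip data
and a fixed transition-rate matrix Q (the empirical MLE, following the
standard empirical-Bayes practice).  Ensembles of maps summarize ancestral
states, expected transition counts and state dwell times; for the clownfish
analyses they reveal the caudo-rostral sequence of stripe losses and the
minimum number of ontogenetic-trajectory shifts.

Endpoint-conditioned branch paths are drawn by uniformization: the CTMC is
embedded in a Poisson process of candidate jump times at the dominating rate
Omega = max_i |Q_ii|, the number of candidate jumps is drawn from its exact
conditional distribution given the branch endpoints, and the jump chain is
filled in by a backward pass through powers of the uniformized kernel
R = I + Q/Omega.  Self-transitions are then collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mk import MorphCoding, _pruning, _root_prior_vector, _tip_partials, _validate_q, marginal_asr, transition_matrices
from .tree import PhyloTree

__all__ = [
    "BranchHistory",
    "TreeHistory",
    "SimmapEnsemble",
    "EnsembleSummary",
    "sample_histories",
    "summarize",
    "count_trajectory_transitions",
]


@dataclass(frozen=True)
class BranchHistory:
    """Ordered (state, duration) segments along one branch, parent to child.

    Durations sum to the branch length; adjacent segments differ in state;
    the first state is the parent node's sampled state and the last the
    child's.
    """

    segments: tuple[tuple[int, float], ...]

    @property
    def n_changes(self) -> int:
        return len(self.segments) - 1

    @property
    def length(self) -> float:
        return float(sum(d for _, d in self.segments))

    def dwell_times(self, k: int) -> np.ndarray:
        out = np.zeros(k)
        for s, d in self.segments:
            out[s] += d
        return out

    def transition_counts(self, k: int) -> np.ndarray:
        out = np.zeros((k, k))
        for (s0, _), (s1, _) in zip(self.segments[:-1], self.segments[1:]):
            out[s0, s1] += 1
        return out


@dataclass(frozen=True)
class TreeHistory:
    """One complete stochastic map: node states plus per-branch histories."""

    node_states: np.ndarray               # (n_nodes,) int
    branches: dict[int, BranchHistory]    # keyed by child node id (root absent)


@dataclass
class SimmapEnsemble:
    """A sample of complete character histories conditional on the tip data."""

    tree: PhyloTree
    coding: MorphCoding
    Q: np.ndarray
    histories: list[TreeHistory]
    seed: int | None

    @property
    def n_maps(self) -> int:
        return len(self.histories)

    @property
    def k(self) -> int:
        return self.coding.k

    def history_newick(self, i: int, precision: int = 6) -> str:
        """Serialize history ``i`` in simmap-annotated Newick
        (``:{state,time:state,time}`` per branch, child-to-parent order)."""
        h = self.histories[i]
        t = self.tree
        fmt = f"%.{precision}g"

        def annot(v: int) -> str:
            segs = list(h.branches[v].segments)[::-1]  # simmap lists child-end first
            lab = self.coding.state_label
            return "{" + ":".join(f"{lab(s)},{fmt % d}" for s, d in segs) + "}"

        def rec(v: int) -> str:
            if t.is_tip(v):
                core = t.tip_labels[v]
            else:
                core = "(" + ",".join(rec(c) for c in t.children[v]) + ")"
            if v == t.root:
                return core
            return core + ":" + annot(v)

        return rec(t.root) + ";"


@dataclass
class EnsembleSummary:
    """Ensemble means over stochastic maps."""

    node_frequencies: np.ndarray     # (n_nodes, k) sampled-state frequencies
    transition_counts: np.ndarray    # (k, k) expected number of i->j changes
    dwell_times: np.ndarray          # (k,) expected total time in each state
    n_maps: int
    tree: PhyloTree
    k: int

    def majority_state(self, v: int, threshold: float = 0.5) -> int | None:
        """State with frequency >= threshold at node v, if any."""
        s = int(np.argmax(self.node_frequencies[v]))
        return s if self.node_frequencies[v, s] >= threshold else None


# ---------------------------------------------------------------------------
# Uniformization bridge
# ---------------------------------------------------------------------------

class _Bridge:
    """Endpoint-conditioned path sampler for one Q, caching powers of R."""

    def __init__(self, Q: np.ndarray, retry_cap: int = 10_000):
        self.Q = Q
        self.k = Q.shape[0]
        self.omega = float(np.max(-np.diag(Q)))
        self.retry_cap = retry_cap
        if self.omega > 0:
            self.R = np.eye(self.k) + Q / self.omega
            self._Rpow = [np.eye(self.k), self.R]
        else:
            self.R = np.eye(self.k)
            self._Rpow = [np.eye(self.k)]

    def rpow(self, n: int) -> np.ndarray:
        while len(self._Rpow) <= n:
            self._Rpow.append(self._Rpow[-1] @ self.R)
        return self._Rpow[n]

    def sample(self, a: int, b: int, t: float, p_ab: float, rng: np.random.Generator) -> BranchHistory:
        """One path on a branch of length t with endpoints a -> b.

        ``p_ab`` is the known transition probability exp(Qt)[a, b] (from the
        pruning pass), used to normalize the jump-count distribution.
        """
        if t == 0.0 or self.omega == 0.0:
            if a != b:
                raise RuntimeError("impossible endpoints on a zero-rate/zero-length branch")
            return BranchHistory(segments=((a, t),))
        mu = self.omega * t
        # jump count N | endpoints: P(N=n) ∝ Poisson(mu, n) * R^n[a, b]
        n_cap = int(np.ceil(mu + 10.0 * np.sqrt(mu) + 50.0))
        target = rng.random() * p_ab
        term = np.exp(-mu)  # Poisson(mu, 0)
        acc = term * (1.0 if a == b else 0.0)
        n = 0
        while acc < target and n < n_cap:
            n += 1
            term *= mu / n
            acc += term * self.rpow(n)[a, b]
        # backward-filled jump chain through R
        states = [a]
        for j in range(1, n):
            prev = states[-1]
            w = self.R[prev, :] * self.rpow(n - j)[:, b]
            tot = w.sum()
            if tot <= 0:
                raise RuntimeError("uniformization jump-chain dead end")
            states.append(int(rng.choice(self.k, p=w / tot)))
        if n >= 1:
            states.append(b)
        times = np.sort(rng.random(n)) * t
        # collapse virtual (self) jumps into segments
        bounds = np.concatenate([[0.0], times, [t]])
        segs: list[tuple[int, float]] = []
        for s, d in zip(states, np.diff(bounds)):
            if segs and segs[-1][0] == s:
                segs[-1] = (s, segs[-1][1] + float(d))
            else:
                segs.append((s, float(d)))
        return BranchHistory(segments=tuple(segs))


def sample_histories(
    tree: PhyloTree,
    coding: MorphCoding,
    Q: np.ndarray,
    root_prior="uniform",
    n_maps: int = 10_000,
    seed: int | None = 0,
    polymorphic: str = "error",
) -> SimmapEnsemble:
    """Draw ``n_maps`` stochastic character maps conditional on tip data and Q.

    Node states are drawn jointly (root from its posterior, then each child
    conditional on its parent and the subtree partials); branch interiors are
    endpoint-conditioned CTMC bridges by uniformization.  Deterministic given
    ``seed``.
    """
    k = coding.k
    Q = _validate_q(Q, k)
    pi = _root_prior_vector(root_prior, Q, k)
    L_tips = _tip_partials(tree, coding, k, polymorphic)
    P = transition_matrices(Q, tree.branch_lengths)
    L, logscale = _pruning(tree, L_tips, P)
    if not np.isfinite(logscale[tree.root]) or (pi * L[tree.root]).sum() <= 0:
        raise ValueError("tip data impossible under Q: cannot sample histories")
    rng = np.random.default_rng(seed)
    bridge = _Bridge(Q)
    root = tree.root
    root_post = pi * L[root]
    root_post = root_post / root_post.sum()
    preorder = tree.postorder[::-1]
    histories: list[TreeHistory] = []
    for _ in range(n_maps):
        node_states = np.empty(tree.n_nodes, dtype=int)
        node_states[root] = rng.choice(k, p=root_post)
        branches: dict[int, BranchHistory] = {}
        for v in preorder:
            for c in tree.children[v]:
                w = P[c][node_states[v], :] * L[c]
                tot = w.sum()
                if tot <= 0:
                    raise RuntimeError(f"no consistent state for node {c}")
                sc = int(rng.choice(k, p=w / tot))
                node_states[c] = sc
                branches[c] = bridge.sample(
                    node_states[v], sc, float(tree.branch_lengths[c]),
                    float(P[c][node_states[v], sc]), rng,
                )
        histories.append(TreeHistory(node_states=node_states, branches=branches))
    return SimmapEnsemble(tree=tree, coding=coding, Q=Q, histories=histories, seed=seed)


def summarize(ensemble: SimmapEnsemble) -> EnsembleSummary:
    """Ensemble means: node-state frequencies, transition counts, dwell times."""
    if ensemble.n_maps == 0:
        raise ValueError("empty ensemble")
    t, k = ensemble.tree, ensemble.k
    freq = np.zeros((t.n_nodes, k))
    trans = np.zeros((k, k))
    dwell = np.zeros(k)
    for h in ensemble.histories:
        freq[np.arange(t.n_nodes), h.node_states] += 1.0
        for bh in h.branches.values():
            trans += bh.transition_counts(k)
            dwell += bh.dwell_times(k)
    n = ensemble.n_maps
    return EnsembleSummary(
        node_frequencies=freq / n,
        transition_counts=trans / n,
        dwell_times=dwell / n,
        n_maps=n,
        tree=t,
        k=k,
    )


def count_trajectory_transitions(summary: EnsembleSummary, threshold: float = 0.5) -> set[int]:
    """Branches carrying a change of majority state (child node ids).

    A node's majority state is the state whose posterior frequency across the
    ensemble is >= ``threshold``; a branch is counted when parent and child
    both have majorities and they differ.  The size of the returned set is
    the reported minimum number of major transitions (e.g. the five shifts in
    ontogenetic stripe loss across clownfishes at threshold 0.5).
    """
    t = summary.tree
    out: set[int] = set()
    for v in range(t.n_nodes):
        p = t.parent[v]
        if p < 0:
            continue
        ms_child = summary.majority_state(v, threshold)
        ms_parent = summary.majority_state(int(p), threshold)
        if ms_child is not None and ms_parent is not None and ms_child != ms_parent:
            out.add(v)
    return out
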