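"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: exhaustive enumeration over internal
node states, truncated power series for the matrix exponential, dense
numerical quadrature for bridge expectations.  None of it shares code with
the implementation paths it checks.
"""

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm


def brute_mk_loglik(tree, coding, Q, prior):
    """Sum over all internal-node state assignments of path-probability products."""
    k = Q.shape[0]
    P = [expm(Q * t) for t in tree.branch_lengths]
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    tipstate = {i: coding.states[lab] for i, lab in enumerate(tree.tip_labels)}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = dict(zip(internal, assign))
        # marginalize polymorphic/ambiguous tips too
        tip_choices = [tipstate[i] for i in range(tree.n_tips)]
        for tips in itertools.product(*tip_choices):
            st.update(dict(enumerate(tips)))
            pr = prior[st[tree.root]]
            for v in range(tree.n_nodes):
                p = tree.parent[v]
                if p >= 0:
                    pr *= P[v][st[p], st[v]]
            total += pr
    return np.log(total) if total > 0 else -np.inf


def brute_node_posteriors(tree, coding, Q, prior):
    """Joint enumeration posterior over states at every node."""
    k = Q.shape[0]
    P = [expm(Q * t) for t in tree.branch_lengths]
    internal = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    tipstate = {i: coding.states[lab][0] for i, lab in enumerate(tree.tip_labels)}
    post = np.zeros((tree.n_nodes, k))
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = dict(zip(internal, assign))
        st.update(tipstate)
        pr = prior[st[tree.root]]
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p >= 0:
                pr *= P[v][st[p], st[v]]
        total += pr
        for v in range(tree.n_nodes):
            post[v, st[v]] += pr
    return post / total


def expm_series(Q, t, n_terms=120):
    """Truncated Taylor series for exp(Q t); adequate for ||Q t|| <= 10."""
    A = Q * t
    out = np.eye(Q.shape[0])
    term = np.eye(Q.shape[0])
    for n in range(1, n_terms):
        term = term @ A / n
        out = out + term
    return out


def bridge_expected_transitions(Q, t, a, b):
    """E[# i->j changes | X(0)=a, X(t)=b] by dense numerical integration.

    E[N_ij] = q_ij * int_0^t P_ai(s) P_jb(t-s) ds / P_ab(t), summed over all
    ordered state pairs i != j.
    """
    k = Q.shape[0]
    p_ab = expm(Q * t)[a, b]
    total = 0.0
    for i in range(k):
        for j in range(k):
            if i == j or Q[i, j] == 0:
                continue
            val, _ = quad(
                lambda s: expm(Q * s)[a, i] * expm(Q * (t - s))[j, b], 0, t,
                limit=200,
            )
            total += Q[i, j] * val / p_ab
    return total


def vcv_by_mrca_paths(tree):
    """Per-pair shared root-path length by explicit ancestor-path intersection."""
    n = tree.n_tips

    def path(v):
        out = []
        while v >= 0:
            out.append(v)
            v = tree.parent[v]
        return out

    depths = tree.node_depths()
    C = np.zeros((n, n))
    for a in range(n):
        pa = set(path(a))
        for b in range(n):
            shared = [v for v in path(b) if v in pa]
            mrca = max(shared, key=lambda v: depths[v])
            C[a, b] = depths[mrca] if a != b else depths[a]
    return C
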