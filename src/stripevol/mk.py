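"""Mk (continuous-time Markov) models for discrete characters on a phylogeny.

Implements the likelihood machinery behind ancestral-state reconstruction and
the transition-model comparison for clownfish stripe morphs: Felsenstein
pruning with arbitrary constrained rate matrices, ML fitting, likelihood-ratio
tests, AIC/AICc model tables, marginal ancestral states, and enumeration of
polymorphic-species coding combinations.

Stripe morphs are the four adult categories A–D: 0 stripes, one stripe on the
head, two (head + trunk), three (head + trunk + caudal peduncle).  The same
machinery serves the binary ontogenetic-trajectory character (whether
juveniles lose extra stripes before adulthood) with k = 2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .tree import PhyloTree

__all__ = [
    "STRIPE_LABELS",
    "MorphCoding",
    "ConstraintSpec",
    "build_model_matrix",
    "transition_matrices",
    "mk_loglik",
    "MkModel",
    "MkResults",
    "fit_mk",
    "likelihood_ratio_test",
    "aicc",
    "aicc_table",
    "marginal_asr",
    "enumerate_codings",
    "read_coding",
]

#: Stripe-morph category labels, index = number of white stripes.
STRIPE_LABELS = ("A", "B", "C", "D")

RATE_LO, RATE_HI = 1e-9, 1e3  # per-Myr bounds for ML rate search


# ---------------------------------------------------------------------------
# Character codings
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorphCoding:
    """Map species -> non-empty set of character states (ints ``0..k-1``).

    Singleton sets are monomorphic species; larger sets are polymorphic
    (two stripe patterns observed in natural populations).
    """

    states: dict[str, tuple[int, ...]]
    k: int
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for sp, st in self.states.items():
            if not st:
                raise ValueError(f"species {sp!r} has an empty state set")
            if any(s < 0 or s >= self.k for s in st):
                raise ValueError(f"species {sp!r} has states outside 0..{self.k - 1}")
            if len(set(st)) != len(st):
                raise ValueError(f"species {sp!r} repeats a state")

    @classmethod
    def from_dict(
        cls, d: dict[str, object], k: int, labels: tuple[str, ...] | None = None
    ) -> "MorphCoding":
        states = {}
        for sp, st in d.items():
            if isinstance(st, (int, np.integer)):
                states[sp] = (int(st),)
            else:
                states[sp] = tuple(sorted(int(s) for s in st))
        return cls(states=states, k=k, labels=labels)

    @property
    def species(self) -> list[str]:
        return list(self.states)

    @property
    def polymorphic_species(self) -> list[str]:
        return [sp for sp, st in self.states.items() if len(st) > 1]

    @property
    def is_resolved(self) -> bool:
        return not self.polymorphic_species

    def observed_states(self) -> set[int]:
        return {s for st in self.states.values() for s in st}

    def __getitem__(self, sp: str) -> tuple[int, ...]:
        return self.states[sp]

    def state_label(self, s: int) -> str:
        if self.labels is not None:
            return self.labels[s]
        return STRIPE_LABELS[s] if self.k == 4 else str(s)


def enumerate_codings(coding: MorphCoding) -> list[MorphCoding]:
    """All fully-resolved codings: Cartesian product over polymorphic species.

    With the paper's three polymorphic species (two morphs each) this yields
    the eight coding combinations; deterministic order (species alphabetical,
    states ascending).
    """
    poly = sorted(coding.polymorphic_species)
    if not poly:
        return [coding]
    out = []
    for combo in itertools.product(*(coding.states[sp] for sp in poly)):
        states = dict(coding.states)
        for sp, s in zip(poly, combo):
            states[sp] = (s,)
        out.append(MorphCoding(states=states, k=coding.k, labels=coding.labels))
    return out


def read_coding(path: str | Path, k: int = 4, labels=STRIPE_LABELS) -> MorphCoding:
    """Read a character TSV with columns ``species`` and ``state``.

    ``state`` may be a label (A–D), an integer, or a comma-joined set
    (e.g. ``"C,D"``) for polymorphic species.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "species" not in df.columns or "state" not in df.columns:
        raise ValueError("character table needs 'species' and 'state' columns")
    lab2i = {lab: i for i, lab in enumerate(labels[:k])}
    states = {}
    for _, row in df.iterrows():
        toks = [t.strip() for t in str(row["state"]).split(",")]
        vals = []
        for t in toks:
            if t in lab2i:
                vals.append(lab2i[t])
            else:
                vals.append(int(t))
        states[str(row["species"])] = tuple(sorted(vals))
    return MorphCoding(states=states, k=k, labels=tuple(labels[:k]))


# ---------------------------------------------------------------------------
# Constrained rate matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConstraintSpec:
    """Parameterization of a k-state transition-rate matrix.

    ``index[i, j]`` (off-diagonal, 1-based classes) assigns cell (i, j) to a
    shared rate class; 0 forces the rate to zero.  The number of free
    parameters is the number of distinct classes.
    """

    index: np.ndarray
    name: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.index, dtype=int)
        if idx.ndim != 2 or idx.shape[0] != idx.shape[1]:
            raise ValueError("constraint index must be square")
        object.__setattr__(self, "index", idx)
        classes = sorted(set(idx[~np.eye(len(idx), dtype=bool)]) - {0})
        if classes != list(range(1, len(classes) + 1)):
            raise ValueError("parameter classes must be contiguous from 1")

    @property
    def k(self) -> int:
        return self.index.shape[0]

    @property
    def n_free(self) -> int:
        off = self.index[~np.eye(self.k, dtype=bool)]
        return int(len(set(off) - {0}))

    def build_q(self, rates: np.ndarray) -> np.ndarray:
        """Assemble Q from the free-rate vector (class c uses ``rates[c-1]``)."""
        rates = np.asarray(rates, dtype=float)
        if rates.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} rates, got {rates.shape}")
        if np.any(rates < 0):
            raise ValueError("rates must be non-negative")
        Q = np.zeros((self.k, self.k))
        off = ~np.eye(self.k, dtype=bool)
        cls = self.index[off]
        vals = np.where(cls > 0, rates[np.maximum(cls - 1, 0)], 0.0)
        Q[off] = vals
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


def build_model_matrix(model_id: str, k: int = 4) -> ConstraintSpec:
    """Constraint structure of the four stripe-evolution models.

    * ``i``  — all k(k-1) transition rates vary independently;
    * ``ii`` — symmetric rates, q_ij = q_ji;
    * ``iii`` — gain or loss of two or more stripes at once forbidden
      (for 4 ordered states: q31 = q41 = q42 = q13 = q14 = q24 = 0),
      remaining rates free;
    * ``iv`` — symmetry and the model-iii zero set combined (three free
      classes: A<->B, B<->C, C<->D).
    """
    model_id = str(model_id).lower()
    if model_id not in ("i", "ii", "iii", "iv"):
        raise ValueError(f"unknown model id {model_id!r}; expected i, ii, iii or iv")
    if model_id in ("iii", "iv") and k != 4:
        raise ValueError("models iii and iv are defined for the 4-state stripe character")
    if k < 2:
        raise ValueError("need k >= 2 states")
    idx = np.zeros((k, k), dtype=int)
    off = [(i, j) for i in range(k) for j in range(k) if i != j]
    if model_id == "i":
        for c, (i, j) in enumerate(off, start=1):
            idx[i, j] = c
        desc = "all transition rates free"
    elif model_id == "ii":
        c = 0
        for i in range(k):
            for j in range(i + 1, k):
                c += 1
                idx[i, j] = idx[j, i] = c
        desc = "symmetric rates of transition among states"
    else:
        allowed = [(i, j) for (i, j) in off if abs(i - j) == 1]
        if model_id == "iii":
            for c, (i, j) in enumerate(allowed, start=1):
                idx[i, j] = c
            desc = "loss or gain of two stripes forced to 0"
        else:
            c = 0
            for i in range(k - 1):
                c += 1
                idx[i, i + 1] = idx[i + 1, i] = c
            desc = "model ii + model iii"
    return ConstraintSpec(index=idx, name=f"model {model_id}", description=desc)


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def _validate_q(Q: np.ndarray, k: int) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    if Q.shape != (k, k):
        raise ValueError(f"Q must be {k}x{k}")
    off = Q[~np.eye(k, dtype=bool)]
    if not np.all(np.isfinite(Q)) or np.any(off < 0):
        raise ValueError("Q off-diagonal entries must be finite and >= 0")
    if np.max(np.abs(Q.sum(axis=1))) > 1e-8 * max(1.0, np.max(np.abs(Q))):
        raise ValueError("Q rows must sum to zero")
    return Q


def transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """P(t) = exp(Q t) for every branch length, shape (n_branches, k, k).

    Uses an eigendecomposition fast path (one decomposition, batched
    reconstruction) validated against scipy's Pade scaling-and-squaring
    ``expm`` on the longest branch; falls back to per-branch ``expm`` when the
    decomposition is ill-conditioned (e.g. defective Q).
    """
    lengths = np.asarray(lengths, dtype=float)
    k = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        P = np.einsum("ij,tj,jk->tik", V, np.exp(np.outer(lengths, w)), Vinv).real
        t_chk = int(np.argmax(lengths))
        ref = linalg.expm(Q * lengths[t_chk])
        if np.max(np.abs(P[t_chk] - ref)) > 1e-9:
            raise np.linalg.LinAlgError("eig path inaccurate")
        np.clip(P, 0.0, None, out=P)
        P[lengths == 0.0] = np.eye(k)  # exact: impossible endpoint pairs stay 0
        return P
    except np.linalg.LinAlgError:
        return np.stack([linalg.expm(Q * t) for t in lengths])


def _tip_partials(tree: PhyloTree, coding: MorphCoding, k: int, polymorphic: str) -> np.ndarray:
    L = np.zeros((tree.n_nodes, k))
    for i, lab in enumerate(tree.tip_labels):
        if lab not in coding.states:
            raise ValueError(f"tip {lab!r} absent from character coding")
        st = coding.states[lab]
        if len(st) > 1 and polymorphic == "error":
            raise ValueError(
                f"tip {lab!r} is polymorphic; resolve via enumerate_codings() or "
                "pass polymorphic='ambiguous'"
            )
        for s in st:
            L[i, s] = 1.0
    return L


def _pruning(tree: PhyloTree, L_tips: np.ndarray, P: np.ndarray):
    """Post-order pruning pass.

    Returns (scaled partials (n_nodes, k), per-node log scale factors).
    ``P[v]`` is the transition matrix over the branch subtending node v.
    """
    n, k = L_tips.shape[0], L_tips.shape[1]
    L = L_tips.copy()
    logscale = np.zeros(n)
    for v in tree.postorder:
        if tree.is_tip(v):
            continue
        part = np.ones(k)
        ls = 0.0
        for c in tree.children[v]:
            part = part * (P[c] @ L[c])
            ls += logscale[c]
        m = part.max()
        if m <= 0:
            L[v] = 0.0
            logscale[v] = -np.inf
        else:
            L[v] = part / m
            logscale[v] = ls + np.log(m)
    return L, logscale


def _root_prior_vector(root_prior, Q: np.ndarray, k: int) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior == "uniform":
            return np.full(k, 1.0 / k)
        if root_prior == "stationary":
            # left null vector of Q
            w, V = np.linalg.eig(Q.T)
            i = int(np.argmin(np.abs(w)))
            pi = np.abs(V[:, i].real)
            return pi / pi.sum()
        raise ValueError(f"unknown root prior {root_prior!r}")
    pi = np.asarray(root_prior, dtype=float)
    if pi.shape != (k,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("root prior must be a length-k distribution summing to 1")
    return pi


def mk_loglik(
    tree: PhyloTree,
    coding: MorphCoding,
    Q: np.ndarray,
    root_prior="uniform",
    polymorphic: str = "error",
) -> float:
    """Log-likelihood of tip states under the Mk process with rate matrix Q.

    Felsenstein pruning: tip partials are state indicators (polymorphic tips
    as ambiguity sets when ``polymorphic='ambiguous'``), branch propagation by
    exp(Q t), root combination against ``root_prior``.  Returns ``-inf`` for
    data impossible under Q.
    """
    k = coding.k
    Q = _validate_q(Q, k)
    pi = _root_prior_vector(root_prior, Q, k)
    L_tips = _tip_partials(tree, coding, k, polymorphic)
    P = transition_matrices(Q, tree.branch_lengths)
    L, logscale = _pruning(tree, L_tips, P)
    r = tree.root
    val = float(pi @ L[r])
    if val <= 0 or not np.isfinite(logscale[r]):
        return -np.inf
    return float(np.log(val) + logscale[r])


def marginal_asr(
    tree: PhyloTree,
    coding: MorphCoding,
    Q: np.ndarray,
    root_prior="uniform",
    polymorphic: str = "error",
) -> np.ndarray:
    """Marginal ancestral-state posterior at every node, shape (n_nodes, k).

    Standard two-pass algorithm: post-order conditional partials, pre-order
    "outside" vectors, normalized product at each node.  Tip rows are point
    masses for singleton codings.
    """
    k = coding.k
    Q = _validate_q(Q, k)
    pi = _root_prior_vector(root_prior, Q, k)
    L_tips = _tip_partials(tree, coding, k, polymorphic)
    P = transition_matrices(Q, tree.branch_lengths)
    L, _ = _pruning(tree, L_tips, P)
    A = np.zeros((tree.n_nodes, k))  # outside vectors, normalized per node
    A[tree.root] = pi
    for v in tree.postorder[::-1]:
        for c in tree.children[v]:
            out = A[v].copy()
            for s in tree.children[v]:
                if s != c:
                    out = out * (P[s] @ L[s])
            vec = P[c].T @ out
            tot = vec.sum()
            A[c] = vec / tot if tot > 0 else vec
    post = A * L
    sums = post.sum(axis=1, keepdims=True)
    bad = sums[:, 0] <= 0
    if np.any(bad):
        raise ValueError("zero posterior mass at some node: data impossible under Q")
    return post / sums


# ---------------------------------------------------------------------------
# Model objects and fitting
# ---------------------------------------------------------------------------

class MkModel:
    """Mk model of a discrete character on a phylogeny.

    Parameters
    ----------
    tree : PhyloTree
        Rooted, branch-length-bearing phylogeny (lengths in Myr).
    coding : MorphCoding
        Tip character states; must be fully resolved unless
        ``polymorphic='ambiguous'``.
    constraint : ConstraintSpec or str
        Rate-matrix parameterization; a string is passed through
        :func:`build_model_matrix` (``"i"`` = ER-free ARD, ``"ii"`` =
        symmetric, etc.).  For the classic ER model on k states use
        ``ConstraintSpec`` with a single class, available as ``MkModel.er(k)``.
    root_prior : {"uniform", "stationary"} or array
        Distribution over root states; uniform by default.
    """

    def __init__(
        self,
        tree: PhyloTree,
        coding: MorphCoding,
        constraint: ConstraintSpec | str,
        root_prior="uniform",
        polymorphic: str = "error",
    ) -> None:
        if isinstance(constraint, str):
            constraint = build_model_matrix(constraint, coding.k)
        if constraint.k != coding.k:
            raise ValueError("constraint and coding disagree on state count")
        self.tree = tree
        self.coding = coding
        self.constraint = constraint
        self.root_prior = root_prior
        self.polymorphic = polymorphic
        # fail fast on coding problems
        _tip_partials(tree, coding, coding.k, polymorphic)

    @staticmethod
    def er_spec(k: int) -> ConstraintSpec:
        """Equal-rates constraint: one shared class for every off-diagonal cell."""
        idx = np.where(~np.eye(k, dtype=bool), 1, 0)
        return ConstraintSpec(index=idx, name="ER", description="equal rates")

    @staticmethod
    def ard_spec(k: int) -> ConstraintSpec:
        """All-rates-different constraint (alias of model i)."""
        spec = build_model_matrix("i", k)
        return ConstraintSpec(index=spec.index, name="ARD", description="all rates different")

    def loglike(self, rates: np.ndarray) -> float:
        Q = self.constraint.build_q(rates)
        return mk_loglik(self.tree, self.coding, Q, self.root_prior, self.polymorphic)

    def fit(self, n_starts: int = 10, seed: int | None = 0, **_) -> "MkResults":
        """Maximize the likelihood over non-negative free rates.

        Multi-start box-constrained quasi-Newton search on the log-rate scale
        (rates bounded in [1e-9, 1e3] per Myr); deterministic given ``seed``.
        """
        if len(self.coding.observed_states()) < 2:
            # single observed state: rates go to zero, lnL = log prior mass
            rates = np.full(self.constraint.n_free, RATE_LO)
            return MkResults(self, rates, self.loglike(rates), converged=True)
        rng = np.random.default_rng(seed)
        m = self.constraint.n_free
        # heuristic scale: one expected change per total tree length
        base = max(1.0 / max(self.tree.total_length(), 1e-9), 10 * RATE_LO)
        starts = [np.full(m, base)]
        for _i in range(n_starts - 1):
            starts.append(base * np.exp(rng.uniform(-3, 3, size=m)))
        best = None
        lo, hi = np.log(RATE_LO), np.log(RATE_HI)

        def nll(logr):
            v = self.loglike(np.exp(logr))
            # large finite penalty keeps L-BFGS-B's finite differences clean
            return 1e10 if not np.isfinite(v) else -v

        for x0 in starts:
            z0 = np.clip(np.log(x0), lo, hi)
            # preliminary common-scale line search: keeps the quasi-Newton
            # step from overshooting onto the flat stationary-rate plateau
            scale = optimize.minimize_scalar(
                lambda s: nll(np.clip(z0 + s, lo, hi)),
                bounds=(-8.0, 8.0), method="bounded",
                options={"xatol": 0.05},
            )
            z0 = np.clip(z0 + scale.x, lo, hi)
            res = optimize.minimize(
                nll, z0, method="L-BFGS-B",
                bounds=[(lo, hi)] * m,
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None or best.fun >= 1e9:
            raise RuntimeError(
                f"Mk optimization failed to converge after {n_starts} starts; "
                f"best objective: {None if best is None else best.fun}"
            )
        return MkResults(self, np.exp(best.x), -float(best.fun), converged=bool(best.success))


class MkResults:
    """ML fit of an :class:`MkModel`: rate estimates, lnL, information criteria."""

    def __init__(self, model: MkModel, rates: np.ndarray, llf: float, converged: bool = True):
        self.model = model
        self.rates = np.asarray(rates, dtype=float)
        self.llf = float(llf)
        self.converged = converged

    @property
    def Q(self) -> np.ndarray:
        return self.model.constraint.build_q(self.rates)

    @property
    def df_model(self) -> int:
        return self.model.constraint.n_free

    @property
    def nobs(self) -> int:
        # AICc sample size: number of tips
        return self.model.tree.n_tips

    @property
    def aic(self) -> float:
        return -2 * self.llf + 2 * self.df_model

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.df_model, self.nobs)

    def ancestral_states(self) -> pd.DataFrame:
        """Marginal posterior state probabilities at every node."""
        post = marginal_asr(
            self.model.tree, self.model.coding, self.Q,
            self.model.root_prior, self.model.polymorphic,
        )
        cols = [self.model.coding.state_label(s) for s in range(self.model.coding.k)]
        names = list(self.model.tree.tip_labels) + [
            f"node{v}" for v in range(self.model.tree.n_tips, self.model.tree.n_nodes)
        ]
        return pd.DataFrame(post, index=names, columns=cols)

    def simulate_histories(self, n_maps: int = 10_000, seed: int | None = 0):
        """Stochastic character maps conditional on the data and the MLE Q."""
        from .simmap import sample_histories

        return sample_histories(
            self.model.tree, self.model.coding, self.Q,
            root_prior=self.model.root_prior, n_maps=n_maps, seed=seed,
            polymorphic=self.model.polymorphic,
        )

    def summary(self) -> str:
        spec = self.model.constraint
        lines = [
            f"Mk model fit: {spec.name or 'custom constraint'}"
            + (f" ({spec.description})" if spec.description else ""),
            f"  states: {self.model.coding.k}   tips: {self.nobs}",
            f"  free rate classes: {self.df_model}",
            f"  lnL = {self.llf:.4f}   AIC = {self.aic:.2f}   AICc = {self.aicc:.2f}",
            "  rates (per Myr): "
            + ", ".join(f"q[{c + 1}]={r:.5g}" for c, r in enumerate(self.rates)),
        ]
        return "\n".join(lines)


def fit_mk(
    tree: PhyloTree,
    coding: MorphCoding,
    spec: ConstraintSpec | str,
    n_starts: int = 10,
    seed: int | None = 0,
    root_prior="uniform",
    polymorphic: str = "error",
) -> MkResults:
    """Functional wrapper: ``MkModel(tree, coding, spec, ...).fit(...)``."""
    return MkModel(tree, coding, spec, root_prior, polymorphic).fit(n_starts, seed)


def likelihood_ratio_test(fit_nested, fit_full, tol: float = 1e-6):
    """LRT of a nested against a fuller model.

    Returns (statistic, df, p).  The statistic is 2(lnL_full - lnL_nested),
    df the difference in free parameters, p the chi-square upper tail.  A
    statistic below ``-tol`` signals optimizer failure and raises.
    """
    k_n, k_f = fit_nested.df_model, fit_full.df_model
    if k_n >= k_f:
        raise ValueError("nested model must have fewer free parameters")
    stat = 2.0 * (fit_full.llf - fit_nested.llf)
    if stat < -tol:
        raise RuntimeError(
            f"negative LRT statistic ({stat:.3g}): the fuller model fit worse; "
            "rerun the optimizer with more starts"
        )
    stat = max(stat, 0.0)
    df = k_f - k_n
    p = float(stats.chi2.sf(stat, df))
    return stat, df, p


def aicc(llf: float, k_params: int, n: int) -> float:
    """Sample-size-corrected AIC: -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k_params + 1:
        raise ValueError(f"AICc undefined: n={n} <= k+1={k_params + 1}")
    return -2.0 * llf + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (n - k_params - 1)


def aicc_table(fits, n: int | None = None) -> pd.DataFrame:
    """Model-comparison table: AIC, AICc, ΔAICc vs best, Akaike weights.

    ``fits`` is a list of fitted results (Mk or MuSSE); ``n`` defaults to each
    fit's own sample size (number of tips).  Rows are sorted best-first.
    """
    def fit_name(f):
        name = getattr(f, "name", "")
        if name:
            return name
        c = getattr(getattr(f, "model", None), "constraint", None)
        return getattr(c, "name", "") or "model"

    rows = []
    for f in fits:
        nn = n if n is not None else f.nobs
        rows.append(
            {
                "model": fit_name(f),
                "lnL": f.llf,
                "k": f.df_model,
                "AIC": -2 * f.llf + 2 * f.df_model,
                "AICc": aicc(f.llf, f.df_model, nn),
            }
        )
    df = pd.DataFrame(rows)
    best = df["AICc"].min()
    df["dAICc"] = df["AICc"] - best
    w = np.exp(-df["dAICc"] / 2.0)
    df["weight"] = w / w.sum()
    return df.sort_values("AICc", kind="stable").reset_index(drop=True)
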