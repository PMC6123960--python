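"""Seeded generators for trees, characters, traits and communities.

Every analysis stage in the package can be exercised without any external
dataset: birth-death ultrametric trees, discrete characters evolved forward
under a known transition-rate matrix (with the full latent history retained
as ground truth), Brownian traits with a known regression slope, and
species pools / communities with controllable morph structure.  All
generators are pure functions of their parameters and a seed.

The packaged default fixture mirrors the scale of the clownfish study:
a 27-tip ultrametric tree of about 15 Myr depth, a 4-state stripe character
evolved under the caudo-rostral stepwise model with the empirical rate
ordering (head stripe fastest, peduncle stripe slowest), three polymorphic
species, a 10-species regional pool, and communities of richness 3-6.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .community import Community, SpeciesPool
from .mk import MorphCoding, STRIPE_LABELS, build_model_matrix
from .simmap import BranchHistory
from .tree import PhyloTree

__all__ = [
    "SimulationRecord",
    "simulate_bd_tree",
    "simulate_mk",
    "MkSimulation",
    "simulate_bm_traits",
    "simulate_pool_and_communities",
    "default_fixture",
    "Fixture",
]


@dataclass(frozen=True)
class SimulationRecord:
    """Provenance of one generated object: regenerate it from kind+params+seed."""

    kind: str
    params: dict
    seed: int | None

    def to_json(self) -> str:
        return json.dumps({"kind": self.kind, "params": self.params, "seed": self.seed},
                          sort_keys=True)


# ---------------------------------------------------------------------------
# Birth-death trees
# ---------------------------------------------------------------------------

def simulate_bd_tree(
    birth_rate: float,
    death_rate: float,
    n_tips: int,
    seed: int | None = 0,
    max_tries: int = 1000,
) -> PhyloTree:
    """Forward birth-death simulation conditioned on the extant tip count.

    Starts from a crown split (two lineages), waits exponential times between
    events, and stops the first time the extant lineage count reaches
    ``n_tips``; the present is placed a uniform fraction of the following
    inter-event wait later, so terminal branches have positive length.
    Replicates in which the clade dies or exceeds limits are rejected and
    redrawn (reject-and-retry conditioning).
    """
    if not (birth_rate > death_rate >= 0):
        raise ValueError("need birth_rate > death_rate >= 0")
    if n_tips < 2:
        raise ValueError("need n_tips >= 2")
    rng = np.random.default_rng(seed)
    for _try in range(max_tries):
        tree = _bd_attempt(birth_rate, death_rate, n_tips, rng)
        if tree is not None:
            return tree
    raise RuntimeError(f"birth-death simulation failed in {max_tries} attempts")


def _bd_attempt(b: float, d: float, n_tips: int, rng) -> PhyloTree | None:
    # node bookkeeping: parents/children resolved at the end
    parent_of: dict[int, int] = {}
    birth_time: dict[int, float] = {0: 0.0, 1: 0.0, 2: 0.0}
    parent_of[1] = 0
    parent_of[2] = 0
    children_of: dict[int, list[int]] = {0: [1, 2]}
    active = [1, 2]
    nxt = 3
    t = 0.0
    rate_per = b + d
    while True:
        n = len(active)
        if n == 0:
            return None
        if n == n_tips:
            t_stop = t + rng.random() * rng.exponential(1.0 / (n * rate_per))
            break
        if n > 5 * n_tips + 50:
            return None  # runaway; reject to bound memory
        t += rng.exponential(1.0 / (n * rate_per))
        lin = active[rng.integers(n)]
        if rng.random() < b / rate_per:  # speciation
            active.remove(lin)
            c1, c2 = nxt, nxt + 1
            nxt += 2
            parent_of[c1] = lin
            parent_of[c2] = lin
            birth_time[c1] = birth_time[c2] = t
            children_of[lin] = [c1, c2]
            active.extend([c1, c2])
        else:  # extinction: prune the lineage and its naked ancestors
            active.remove(lin)
            _prune(lin, parent_of, children_of, birth_time)
            if 0 not in children_of or len(children_of.get(0, [])) < 2:
                return None  # root lost a side entirely
    # assemble arrays: tips first
    tips = sorted(active)
    internal = sorted(k for k in children_of if children_of[k])
    ids = {old: i for i, old in enumerate(tips)}
    for old in internal:
        ids[old] = len(ids)
    n_nodes = len(ids)
    parent = np.full(n_nodes, -1, dtype=int)
    blen = np.zeros(n_nodes)
    children: list[list[int]] = [[] for _ in range(n_nodes)]
    death_time = {old: t_stop for old in tips}
    for old in internal:
        death_time[old] = birth_time[children_of[old][0]]
    for old, new in ids.items():
        p = parent_of.get(old)
        if p is not None:
            parent[new] = ids[p]
            blen[new] = death_time[old] - birth_time[old]
            children[ids[p]].append(new)
    labels = [f"t{i + 1}" for i in range(len(tips))]
    return PhyloTree(tip_labels=labels, parent=parent, children=children,
                     branch_lengths=blen)


def _prune(lin, parent_of, children_of, birth_time):
    """Remove an extinct lineage, collapsing unifurcating ancestors."""
    while True:
        p = parent_of.pop(lin, None)
        birth_time.pop(lin, None)
        children_of.pop(lin, None)
        if p is None:
            return
        sibs = [c for c in children_of[p] if c != lin]
        children_of[p] = sibs
        if sibs:
            if len(sibs) == 1 and p != 0:
                # collapse p: graft the surviving child onto p's parent
                gp = parent_of.get(p)
                c = sibs[0]
                if gp is None:
                    return
                parent_of[c] = gp
                children_of[gp] = [c if x == p else x for x in children_of[gp]]
                # the surviving child inherits the start of p's branch, so the
                # collapsed edge gp -> p -> c keeps its full length
                birth_time[c] = birth_time[p]
                parent_of.pop(p, None)
                birth_time.pop(p, None)
                children_of.pop(p, None)
            return
        lin = p  # p is now childless: remove it too


# ---------------------------------------------------------------------------
# Discrete characters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MkSimulation:
    """Forward CTMC simulation with its complete latent history."""

    coding: MorphCoding
    node_states: np.ndarray
    histories: dict[int, BranchHistory]   # keyed by child node id
    record: SimulationRecord = field(compare=False, default=None)


def simulate_mk(
    tree: PhyloTree,
    Q: np.ndarray,
    root_state: int | None = None,
    root_prior=None,
    seed: int | None = 0,
    labels: tuple[str, ...] | None = None,
) -> MkSimulation:
    """Evolve a discrete character forward along every branch of the tree.

    Exponential waiting times at rate -Q[s, s]; jump targets proportional to
    Q[s, :].  Returns tip states as a (singleton) MorphCoding plus the true
    node states and per-branch histories.
    """
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    rng = np.random.default_rng(seed)
    if root_state is None:
        p = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior, float)
        root_state = int(rng.choice(k, p=p / p.sum()))
    states = np.empty(tree.n_nodes, dtype=int)
    states[tree.root] = root_state
    histories: dict[int, BranchHistory] = {}
    for v in tree.postorder[::-1]:
        for c in tree.children[v]:
            s = states[v]
            remaining = float(tree.branch_lengths[c])
            segs: list[tuple[int, float]] = []
            while True:
                rate = -Q[s, s]
                wait = rng.exponential(1.0 / rate) if rate > 0 else np.inf
                if wait >= remaining:
                    segs.append((s, remaining))
                    break
                segs.append((s, wait))
                remaining -= wait
                w = Q[s].clip(min=0.0)
                w[s] = 0.0
                s = int(rng.choice(k, p=w / w.sum()))
            states[c] = s
            histories[c] = BranchHistory(segments=tuple(segs))
    coding = MorphCoding(
        states={lab: (int(states[i]),) for i, lab in enumerate(tree.tip_labels)},
        k=k,
        labels=labels or (STRIPE_LABELS if k == 4 else None),
    )
    rec = SimulationRecord("mk_character", {"Q": Q.tolist(), "root_state": int(root_state)}, seed)
    return MkSimulation(coding=coding, node_states=states, histories=histories, record=rec)


# ---------------------------------------------------------------------------
# Brownian traits
# ---------------------------------------------------------------------------

def simulate_bm_traits(
    tree: PhyloTree,
    sigma2: float,
    slope: float = 0.0,
    intercept: float = 0.0,
    predictor=None,
    predictor_sigma2: float = 1.0,
    seed: int | None = 0,
):
    """Predictor and response with phylogenetic (Brownian) structure.

    The predictor is Brownian motion on the tree with rate
    ``predictor_sigma2`` unless supplied; the response is
    ``intercept + slope * x`` plus Brownian noise of rate ``sigma2``.
    Returns two dicts keyed by tip label (x, y).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    from .tree import vcv_matrix

    rng = np.random.default_rng(seed)
    C, labels = vcv_matrix(tree)
    Lc = np.linalg.cholesky(C + 1e-12 * np.eye(len(C)))
    if predictor is None:
        x = Lc @ rng.standard_normal(len(C)) * np.sqrt(predictor_sigma2)
    else:
        x = np.asarray([predictor[lab] for lab in labels], dtype=float)
    noise = Lc @ rng.standard_normal(len(C)) * np.sqrt(sigma2) if sigma2 > 0 else 0.0
    y = intercept + slope * x + noise
    return (
        {lab: float(v) for lab, v in zip(labels, x)},
        {lab: float(v) for lab, v in zip(labels, y)},
    )


# ---------------------------------------------------------------------------
# Pools and communities
# ---------------------------------------------------------------------------

def simulate_pool_and_communities(
    n_species: int = 10,
    morph_distribution=(0.1, 0.2, 0.3, 0.4),
    polymorphic_fraction: float = 0.3,
    richness_list=(3, 3, 4, 5),
    seed: int | None = 0,
    selection_strength: float = 0.0,
):
    """A regional species pool and communities drawn from it.

    Morphs are drawn from ``morph_distribution``; a ``polymorphic_fraction``
    of species receive a second (adjacent) morph.  Communities are uniform
    richness-preserving draws when ``selection_strength`` is 0 (the null is
    true); with positive strength, species are added sequentially with weight
    exp(-strength * added identical pairs), biasing assemblages toward morph
    dissimilarity (the species-recognition alternative).
    """
    rng = np.random.default_rng(seed)
    p = np.asarray(morph_distribution, dtype=float)
    p = p / p.sum()
    k = len(p)
    names = [f"sp{i + 1:02d}" for i in range(n_species)]
    morphs = {}
    n_poly = int(round(polymorphic_fraction * n_species))
    poly_idx = set(rng.choice(n_species, size=n_poly, replace=False).tolist())
    for i, name in enumerate(names):
        m = int(rng.choice(k, p=p))
        if i in poly_idx:
            second = m + 1 if m < k - 1 else m - 1
            morphs[name] = tuple(sorted((m, second)))
        else:
            morphs[name] = (m,)
    pool = SpeciesPool(morphs=morphs)
    communities = []
    from .community import max_identical_pairs

    for j, r in enumerate(richness_list):
        if r > n_species:
            raise ValueError("richness exceeds pool size")
        if selection_strength <= 0:
            chosen = list(np.array(names)[rng.choice(n_species, size=r, replace=False)])
        else:
            chosen = []
            avail = list(names)
            while len(chosen) < r:
                w = []
                base = max_identical_pairs(chosen, pool) if chosen else 0
                for sp in avail:
                    added = max_identical_pairs(chosen + [sp], pool) - base
                    w.append(np.exp(-selection_strength * added))
                w = np.asarray(w)
                pick = int(rng.choice(len(avail), p=w / w.sum()))
                chosen.append(avail.pop(pick))
        communities.append(Community(location=f"loc{j + 1}", species=tuple(chosen)))
    return pool, communities


# ---------------------------------------------------------------------------
# Default desk-scale fixture
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """Self-contained synthetic dataset exercising every analysis stage."""

    tree: PhyloTree
    stripes: MorphCoding          # 4-state, three polymorphic species
    stripes_true: MkSimulation    # latent truth of the monomorphic base coding
    ontogeny: MorphCoding         # binary loss / no-loss character
    ontogeny_true: MkSimulation
    traits: "object"              # pandas DataFrame of morphometrics
    pool: SpeciesPool
    communities: list[Community]
    seed: int
    manifest: dict

    @property
    def n_coding_combinations(self) -> int:
        return int(np.prod([len(s) for s in self.stripes.states.values()]))


def default_fixture(seed: int = 0) -> Fixture:
    """The packaged study-scale dataset.

    27-tip birth-death tree (birth 0.25, death 0.05 per Myr; depth ~15 Myr),
    stripe character under the stepwise symmetric model with rates
    (0.123, 0.103, 0.052) per Myr from a three-striped root, three
    polymorphic species (second morph adjacent), binary ontogeny character
    (equal rates 0.04), Brownian morphometrics in which only the anterior
    lobe index truly covaries with stripe number, a 10-species pool and
    eight communities of richness 3-6.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    s_tree, s_chr, s_ont, s_tr, s_pool = [int(x) for x in
                                          rng.integers(0, 2**31 - 1, size=5)]
    tree = simulate_bd_tree(0.25, 0.05, 27, seed=s_tree)
    Q_iv = build_model_matrix("iv", 4).build_q(np.array([0.123, 0.103, 0.052]))
    stripes_true = simulate_mk(tree, Q_iv, root_state=3, seed=s_chr)
    # mark three species polymorphic with an adjacent second morph
    states = dict(stripes_true.coding.states)
    poly = [tree.tip_labels[i] for i in rng.choice(27, size=3, replace=False)]
    for sp in poly:
        (m,) = states[sp]
        second = m + 1 if m < 3 else m - 1
        states[sp] = tuple(sorted((m, second)))
    stripes = MorphCoding(states=states, k=4, labels=STRIPE_LABELS)
    Q_ont = np.array([[-0.04, 0.04], [0.04, -0.04]])
    ontogeny_true = simulate_mk(tree, Q_ont, root_state=0, seed=s_ont,
                                labels=("no_loss", "loss"))
    # morphometrics: anterior index tracks stripe number; the rest is noise
    stripe_num = {sp: float(st[0]) for sp, st in stripes_true.coding.states.items()}
    _, anterior = simulate_bm_traits(tree, sigma2=0.0005, slope=0.05, intercept=0.05,
                                     predictor=stripe_num, seed=s_tr)
    rng_tr = np.random.default_rng(s_tr + 1)
    rows = []
    for sp in tree.tip_labels:
        L = rng_tr.uniform(1.5, 2.5)
        l2 = rng_tr.uniform(0.15, 0.3) * L
        l1 = l2 + anterior[sp] * L
        lr = l2 + rng_tr.uniform(0.0, 0.15) * L
        SL = rng_tr.uniform(6.0, 11.0)
        height = SL * rng_tr.uniform(0.35, 0.6)
        rows.append({
            "species": sp, "stripes": int(stripe_num[sp]),
            "l1": round(l1, 4), "l2": round(l2, 4), "lr": round(lr, 4),
            "L": round(L, 4), "height": round(height, 4), "SL": round(SL, 4),
            "max_size": round(rng_tr.uniform(8.0, 16.0), 2),
            "n_hosts": int(rng_tr.integers(1, 11)),
        })
    traits = pd.DataFrame(rows)
    pool, communities = simulate_pool_and_communities(
        n_species=10, morph_distribution=(2, 5, 9, 11),
        polymorphic_fraction=0.3, richness_list=(4, 3, 3, 3, 3, 5, 3, 6),
        seed=s_pool, selection_strength=2.0,
    )
    manifest = {
        "seed": seed,
        "tree": {"birth": 0.25, "death": 0.05, "n_tips": 27, "seed": s_tree},
        "stripes": {"model": "iv", "rates": [0.123, 0.103, 0.052],
                    "root_state": 3, "seed": s_chr, "polymorphic": sorted(poly)},
        "ontogeny": {"q": 0.04, "root_state": 0, "seed": s_ont},
        "traits": {"slope": 0.05, "sigma2": 0.0005, "seed": s_tr},
        "communities": {"n_species": 10, "richness": [4, 3, 3, 3, 3, 5, 3, 6],
                        "selection_strength": 2.0, "seed": s_pool},
    }
    return Fixture(
        tree=tree, stripes=stripes, stripes_true=stripes_true,
        ontogeny=ontogeny_true.coding, ontogeny_true=ontogeny_true,
        traits=traits, pool=pool, communities=communities,
        seed=seed, manifest=manifest,
    )
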