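"""Synthetic validation data: birth-death trees with fossils, BM traits.

Trees are grown by a forward (Gillespie) birth-death simulation conditioned
on reaching a target number of living lineages; extinct lineages are kept as
fossil tips at their true extinction times (no preservation model — a fixed
number of fossils is retained by uniform subsampling, matching the study
design of "20, 5, 1, 0 fossils included"). Extant tips can additionally be
subsampled uniformly to emulate incomplete present-day sampling.

Traits are then evolved on the *analysis* tree under Brownian motion with an
optional trend and optional rate shifts anchored at internal nodes, so the
true ancestral states, parameters and shift count are defined exactly at the
nodes the sampler sees.

Scenario conventions (validation grid):

* scenario 1 — constant rate, no trend (mu0 = 0);
* scenario 2 — constant rate, a positive or negative trend;
* shifted variants — scenario-1 data with 1 or 2 true rate shifts;
* "platy" — platyrrhine-sized: 200 extant taxa of which 44% are sampled,
  plus 20 fossils, evolving with a trend.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .phylo_io import TimeTree, TraitTable, StateVector, preorder, clade_nodes
from .bm_likelihood import ShiftConfig, BMParams, resolve_classes

__all__ = ["SimScenario", "SimReplicate", "simulate_tree", "subsample_fossils",
           "subsample_extant", "simulate_traits", "make_scenario_grid",
           "simulate_replicate"]

# default diversification regime: birth 0.25 / Myr, death 0.15 / Myr gives
# ~40 Myr-deep trees at 50 extant tips with a rich supply of extinct lineages
BIRTH = 0.25
DEATH = 0.15


@dataclass
class SimScenario:
    """One cell of the validation grid."""

    scenario_id: str
    n_extant: int = 50
    sampling_fraction: float = 1.0
    n_fossils: int = 20
    trend: bool = False                  # scenario 2: mu0 != 0
    n_rate_shifts: int = 0
    sigma2_range: tuple = (0.1, 1.0)
    trend_rel_range: tuple = (0.2, 1.0)  # |mu0| = U * sqrt(sigma2)
    shift_factor: float = 10.0           # rate multiplier of a true shift
    clade_frac: tuple = (0.15, 0.40)     # true-shift clade size, fraction of tips
    birth: float = BIRTH
    death: float = DEATH
    replicates: int = 25
    seed: int = 0

    @property
    def true_shift_count(self) -> int:
        return self.n_rate_shifts


@dataclass
class SimReplicate:
    tree: TimeTree
    traits: TraitTable
    true_states: StateVector
    true_params: BMParams
    true_n_rate_shifts: int
    true_n_trend_shifts: int = 0


# ---------------------------------------------------------------------------
# Birth-death trees

def simulate_tree(birth: float, death: float, n_extant: int,
                  rng: np.random.Generator, min_fossils: int = 0,
                  max_tries: int = 1000) -> TimeTree:
    """Forward birth-death simulation conditioned on n_extant survivors.

    The clock stops at a uniform point inside the first inter-event interval
    during which the target number of living lineages is reached, so terminal
    branches have positive length. Extinct side branches are retained. Trees
    that die out, or end with fewer than ``min_fossils`` extinct tips, are
    resimulated (bounded retries).
    """
    if not birth > death >= 0:
        raise ValueError("need birth > death >= 0")
    for _ in range(max_tries):
        tree = _grow(birth, death, n_extant, rng)
        if tree is not None and len(tree.fossil_tips()) >= min_fossils:
            return tree
    raise RuntimeError("failed to simulate a suitable tree in %d tries" % max_tries)


def _grow(birth, death, n_target, rng):
    # records: parent id, birth time; alive lineages end at present
    parent = [-1]
    t_birth = [0.0]
    t_end = [np.nan]
    alive = [0]
    t = 0.0
    while len(alive) < n_target:
        if not alive:
            return None
        rate = len(alive) * (birth + death)
        dt = rng.exponential(1.0 / rate)
        t += dt
        k = alive[rng.integers(len(alive))]
        if rng.random() < birth / (birth + death):
            for _ in range(2):
                parent.append(k)
                t_birth.append(t)
                t_end.append(np.nan)
                alive.append(len(parent) - 1)
            t_end[k] = t
            alive.remove(k)
        else:
            t_end[k] = t
            alive.remove(k)
    # freeze the present inside the next waiting interval
    rate = len(alive) * (birth + death)
    present = t + rng.exponential(1.0 / rate) * rng.random()
    for k in alive:
        t_end[k] = present
    return _assemble(parent, t_birth, t_end, present, set(alive))


def _assemble(parent, t_birth, t_end, present, alive_set):
    """Convert lineage records into a TimeTree, suppressing dead-end roots."""
    n = len(parent)
    children = [[] for _ in range(n)]
    for i in range(1, n):
        children[parent[i]].append(i)
    # lineage i spans [t_birth[i], t_end[i]]; tips are lineages w/o children
    blen = [t_end[i] - t_birth[i] for i in range(n)]
    blen[0] = 0.0  # the stem above the first split carries no branch
    labels = [None] * n
    n_ext = 0
    n_fos = 0
    for i in range(n):
        if not children[i]:
            if i in alive_set:
                n_ext += 1
                labels[i] = "t%d" % n_ext
            else:
                n_fos += 1
                labels[i] = "f%d" % n_fos
    k = 0
    for i in range(n):
        if children[i]:
            k += 1
            labels[i] = "n%d" % k
    tree = TimeTree(np.array(parent, dtype=np.int64),
                    tuple(tuple(c) for c in children),
                    np.array(blen), labels, root=0)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Pruning

def prune_to_tips(tree: TimeTree, keep_tips) -> TimeTree:
    """New tree with only the given tips; degree-2 pass-through nodes are
    suppressed (their branch lengths merged) and labels of retained nodes are
    preserved, so path lengths among retained tips are unchanged."""
    keep_tips = set(int(i) for i in keep_tips)
    if not keep_tips:
        raise ValueError("cannot prune away every tip")
    needed = [0] * tree.n_nodes
    for i in keep_tips:
        j = i
        while j != -1:
            needed[j] += 1
            j = tree.parent[j]

    # retained node: a kept tip, or an internal node that is the meeting
    # point of >= 2 retained children
    def build(i, acc_blen):
        kept_children = [c for c in tree.children[i] if _has_kept(c)]
        if tree.is_tip(i):
            return ("tip", i, acc_blen, [])
        if len(kept_children) == 1:
            c = kept_children[0]
            return build(c, acc_blen + tree.blen[c])
        subs = [build(c, tree.blen[c]) for c in kept_children]
        return ("node", i, acc_blen, subs)

    def _has_kept(i):
        stack = [i]
        while stack:
            j = stack.pop()
            if tree.is_tip(j) and j in keep_tips:
                return True
            stack.extend(tree.children[j])
        return False

    root_kept = [c for c in tree.children[tree.root] if _has_kept(c)]
    if tree.is_tip(tree.root):
        raise ValueError("degenerate tree")
    if len(root_kept) == 1:
        spec = build(root_kept[0], 0.0)  # drop the stem
    else:
        spec = build(tree.root, 0.0)

    parent_l, blen_l, label_l, children_l = [], [], [], []

    def emit(node_spec, parent_idx):
        kind, orig, bl, subs = node_spec
        idx = len(parent_l)
        parent_l.append(parent_idx)
        blen_l.append(bl)
        label_l.append(tree.label[orig])
        children_l.append([])
        if parent_idx >= 0:
            children_l[parent_idx].append(idx)
        for s in subs:
            emit(s, idx)

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * tree.n_nodes + 100))
    try:
        emit(spec, -1)
    finally:
        sys.setrecursionlimit(old)
    out = TimeTree(np.array(parent_l, dtype=np.int64),
                   tuple(tuple(c) for c in children_l),
                   np.array(blen_l), label_l, root=0)
    out.validate()
    return out


def subsample_fossils(tree: TimeTree, n_fossils: int,
                      rng: np.random.Generator) -> TimeTree:
    """Keep a uniform sample of n_fossils extinct tips plus all extant tips."""
    fossils = tree.fossil_tips()
    if len(fossils) < n_fossils:
        raise ValueError("tree has %d extinct tips, need %d"
                         % (len(fossils), n_fossils))
    keep = (list(rng.choice(fossils, size=n_fossils, replace=False))
            if n_fossils else [])
    return prune_to_tips(tree, list(tree.extant_tips()) + keep)


def subsample_extant(tree: TimeTree, fraction: float,
                     rng: np.random.Generator) -> TimeTree:
    """Uniformly retain ceil(fraction * n_extant) extant tips."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    extant = tree.extant_tips()
    k = int(np.ceil(fraction * len(extant)))
    keep = list(rng.choice(extant, size=k, replace=False))
    return prune_to_tips(tree, keep + list(tree.fossil_tips()))


# ---------------------------------------------------------------------------
# Trait evolution

def simulate_traits(tree: TimeTree, params: BMParams,
                    rng: np.random.Generator) -> StateVector:
    """Evolve a trait down the tree: child = parent + N(mu0 t, sigma2 t)."""
    sig, mu = resolve_classes(tree, params.config)
    v = np.zeros(tree.n_nodes)
    obs = np.zeros(tree.n_nodes, dtype=bool)
    for i in preorder(tree):
        if i == tree.root:
            v[i] = params.root_state
        else:
            t = tree.blen[i]
            v[i] = (v[tree.parent[i]] + mu[i] * t
                    + np.sqrt(sig[i] * t) * rng.standard_normal())
        if tree.is_tip(i):
            obs[i] = True
    return StateVector(v, obs)


def _choose_shift_anchors(tree, k, clade_frac, rng):
    """k internal nodes whose clades are disjoint and of intermediate size."""
    n_tip = tree.n_tips
    lo, hi = int(np.floor(clade_frac[0] * n_tip)), int(np.ceil(clade_frac[1] * n_tip))
    cands = []
    for i in range(tree.n_nodes):
        if i == tree.root or tree.is_tip(i):
            continue
        sz = sum(1 for j in clade_nodes(tree, i) if tree.is_tip(j))
        if lo <= sz <= hi:
            cands.append(i)
    rng.shuffle(cands)
    chosen: list = []
    taken: set = set()
    for c in cands:
        cl = clade_nodes(tree, c)
        if not cl & taken and c not in taken:
            # also exclude ancestors of already-chosen anchors
            if all(c not in clade_nodes(tree, a) for a in chosen):
                chosen.append(c)
                taken |= cl
        if len(chosen) == k:
            return chosen
    raise RuntimeError("could not place %d disjoint shift clades" % k)


def simulate_replicate(scn: SimScenario, index: int, master_seed: int) -> SimReplicate:
    """Fully reproducible replicate from (scenario, replicate index, seed)."""
    scn_key = zlib.crc32(scn.scenario_id.encode()) % 2 ** 31
    ss = np.random.SeedSequence([int(master_seed), scn_key, int(index)])
    rng = np.random.default_rng(ss)
    for attempt in range(200):
        full = simulate_tree(scn.birth, scn.death, scn.n_extant, rng,
                             min_fossils=max(scn.n_fossils, 1))
        tree = subsample_fossils(full, scn.n_fossils, rng)
        if scn.sampling_fraction < 1.0:
            tree = subsample_extant(tree, scn.sampling_fraction, rng)
        sigma2 = float(rng.uniform(*scn.sigma2_range))
        mu0 = 0.0
        if scn.trend:
            mu0 = float(rng.choice([-1.0, 1.0])
                        * rng.uniform(*scn.trend_rel_range) * np.sqrt(sigma2))
        config = ShiftConfig(sigma2_0=sigma2, mu0_0=mu0)
        if scn.n_rate_shifts:
            try:
                anchors = _choose_shift_anchors(tree, scn.n_rate_shifts,
                                                scn.clade_frac, rng)
            except RuntimeError:
                continue
            for j, a in enumerate(anchors):
                factor = scn.shift_factor if j % 2 == 0 else 1.0 / scn.shift_factor
                config.rate_shifts[a] = sigma2 * factor
        params = BMParams(config, root_state=0.0)
        states = simulate_traits(tree, params, rng)
        traits = TraitTable({tree.label[i]: float(states.values[i])
                             for i in tree.tips})
        return SimReplicate(tree, traits, states, params,
                            true_n_rate_shifts=scn.n_rate_shifts)
    raise RuntimeError("scenario %s: no valid replicate in 200 attempts"
                       % scn.scenario_id)


def make_scenario_grid(replicates: int = 25, seed: int = 0) -> list:
    """The validation grid: scenarios 1 and 2 at each fossil count, shifted
    variants with 1 and 2 true rate shifts, and the platyrrhine-sized setting."""
    grid = []
    for nf in (20, 5, 1, 0):
        grid.append(SimScenario("s1_f%d" % nf, n_fossils=nf, trend=False,
                                replicates=replicates, seed=seed))
        grid.append(SimScenario("s2_f%d" % nf, n_fossils=nf, trend=True,
                                replicates=replicates, seed=seed))
    grid.append(SimScenario("s1_k1", n_rate_shifts=1, replicates=replicates,
                            seed=seed))
    grid.append(SimScenario("s1_k2", n_rate_shifts=2, replicates=replicates,
                            seed=seed))
    grid.append(SimScenario("platy", n_extant=200, sampling_fraction=0.44,
                            n_fossils=20, trend=True, replicates=replicates,
                            seed=seed))
    return grid
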