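"""Full sampler orchestration.

One MCMC iteration is: a birth-death move over the shift configuration, a
Metropolis-Hastings multiplier update of every rate class, a sliding-window
update of every trend class and of the root state, and a Gibbs sweep of all
ancestral states. Continuous-parameter priors: exponential on rates
(scale-matched to the data), N(0, 10) on trend parameters, flat on the root
state, Poisson(1) on the number of shifts of each kind.

When the tree has no fossil tips the trend parameter is unidentifiable (on
an ultrametric tree a trend trades off exactly against the root state), so
trend updating is disabled and mu0 is fixed to 0 unless explicitly forced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernel
from .phylo_io import TimeTree, TraitTable, StateVector, bind_traits, postorder, preorder

__all__ = ["PriorConfig", "ChainSettings", "ChainResult", "multiplier_update",
           "sliding_window_update", "mh_accept", "run_chain", "run_replicates"]


@dataclass
class PriorConfig:
    """Hyperparameters of all priors used by the sampler.

    ``sigma2_rate`` (rate of the exponential prior on sigma2) and
    ``shift_rate_mean`` (mean of the exponential prior on newly born shift
    rates) default to None, meaning "match the empirical scale
    Var(tip values) / tree height" at run time.
    """

    sigma2_rate: float | None = None
    trend_sd: float = 10.0
    shift_trend_sd: float = 1.0
    shift_rate_mean: float | None = None
    poisson_lambda: float = 1.0
    birth_rate: float = 1.0
    policy: str = "likelihood_only"


@dataclass
class ChainSettings:
    iterations: int = 200_000
    sample_every: int = 100
    burnin: float = 0.25
    seed: int = 0
    multiplier_d: float = 1.5
    window_w: float | None = None   # None -> 0.5 * sd(tip values)
    trend_enabled: bool | None = None  # None -> on iff fossil tips present
    max_events: int = 100
    likelihood_on: bool = True      # False: sample from the priors only

    def __post_init__(self):
        if self.iterations < self.sample_every:
            raise ValueError("iterations must be >= sample_every")
        if not 0.0 <= self.burnin < 1.0:
            raise ValueError("burn-in fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# Elementary proposals

def multiplier_update(value: float, d: float, rng: np.random.Generator):
    """Scale a positive parameter by m = exp(lambda (u - 1/2)), lambda = 2 ln d.

    Returns (proposal, log Hastings ratio = ln m)."""
    if value <= 0 or d <= 1:
        raise ValueError("multiplier update needs value > 0 and d > 1")
    m = math.exp(2.0 * math.log(d) * (rng.random() - 0.5))
    return value * m, math.log(m)


def sliding_window_update(value: float, w: float, rng: np.random.Generator):
    """Symmetric uniform perturbation on (-w/2, w/2); Hastings ratio 0."""
    if w <= 0:
        raise ValueError("window width must be > 0")
    return value + w * (rng.random() - 0.5), 0.0


def mh_accept(log_post_old: float, log_post_new: float, log_hastings: float,
              rng: np.random.Generator) -> bool:
    """Accept with probability min(1, exp(delta log-posterior + log Hastings))."""
    delta = log_post_new - log_post_old + log_hastings
    return delta >= 0 or rng.random() < math.exp(delta)


# ---------------------------------------------------------------------------
# Chain driver

@dataclass
class ChainResult:
    """Posterior sample of one chain (post burn-in rows only).

    Arrays are aligned with the tree's node indexing of the analysed tree.
    """

    tree: TimeTree
    iteration: np.ndarray
    loglik: np.ndarray
    sigma2_bg: np.ndarray
    mu0_bg: np.ndarray
    root_state: np.ndarray
    k_rate: np.ndarray
    k_trend: np.ndarray
    states: np.ndarray        # (samples, nodes)
    sigma2_branch: np.ndarray  # branch-resolved rate per node, per sample
    mu0_branch: np.ndarray
    rate_anchors: np.ndarray   # bool (samples, nodes)
    rate_values: np.ndarray
    trend_anchors: np.ndarray
    trend_values: np.ndarray
    acceptance: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.iteration)

    def posterior_mean_states(self) -> np.ndarray:
        return self.states.mean(axis=0)

    def sigma2_estimate(self) -> float:
        """Posterior-mean tree-wide rate (average over branches and samples)."""
        keep = np.arange(self.tree.n_nodes) != self.tree.root
        return float(self.sigma2_branch[:, keep].mean())

    def mu0_estimate(self) -> float:
        keep = np.arange(self.tree.n_nodes) != self.tree.root
        return float(self.mu0_branch[:, keep].mean())

    def shift_count_samples(self) -> np.ndarray:
        return self.k_rate + self.k_trend


def _initial_states(tree: TimeTree, sv: StateVector) -> np.ndarray:
    """Internal nodes start at the mean observed value in their clade."""
    vals = sv.values.copy()
    total = np.where(sv.observed, sv.values, 0.0)
    cnt = sv.observed.astype(float)
    for i in postorder(tree):
        for c in tree.children[i]:
            if not sv.observed[i]:
                total[i] += total[c]
                cnt[i] += cnt[c]
    for i in range(tree.n_nodes):
        if not sv.observed[i]:
            vals[i] = total[i] / max(cnt[i], 1.0)
    return vals


def _flat_arrays(tree: TimeTree):
    n = tree.n_nodes
    child1 = np.full(n, -1, dtype=np.int64)
    child2 = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        ch = tree.children[i]
        if len(ch) >= 1:
            child1[i] = ch[0]
        if len(ch) == 2:
            child2[i] = ch[1]
    return child1, child2


def run_chain(tree: TimeTree, traits: TraitTable | StateVector,
              priors: PriorConfig | None = None,
              settings: ChainSettings | None = None) -> ChainResult:
    """Run one MCMC chain and return its post burn-in posterior sample."""
    priors = priors or PriorConfig()
    settings = settings or ChainSettings()
    tree.validate()
    sv = traits if isinstance(traits, StateVector) else bind_traits(tree, traits)

    obs = sv.values[sv.observed]
    height = max(tree.height, 1e-12)
    emp_var = float(np.var(obs)) if len(obs) > 1 else 1.0
    sigma2_init = max(emp_var / height, 1e-8)
    lam_sigma = priors.sigma2_rate if priors.sigma2_rate is not None else 1.0 / sigma2_init
    shift_rate_mean = (priors.shift_rate_mean if priors.shift_rate_mean is not None
                       else sigma2_init)
    win_w = settings.window_w
    if win_w is None:
        win_w = 0.5 * float(np.std(obs)) if len(obs) > 1 and np.std(obs) > 0 else 0.5

    trend_enabled = settings.trend_enabled
    if trend_enabled is None:
        trend_enabled = len(tree.fossil_tips()) > 0

    child1, child2 = _flat_arrays(tree)
    states0 = _initial_states(tree, sv)
    seed = int(settings.seed) % (2 ** 31)

    out = _kernel.run_kernel(
        tree.parent, child1, child2, tree.blen, tree.root,
        preorder(tree).copy(), postorder(tree).copy(), sv.observed,
        states0, int(settings.iterations), int(settings.sample_every), seed,
        sigma2_init, lam_sigma, priors.trend_sd, priors.shift_trend_sd,
        shift_rate_mean, priors.poisson_lambda, priors.birth_rate,
        priors.policy == "stephens", bool(trend_enabled),
        bool(settings.likelihood_on), settings.multiplier_d, win_w,
        4.0 * win_w, int(settings.max_events))

    (s_ll, s_sig_bg, s_mu_bg, s_root, s_kr, s_kt, s_states, s_sig, s_mu,
     s_rval, s_rhas, s_tval, s_thas, counters) = out

    n_samp = len(s_ll)
    iters = (np.arange(n_samp) + 1) * settings.sample_every
    keep = iters > settings.burnin * settings.iterations
    acc = {
        "rate": (int(counters[0]), int(counters[1])),
        "trend": (int(counters[2]), int(counters[3])),
        "root": (int(counters[4]), int(counters[5])),
        "bd_events": int(counters[6]),
        "bd_aborts": int(counters[7]),
    }
    return ChainResult(
        tree=tree, iteration=iters[keep], loglik=s_ll[keep],
        sigma2_bg=s_sig_bg[keep], mu0_bg=s_mu_bg[keep], root_state=s_root[keep],
        k_rate=s_kr[keep], k_trend=s_kt[keep], states=s_states[keep],
        sigma2_branch=s_sig[keep], mu0_branch=s_mu[keep],
        rate_anchors=s_rhas[keep], rate_values=s_rval[keep],
        trend_anchors=s_thas[keep], trend_values=s_tval[keep],
        acceptance=acc)


def run_replicates(trees, traits, priors=None, settings=None,
                   on_error="log") -> list:
    """Independent chains over a posterior sample of trees.

    Seeds are derived per tree from the master seed; failures are logged and
    yield None entries rather than aborting the whole batch.
    """
    import logging

    settings = settings or ChainSettings()
    results = []
    for i, tree in enumerate(trees):
        sub = ChainSettings(**{**asdict(settings),
                               "seed": derive_seed(settings.seed, i)})
        try:
            results.append(run_chain(tree, traits, priors, sub))
        except Exception:
            if on_error == "raise":
                raise
            logging.getLogger(__name__).exception("replicate %d failed", i)
            results.append(None)
    return results


def derive_seed(master: int, index: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    ss = np.random.SeedSequence([int(master), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))
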