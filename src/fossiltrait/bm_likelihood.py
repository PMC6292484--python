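"""Augmented likelihood of Brownian motion with branch-specific rate and trend.

The model: along a branch of duration ``t`` the trait of the child node is
normally distributed around the parent's value displaced by a directional
trend,

    child ~ N(parent + mu0 * t, sigma2 * t),

where ``sigma2`` is the diffusion rate and ``mu0`` the trend (expected change
per unit time). Both parameters may shift at nodes of the tree: a shift
anchored at a non-root node applies to the branch subtending that node and to
every descendant branch, until overridden by a nested shift. The likelihood
of a complete assignment of node states is the product of these normal
densities over all branches ("augmented" likelihood: internal states are
explicit parameters, not integrated out).

:func:`marginal_tip_loglik` provides the classical multivariate-normal
marginal over tips for a homogeneous model; it is used as an independent
oracle in the test suite, never in the sampler itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .phylo_io import TimeTree, StateVector, preorder

__all__ = [
    "ShiftConfig",
    "BMParams",
    "branch_logdensity",
    "resolve_classes",
    "tree_loglik",
    "marginal_tip_loglik",
    "node_covariance",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class ShiftConfig:
    """Assignment of every branch to a rate class and a trend class.

    ``rate_shifts`` / ``trend_shifts`` map anchor node id -> parameter value.
    The background values are those of the root's class.
    """

    sigma2_0: float
    mu0_0: float = 0.0
    rate_shifts: dict = field(default_factory=dict)
    trend_shifts: dict = field(default_factory=dict)

    def n_shifts(self) -> int:
        return len(self.rate_shifts) + len(self.trend_shifts)

    def copy(self) -> "ShiftConfig":
        return ShiftConfig(self.sigma2_0, self.mu0_0,
                           dict(self.rate_shifts), dict(self.trend_shifts))

    def validate(self, tree: TimeTree) -> None:
        if self.sigma2_0 <= 0 or any(v <= 0 for v in self.rate_shifts.values()):
            raise ValueError("all rates sigma2 must be > 0")
        for a in list(self.rate_shifts) + list(self.trend_shifts):
            if a == tree.root:
                raise ValueError("shifts cannot be anchored at the root")
            if not 0 <= a < tree.n_nodes:
                raise ValueError("anchor %r not in tree" % (a,))


@dataclass
class BMParams:
    """Shift configuration plus the state at the root."""

    config: ShiftConfig
    root_state: float = 0.0


def branch_logdensity(parent_state: float, child_state: float, t: float,
                      sigma2: float, mu0: float = 0.0) -> float:
    """Log normal density of a child state given its parent along one branch."""
    if t <= 0:
        raise ValueError("branch length must be > 0")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    var = sigma2 * t
    d = child_state - parent_state - mu0 * t
    return -0.5 * (_LOG2PI + math.log(var) + d * d / var)


def resolve_classes(tree: TimeTree, config: ShiftConfig):
    """Per-node branch-resolved (sigma2, mu0).

    Entry ``i`` gives the parameters of the branch subtending node ``i``
    (the root entry carries the background class). Nested shifts override
    outer shifts.
    """
    config.validate(tree)
    n = tree.n_nodes
    sig = np.empty(n)
    mu = np.empty(n)
    for i in preorder(tree):
        if i == tree.root:
            sig[i], mu[i] = config.sigma2_0, config.mu0_0
        else:
            p = tree.parent[i]
            sig[i] = config.rate_shifts.get(i, sig[p])
            mu[i] = config.trend_shifts.get(i, mu[p])
    return sig, mu


def tree_loglik(tree: TimeTree, states: StateVector, params: BMParams) -> float:
    """Sum of branch log-densities over all branches of the tree.

    Zero-length branches (sampled ancestors) contribute no term. No prior on
    the root state is included.
    """
    if not np.all(np.isfinite(states.values)):
        raise ValueError("all node states must be set and finite")
    sig, mu = resolve_classes(tree, params.config)
    ll = 0.0
    for i in range(tree.n_nodes):
        if i == tree.root or tree.blen[i] == 0.0:
            continue
        ll += branch_logdensity(states.values[tree.parent[i]], states.values[i],
                                tree.blen[i], sig[i], mu[i])
    return ll


# ---------------------------------------------------------------------------
# Marginal multivariate-normal oracle (homogeneous model only)

def node_covariance(tree: TimeTree, nodes, sigma2: float) -> np.ndarray:
    """Covariance of node states given the root: sigma2 * shared path time."""
    nodes = list(nodes)
    depth = tree.age[tree.root] - tree.age
    paths = {i: _root_path_set(tree, i) for i in nodes}
    k = len(nodes)
    cov = np.empty((k, k))
    for a in range(k):
        for b in range(k):
            shared = paths[nodes[a]] & paths[nodes[b]]
            cov[a, b] = sigma2 * sum(tree.blen[j] for j in shared)
    # guard: diagonal equals sigma2 * depth
    assert np.allclose(np.diag(cov), sigma2 * depth[nodes])
    return cov


def _root_path_set(tree, i):
    out = set()
    while tree.parent[i] != -1:
        out.add(int(i))
        i = tree.parent[i]
    return out


def marginal_tip_loglik(tree: TimeTree, tip_values: dict, sigma2: float,
                        mu0: float, v_root: float) -> float:
    """MVN log-likelihood of observed tip values, internal states integrated out.

    Valid for a single rate/trend class. ``tip_values`` maps tip label to
    value. Mean of tip i is ``v_root + mu0 * depth_i``; covariance is
    ``sigma2`` times the shared root-to-tip path time.
    """
    lab2i = tree.label_to_index()
    tips = [lab2i[l] for l in tip_values]
    y = np.array([tip_values[l] for l in tip_values], dtype=float)
    depth = tree.age[tree.root] - tree.age
    mean = v_root + mu0 * depth[tips]
    cov = node_covariance(tree, tips, sigma2)
    if np.linalg.matrix_rank(cov) < len(tips):
        raise np.linalg.LinAlgError("singular tip covariance")
    return float(stats.multivariate_normal(mean=mean, cov=cov).logpdf(y))
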