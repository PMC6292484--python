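"""Gibbs sampling of ancestral states.

Under Brownian motion with trend, the full conditional of an internal node's
state given its three neighbours (parent and two descendants) is the product
of three normal densities and is itself normal:

    ancestor term:    N(x_parent + mu0 t1, sigma2 t1)
    descendant terms: N(x_child  - mu0 t,  sigma2 t)

with each branch contributing its own resolved (sigma2, mu0). A Gibbs sweep
replaces every unobserved, non-root internal state by a direct draw from this
conditional — no accept/reject step — which is what makes the sampler scale
linearly with tree size. The root is excluded here; it is updated by
Metropolis-Hastings in :mod:`fossiltrait.mcmc_engine`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phylo_io import TimeTree, StateVector, postorder
from .bm_likelihood import BMParams, resolve_classes

__all__ = ["NodeConditional", "conditional_posterior", "gibbs_sweep"]


@dataclass
class NodeConditional:
    """Normal full conditional of one ancestral state."""

    mean: float
    variance: float


def conditional_posterior(tree: TimeTree, node: int, states: StateVector,
                          params: BMParams, resolved=None) -> NodeConditional:
    """Precision-weighted combination of the three neighbouring normal terms.

    Zero-length branches (sampled-ancestor attachments) drop out of the
    product; if every neighbouring term is degenerate the conditional is
    undefined and an error is raised.
    """
    node = int(node)
    if tree.is_tip(node) or node == tree.root:
        raise ValueError("conditional posterior is defined for internal, "
                         "non-root nodes")
    sig, mu = resolved if resolved is not None else resolve_classes(tree, params.config)
    v = states.values

    prec = 0.0
    wsum = 0.0
    t1 = tree.blen[node]
    if t1 > 0:  # ancestor: x ~ N(parent + mu t1, sig t1)
        w = 1.0 / (sig[node] * t1)
        prec += w
        wsum += w * (v[tree.parent[node]] + mu[node] * t1)
    for c in tree.children[node]:
        tc = tree.blen[c]
        if tc > 0:  # descendant: x ~ N(child - mu tc, sig tc)
            w = 1.0 / (sig[c] * tc)
            prec += w
            wsum += w * (v[c] - mu[c] * tc)
    if prec <= 0:
        raise ValueError("all neighbouring branches of node %d are degenerate" % node)
    var = 1.0 / prec
    return NodeConditional(mean=wsum * var, variance=var)


def gibbs_sweep(tree: TimeTree, states: StateVector, params: BMParams,
                rng: np.random.Generator) -> StateVector:
    """One systematic-scan Gibbs update of all unobserved internal states.

    Traversal is post-order (tips first), which propagates tip information
    rootward within a single sweep. Observed states (tips, sampled ancestors)
    and the root are left untouched. The input is modified in place and
    returned.
    """
    resolved = resolve_classes(tree, params.config)
    v = states.values
    for i in postorder(tree):
        if i == tree.root or states.observed[i] or tree.is_tip(i):
            continue
        cond = conditional_posterior(tree, i, states, params, resolved=resolved)
        v[i] = cond.mean + np.sqrt(cond.variance) * rng.standard_normal()
    return states
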