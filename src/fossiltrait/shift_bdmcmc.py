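"""Birth-death MCMC over the number and placement of rate/trend shifts.

Model search is trans-dimensional: a shift (new rate or trend class anchored
at a non-root node) can be *born* or can *die*. Instead of an accept/reject
step, one simulates a continuous-time birth-death process on model space for
one unit of virtual time per MCMC iteration:

* births occur at a fixed rate beta = 1, choosing rate-vs-trend with equal
  probability, an anchor uniformly among eligible non-root nodes, and a new
  value drawn from its prior (exponential for rates, standard normal for
  trends);
* each existing shift j dies at rate delta_j proportional to the ratio of the
  augmented likelihood without the shift (its clade reassigned to the parent
  class's current value) to the likelihood with it. Shifts that improve the
  fit have delta_j near 0 and persist; shifts that do not are removed almost
  immediately.

The default `likelihood_only` policy uses the bare likelihood ratio as the
death rate. The `stephens` policy additionally carries the exact
detailed-balance correction for prior-sampled births, which reduces to the
constant factor beta_kind / lambda (lambda = 1 is the Poisson prior mean on
the number of shifts of each kind) and makes the no-data stationary
distribution of the per-kind shift count exactly Poisson(lambda); the bare
ratio is equivalent to halving that prior mean, i.e. it is slightly more
parsimonious.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .phylo_io import TimeTree, StateVector
from .bm_likelihood import BMParams, ShiftConfig, tree_loglik

__all__ = ["ShiftPriors", "eligible_anchors", "propose_birth", "death_rate",
           "bdmcmc_step"]

_LOG_DELTA_CAP = 40.0  # caps death rates at e^40; beyond this removal is certain


@dataclass
class ShiftPriors:
    """Priors/proposals governing the birth-death model search."""

    poisson_lambda: float = 1.0      # prior mean number of shifts per kind
    rate_value_mean: float = 1.0     # mean of the exponential prior on new sigma2
    trend_value_sd: float = 1.0      # sd of the normal prior on new trend values
    birth_rate: float = 1.0          # fixed
    policy: str = "likelihood_only"  # or "stephens"
    trend_shifts_enabled: bool = True


def eligible_anchors(tree: TimeTree, config: ShiftConfig, kind: str) -> list:
    """Non-root nodes not already carrying a shift of the given kind."""
    taken = config.rate_shifts if kind == "rate" else config.trend_shifts
    return [i for i in range(tree.n_nodes) if i != tree.root and i not in taken]


def propose_birth(tree: TimeTree, config: ShiftConfig, states: StateVector,
                  priors: ShiftPriors, rng: np.random.Generator) -> ShiftConfig:
    """Add one shift: uniform anchor, kind with probability 1/2, value from prior.

    Returns a new configuration; if no anchor is eligible for the chosen kind
    the proposal is a no-op and the input configuration is returned unchanged.
    """
    kind = "rate"
    if priors.trend_shifts_enabled and rng.random() < 0.5:
        kind = "trend"
    anchors = eligible_anchors(tree, config, kind)
    if not anchors:
        return config
    anchor = int(anchors[rng.integers(len(anchors))])
    new = config.copy()
    if kind == "rate":
        new.rate_shifts[anchor] = float(rng.exponential(priors.rate_value_mean))
    else:
        new.trend_shifts[anchor] = float(rng.normal(0.0, priors.trend_value_sd))
    return new


def _without(config: ShiftConfig, kind: str, anchor: int) -> ShiftConfig:
    new = config.copy()
    if kind == "rate":
        del new.rate_shifts[anchor]
    else:
        del new.trend_shifts[anchor]
    return new


def _log_correction(priors: ShiftPriors) -> float:
    if priors.policy == "likelihood_only":
        return 0.0
    beta_kind = priors.birth_rate * (0.5 if priors.trend_shifts_enabled else 1.0)
    return math.log(beta_kind / priors.poisson_lambda)


def death_rate(tree: TimeTree, config: ShiftConfig, states: StateVector,
               kind: str, anchor: int, params_root: float,
               priors: ShiftPriors) -> float:
    """delta_j = L(without shift j) / L(with shift j), prior-corrected.

    Removing the shift reassigns its clade to the current value of its parent
    class; nested shifts are preserved. Computed in log space and capped.
    """
    with_ll = tree_loglik(tree, states, BMParams(config, params_root))
    without_ll = tree_loglik(tree, states,
                             BMParams(_without(config, kind, anchor), params_root))
    log_delta = (without_ll - with_ll) + _log_correction(priors)
    return math.exp(min(log_delta, _LOG_DELTA_CAP))


def bdmcmc_step(tree: TimeTree, config: ShiftConfig, states: StateVector,
                priors: ShiftPriors, rng: np.random.Generator,
                root_state: float = 0.0, max_events: int = 100) -> ShiftConfig:
    """Simulate the model-space birth-death process for one unit of virtual time.

    Repeatedly: compute the total event rate R = beta + sum(delta_j), draw an
    exponential waiting time with rate R, and stop once accumulated virtual
    time exceeds 1; otherwise execute a birth with probability beta / R or
    kill shift j with probability delta_j / R.
    """
    t_acc = 0.0
    events = 0
    config = config.copy()
    while True:
        if events >= max_events:
            warnings.warn("birth-death step aborted after %d events" % events)
            break
        shifts = ([("rate", a) for a in config.rate_shifts]
                  + [("trend", a) for a in config.trend_shifts])
        deltas = [death_rate(tree, config, states, k, a, root_state, priors)
                  for k, a in shifts]
        rate_total = priors.birth_rate + sum(deltas)
        t_acc += rng.exponential(1.0 / rate_total)
        if t_acc > 1.0:
            break
        u = rng.random() * rate_total
        if u < priors.birth_rate:
            config = propose_birth(tree, config, states, priors, rng)
        else:
            u -= priors.birth_rate
            for (k, a), d in zip(shifts, deltas):
                if u < d:
                    config = _without(config, k, a)
                    break
                u -= d
        events += 1
    return config
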