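"""Conjugate conditional of an ancestral state and the Gibbs sweep."""

import numpy as np
import pytest
from scipy import stats

from fossiltrait.phylo_io import read_newick, bind_traits, TraitTable, StateVector
from fossiltrait.bm_likelihood import (ShiftConfig, BMParams, branch_logdensity,
                                       node_covariance)
from fossiltrait.ancestral_gibbs import conditional_posterior, gibbs_sweep


def make_states(tree, tips, internal=0.0):
    sv = bind_traits(tree, TraitTable(tips))
    sv.values[~sv.observed] = internal
    return sv


def test_symmetric_precision_weighted_mean(three_tip):
    """Equal branches and rates, mu0 = 0: mean is the plain average."""
    tree = read_newick("((A:1,B:1):1,C:1);")
    sv = make_states(tree, {"A": 1.0, "B": 2.0, "C": 0.0})
    sv.values[tree.root] = 3.0  # parent neighbour of the internal node
    node = tree.parent[tree.label_to_index()["A"]]
    cond = conditional_posterior(tree, node, sv, BMParams(ShiftConfig(0.7)))
    assert cond.mean == pytest.approx((1.0 + 2.0 + 3.0) / 3.0)
    assert cond.variance == pytest.approx(0.7 * 1.0 / 3.0)


def test_trend_sign_convention():
    """Ancestor term adds mu0*t, descendant terms subtract it: with all
    neighbours at 0 the conditional mean is -m*t/3."""
    tree = read_newick("((A:1,B:1):1,C:1);")
    m = 0.8
    sv = make_states(tree, {"A": 0.0, "B": 0.0, "C": 0.0})
    sv.values[tree.root] = 0.0
    node = tree.parent[tree.label_to_index()["A"]]
    cond = conditional_posterior(tree, node, sv, BMParams(ShiftConfig(1.0, m)))
    assert cond.mean == pytest.approx((m - m - m) / 3.0)


def test_distant_parent_limit():
    """As t1 -> inf the ancestor term's precision vanishes and the conditional
    tends to the two-descendant combination."""
    far = read_newick("((A:1,B:1):1e9,C:2e9);")
    sv = make_states(far, {"A": 1.0, "B": 3.0, "C": 0.0})
    sv.values[far.root] = -500.0
    node = far.parent[far.label_to_index()["A"]]
    cond = conditional_posterior(far, node, sv, BMParams(ShiftConfig(1.0)))
    assert cond.mean == pytest.approx(2.0, abs=1e-5)
    assert cond.variance == pytest.approx(0.5, rel=1e-5)


def test_branch_specific_parameters_enter_each_term():
    tree = read_newick("((A:2,B:1):1,C:1);")
    lab = tree.label_to_index()
    node = int(tree.parent[lab["A"]])
    cfg = ShiftConfig(sigma2_0=1.0, mu0_0=0.0,
                      rate_shifts={lab["A"]: 4.0}, trend_shifts={lab["B"]: 1.5})
    sv = make_states(tree, {"A": 2.0, "B": 1.0, "C": 0.0})
    sv.values[tree.root] = -1.0
    cond = conditional_posterior(tree, node, sv, BMParams(cfg))
    # by hand: parent (t=1, s2=1, mu=0); A (t=2, s2=4, mu=0); B (t=1, s2=1, mu=1.5)
    w = np.array([1.0, 1.0 / 8.0, 1.0])
    means = np.array([-1.0, 2.0, 1.0 - 1.5])
    assert cond.variance == pytest.approx(1.0 / w.sum())
    assert cond.mean == pytest.approx((w * means).sum() / w.sum())


def test_conditional_matches_normalized_product_ks(rng):
    """Draws from the conditional pass a KS test against the numerically
    normalized product of the three neighbour densities."""
    tree = read_newick("((A:1.3,B:0.6):0.9,C:1.5);")
    sv = make_states(tree, {"A": 0.4, "B": -0.8, "C": 0.3})
    sv.values[tree.root] = 0.1
    params = BMParams(ShiftConfig(0.6, 0.35))
    node = int(tree.parent[tree.label_to_index()["A"]])
    cond = conditional_posterior(tree, node, sv, params)

    grid = np.linspace(cond.mean - 8 * np.sqrt(cond.variance),
                       cond.mean + 8 * np.sqrt(cond.variance), 4001)
    logp = np.array([
        branch_logdensity(sv.values[tree.root], x, 0.9, 0.6, 0.35)
        + branch_logdensity(x, 0.4, 1.3, 0.6, 0.35)
        + branch_logdensity(x, -0.8, 0.6, 0.6, 0.35) for x in grid])
    pdf = np.exp(logp - logp.max())
    cdf = np.cumsum(pdf)
    cdf /= cdf[-1]

    draws = cond.mean + np.sqrt(cond.variance) * rng.standard_normal(100_000)
    ks = stats.kstest(draws, lambda x: np.interp(x, grid, cdf))
    assert ks.pvalue > 1e-3


def test_sweep_noop_when_everything_observed(three_tip, rng):
    sv = make_states(three_tip, {"A": 1.0, "B": 2.0, "C": 3.0})
    sv.observed[:] = True
    before = sv.values.copy()
    gibbs_sweep(three_tip, sv, BMParams(ShiftConfig(1.0)), rng)
    assert np.array_equal(sv.values, before)


def test_sweep_seed_reproducible(five_tip):
    tips = {k: float(i) for i, k in enumerate("ABCDE")}
    out = []
    for _ in range(2):
        sv = make_states(five_tip, tips)
        r = np.random.default_rng(42)
        for _ in range(10):
            gibbs_sweep(five_tip, sv, BMParams(ShiftConfig(1.0)), r)
        out.append(sv.values.copy())
    assert np.array_equal(out[0], out[1])


def _mvn_conditional_mean(tree, internal, tips, tip_vals, sigma2, mu0, root_val):
    """Conditional mean of internal states given tips, from MVN path algebra."""
    idx = list(internal) + list(tips)
    cov = node_covariance(tree, idx, sigma2)
    depth = tree.age[tree.root] - tree.age
    mean = root_val + mu0 * depth[idx]
    k = len(internal)
    S11, S12, S22 = cov[:k, :k], cov[:k, k:], cov[k:, k:]
    y = np.asarray(tip_vals) - mean[k:]
    return mean[:k] + S12 @ np.linalg.solve(S22, y)


@pytest.mark.parametrize("mu0", [0.0, 0.4])
def test_gibbs_long_run_matches_mvn_conditional(five_tip, mu0, rng):
    """Posterior mean of Gibbs-sampled internal states (root fixed) equals the
    marginal-MVN conditional mean within Monte-Carlo error."""
    tips = {"A": 1.0, "B": 0.3, "C": -0.5, "D": 0.1, "E": 1.4}
    sv = make_states(five_tip, tips)
    root_val = 0.2
    sv.values[five_tip.root] = root_val
    sv.observed[five_tip.root] = True  # hold the root fixed for this check
    params = BMParams(ShiftConfig(0.8, mu0), root_state=root_val)

    lab = five_tip.label_to_index()
    internal = [i for i in range(five_tip.n_nodes)
                if not five_tip.is_tip(i) and i != five_tip.root]
    tip_idx = [lab[k] for k in tips]
    want = _mvn_conditional_mean(five_tip, internal, tip_idx,
                                 list(tips.values()), 0.8, mu0, root_val)

    n_it, burn = 6000, 500
    acc = np.zeros(len(internal))
    draws = np.zeros((n_it - burn, len(internal)))
    for it in range(n_it):
        gibbs_sweep(five_tip, sv, params, rng)
        if it >= burn:
            draws[it - burn] = sv.values[internal]
    got = draws.mean(axis=0)
    se = draws.std(axis=0) / np.sqrt(len(draws) / 20.0)  # crude autocorr. factor
    assert np.all(np.abs(got - want) < 3 * se + 0.02)


def test_gibbs_moments_stationary_between_1k_and_10k(three_tip, rng):
    """Detailed balance: the sampled conditional moments do not drift."""
    sv = make_states(three_tip, {"A": 1.0, "B": -1.0, "C": 0.5})
    sv.values[three_tip.root] = 0.0
    sv.observed[three_tip.root] = True
    params = BMParams(ShiftConfig(1.0))
    node = int(three_tip.parent[three_tip.label_to_index()["A"]])
    chunks = []
    trace = []
    for it in range(10_000):
        gibbs_sweep(three_tip, sv, params, rng)
        trace.append(sv.values[node])
    early = np.mean(trace[500:1000])
    late = np.mean(trace[5000:])
    assert abs(early - late) < 0.1
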