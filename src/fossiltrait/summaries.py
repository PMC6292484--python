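"""Accuracy metrics and posterior post-processing.

Parameter recovery across simulation replicates is summarised by the mean
absolute percentage error (MAPE) for rates, the mean absolute error (MAE)
for trends, the coefficient of determination (R^2) between true and
posterior-mean ancestral states, and the frequency with which the
posterior-mode shift count matches the truth. Empirical-style summaries:
clade-averaged rates and trends, per-clade credible intervals of ancestral
states, and the range of trait values occupied through time (min/max of
reconstructed states among lineages crossing each 1-Myr bin).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phylo_io import TimeTree, clade_nodes, mrca

__all__ = ["AccuracyReport", "mape", "mae", "r_squared", "posterior_mode_count",
           "shift_recovery", "clade_average_params", "range_through_time",
           "ancestral_credible_intervals", "RangeThroughTime"]


def mape(true_values, estimates) -> float:
    """Mean over replicates of |est - true| / |true|."""
    t = np.asarray(true_values, dtype=float)
    e = np.asarray(estimates, dtype=float)
    if np.any(t == 0):
        raise ValueError("MAPE undefined for a true value of 0")
    return float(np.mean(np.abs(e - t) / np.abs(t)))


def mae(true_values, estimates) -> float:
    """Mean absolute error."""
    t = np.asarray(true_values, dtype=float)
    e = np.asarray(estimates, dtype=float)
    return float(np.mean(np.abs(e - t)))


def r_squared(true_states, estimated_states) -> float:
    """1 - SS_res / SS_tot of estimates against true values (one replicate)."""
    t = np.asarray(true_states, dtype=float)
    e = np.asarray(estimated_states, dtype=float)
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant true states")
    return 1.0 - float(np.sum((e - t) ** 2)) / ss_tot


def r_squared_fit(true_states, estimated_states) -> float:
    """Coefficient of determination of the regression of estimates on truth.

    Equals the squared Pearson correlation. Unlike :func:`r_squared` it is
    insensitive to a systematic offset or shrinkage of the estimates, which
    is the appropriate summary of reconstruction accuracy when the estimator
    is biased by design (e.g. trend-free reconstruction of trended data).
    """
    t = np.asarray(true_states, dtype=float)
    e = np.asarray(estimated_states, dtype=float)
    if np.std(t) == 0 or np.std(e) == 0:
        raise ValueError("R^2 undefined for constant input")
    return float(np.corrcoef(t, e)[0, 1] ** 2)


def posterior_mode_count(samples) -> int:
    """Mode of sampled shift counts; ties resolve toward the smaller count."""
    samples = np.asarray(samples, dtype=int)
    vals, cnt = np.unique(samples, return_counts=True)
    return int(vals[np.argmax(cnt)])  # np.unique sorts, argmax takes first max


def shift_recovery(true_counts, posterior_count_samples) -> float:
    """Fraction of replicates whose posterior-mode total count equals truth."""
    hits = [posterior_mode_count(s) == t
            for t, s in zip(true_counts, posterior_count_samples)]
    return float(np.mean(hits))


@dataclass
class AccuracyReport:
    """Per-scenario recovery metrics across simulation replicates."""

    scenario_id: str
    n_replicates: int
    mape_sigma2: float
    mae_mu0: float
    mean_r2: float
    shift_recovery: float
    settings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"scenario": self.scenario_id, "replicates": self.n_replicates,
                "mape_sigma2": self.mape_sigma2, "mae_mu0": self.mae_mu0,
                "mean_r2": self.mean_r2, "shift_recovery": self.shift_recovery}


# ---------------------------------------------------------------------------
# Clade summaries

def clade_average_params(result, clade_tips: dict) -> dict:
    """Average branch-resolved (sigma2, mu0) over each named clade's branches
    and over posterior samples.

    ``clade_tips`` maps clade name -> iterable of tip labels; the MRCA is
    located per tree so the summary tolerates topological variation across a
    posterior tree sample.
    """
    tree = result.tree
    lab2i = tree.label_to_index()
    out = {}
    for name, tips in clade_tips.items():
        idx = [lab2i[t] for t in tips]
        anc = mrca(tree, idx)
        members = sorted(clade_nodes(tree, anc) - {tree.root})
        out[name] = {
            "sigma2": float(result.sigma2_branch[:, members].mean()),
            "mu0": float(result.mu0_branch[:, members].mean()),
        }
    return out


def ancestral_credible_intervals(results, clade_tips: dict,
                                 level: float = 0.95) -> dict:
    """Equal-tailed credible interval of the state at each clade's MRCA,
    pooled over a list of chain results (replicate trees)."""
    a = (1.0 - level) / 2.0
    pooled: dict = {name: [] for name in clade_tips}
    for res in results:
        if res is None:
            continue
        lab2i = res.tree.label_to_index()
        for name, tips in clade_tips.items():
            idx = [lab2i[t] for t in tips if t in lab2i]
            if not idx:
                continue
            anc = mrca(res.tree, idx)
            pooled[name].append(res.states[:, anc])
    out = {}
    for name, chunks in pooled.items():
        allv = np.concatenate(chunks)
        lo, mid, hi = np.quantile(allv, [a, 0.5, 1.0 - a])
        out[name] = {"lower": float(lo), "median": float(mid), "upper": float(hi)}
    return out


# ---------------------------------------------------------------------------
# Range through time

@dataclass
class RangeThroughTime:
    """Min/max envelope of reconstructed trait values per 1-Myr time bin."""

    bin_edges: np.ndarray   # ages, oldest first is bin_edges[0]
    minimum: np.ndarray
    maximum: np.ndarray


def range_through_time(results, bin_width: float = 1.0) -> RangeThroughTime:
    """Envelope of posterior-mean states among lineages alive in each bin.

    States are interpolated linearly in time along each branch (the BM
    conditional expectation between two known endpoints is linear); per bin
    the min and max over all branch segments crossing the bin are taken, then
    averaged across replicate analyses.
    """
    results = [r for r in results if r is not None]
    if not results:
        raise ValueError("no results to summarize")
    max_age = max(r.tree.height for r in results)
    n_bins = int(np.ceil(max_age / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    mins = np.full((len(results), n_bins), np.nan)
    maxs = np.full((len(results), n_bins), np.nan)
    for ri, res in enumerate(results):
        tree = res.tree
        v = res.posterior_mean_states()
        age = tree.age
        for i in range(tree.n_nodes):
            p = tree.parent[i]
            if p == -1:
                lo_t, hi_t = age[i], age[i]
                lo_v = hi_v = v[i]
            else:
                lo_t, hi_t = age[i], age[p]
                lo_v, hi_v = v[i], v[p]
            b0 = int(np.floor(lo_t / bin_width))
            b1 = min(int(np.ceil(hi_t / bin_width)), n_bins) - 1
            for b in range(b0, max(b1, b0) + 1):
                if b >= n_bins:
                    continue
                t_lo = max(lo_t, edges[b])
                t_hi = min(hi_t, edges[b + 1])
                if hi_t > lo_t:
                    f_lo = (t_lo - lo_t) / (hi_t - lo_t)
                    f_hi = (t_hi - lo_t) / (hi_t - lo_t)
                    seg = (lo_v + f_lo * (hi_v - lo_v), lo_v + f_hi * (hi_v - lo_v))
                else:
                    seg = (lo_v, hi_v)
                mins[ri, b] = np.nanmin([mins[ri, b], min(seg)])
                maxs[ri, b] = np.nanmax([maxs[ri, b], max(seg)])
    with np.errstate(invalid="ignore"):
        return RangeThroughTime(edges, np.nanmean(mins, axis=0),
                                np.nanmean(maxs, axis=0))
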