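"""Compiled inner loop of the sampler.

The MCMC over (states, rates, trends, shift configuration) is executed over
flat arrays by numba-compiled routines: per iteration one virtual-time unit
of the model-space birth-death process, Metropolis-Hastings updates of every
rate and trend class and of the root state, and a full Gibbs sweep of the
ancestral states. The pure-Python operations in :mod:`bm_likelihood`,
:mod:`ancestral_gibbs` and :mod:`shift_bdmcmc` define the same computations
one step at a time and serve as the reference implementation in the tests.

All randomness uses numba's internal global RNG seeded once per chain.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_LOG2PI = math.log(2.0 * math.pi)
_LOG_DELTA_CAP = 40.0


@njit(cache=True)
def _resolve(pre, parent, root, bg, has, val, out):
    for k in range(pre.shape[0]):
        i = pre[k]
        if i == root:
            out[i] = bg
        elif has[i]:
            out[i] = val[i]
        else:
            out[i] = out[parent[i]]


@njit(cache=True)
def _loglik(parent, blen, root, states, sig, mu):
    ll = 0.0
    for i in range(parent.shape[0]):
        if i == root or blen[i] <= 0.0:
            continue
        var = sig[i] * blen[i]
        d = states[i] - states[parent[i]] - mu[i] * blen[i]
        ll += -0.5 * (_LOG2PI + math.log(var) + d * d / var)
    return ll


@njit(cache=True)
def _gibbs_sweep(post, parent, child1, child2, blen, root, observed,
                 states, sig, mu):
    for k in range(post.shape[0]):
        i = post[k]
        if i == root or observed[i] or child1[i] < 0:
            continue
        prec = 0.0
        wsum = 0.0
        t1 = blen[i]
        if t1 > 0.0:
            w = 1.0 / (sig[i] * t1)
            prec += w
            wsum += w * (states[parent[i]] + mu[i] * t1)
        c = child1[i]
        if c >= 0 and blen[c] > 0.0:
            w = 1.0 / (sig[c] * blen[c])
            prec += w
            wsum += w * (states[c] - mu[c] * blen[c])
        c = child2[i]
        if c >= 0 and blen[c] > 0.0:
            w = 1.0 / (sig[c] * blen[c])
            prec += w
            wsum += w * (states[c] - mu[c] * blen[c])
        if prec > 0.0:
            v = 1.0 / prec
            states[i] = wsum * v + math.sqrt(v) * np.random.standard_normal()


@njit(cache=True)
def _pick_anchor(root, has, j):
    """Return the j-th non-root node without a same-kind shift."""
    n = has.shape[0]
    cnt = -1
    for i in range(n):
        if i == root or has[i]:
            continue
        cnt += 1
        if cnt == j:
            return i
    return -1


@njit(cache=True)
def run_kernel(parent, child1, child2, blen, root, pre, post, observed,
               states0, n_iter, sample_every, seed,
               sigma2_init, lam_sigma, trend_bg_sd, trend_shift_sd,
               shift_rate_mean, pois_lambda, birth_rate, stephens,
               trend_enabled, likelihood_on, mult_d, win_w, win_root,
               max_events):
    np.random.seed(seed)
    n = parent.shape[0]
    states = states0.copy()

    # shift bookkeeping: value arrays indexed by anchor node
    r_has = np.zeros(n, dtype=np.bool_)
    r_val = np.zeros(n)
    t_has = np.zeros(n, dtype=np.bool_)
    t_val = np.zeros(n)
    sig_bg = sigma2_init
    mu_bg = 0.0

    sig = np.empty(n)
    mu = np.empty(n)
    scratch = np.empty(n)
    _resolve(pre, parent, root, sig_bg, r_has, r_val, sig)
    _resolve(pre, parent, root, mu_bg, t_has, t_val, mu)

    lam = 2.0 * math.log(mult_d)
    lp = 1.0 if likelihood_on else 0.0
    if stephens:
        beta_kind = birth_rate * (0.5 if trend_enabled else 1.0)
        log_corr = math.log(beta_kind / pois_lambda)
    else:
        log_corr = 0.0

    n_samp = n_iter // sample_every
    s_ll = np.zeros(n_samp)
    s_sig_bg = np.zeros(n_samp)
    s_mu_bg = np.zeros(n_samp)
    s_root = np.zeros(n_samp)
    s_kr = np.zeros(n_samp, dtype=np.int64)
    s_kt = np.zeros(n_samp, dtype=np.int64)
    s_states = np.zeros((n_samp, n))
    s_sig = np.zeros((n_samp, n))
    s_mu = np.zeros((n_samp, n))
    s_rval = np.zeros((n_samp, n))
    s_rhas = np.zeros((n_samp, n), dtype=np.bool_)
    s_tval = np.zeros((n_samp, n))
    s_thas = np.zeros((n_samp, n), dtype=np.bool_)
    counters = np.zeros(8, dtype=np.int64)  # racc rtot tacc ttot root_acc root_tot bd_ev bd_abort

    deltas = np.empty(2 * n)
    d_anchor = np.empty(2 * n, dtype=np.int64)
    d_kind = np.empty(2 * n, dtype=np.int64)  # 0 rate, 1 trend

    for it in range(n_iter):
        # ---- birth-death move over the shift configuration -----------------
        t_acc = 0.0
        events = 0
        while True:
            if events >= max_events:
                counters[7] += 1
                break
            ll_with = lp * _loglik(parent, blen, root, states, sig, mu)
            nshift = 0
            for i in range(n):
                if r_has[i]:
                    r_has[i] = False
                    _resolve(pre, parent, root, sig_bg, r_has, r_val, scratch)
                    ll_wo = lp * _loglik(parent, blen, root, states, scratch, mu)
                    r_has[i] = True
                    ld = (ll_wo - ll_with) + log_corr
                    if ld > _LOG_DELTA_CAP:
                        ld = _LOG_DELTA_CAP
                    deltas[nshift] = math.exp(ld)
                    d_anchor[nshift] = i
                    d_kind[nshift] = 0
                    nshift += 1
                if t_has[i]:
                    t_has[i] = False
                    _resolve(pre, parent, root, mu_bg, t_has, t_val, scratch)
                    ll_wo = lp * _loglik(parent, blen, root, states, sig, scratch)
                    t_has[i] = True
                    ld = (ll_wo - ll_with) + log_corr
                    if ld > _LOG_DELTA_CAP:
                        ld = _LOG_DELTA_CAP
                    deltas[nshift] = math.exp(ld)
                    d_anchor[nshift] = i
                    d_kind[nshift] = 1
                    nshift += 1
            total = birth_rate
            for j in range(nshift):
                total += deltas[j]
            t_acc += np.random.exponential(1.0 / total)
            if t_acc > 1.0:
                break
            u = np.random.random() * total
            if u < birth_rate:
                # birth: kind 1/2, anchor uniform among eligible, value from prior
                want_trend = trend_enabled and np.random.random() < 0.5
                if want_trend:
                    m = 0
                    for i in range(n):
                        if i != root and not t_has[i]:
                            m += 1
                    if m > 0:
                        a = _pick_anchor(root, t_has, np.random.randint(m))
                        t_has[a] = True
                        t_val[a] = trend_shift_sd * np.random.standard_normal()
                        _resolve(pre, parent, root, mu_bg, t_has, t_val, mu)
                else:
                    m = 0
                    for i in range(n):
                        if i != root and not r_has[i]:
                            m += 1
                    if m > 0:
                        a = _pick_anchor(root, r_has, np.random.randint(m))
                        r_has[a] = True
                        r_val[a] = np.random.exponential(shift_rate_mean)
                        _resolve(pre, parent, root, sig_bg, r_has, r_val, sig)
            else:
                u -= birth_rate
                for j in range(nshift):
                    if u < deltas[j]:
                        a = d_anchor[j]
                        if d_kind[j] == 0:
                            r_has[a] = False
                            _resolve(pre, parent, root, sig_bg, r_has, r_val, sig)
                        else:
                            t_has[a] = False
                            _resolve(pre, parent, root, mu_bg, t_has, t_val, mu)
                        break
                    u -= deltas[j]
            events += 1
            counters[6] += 1

        # ---- MH multiplier updates of every rate class ---------------------
        ll_cur = lp * _loglik(parent, blen, root, states, sig, mu)
        for cls in range(-1, n):
            if cls >= 0 and not r_has[cls]:
                continue
            old = sig_bg if cls < 0 else r_val[cls]
            mlt = math.exp(lam * (np.random.random() - 0.5))
            new = old * mlt
            if cls < 0:
                sig_bg = new
                dprior = -lam_sigma * (new - old)
            else:
                r_val[cls] = new
                dprior = -(new - old) / shift_rate_mean
            _resolve(pre, parent, root, sig_bg, r_has, r_val, scratch)
            ll_new = lp * _loglik(parent, blen, root, states, scratch, mu)
            if math.log(np.random.random()) < ll_new - ll_cur + dprior + math.log(mlt):
                sig[:] = scratch
                ll_cur = ll_new
                counters[0] += 1
            else:
                if cls < 0:
                    sig_bg = old
                else:
                    r_val[cls] = old
            counters[1] += 1

        # ---- MH sliding-window updates of every trend class ----------------
        if trend_enabled:
            for cls in range(-1, n):
                if cls >= 0 and not t_has[cls]:
                    continue
                old = mu_bg if cls < 0 else t_val[cls]
                new = old + win_w * (np.random.random() - 0.5)
                if cls < 0:
                    mu_bg = new
                    dprior = -(new * new - old * old) / (2.0 * trend_bg_sd ** 2)
                else:
                    t_val[cls] = new
                    dprior = -(new * new - old * old) / (2.0 * trend_shift_sd ** 2)
                _resolve(pre, parent, root, mu_bg, t_has, t_val, scratch)
                ll_new = lp * _loglik(parent, blen, root, states, sig, scratch)
                if math.log(np.random.random()) < ll_new - ll_cur + dprior:
                    mu[:] = scratch
                    ll_cur = ll_new
                    counters[2] += 1
                else:
                    if cls < 0:
                        mu_bg = old
                    else:
                        t_val[cls] = old
                counters[3] += 1

        # ---- MH sliding-window update of the root state (flat prior) -------
        if likelihood_on and not observed[root]:
            old = states[root]
            states[root] = old + win_root * (np.random.random() - 0.5)
            ll_new = _loglik(parent, blen, root, states, sig, mu)
            if math.log(np.random.random()) < ll_new - ll_cur:
                ll_cur = ll_new
                counters[4] += 1
            else:
                states[root] = old
            counters[5] += 1

        # ---- Gibbs sweep of ancestral states -------------------------------
        if likelihood_on:
            _gibbs_sweep(post, parent, child1, child2, blen, root, observed,
                         states, sig, mu)

        if (it + 1) % sample_every == 0:
            s = (it + 1) // sample_every - 1
            s_ll[s] = _loglik(parent, blen, root, states, sig, mu)
            s_sig_bg[s] = sig_bg
            s_mu_bg[s] = mu_bg
            s_root[s] = states[root]
            kr = 0
            kt = 0
            for i in range(n):
                if r_has[i]:
                    kr += 1
                if t_has[i]:
                    kt += 1
            s_kr[s] = kr
            s_kt[s] = kt
            s_states[s] = states
            s_sig[s] = sig
            s_mu[s] = mu
            s_rval[s] = r_val
            s_rhas[s] = r_has
            s_tval[s] = t_val
            s_thas[s] = t_has

    return (s_ll, s_sig_bg, s_mu_bg, s_root, s_kr, s_kt, s_states, s_sig,
            s_mu, s_rval, s_rhas, s_tval, s_thas, counters)
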