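"""Compiled inner loops of the samplers (numba nopython kernels).

The collapsed CRP label scan and the restricted Gibbs scan of the
split-merge move are sequential over items with O(d^3) work per step, which
is pure interpreter overhead in numpy; the kernels here run them at machine
speed while consuming the same `numpy.random.Generator` stream as the
Python callers, so runs remain exactly reproducible given the seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["crp_scan", "restricted_scan_kernel", "pred_logpdf_stats", "block_log_marginal"]


@njit(cache=False, inline="always")
def _log_multigamma(d, x):
    out = 0.25 * d * (d - 1) * math.log(math.pi)
    for j in range(d):
        out += math.lgamma(x - 0.5 * j)
    return out


@njit(cache=False)
def block_log_marginal(block, kappa0, nu0, xi2):
    """Log NIW marginal likelihood of a block of latent factors (Lambda0 = xi2 I, mu0 = 0)."""
    m, d = block.shape
    if m == 0:
        return 0.0
    km = kappa0 + m
    S = np.empty((d, d))
    s_vec = np.zeros(d)
    for i in range(m):
        for a in range(d):
            s_vec[a] += block[i, a]
    for a in range(d):
        for b in range(d):
            acc = 0.0
            for i in range(m):
                acc += block[i, a] * block[i, b]
            S[a, b] = acc - s_vec[a] * s_vec[b] / km
        S[a, a] += xi2
    L = np.empty((d, d))
    ok = _cholesky_inplace(S, L)
    if not ok:
        for a in range(d):
            S[a, a] += 1e-10
        _cholesky_inplace(S, L)
    logdet = 0.0
    for a in range(d):
        logdet += 2.0 * math.log(L[a, a])
    return (
        -0.5 * m * d * math.log(math.pi)
        + 0.5 * d * math.log(kappa0 / km)
        + _log_multigamma(d, 0.5 * (nu0 + m))
        - _log_multigamma(d, 0.5 * nu0)
        + 0.5 * nu0 * d * math.log(xi2)
        - 0.5 * (nu0 + m) * logdet
    )


@njit(cache=False, inline="always")
def _cholesky_inplace(S, L):
    """Lower Cholesky of S into L; returns False on a nonpositive pivot."""
    d = S.shape[0]
    for a in range(d):
        for b in range(d):
            L[a, b] = 0.0
    for a in range(d):
        for b in range(a + 1):
            s = S[a, b]
            for c in range(b):
                s -= L[a, c] * L[b, c]
            if a == b:
                if s <= 0.0:
                    return False
                L[a, a] = math.sqrt(s)
            else:
                L[a, b] = s / L[b, b]
    return True


@njit(cache=False, inline="always")
def _pred_logpdf(count, s_vec, outer, x, kappa0, nu0, xi2, S, L, v):
    """NIW posterior-predictive Student-t log-density of x given block stats."""
    d = x.shape[0]
    kn = kappa0 + count
    df = nu0 + count - d + 1.0
    c = (kn + 1.0) / (kn * df)
    for a in range(d):
        for b in range(d):
            S[a, b] = c * (outer[a, b] - s_vec[a] * s_vec[b] / kn)
        S[a, a] += c * xi2
    ok = _cholesky_inplace(S, L)
    if not ok:
        for a in range(d):
            S[a, a] += 1e-10
        ok = _cholesky_inplace(S, L)
        if not ok:
            return -np.inf
    logdet = 0.0
    for a in range(d):
        logdet += 2.0 * math.log(L[a, a])
    # forward solve L v = x - mu_n
    quad = 0.0
    for a in range(d):
        r = x[a] - s_vec[a] / kn
        for b in range(a):
            r -= L[a, b] * v[b]
        v[a] = r / L[a, a]
        quad += v[a] * v[a]
    return (
        math.lgamma((df + d) / 2.0)
        - math.lgamma(df / 2.0)
        - 0.5 * d * math.log(df * math.pi)
        - 0.5 * logdet
        - 0.5 * (df + d) * math.log1p(quad / df)
    )


@njit(cache=False)
def pred_logpdf_stats(x, counts, sums, outers, kappa0, nu0, xi2):
    """Vector of predictive log-densities of x for each block of statistics."""
    k = counts.shape[0]
    d = x.shape[0]
    out = np.empty(k)
    S = np.empty((d, d))
    L = np.empty((d, d))
    v = np.empty(d)
    for h in range(k):
        out[h] = _pred_logpdf(counts[h], sums[h], outers[h], x, kappa0, nu0, xi2, S, L, v)
    return out


@njit(cache=False)
def crp_scan(eta, labels, ids, counts, sums, outers, k, alpha, kappa0, nu0, xi2, rng):
    """One sequential collapsed-CRP pass over all items.

    Arrays have capacity >= n + 1 clusters; ``ids`` tracks the original slot
    of surviving clusters (-1 for clusters opened during the scan).  Returns
    the new number of occupied clusters.  Weights are normalized through the
    running maximum (log-sum-exp), never in raw space.
    """
    n, d = eta.shape
    S = np.empty((d, d))
    L = np.empty((d, d))
    v = np.empty(d)
    zs = np.zeros(d)
    zo = np.zeros((d, d))
    logw = np.empty(n + 1)
    log_alpha = math.log(alpha)
    for i in range(n):
        x = eta[i]
        h = labels[i]
        counts[h] -= 1.0
        for a in range(d):
            sums[h, a] -= x[a]
            for b in range(d):
                outers[h, a, b] -= x[a] * x[b]
        if counts[h] == 0.0:
            last = k - 1
            if h != last:
                counts[h] = counts[last]
                ids[h] = ids[last]
                for a in range(d):
                    sums[h, a] = sums[last, a]
                    for b in range(d):
                        outers[h, a, b] = outers[last, a, b]
                for j in range(n):
                    if labels[j] == last:
                        labels[j] = h
            k = last
            h = -1
        for h2 in range(k):
            logw[h2] = (
                _pred_logpdf(counts[h2], sums[h2], outers[h2], x, kappa0, nu0, xi2, S, L, v)
                + math.log(counts[h2])
            )
        logw[k] = _pred_logpdf(0.0, zs, zo, x, kappa0, nu0, xi2, S, L, v) + log_alpha
        mx = logw[0]
        for h2 in range(1, k + 1):
            if logw[h2] > mx:
                mx = logw[h2]
        tot = 0.0
        for h2 in range(k + 1):
            logw[h2] = math.exp(logw[h2] - mx)
            tot += logw[h2]
        u = rng.random() * tot
        acc = 0.0
        choice = k
        for h2 in range(k + 1):
            acc += logw[h2]
            if u <= acc:
                choice = h2
                break
        if choice == k:
            ids[k] = -1
            counts[k] = 0.0
            for a in range(d):
                sums[k, a] = 0.0
                for b in range(d):
                    outers[k, a, b] = 0.0
            k += 1
        labels[i] = choice
        counts[choice] += 1.0
        for a in range(d):
            sums[choice, a] += x[a]
            for b in range(d):
                outers[choice, a, b] += x[a] * x[b]
    return k


@njit(cache=False)
def restricted_scan_kernel(
    eta, items, assign, counts, sums, outers, kappa0, nu0, xi2, rng, forced, target
):
    """One restricted Gibbs scan of the free items between two clusters.

    ``assign[i]`` in {0, 1} indexes the candidate cluster of item i;
    ``counts/sums/outers`` hold the two clusters' statistics (anchors
    included) and are updated in place.  With ``forced`` true the scan is
    driven through ``target`` instead of sampling.  Returns the accumulated
    log probability of the resulting configuration.
    """
    d = eta.shape[1]
    S = np.empty((d, d))
    L = np.empty((d, d))
    v = np.empty(d)
    logq = 0.0
    for idx in range(items.shape[0]):
        i = items[idx]
        x = eta[i]
        c_old = assign[i]
        counts[c_old] -= 1.0
        for a in range(d):
            sums[c_old, a] -= x[a]
            for b in range(d):
                outers[c_old, a, b] -= x[a] * x[b]
        lp0 = (
            _pred_logpdf(counts[0], sums[0], outers[0], x, kappa0, nu0, xi2, S, L, v)
            + math.log(counts[0])
        )
        lp1 = (
            _pred_logpdf(counts[1], sums[1], outers[1], x, kappa0, nu0, xi2, S, L, v)
            + math.log(counts[1])
        )
        mx = lp0 if lp0 > lp1 else lp1
        w0 = math.exp(lp0 - mx)
        w1 = math.exp(lp1 - mx)
        p1 = w1 / (w0 + w1)
        if forced:
            c_new = target[i]
        else:
            c_new = 1 if rng.random() < p1 else 0
        logq += math.log(p1) if c_new == 1 else math.log(1.0 - p1)
        assign[i] = c_new
        counts[c_new] += 1.0
        for a in range(d):
            sums[c_new, a] += x[a]
            for b in range(d):
                outers[c_new, a, b] += x[a] * x[b]
    return logq
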