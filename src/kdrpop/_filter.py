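"""Numba kernels for the bootstrap particle filter.

The latent state is the resistance allele frequency; one transition =
deterministic selection with dominance followed by binomial Wright-Fisher
resampling of 2*Ne gametes.  Observations are Dirichlet-multinomial counts
over the three genotype classes around Hardy-Weinberg proportions with
concentration A.  Kept separate from the Python API so the hot loop stays
fully jitted.

Implementation notes: weights are carried between observations and
multinomial resampling is triggered when the effective sample size drops
below half the particle count (the marginal-likelihood estimator remains
unbiased under adaptive resampling).  Resampling uses the exponential-
spacings construction of sorted uniforms plus a single merge pass, which
is O(N) rather than O(N log N).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_EPS = 1e-12
_NEG_BIG = -1e290


@njit(cache=True)
def dm_logpmf_kernel(c0, c1, c2, q0, q1, q2, A):
    """Dirichlet-multinomial log-pmf for 3 classes, probs epsilon-floored."""
    q0 = max(q0, _EPS)
    q1 = max(q1, _EPS)
    q2 = max(q2, _EPS)
    s = q0 + q1 + q2
    q0 /= s
    q1 /= s
    q2 /= s
    n = c0 + c1 + c2
    out = (math.lgamma(n + 1) - math.lgamma(c0 + 1) - math.lgamma(c1 + 1)
           - math.lgamma(c2 + 1))
    out += math.lgamma(A) - math.lgamma(n + A)
    out += math.lgamma(c0 + A * q0) - math.lgamma(A * q0)
    out += math.lgamma(c1 + A * q1) - math.lgamma(A * q1)
    out += math.lgamma(c2 + A * q2) - math.lgamma(A * q2)
    return out


@njit(cache=True)
def particle_filter(obs_t, counts, s, h, R0, A, two_ne, n_particles, seed,
                    return_path):
    """Bootstrap particle filter for the genotype-frequency HMM.

    Returns ``(loglik, path)``; ``path`` is one ancestral latent trajectory
    (months 0..obs_t[-1]) when ``return_path`` is True, else a length-1
    placeholder.  All weights vanishing at any step returns -inf.
    """
    np.random.seed(seed)
    n_obs = obs_t.shape[0]
    n_months = obs_t[n_obs - 1] + 1
    path_len = n_months if return_path else 1
    path = np.zeros(path_len)

    p = np.full(n_particles, R0)
    hist = np.zeros((path_len, n_particles))
    if return_path:
        for i in range(n_particles):
            hist[0, i] = p[i]

    logw = np.empty(n_particles)
    v = np.empty(n_particles)
    w_norm = np.full(n_particles, 1.0 / n_particles)   # carried weights
    idx = np.empty(n_particles, np.int64)
    su = np.empty(n_particles)
    p_new = np.empty(n_particles)
    ll = 0.0
    t_cur = 0
    wrs = 1.0 - h * s
    wss = 1.0 - s
    for j in range(n_obs):
        target = obs_t[j]
        while t_cur < target:
            for i in range(n_particles):
                pi = p[i]
                qi = 1.0 - pi
                num = pi * pi + pi * qi * wrs
                wbar = pi * pi + 2.0 * pi * qi * wrs + qi * qi * wss
                pd = pi if wbar <= 0.0 else num / wbar
                if pd <= 0.0:
                    p[i] = 0.0      # fixation is absorbing
                elif pd >= 1.0:
                    p[i] = 1.0
                else:
                    p[i] = np.random.binomial(two_ne, pd) / two_ne
            t_cur += 1
            if return_path:
                for i in range(n_particles):
                    hist[t_cur, i] = p[i]

        c0 = counts[j, 0]
        c1 = counts[j, 1]
        c2 = counts[j, 2]
        n_j = c0 + c1 + c2
        # particle-independent part of the Dirichlet-multinomial log-pmf
        const = (math.lgamma(n_j + 1) - math.lgamma(c0 + 1)
                 - math.lgamma(c1 + 1) - math.lgamma(c2 + 1)
                 + math.lgamma(A) - math.lgamma(n_j + A))
        m = -np.inf
        memo_p = -1.0   # consecutive duplicate particles share their weight
        memo_lw = 0.0
        for i in range(n_particles):
            pi = p[i]
            if pi == memo_p:
                logw[i] = memo_lw
                if memo_lw > m:
                    m = memo_lw
                continue
            qi = 1.0 - pi
            g0 = pi * pi
            g1 = 2.0 * pi * qi
            g2 = qi * qi
            if g0 < _EPS:
                g0 = _EPS
            if g1 < _EPS:
                g1 = _EPS
            if g2 < _EPS:
                g2 = _EPS
            norm = A / (g0 + g1 + g2)
            a0 = g0 * norm
            a1 = g1 * norm
            a2 = g2 * norm
            lw = const
            if c0 > 0.0:
                lw += math.lgamma(c0 + a0) - math.lgamma(a0)
            if c1 > 0.0:
                lw += math.lgamma(c1 + a1) - math.lgamma(a1)
            if c2 > 0.0:
                lw += math.lgamma(c2 + a2) - math.lgamma(a2)
            logw[i] = lw
            memo_p = pi
            memo_lw = lw
            if lw > m:
                m = lw
        if m < _NEG_BIG or m == -np.inf:
            return -np.inf, path

        # combine with carried weights; accumulate marginal likelihood
        vsum = 0.0
        for i in range(n_particles):
            v[i] = w_norm[i] * math.exp(logw[i] - m)
            vsum += v[i]
        if vsum <= 0.0:
            return -np.inf, path
        ll += m + math.log(vsum)
        ess_inv = 0.0
        for i in range(n_particles):
            w_norm[i] = v[i] / vsum
            ess_inv += w_norm[i] * w_norm[i]

        if 1.0 / ess_inv < 0.5 * n_particles:
            # multinomial resampling via exponential spacings: sorted
            # uniforms in one O(N) pass, then a single merge with the CDF
            acc = 0.0
            for i in range(n_particles):
                acc -= math.log(np.random.random())
                su[i] = acc
            acc -= math.log(np.random.random())
            for i in range(n_particles):
                su[i] /= acc
            kk = 0
            cw = w_norm[0]
            for i in range(n_particles):
                while cw < su[i] and kk < n_particles - 1:
                    kk += 1
                    cw += w_norm[kk]
                idx[i] = kk
            for i in range(n_particles):
                p_new[i] = p[idx[i]]
            tmp = p
            p = p_new
            p_new = tmp
            for i in range(n_particles):
                w_norm[i] = 1.0 / n_particles
            if return_path:
                upto = t_cur + 1
                htmp = np.empty((upto, n_particles))
                for r in range(upto):
                    for i in range(n_particles):
                        htmp[r, i] = hist[r, idx[i]]
                hist[:upto] = htmp

    if return_path:
        # sample one ancestral trajectory proportional to final weights
        u = np.random.random()
        acc = 0.0
        k = n_particles - 1
        for i in range(n_particles):
            acc += w_norm[i]
            if u <= acc:
                k = i
                break
        for r in range(n_months):
            path[r] = hist[r, k]
    return ll, path
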