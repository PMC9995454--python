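"""Numba inner loop of the spike-slab (BayesC) Gibbs sampler."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_kernel(
    X,  # n x p, Fortran order, column-centered
    y,  # length n, centered
    c,  # precomputed column squared norms
    alpha1,
    alpha2,
    df_b,
    S_b,
    df_e,
    S_e,
    pi0,
    s2b0,
    s2e0,
    n_iter,
    burn_in,
    thin,
    seed,
    permute,
):
    np.random.seed(seed)
    n, p = X.shape
    n_keep = (n_iter - burn_in + thin - 1) // thin

    beta = np.zeros(p)
    delta = np.zeros(p, dtype=np.int8)
    e = y.copy()
    pi = pi0
    s2b = s2b0
    s2e = s2e0

    beta_out = np.zeros((n_keep, p))
    delta_out = np.zeros((n_keep, p), dtype=np.int8)
    pi_out = np.zeros(n_keep)
    s2b_out = np.zeros(n_keep)
    s2e_out = np.zeros(n_keep)

    order = np.arange(p)
    kept = 0
    for t in range(n_iter):
        if permute:
            order = np.random.permutation(p)
        log_pi_odds = np.log(pi) - np.log(1.0 - pi)
        for u in range(p):
            j = order[u]
            rhs = c[j] * beta[j]
            for i in range(n):
                rhs += X[i, j] * e[i]
            v = 1.0 / (c[j] / s2e + 1.0 / s2b)
            m = v * rhs / s2e
            logodds = log_pi_odds + 0.5 * np.log(v / s2b) + 0.5 * m * m / v
            if logodds > 35.0:
                prob = 1.0
            elif logodds < -35.0:
                prob = 0.0
            else:
                prob = 1.0 / (1.0 + np.exp(-logodds))
            if np.random.random() < prob:
                b_new = m + np.sqrt(v) * np.random.standard_normal()
                d_new = np.int8(1)
            else:
                b_new = 0.0
                d_new = np.int8(0)
            diff = b_new - beta[j]
            if diff != 0.0:
                for i in range(n):
                    e[i] -= X[i, j] * diff
            beta[j] = b_new
            delta[j] = d_new

        k = 0
        ssb = 0.0
        for j in range(p):
            if delta[j] == 1:
                k += 1
                ssb += beta[j] * beta[j]
        pi = np.random.beta(alpha1 + k, alpha2 + p - k)
        if pi <= 1e-12:
            pi = 1e-12
        elif pi >= 1.0 - 1e-12:
            pi = 1.0 - 1e-12
        s2b = (df_b * S_b + ssb) / np.random.chisquare(df_b + k)
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        s2e = (df_e * S_e + sse) / np.random.chisquare(df_e + n)

        if t >= burn_in and (t - burn_in) % thin == 0:
            beta_out[kept] = beta
            delta_out[kept] = delta
            pi_out[kept] = pi
            s2b_out[kept] = s2b
            s2e_out[kept] = s2e
            kept += 1

    return beta_out, delta_out, pi_out, s2b_out, s2e_out, e
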