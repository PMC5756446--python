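"""Single-site Gibbs sampler kernel for Bayesian whole-genome regression.

One compiled routine covers the three model variants:

* code 0 — all design SNPs always in the model, locus-specific effect
  variances (BayesA-like; used for the F_ST-preselected design),
* code 1 — BayesB: per-locus inclusion indicator sampled with the effect
  integrated out, locus-specific variances,
* code 2 — BayesC: inclusion indicators with one effect variance shared
  across included SNPs.

Effect and residual variances carry scaled-inverse-chi-square priors.
The kernel operates on the transposed, centered design (m x n, C order)
so each locus update is a contiguous dot product and residual update.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

MODEL_CODES = {"fst_preselect": 0, "bayesB": 1, "bayesC": 2}


@njit(cache=True)
def gibbs_chain(
    Xt: np.ndarray,        # (m, n) centered dosages, C-contiguous
    y: np.ndarray,         # (n,)
    model: int,            # 0 preselect/BayesA-like, 1 BayesB, 2 BayesC
    pi_zero: float,
    df_g: float,
    scale_g_locus: float,  # per-locus (or common, BayesC) prior scale
    df_e: float,
    scale_e: float,
    n_iter: int,
    burn_in: int,
    thin: int,
    seed: int,
):
    np.random.seed(seed)
    m, n = Xt.shape
    xtx = np.empty(m)
    for j in range(m):
        xtx[j] = np.dot(Xt[j], Xt[j])

    beta = np.zeros(m)
    gamma = np.ones(m, dtype=np.uint8)
    if model >= 1:
        for j in range(m):
            gamma[j] = 1 if np.random.random() < (1.0 - pi_zero) else 0
    sigma2_j = np.full(m, scale_g_locus)
    sigma2_c = scale_g_locus
    sigma2_e = scale_e
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    e = y - mu  # residual y - mu - X beta (beta starts at 0)

    beta_sum = np.zeros(m)
    gamma_sum = np.zeros(m)
    mu_sum = 0.0
    s2e_sum = 0.0
    kept = 0

    for it in range(n_iter):
        # intercept (flat prior)
        ebar = 0.0
        for i in range(n):
            ebar += e[i]
        ebar /= n
        mu_new = mu + ebar + np.random.normal(0.0, 1.0) * math.sqrt(sigma2_e / n)
        diff = mu_new - mu
        for i in range(n):
            e[i] -= diff
        mu = mu_new

        for j in range(m):
            if xtx[j] <= 0.0:
                beta[j] = 0.0
                gamma[j] = 1 if model == 0 else 0
                continue
            s2j = sigma2_c if model == 2 else sigma2_j[j]
            xj = Xt[j]
            rhs = np.dot(xj, e) + xtx[j] * beta[j]
            if model == 0:
                newg = 1
            else:
                v0 = xtx[j] * sigma2_e
                v1 = v0 + xtx[j] * xtx[j] * s2j
                logbf = 0.5 * math.log(v0 / v1) + 0.5 * rhs * rhs * (1.0 / v0 - 1.0 / v1)
                if logbf > 50.0:
                    p1 = 1.0
                else:
                    r = (1.0 - pi_zero) * math.exp(logbf)
                    p1 = r / (r + pi_zero)
                newg = 1 if np.random.random() < p1 else 0
            old = beta[j]
            if newg == 1:
                c = xtx[j] + sigma2_e / s2j
                b = rhs / c + np.random.normal(0.0, 1.0) * math.sqrt(sigma2_e / c)
            else:
                b = 0.0
            d = old - b
            if d != 0.0:
                for i in range(n):
                    e[i] += xj[i] * d
            beta[j] = b
            gamma[j] = newg

        # effect variances
        if model == 2:
            m_in = 0
            ssb = 0.0
            for j in range(m):
                if gamma[j] == 1:
                    m_in += 1
                    ssb += beta[j] * beta[j]
            sigma2_c = (df_g * scale_g_locus + ssb) / np.random.chisquare(df_g + m_in)
        else:
            for j in range(m):
                if gamma[j] == 1:
                    sigma2_j[j] = (df_g * scale_g_locus + beta[j] * beta[j]) / np.random.chisquare(df_g + 1.0)
                else:
                    sigma2_j[j] = (df_g * scale_g_locus) / np.random.chisquare(df_g)

        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        sigma2_e = (df_e * scale_e + sse) / np.random.chisquare(df_e + n)

        if it >= burn_in and (it - burn_in) % thin == 0:
            kept += 1
            mu_sum += mu
            s2e_sum += sigma2_e
            for j in range(m):
                beta_sum[j] += beta[j]
                gamma_sum[j] += gamma[j]

    return beta_sum / kept, gamma_sum / kept, mu_sum / kept, s2e_sum / kept, kept
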