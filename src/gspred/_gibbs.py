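"""Numba kernel for the BayesA/B Gibbs sampler.

One compiled function runs the whole chain; the marker sweep maintains the
residual vector e = y - mu - M q so each conditional update costs O(r).
``pi_fix >= 0`` clamps the exclusion probability (0 for BayesA); ``-1``
lets pi follow its Beta conditional.

Sampling conventions:
* scaled-inv-chi2(nu, s2) is drawn as nu * s2 / chi2(nu);
* the inclusion indicator uses the marginal odds with q_j integrated out,
  log BF = 0.5 [ log(1 / (sigma2_j c_j)) + c_j qhat_j^2 ],
  c_j = m_j'm_j / s2e + 1 / sigma2_j, qhat_j = (m_j'e_j / s2e) / c_j,
  where e_j is the residual with marker j's contribution restored.

A uniform is consumed for every delta decision even when pi is clamped, so
clamped and free chains draw from identical stream positions.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gibbs_sample(
    X, y, pi_fix, pi0, p0, nu, shape_s, rate, nu_e, Se,
    n_iter, burn_in, thin, seed,
):
    np.random.seed(seed)
    r, p = X.shape
    n = float(r)

    xtx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(r):
            s += X[i, j] * X[i, j]
        xtx[j] = s

    # initial state
    mu = 0.0
    for i in range(r):
        mu += y[i]
    mu /= n
    s2q = shape_s / rate
    s2e = 0.0
    for i in range(r):
        s2e += (y[i] - mu) ** 2
    s2e = s2e / (n - 1.0) * 0.5 + 1e-12
    q = np.zeros(p)
    delta = np.ones(p, dtype=np.int64)
    sig2 = np.full(p, nu * s2q / max(nu - 2.0, 0.5))
    pi = pi0 if pi_fix < 0.0 else pi_fix

    e = np.empty(r)
    for i in range(r):
        e[i] = y[i] - mu

    q_acc = np.zeros(p)
    incl_acc = np.zeros(p)
    mu_acc = 0.0
    s2e_acc = 0.0
    s2q_acc = 0.0
    pi_acc = 0.0
    n_kept = 0
    flips = 0
    n_flip_trials = 0

    n_rec = (n_iter - burn_in) // thin
    tr_mu = np.empty(n_rec)
    tr_s2e = np.empty(n_rec)
    tr_s2q = np.empty(n_rec)
    tr_pi = np.empty(n_rec)

    for it in range(n_iter):
        # marker sweep
        for j in range(p):
            qj = q[j]
            if qj != 0.0:
                for i in range(r):
                    e[i] += X[i, j] * qj
            rhs = 0.0
            for i in range(r):
                rhs += X[i, j] * e[i]
            c = xtx[j] / s2e + 1.0 / sig2[j]
            qhat = (rhs / s2e) / c

            u = np.random.random()  # always consumed (stream parity)
            if pi <= 0.0:
                new_delta = 1
            elif pi >= 1.0:
                new_delta = 0
            else:
                log_odds = (
                    np.log((1.0 - pi) / pi)
                    - 0.5 * np.log(sig2[j] * c)
                    + 0.5 * c * qhat * qhat
                )
                if log_odds > 35.0:
                    p_incl = 1.0
                elif log_odds < -35.0:
                    p_incl = 0.0
                else:
                    p_incl = 1.0 / (1.0 + np.exp(-log_odds))
                new_delta = 1 if u < p_incl else 0
            if new_delta != delta[j]:
                flips += 1
            n_flip_trials += 1
            delta[j] = new_delta

            if new_delta == 1:
                qj = qhat + np.random.standard_normal() / np.sqrt(c)
                q[j] = qj
                for i in range(r):
                    e[i] -= X[i, j] * qj
                # conditional: scaled-inv-chi2(nu + 1, (nu s2q + q^2)/(nu + 1))
                sig2[j] = (nu * s2q + qj * qj) / np.random.chisquare(nu + 1.0)
            else:
                q[j] = 0.0
                # refresh from the prior
                sig2[j] = nu * s2q / np.random.chisquare(nu)

        # grand mean
        for i in range(r):
            e[i] += mu
        em = 0.0
        for i in range(r):
            em += e[i]
        em /= n
        mu = em + np.random.standard_normal() * np.sqrt(s2e / n)
        for i in range(r):
            e[i] -= mu

        # residual variance
        sse = 0.0
        for i in range(r):
            sse += e[i] * e[i]
        s2e = (nu_e * Se + sse) / np.random.chisquare(nu_e + n)

        # slab scale: Gamma(shape_s + p nu / 2, rate + (nu/2) sum 1/sig2)
        inv_sum = 0.0
        for j in range(p):
            inv_sum += 1.0 / sig2[j]
        s2q = np.random.gamma(shape_s + 0.5 * nu * p, 1.0 / (rate + 0.5 * nu * inv_sum))

        # exclusion probability
        if pi_fix < 0.0:
            n_incl = 0
            for j in range(p):
                n_incl += delta[j]
            pi = np.random.beta(pi0 * p0 + (p - n_incl), (1.0 - pi0) * p0 + n_incl)

        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(p):
                q_acc[j] += q[j]
                incl_acc[j] += delta[j]
            mu_acc += mu
            s2e_acc += s2e
            s2q_acc += s2q
            pi_acc += pi
            tr_mu[n_kept] = mu
            tr_s2e[n_kept] = s2e
            tr_s2q[n_kept] = s2q
            tr_pi[n_kept] = pi
            n_kept += 1

    k = float(n_kept)
    return (
        q_acc / k,
        incl_acc / k,
        mu_acc / k,
        s2e_acc / k,
        s2q_acc / k,
        pi_acc / k,
        flips / max(n_flip_trials, 1),
        tr_mu,
        tr_s2e,
        tr_s2q,
        tr_pi,
    )


@njit(cache=True)
def sample_scaled_inv_chi2(nu, s2, n_draws, seed):
    """Draws from scaled-inv-chi2(nu, s2); exposed for conditional checks."""
    np.random.seed(seed)
    out = np.empty(n_draws)
    for i in range(n_draws):
        out[i] = nu * s2 / np.random.chisquare(nu)
    return out
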