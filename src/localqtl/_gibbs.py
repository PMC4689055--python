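"""Single-site Gibbs kernel for the Bayesian alphabet (numba-compiled).

One kernel covers BayesA/B/C/C0/Cpi via flags:

* ``per_marker_var``  — per-marker effect variances (A, B) vs one common
  variance (C family);
* ``pi0 > 0``         — spike-and-slab inclusion indicators (B, C) with the
  indicator sampled from its Bernoulli full conditional with the effect
  integrated out;
* ``sample_pi``       — Cpi: pi gets a uniform prior and a Beta full
  conditional.

Effect variances follow scaled inverse chi-square full conditionals; for
per-marker variances an excluded locus draws its variance from the prior
(GenSel-style Gibbs).  Marker update order is fixed ascending for
reproducibility.  All randomness comes from numpy's global RNG seeded inside
the kernel, so identical inputs + seed give identical output.
"""

import numpy as np
from numba import njit

SIGMA2_E_FLOOR = 1e-8


@njit(cache=True)
def gibbs_chain(
    Zc,              # (n, p) centered dosages, Fortran order
    y,               # (n,)
    pi0,             # prior exclusion probability (start value for Cpi)
    per_marker_var,  # bool
    sample_pi,       # bool
    nu_b, S_b,       # effect-variance prior
    nu_e, S_e,       # residual-variance prior
    fix_var_beta, sigma2_beta0,
    fix_var_e, sigma2_e0,
    n_iter, burn_in, thin, n_store,
    seed,
):
    np.random.seed(seed)
    n, p = Zc.shape

    czz = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += Zc[i, j] * Zc[i, j]
        czz[j] = s

    prior_var = S_b * nu_b / (nu_b - 2.0)
    s2b = np.full(p, sigma2_beta0 if fix_var_beta else prior_var)
    s2b_common = sigma2_beta0 if fix_var_beta else prior_var
    sigma2_e = sigma2_e0 if fix_var_e else S_e * nu_e / (nu_e - 2.0)

    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    e = y - mu
    beta = np.zeros(p)
    delta = np.zeros(p, np.int8)
    pi_cur = pi0

    n_samples = n_iter - burn_in
    sum_eff = np.zeros(p)
    sum_delta = np.zeros(p)
    sum_mu = 0.0
    sum_s2b = 0.0
    sum_s2e = 0.0
    sum_pi = 0.0
    sum_incl = 0.0
    samples = np.zeros((n_store, p))
    offsets = np.zeros(n_store, np.int64)
    pi_trace = np.zeros(n_samples if sample_pi else 0)

    for it in range(n_iter):
        # --- intercept ---
        ebar = 0.0
        for i in range(n):
            ebar += e[i]
        ebar /= n
        mu_new = (mu + ebar) + np.random.normal(0.0, 1.0) * np.sqrt(sigma2_e / n)
        shift = mu - mu_new
        for i in range(n):
            e[i] += shift
        mu = mu_new

        # --- marker effects, fixed ascending order ---
        n_incl = 0
        for j in range(p):
            c = czz[j]
            old = beta[j]
            if c <= 0.0:
                # monomorphic column: no information, indicator from prior
                if pi_cur <= 0.0 or np.random.random() < 1.0 - pi_cur:
                    delta[j] = 1
                    n_incl += 1
                else:
                    delta[j] = 0
                beta[j] = 0.0
                continue
            r = 0.0
            for i in range(n):
                r += Zc[i, j] * e[i]
            r += c * old
            s2j = s2b[j] if per_marker_var else s2b_common

            if pi_cur <= 0.0:
                incl = True
            else:
                v0 = c * sigma2_e
                v1 = c * c * s2j + c * sigma2_e
                logodds = (
                    np.log((1.0 - pi_cur) / pi_cur)
                    + 0.5 * (np.log(v0 / v1) + r * r * (1.0 / v0 - 1.0 / v1))
                )
                if logodds > 35.0:
                    incl = True
                elif logodds < -35.0:
                    incl = False
                else:
                    incl = np.random.random() < 1.0 / (1.0 + np.exp(-logodds))

            if incl:
                lhs = c + sigma2_e / s2j
                bnew = r / lhs + np.random.normal(0.0, 1.0) * np.sqrt(sigma2_e / lhs)
                diff = old - bnew
                if diff != 0.0:
                    for i in range(n):
                        e[i] += Zc[i, j] * diff
                beta[j] = bnew
                delta[j] = 1
                n_incl += 1
            else:
                if old != 0.0:
                    for i in range(n):
                        e[i] += Zc[i, j] * old
                beta[j] = 0.0
                delta[j] = 0

        # --- variance components ---
        if not fix_var_beta:
            if per_marker_var:
                for j in range(p):
                    if delta[j] == 1 and czz[j] > 0.0:
                        s2b[j] = (nu_b * S_b + beta[j] * beta[j]) / np.random.chisquare(nu_b + 1.0)
                    else:
                        s2b[j] = nu_b * S_b / np.random.chisquare(nu_b)
            else:
                m = 0
                ssb = 0.0
                for j in range(p):
                    if delta[j] == 1 and czz[j] > 0.0:
                        m += 1
                        ssb += beta[j] * beta[j]
                s2b_common = (nu_b * S_b + ssb) / np.random.chisquare(nu_b + m)
        if not fix_var_e:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            sigma2_e = (nu_e * S_e + sse) / np.random.chisquare(nu_e + n)
            if sigma2_e < SIGMA2_E_FLOOR:
                sigma2_e = SIGMA2_E_FLOOR
        if sample_pi:
            m_total = 0
            for j in range(p):
                if delta[j] == 1:
                    m_total += 1
            pi_cur = np.random.beta(p - m_total + 1.0, m_total + 1.0)
            if pi_cur >= 1.0:
                pi_cur = 1.0 - 1e-12

        # --- accumulate post-burn-in ---
        if it >= burn_in:
            k = it - burn_in
            for j in range(p):
                sum_eff[j] += beta[j]
                sum_delta[j] += delta[j]
            sum_mu += mu
            if per_marker_var:
                sm = 0.0
                for j in range(p):
                    sm += s2b[j]
                sum_s2b += sm / p
            else:
                sum_s2b += s2b_common
            sum_s2e += sigma2_e
            sum_pi += pi_cur
            sum_incl += n_incl
            if sample_pi:
                pi_trace[k] = pi_cur
            if n_store > 0 and k % thin == 0:
                row = k // thin
                if row < n_store:
                    for j in range(p):
                        samples[row, j] = beta[j]
                    offsets[row] = k + 1

    return (
        sum_eff / n_samples,
        sum_delta / n_samples,
        sum_mu / n_samples,
        sum_s2b / n_samples,
        sum_s2e / n_samples,
        sum_pi / n_samples,
        sum_incl / n_samples,
        samples,
        offsets,
        pi_trace,
    )
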