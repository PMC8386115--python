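"""Single-site Gibbs sampler kernel for the spike-slab whole-genome
regression models (compiled with numba).

The model is y = X b + sum_j a_j beta_j delta_j + e with flat priors on b,
delta_j ~ Bernoulli(1 - pi), beta_j | delta_j=1 ~ N(0, s2_j) and scaled
inverse chi-square priors on the marker and residual variances.  The same
kernel serves both the common-marker-variance model (variance estimation)
and the per-locus-variance model (marker mapping) via ``per_locus``.

For each marker, delta_j is sampled with beta_j integrated out (comparing
the marginal likelihood of the adjusted right-hand side under inclusion vs
exclusion), then beta_j from its normal full conditional when included.
Residual and genomic-value vectors are updated incrementally.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False, fastmath=True)
def run_chain(
    y,
    X,
    A,
    pi,
    per_locus,
    n_iter,
    burn_in,
    thin,
    nu_b,
    s2_b,
    nu_e,
    s2_e,
    update_marker_var,
    update_resid_var,
    seed,
):
    """Run one chain; returns posterior summaries and thinned effect draws.

    A must be column-centered; columns with zero variance are permanently
    excluded (delta=0).  ``update_marker_var``/``update_resid_var`` pin the
    corresponding variances when False (used for closed-form checks).
    """
    np.random.seed(seed)
    n = y.shape[0]
    p = X.shape[1]
    k = A.shape[1]

    xtx = np.empty(p)
    for i in range(p):
        s = 0.0
        for r in range(n):
            s += X[r, i] * X[r, i]
        xtx[i] = s
    ajtaj = np.empty(k)
    for j in range(k):
        s = 0.0
        for r in range(n):
            s += A[r, j] * A[r, j]
        ajtaj[j] = s
    active = ajtaj > 1e-12

    b = np.zeros(p)
    beta = np.zeros(k)
    delta = np.zeros(k, dtype=np.uint8)
    sigma2_loc = np.full(k, s2_b)
    sigma2_common = s2_b
    sigma2_e = s2_e
    e = y.copy()
    g = np.zeros(n)

    n_keep = n_iter - burn_in
    n_thin = n_keep // thin if thin > 0 else 0
    thinned = np.zeros((n_thin, k))
    beta_sum = np.zeros(k)
    beta_sumsq = np.zeros(k)
    delta_sum = np.zeros(k)
    b_sum = np.zeros(p)
    genvar = np.zeros(n_keep)
    resvar = np.zeros(n_keep)

    log_prior_odds = np.log(1.0 - pi) - np.log(pi) if pi > 0.0 else np.inf

    for it in range(n_iter):
        # --- fixed effects, flat prior ---
        for i in range(p):
            old = b[i]
            rhs = xtx[i] * old
            for r in range(n):
                rhs += X[r, i] * e[r]
            mean = rhs / xtx[i]
            new = mean + np.random.normal() * np.sqrt(sigma2_e / xtx[i])
            diff = new - old
            if diff != 0.0:
                for r in range(n):
                    e[r] -= X[r, i] * diff
            b[i] = new

        # --- markers ---
        sum_beta2 = 0.0
        n_in = 0
        for j in range(k):
            if not active[j]:
                continue
            old = beta[j]
            rhs = ajtaj[j] * old
            for r in range(n):
                rhs += A[r, j] * e[r]
            s2j = sigma2_loc[j] if per_locus else sigma2_common
            include = False
            if pi <= 0.0:
                include = True
            else:
                v0 = ajtaj[j] * sigma2_e
                v1 = v0 + ajtaj[j] * ajtaj[j] * s2j
                log_bf = -0.5 * (np.log(v1) - np.log(v0)) - 0.5 * rhs * rhs * (1.0 / v1 - 1.0 / v0)
                t = log_prior_odds + log_bf
                if t > 35.0:
                    prob_in = 1.0
                elif t < -35.0:
                    prob_in = 0.0
                else:
                    prob_in = 1.0 / (1.0 + np.exp(-t))
                include = np.random.random() < prob_in
            if include:
                c = ajtaj[j] + sigma2_e / s2j
                new = rhs / c + np.random.normal() * np.sqrt(sigma2_e / c)
                delta[j] = 1
            else:
                new = 0.0
                delta[j] = 0
            diff = new - old
            if diff != 0.0:
                for r in range(n):
                    e[r] -= A[r, j] * diff
                    g[r] += A[r, j] * diff
            beta[j] = new
            if per_locus:
                if update_marker_var:
                    if delta[j] == 1:
                        sigma2_loc[j] = (nu_b * s2_b + new * new) / np.random.chisquare(nu_b + 1.0)
                    else:
                        sigma2_loc[j] = nu_b * s2_b / np.random.chisquare(nu_b)
            else:
                if delta[j] == 1:
                    sum_beta2 += new * new
                    n_in += 1
        if (not per_locus) and update_marker_var:
            sigma2_common = (nu_b * s2_b + sum_beta2) / np.random.chisquare(nu_b + n_in)

        # --- residual variance ---
        if update_resid_var:
            sse = 0.0
            for r in range(n):
                sse += e[r] * e[r]
            sigma2_e = (sse + nu_e * s2_e) / np.random.chisquare(n + nu_e)
            if not np.isfinite(sigma2_e):
                raise FloatingPointError("residual variance diverged")

        # --- accumulate ---
        if it >= burn_in:
            d = it - burn_in
            for j in range(k):
                beta_sum[j] += beta[j]
                beta_sumsq[j] += beta[j] * beta[j]
                delta_sum[j] += delta[j]
            for i in range(p):
                b_sum[i] += b[i]
            gm = 0.0
            for r in range(n):
                gm += g[r]
            gm /= n
            gv = 0.0
            for r in range(n):
                gv += (g[r] - gm) * (g[r] - gm)
            genvar[d] = gv / n
            resvar[d] = sigma2_e
            if thin > 0 and (d % thin) == (thin - 1) and (d // thin) < n_thin:
                for j in range(k):
                    thinned[d // thin, j] = beta[j]

    return beta_sum, beta_sumsq, delta_sum, b_sum, genvar, resvar, thinned
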