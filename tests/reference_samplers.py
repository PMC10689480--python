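"""Independent random-walk Metropolis reference for the global model.

Kept deliberately separate from the package: a slow, simple sampler whose
only shared ingredient with the Gibbs implementation is the model density
itself, written here from scratch.  Used to cross-validate posterior
summaries on small instances.
"""

from math import log

import numpy as np

A_GAMMA = 1e-3  # gamma shape on precisions
B_GAMMA = 1e-3  # gamma rate on precisions
COEF_PRECISION = 1e-6  # normal prior precision on intercept/slope


def metropolis_global(y, site_index, V, n_iter=300_000, burn=50_000, seed=0,
                      scales=None):
    """Componentwise random-walk Metropolis for the across-mountain model.

    Parameters are (alpha_site[J], alpha_V, beta_V, log tau_RS, log tau_site);
    precisions are sampled on the log scale with the Jacobian included.
    Returns a dict of named draw arrays.
    """
    y = np.asarray(y, float)
    site_index = np.asarray(site_index, int)
    V = np.asarray(V, float)
    J = V.size
    N = y.size
    ns = np.bincount(site_index, minlength=J).astype(float)
    sumy = np.bincount(site_index, weights=y, minlength=J)
    ssy = float(y @ y)

    def logpost(th):
        a = th[:J]
        aV, bV = th[J], th[J + 1]
        ltRS, ltS = th[J + 2], th[J + 3]
        tRS, tS = np.exp(ltRS), np.exp(ltS)
        sse_w = ssy - 2.0 * float(a @ sumy) + float((a * a) @ ns)
        mu = aV + bV * V
        sse_s = float(((a - mu) ** 2).sum())
        lp = 0.5 * N * ltRS - 0.5 * tRS * sse_w
        lp += 0.5 * J * ltS - 0.5 * tS * sse_s
        lp += -0.5 * COEF_PRECISION * (aV * aV + bV * bV)
        # Gamma(A, B) prior on tau, log-scale parameterization (Jacobian in)
        lp += A_GAMMA * ltRS - B_GAMMA * tRS + A_GAMMA * ltS - B_GAMMA * tS
        return lp

    rng = np.random.default_rng(seed)
    site_means = sumy / ns
    slope = np.polyfit(V, site_means, 1)
    th = np.concatenate(
        [site_means, [slope[1], slope[0]],
         [log(1.0 / max(np.var(y - site_means[site_index]), 1e-4)), log(20.0)]]
    )
    n_par = J + 4
    if scales is None:
        scales = np.concatenate(
            [np.full(J, 0.12), [0.5, 0.08], [0.5, 1.6]]
        )
    draws = np.empty((n_iter - burn, n_par))
    lp = logpost(th)
    for it in range(n_iter):
        for k in range(n_par):
            prop = th.copy()
            prop[k] += rng.normal(0.0, scales[k])
            lpp = logpost(prop)
            if log(rng.random()) < lpp - lp:
                th, lp = prop, lpp
        if it >= burn:
            draws[it - burn] = th
    return {
        "alpha_site": draws[:, :J],
        "alpha_V": draws[:, J],
        "beta_V": draws[:, J + 1],
        "sigma2_RS": np.exp(-draws[:, J + 2]),
        "sigma2_site": np.exp(-draws[:, J + 3]),
    }
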