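"""Model comparison, posterior summaries and convergence diagnostics.

Model comparison uses within-sample predictive criteria computed from the
pointwise log-likelihood draws: WAIC (lower is better) and PSIS-LOO
(higher elpd is better).  Convergence is judged by the classic split-chain
Gelman-Rubin potential scale reduction factor (converged when R-hat <=
1.01) and an autocorrelation-based effective sample size (target 3000 per
parameter).  Strength and support of a slope are reported through its
posterior distribution: mean, SD, equal-tailed 95% credible interval and
P(beta < 0), the fraction of draws below zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from arviz import psislw
from scipy.special import logsumexp

from .models import PosteriorDraws

RHAT_THRESHOLD = 1.01
PARETO_K_THRESHOLD = 0.7


# ---------------------------------------------------------------------------
# Information criteria
# ---------------------------------------------------------------------------


def _check_loglik(pointwise_loglik: np.ndarray, min_draws: int = 100) -> np.ndarray:
    ll = np.asarray(pointwise_loglik, dtype=float)
    if ll.ndim == 3:  # (chains, draws, obs) -> pooled
        ll = ll.reshape(-1, ll.shape[2])
    if ll.shape[0] < min_draws:
        raise ValueError(f"need >= {min_draws} draws, got {ll.shape[0]}")
    if not np.all(np.isfinite(ll)):
        bad = int(np.argwhere(~np.all(np.isfinite(ll), axis=0))[0, 0])
        raise ValueError(f"non-finite log-likelihood for observation {bad}")
    return ll


def compute_waic(pointwise_loglik: np.ndarray) -> tuple[float, float, float]:
    """WAIC on the deviance scale, with its SE and effective parameters.

    ``WAIC = -2 * sum_i [lppd_i - p_i]`` where ``lppd_i`` is the log of
    the posterior-mean pointwise density and ``p_i`` the posterior variance
    of the pointwise log-likelihood.  Returns ``(waic, se, p_waic)``.
    """
    ll = _check_loglik(pointwise_loglik)
    S, n = ll.shape
    lppd_i = logsumexp(ll, axis=0) - np.log(S)
    p_i = np.var(ll, axis=0, ddof=1)
    elpd_i = lppd_i - p_i
    waic = -2.0 * float(np.sum(elpd_i))
    se = 2.0 * float(np.sqrt(n * np.var(elpd_i, ddof=1)))
    return waic, se, float(np.sum(p_i))


def compute_loo(
    pointwise_loglik: np.ndarray,
) -> tuple[float, float, np.ndarray]:
    """Pareto-smoothed importance-sampling LOO.

    Returns ``(elpd_loo, se, pareto_k)`` where ``pareto_k`` holds the
    per-observation tail-shape diagnostics; values above 0.7 indicate an
    unreliable pointwise estimate.
    """
    ll = _check_loglik(pointwise_loglik)
    S, n = ll.shape
    # importance ratios for leaving observation i out are 1/p(y_i|theta)
    lw, k = psislw(-ll.T)  # (n_obs, draws) in, smoothed normalized out
    elpd_i = logsumexp(ll.T + lw, axis=1)
    elpd = float(np.sum(elpd_i))
    se = float(np.sqrt(n * np.var(elpd_i, ddof=1)))
    return elpd, se, np.asarray(k, dtype=float)


def exact_loo(refit_fn, n_obs: int) -> float:
    """Exact leave-one-out elpd by n refits (oracle, small n only).

    ``refit_fn(i)`` must return the pointwise log-likelihood draws of the
    held-out observation i under a fit that excluded it, shape (draws,).
    """
    total = 0.0
    for i in range(n_obs):
        ll_i = np.asarray(refit_fn(i), dtype=float).ravel()
        total += float(logsumexp(ll_i) - np.log(ll_i.size))
    return total


@dataclass
class ComparisonTable:
    """Per-model WAIC/LOO comparison; lower WAIC / higher elpd is better."""

    table: pd.DataFrame

    @classmethod
    def from_fits(cls, fits: dict[str, PosteriorDraws]) -> "ComparisonTable":
        rows = []
        for name, fit in fits.items():
            ll = fit.loglik_flat()
            waic, waic_se, p_waic = compute_waic(ll)
            elpd, loo_se, k = compute_loo(ll)
            rows.append(
                {
                    "model": name,
                    "waic": waic,
                    "waic_se": waic_se,
                    "p_waic": p_waic,
                    "elpd_loo": elpd,
                    "loo_se": loo_se,
                    "max_pareto_k": float(np.max(k)),
                    "n_high_pareto_k": int(np.sum(k > PARETO_K_THRESHOLD)),
                }
            )
        df = pd.DataFrame(rows).sort_values("waic", ignore_index=True)
        return cls(df)

    def best_by_waic(self) -> str:
        return str(self.table.loc[self.table["waic"].idxmin(), "model"])

    def best_by_loo(self) -> str:
        return str(self.table.loc[self.table["elpd_loo"].idxmax(), "model"])


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


def posterior_prob_negative(slope_draws: np.ndarray) -> float:
    """P(beta < 0): fraction of posterior draws strictly below zero."""
    draws = np.asarray(slope_draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("no draws")
    return float(np.mean(draws < 0.0))


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval."""
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(np.asarray(draws, float).ravel(), [a, 1.0 - a])
    return float(lo), float(hi)


def bayesian_r2(fit: PosteriorDraws, X: np.ndarray) -> tuple[float, np.ndarray]:
    """Site-level variance explained, per posterior draw.

    For each draw, ``r2 = var(fitted) / (var(fitted) + var(residual))``
    where fitted values are the site-level regression predictions and
    residuals are the site means minus the fit.  Returns the posterior
    mean and the per-draw values.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("site-level R2 needs at least 2 sites")
    coef = np.stack(
        [fit.stacked(name) for name in fit.coef_names], axis=1
    )  # (draws, p)
    alpha_site = fit.stacked("alpha_site")  # (draws, J)
    fitted = coef @ X.T  # (draws, J)
    resid = alpha_site - fitted
    var_f = np.var(fitted, axis=1, ddof=1)
    var_r = np.var(resid, axis=1, ddof=1)
    r2 = var_f / (var_f + var_r)
    return float(np.mean(r2)), r2


@dataclass
class SlopeSummary:
    """Posterior summary of one slope: mean, SD, 95% CI, P(beta<0), R2."""

    covariate: str
    mean: float
    sd: float
    ci_lower: float
    ci_upper: float
    prob_negative: float
    r2: float | None = None

    @classmethod
    def from_fit(
        cls, fit: PosteriorDraws, slope_name: str, X: np.ndarray | None = None
    ) -> "SlopeSummary":
        draws = fit.stacked(slope_name)
        lo, hi = credible_interval(draws)
        r2 = bayesian_r2(fit, X)[0] if X is not None else None
        return cls(
            covariate=slope_name,
            mean=float(np.mean(draws)),
            sd=float(np.std(draws, ddof=1)),
            ci_lower=lo,
            ci_upper=hi,
            prob_negative=posterior_prob_negative(draws),
            r2=r2,
        )


# ---------------------------------------------------------------------------
# Convergence diagnostics
# ---------------------------------------------------------------------------


def _as_chains(chains: np.ndarray) -> np.ndarray:
    a = np.asarray(chains, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.ndim != 2:
        raise ValueError("expected (n_chains, n_draws) draws")
    return a


def rhat(chains: np.ndarray) -> float:
    """Classic split-chain Gelman-Rubin potential scale reduction factor.

    Each chain is split in half; R-hat compares between- to within-chain
    variance of the split chains.  Values <= 1.01 are taken as converged.
    Degenerate case: all chains constant and equal returns exactly 1.
    """
    a = _as_chains(chains)
    if a.shape[0] < 2:
        raise ValueError("R-hat needs at least 2 chains")
    n = a.shape[1] // 2
    splits = np.concatenate([a[:, :n], a[:, n : 2 * n]], axis=0)
    m, n = splits.shape
    means = splits.mean(axis=1)
    W = float(np.mean(np.var(splits, axis=1, ddof=1)))
    B = n * float(np.var(means, ddof=1))
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def effective_sample_size(chains: np.ndarray) -> float:
    """Autocorrelation-based ESS (initial positive sequence estimator).

    Pools the chains' autocovariances (BDA-style multi-chain estimator),
    truncates the autocorrelation sum at the first negative paired sum
    (Geyer's initial positive sequence) and returns ``m*n / (1 + 2*sum
    rho_t)``, capped at the total number of draws.  A constant chain is
    degenerate; its ESS is reported as the total draw count.
    """
    a = _as_chains(chains)
    m, n = a.shape
    total = m * n
    if n < 4 or np.all(np.ptp(a, axis=1) == 0):
        return float(total)
    means = a.mean(axis=1)
    W = float(np.mean(np.var(a, axis=1, ddof=1)))
    B_over_n = float(np.var(means, ddof=1)) if m > 1 else 0.0
    var_plus = (n - 1) / n * W + B_over_n
    if var_plus == 0:
        return float(total)
    # per-chain autocovariance via FFT, averaged across chains
    centered = a - means[:, None]
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, n=nfft, axis=1)
    acov = np.fft.irfft(f * np.conjugate(f), n=nfft, axis=1)[:, :n].real / n
    mean_acov = acov.mean(axis=0)
    rho = 1.0 - (W - mean_acov) / var_plus
    # Geyer initial positive sequence on paired sums rho_{2k} + rho_{2k+1}
    tau = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        tau += pair
        t += 2
    ess = total / (1.0 + 2.0 * tau)
    return float(min(ess, total))


def diagnostics_table(fit: PosteriorDraws) -> pd.DataFrame:
    """R-hat and ESS for every scalar parameter of a fit."""
    rows = []
    for name, arr in fit.scalar_chains().items():
        rows.append(
            {
                "parameter": name,
                "rhat": rhat(arr),
                "ess": effective_sample_size(arr),
            }
        )
    df = pd.DataFrame(rows)
    df["converged"] = df["rhat"] <= RHAT_THRESHOLD
    return df


# ---------------------------------------------------------------------------
# Posterior predictive checks
# ---------------------------------------------------------------------------

_PPC_STATS = {
    "mean": np.mean,
    "sd": lambda x: np.std(x, ddof=1) if len(x) > 1 else 0.0,
    "min": np.min,
    "max": np.max,
}


def posterior_predictive_check(
    fit: PosteriorDraws,
    y: np.ndarray,
    site_index: np.ndarray,
    v: np.ndarray | None = None,
    statistics: tuple[str, ...] = ("mean", "sd", "min", "max"),
    n_rep: int = 500,
    seed: int = 0,
    flag_band: float = 0.025,
) -> pd.DataFrame:
    """Tail probabilities of observed per-site statistics under the fit.

    Draws ``n_rep`` replicated datasets from the posterior (one per
    subsampled draw), computes each statistic of the log range per site,
    and reports ``p = P(T_rep <= T_obs)``; values within ``flag_band`` of
    0 or 1 are flagged as misfit.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float)
    site_index = np.asarray(site_index, int)
    J = int(site_index.max()) + 1
    if fit.model == "global":
        alpha = fit.stacked("alpha_site")
        sigma2 = fit.stacked("sigma2_RS")
        mean_of = lambda d: alpha[d][site_index]
    else:
        a = fit.stacked("alpha")
        b = fit.stacked("beta")
        sigma2 = fit.stacked("sigma2")
        vv = np.asarray(v, float)
        mean_of = lambda d: a[d][site_index] + b[d][site_index] * vv
    S = sigma2.shape[0]
    picks = rng.choice(S, size=min(n_rep, S), replace=False)
    site_masks = [site_index == j for j in range(J)]
    obs = {
        s: np.array([_PPC_STATS[s](y[mask]) for mask in site_masks])
        for s in statistics
    }
    exceed = {s: np.zeros(J) for s in statistics}
    for d in picks:
        y_rep = rng.normal(mean_of(d), np.sqrt(sigma2[d]))
        for s in statistics:
            t_rep = np.array([_PPC_STATS[s](y_rep[mask]) for mask in site_masks])
            for stat_name in (s,):
                exceed[stat_name] += (t_rep <= obs[stat_name]).astype(float)
    rows = []
    for s in statistics:
        p = exceed[s] / len(picks)
        for j in range(J):
            rows.append(
                {
                    "site": j,
                    "statistic": s,
                    "p_tail": p[j],
                    "flagged": bool(p[j] < flag_band or p[j] > 1 - flag_band),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Local-slope classification
# ---------------------------------------------------------------------------


def classify_local_slopes(fit: PosteriorDraws) -> tuple[pd.DataFrame, dict[str, float]]:
    """Sign and uncertainty class of every mountain's local slope.

    Per site: sign of the posterior-mean slope, the mean/SD ratio, and a
    low-uncertainty flag when the equal-tailed 95% CI excludes 0.  Sites
    whose covariate was constant (flagged at fit time) are excluded from
    reporting.  Aggregates are percentages of reported sites: positive,
    negative, and the low-uncertainty subsets of each.
    """
    if fit.model != "local":
        raise ValueError("slope classification applies to local fits")
    beta = fit.stacked("beta")  # (draws, J)
    J = beta.shape[1]
    flagged = set(map(int, fit.flagged_sites)) if fit.flagged_sites is not None else set()
    rows = []
    for j in range(J):
        if j in flagged:
            continue
        d = beta[:, j]
        lo, hi = credible_interval(d)
        mean = float(np.mean(d))
        sd = float(np.std(d, ddof=1))
        rows.append(
            {
                "site": j,
                "site_id": fit.site_ids[j] if fit.site_ids else str(j),
                "mean": mean,
                "sd": sd,
                "mean_sd_ratio": mean / sd if sd > 0 else np.inf,
                "ci_lower": lo,
                "ci_upper": hi,
                "sign": "positive" if mean > 0 else "negative",
                "low_uncertainty": bool(lo > 0 or hi < 0),
            }
        )
    df = pd.DataFrame(rows)
    n = len(df)
    agg = {
        "pct_positive": 100.0 * float((df["sign"] == "positive").sum()) / n,
        "pct_negative": 100.0 * float((df["sign"] == "negative").sum()) / n,
        "pct_positive_low_uncertainty": 100.0
        * float(((df["sign"] == "positive") & df["low_uncertainty"]).sum())
        / n,
        "pct_negative_low_uncertainty": 100.0
        * float(((df["sign"] == "negative") & df["low_uncertainty"]).sum())
        / n,
        "n_sites": n,
    }
    return df, agg
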