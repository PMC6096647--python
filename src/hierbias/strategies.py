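"""The five analysis strategies applied to each simulated dataset.

Bayesian strategies test the point null ``delta = 0`` against the standard
normal prior ``delta ~ N(0, 1)`` with the Savage-Dickey density ratio

    BF10 = p(delta = 0 | H1) / p(delta = 0 | data, H1),

the prior density at zero divided by the posterior density at zero, so that
``BF10 > 1`` (log BF10 > 0) favours the alternative.  The posterior density
at zero is estimated from MCMC draws with a log-spline density fit (Poisson
regression of binned counts on a cubic B-spline basis), with a Gaussian
kernel estimate on the log scale as fallback.

Frequentist strategies are equal-n pooled two-sample t tests

    t = (mu2_hat - mu1_hat) / sqrt((tau2_1_hat + tau2_2_hat) / N)

with ``2N - 2`` degrees of freedom, differing only in what they feed in:

* TR — the true participant means (the unobservable gold standard);
* NF — participant sample means (ignoring the hierarchy);
* TF — participant-level posterior medians from the hierarchical model
  (the two-step shortcut);
* HF — group-level posterior medians ``mu_g`` and ``tau`` from the
  hierarchical model, with standard error ``sqrt(2 tau_hat^2 / N)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import interpolate, stats
from scipy.special import logsumexp

from .generate import ParticipantTruth, TrialData, participant_means
from .mcmc import PosteriorDraws, posterior_point

__all__ = [
    "BayesFactorResult",
    "TTestResult",
    "prior_density_delta",
    "estimate_density_at_zero",
    "savage_dickey_bf10",
    "t_statistic",
    "p_value_two_sided",
    "strategy_true",
    "strategy_nf",
    "strategy_tf",
    "strategy_hf",
]

ALPHA_DEFAULT = 0.05
#: Floor applied to the estimated posterior density at zero, so Bayes factors
#: stay finite when the posterior has essentially no mass at the null.
DENSITY_FLOOR = 1e-300


@dataclass(frozen=True)
class BayesFactorResult:
    """Savage-Dickey Bayes factor record for one model fit."""

    log_bf10: float
    prior_density_at_zero: float
    posterior_density_at_zero: float
    model_tag: str
    floored: bool = False


@dataclass(frozen=True)
class TTestResult:
    """Two-sided two-sample t-test record for one strategy."""

    strategy_tag: str
    t: float
    df: int
    p: float
    alpha: float
    reject: bool
    mu_hat: tuple
    var_hat: tuple


def prior_density_delta(x) -> float:
    """Density of the effect-size prior ``delta ~ N(0, 1)``."""
    return stats.norm.pdf(x)


# ---------------------------------------------------------------------------
# posterior density at the point null


def _log_density_logspline(draws: np.ndarray, x0: float) -> float:
    """Log-spline density estimate evaluated (on the log scale) at ``x0``.

    Bins the draws, fits a Poisson regression of the counts on a cubic
    B-spline basis over the data range, normalises the fitted curve
    numerically, and evaluates the log density at ``x0``.  Outside the data
    range the log density is continued linearly from the boundary slope,
    matching the linear log-density tails of classic log-spline estimators.
    """
    import statsmodels.api as sm

    lo, hi = float(draws.min()), float(draws.max())
    span = hi - lo
    n_bins = 300
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(draws, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    width = span / n_bins

    n_interior = 12
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([[lo] * 4, interior, [hi] * 4])
    X = interpolate.BSpline.design_matrix(centers, knots, 3).toarray()

    offset = np.full(n_bins, math.log(draws.size * width))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(counts, X, family=sm.families.Poisson(), offset=offset)
        beta = model.fit(maxiter=200).params

    # normalise on a fine grid
    grid = np.linspace(lo, hi, 2001)
    Xg = interpolate.BSpline.design_matrix(grid, knots, 3).toarray()
    log_f = Xg @ beta
    log_norm = logsumexp(log_f) + math.log(grid[1] - grid[0])
    log_f = log_f - log_norm

    if lo <= x0 <= hi:
        xb = interpolate.BSpline.design_matrix(np.array([x0]), knots, 3).toarray()
        return float(xb @ beta) - log_norm
    # linear continuation from the nearest boundary; the continued tail is
    # forced to be non-increasing away from the data so a noisy boundary
    # slope can never manufacture density far outside the draw range
    if x0 < lo:
        slope = max((log_f[1] - log_f[0]) / (grid[1] - grid[0]), 0.0)
        return float(log_f[0] + slope * (x0 - lo))
    slope = min((log_f[-1] - log_f[-2]) / (grid[1] - grid[0]), 0.0)
    return float(log_f[-1] + slope * (x0 - hi))


def _log_density_kde(draws: np.ndarray, x0: float) -> float:
    """Gaussian-kernel log density at ``x0`` (Silverman bandwidth)."""
    n = draws.size
    sd = draws.std(ddof=1)
    iqr = np.subtract(*np.percentile(draws, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    h = 0.9 * scale * n ** (-0.2)
    z = (x0 - draws) / h
    return float(logsumexp(-0.5 * z * z) - math.log(n * h * math.sqrt(2 * math.pi)))


def estimate_density_at_zero(delta_draws, method: str = "logspline",
                             return_flag: bool = False):
    """Estimate the posterior density of the effect size at ``delta = 0``.

    Needs at least 1,000 pooled draws with non-zero spread.  When the
    posterior mass sits so far from zero that the estimate underflows, the
    value is floored at a tiny positive constant and flagged, keeping the
    resulting Bayes factor finite.
    """
    draws = np.asarray(delta_draws, dtype=float).ravel()
    if draws.size < 1000:
        raise ValueError(f"need at least 1000 draws, got {draws.size}")
    if draws.std(ddof=1) == 0.0:
        raise ValueError("draws are constant; density at a point is undefined")
    if method == "logspline":
        if draws.min() <= 0.0 <= draws.max():
            try:
                log_f = _log_density_logspline(draws, 0.0)
            except Exception:
                log_f = _log_density_kde(draws, 0.0)
        else:
            # zero lies outside the sampled range: the spline has no data
            # there, so use the Gaussian-tailed kernel estimate instead
            log_f = _log_density_kde(draws, 0.0)
    elif method == "kde":
        log_f = _log_density_kde(draws, 0.0)
    else:
        raise ValueError(f"unknown density method {method!r}")
    floored = not np.isfinite(log_f) or log_f < math.log(DENSITY_FLOOR)
    value = DENSITY_FLOOR if floored else math.exp(min(log_f, 690.0))
    if floored:
        warnings.warn("posterior density at 0 underflowed; floored", RuntimeWarning)
    return (value, floored) if return_flag else value


def savage_dickey_bf10(delta_draws, model_tag: str = "hierarchical",
                       method: str = "logspline") -> BayesFactorResult:
    """Savage-Dickey Bayes factor BF10 from pooled posterior draws of delta.

    ``log BF10 = log p(0 | H1) - log p(0 | data, H1)``; positive values
    favour the alternative hypothesis.
    """
    post0, floored = estimate_density_at_zero(delta_draws, method=method,
                                              return_flag=True)
    prior0 = float(prior_density_delta(0.0))
    return BayesFactorResult(
        log_bf10=math.log(prior0) - math.log(post0),
        prior_density_at_zero=prior0,
        posterior_density_at_zero=post0,
        model_tag=model_tag,
        floored=floored,
    )


# ---------------------------------------------------------------------------
# frequentist t tests


def t_statistic(mu1_hat: float, mu2_hat: float, tau2_1_hat: float,
                tau2_2_hat: float, N: int) -> float:
    """Two-sample t statistic with standard error ``sqrt((tau2_1 + tau2_2)/N)``."""
    if N < 2:
        raise ValueError("need N >= 2 per group")
    if tau2_1_hat < 0 or tau2_2_hat < 0:
        raise ValueError("variance estimates must be non-negative")
    se = math.sqrt((tau2_1_hat + tau2_2_hat) / N)
    if se == 0.0:
        raise ValueError("zero standard error: both variance estimates are zero")
    return (mu2_hat - mu1_hat) / se


def p_value_two_sided(t: float, df: int) -> float:
    """Two-sided p value, ``2 P(T_df >= |t|)``."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * stats.t.sf(abs(t), df))


def _ttest_from_values(values: np.ndarray, tag: str, alpha: float) -> TTestResult:
    """Pooled equal-n t test from a (2, N) matrix of participant-level values."""
    values = np.asarray(values, dtype=float)
    N = values.shape[1]
    mu_hat = values.mean(axis=1)
    var_hat = values.var(axis=1, ddof=1)
    t = t_statistic(mu_hat[0], mu_hat[1], var_hat[0], var_hat[1], N)
    df = 2 * N - 2
    p = p_value_two_sided(t, df)
    return TTestResult(strategy_tag=tag, t=t, df=df, p=p, alpha=alpha,
                       reject=p < alpha, mu_hat=tuple(mu_hat),
                       var_hat=tuple(var_hat))


def strategy_true(truth: ParticipantTruth, alpha: float = ALPHA_DEFAULT) -> TTestResult:
    """TR: t test on the true participant means (oracle reference)."""
    return _ttest_from_values(truth.theta, "TR", alpha)


def strategy_nf(data: TrialData, alpha: float = ALPHA_DEFAULT) -> TTestResult:
    """NF: t test on participant sample means (ignores the hierarchy)."""
    return _ttest_from_values(participant_means(data), "NF", alpha)


def strategy_tf(hier_draws: PosteriorDraws, alpha: float = ALPHA_DEFAULT) -> TTestResult:
    """TF: t test on participant-level posterior medians (two-step shortcut)."""
    theta_med = posterior_point(hier_draws, "theta", "median")
    return _ttest_from_values(theta_med, "TF", alpha)


def strategy_hf(hier_draws: PosteriorDraws, N: int,
                alpha: float = ALPHA_DEFAULT) -> TTestResult:
    """HF: t test on group-level posterior medians from the hierarchical fit.

    Uses the posterior medians of ``mu_1``, ``mu_2`` and the single
    group-level SD ``tau``; standard error ``sqrt(2 tau_hat^2 / N)``.
    """
    for name in ("mu1", "mu2", "tau"):
        if name not in hier_draws:
            raise KeyError(f"hierarchical draws lack group-level parameter {name!r}")
    mu1_hat = float(posterior_point(hier_draws, "mu1", "median"))
    mu2_hat = float(posterior_point(hier_draws, "mu2", "median"))
    tau_hat = float(posterior_point(hier_draws, "tau", "median"))
    t = t_statistic(mu1_hat, mu2_hat, tau_hat**2, tau_hat**2, N)
    df = 2 * N - 2
    p = p_value_two_sided(t, df)
    return TTestResult(strategy_tag="HF", t=t, df=df, p=p, alpha=alpha,
                       reject=p < alpha, mu_hat=(mu1_hat, mu2_hat),
                       var_hat=(tau_hat**2, tau_hat**2))
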