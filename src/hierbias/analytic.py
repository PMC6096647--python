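"""Closed-form results for the two-level normal model.

A participant's trials are normal around the participant's true mean,
``x_ij ~ N(theta_i, sigma2)``, and true means are normal around the group
mean, ``theta_i ~ N(mu, tau2)``.  The participant sample mean over ``K``
trials therefore varies around the group mean with two variance components,
the group-level variance ``tau2`` and the sampling variance ``sigma2 / K``.
These identities are the analytical backbone of the bias study: ignoring the
hierarchy inflates the apparent group-level variance by ``sigma2 / K``, while
two-step analyses deflate it through shrinkage.  The functions here are pure
and are also used as oracles when testing the samplers and the generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HierNormalSpec",
    "marginal_mean_variance",
    "shrinkage_estimate",
    "conditional_posterior_variance",
    "flat_prior_group_posterior",
]


@dataclass(frozen=True)
class HierNormalSpec:
    """Known-variance two-level normal specification.

    Parameters
    ----------
    mu : float
        Group-level mean (measurement units).
    tau2 : float
        Group-level variance: variance of participants' true means around
        ``mu`` (units squared).  Must be non-negative.
    sigma2 : float
        Trial-level variance within a participant (units squared).  Must be
        non-negative.
    K : int
        Number of trials per participant, at least 1.
    """

    mu: float
    tau2: float
    sigma2: float
    K: int

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError(f"tau2 must be >= 0, got {self.tau2}")
        if self.sigma2 < 0:
            raise ValueError(f"sigma2 must be >= 0, got {self.sigma2}")
        if int(self.K) != self.K or self.K < 1:
            raise ValueError(f"K must be an integer >= 1, got {self.K}")

    @property
    def sampling_variance(self) -> float:
        """Variance ``sigma2 / K`` of a participant sample mean around theta."""
        return self.sigma2 / self.K

    def _require_nondegenerate(self) -> None:
        # The conditional posterior of theta is ill-defined when both
        # variance components vanish; fail loudly rather than guess.
        if self.tau2 == 0 and self.sigma2 == 0:
            raise ValueError("degenerate spec: tau2 and sigma2 are both zero")


def marginal_mean_variance(spec: HierNormalSpec) -> float:
    """Variance of a participant sample mean around the group mean.

    Integrating over the participant's true mean gives
    ``Var(xbar_i) = tau2 + sigma2 / K``: the group-level variance plus the
    sampling variance of the mean of ``K`` trials.
    """
    return spec.tau2 + spec.sampling_variance


def shrinkage_estimate(xbar, spec: HierNormalSpec):
    """Posterior mean of a participant's true mean given its sample mean.

    With known variances the posterior of ``theta_i`` given ``xbar_i`` is
    normal and its mean is the precision-weighted average

    ``(xbar * tau2 + mu * sigma2/K) / (tau2 + sigma2/K)``,

    which pulls (shrinks) the sample mean towards the group mean; the pull is
    stronger the larger the sampling variance ``sigma2 / K``.  Accepts a
    scalar or an array of sample means.
    """
    spec._require_nondegenerate()
    s = spec.sampling_variance
    w = spec.tau2 / (spec.tau2 + s)
    return w * np.asarray(xbar, dtype=float) + (1.0 - w) * spec.mu


def conditional_posterior_variance(spec: HierNormalSpec) -> float:
    """Posterior variance of a participant's true mean given its sample mean.

    Equals ``(tau2 * sigma2/K) / (tau2 + sigma2/K)``, the harmonic combination
    of the two variance components; it never exceeds either of them.
    """
    spec._require_nondegenerate()
    s = spec.sampling_variance
    return spec.tau2 * s / (spec.tau2 + s)


def flat_prior_group_posterior(xbars, spec: HierNormalSpec) -> tuple[float, float]:
    """Posterior of the group mean under a flat prior and known variances.

    Given ``N`` participant sample means, each marginally
    ``N(mu, tau2 + sigma2/K)``, and an improper uniform prior ``p(mu) ∝ 1``,
    the posterior of ``mu`` is normal with mean the average of the sample
    means and variance ``(tau2 + sigma2/K) / N``.

    Returns
    -------
    (mean, variance) of the normal posterior of the group mean.
    """
    xbars = np.asarray(xbars, dtype=float)
    if xbars.size == 0:
        raise ValueError("need at least one participant sample mean")
    v = marginal_mean_variance(spec)
    return float(xbars.mean()), v / xbars.size
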