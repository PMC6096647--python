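"""Posterior samplers for the hierarchical and non-hierarchical Bayes models.

Two models are fit throughout the study:

* the **hierarchical model** — the generating model itself:
  ``x_gij ~ N(theta_gi, sigma2_gi)``, ``theta_gi ~ N(mu_g, tau^2)``, with a
  half-normal(``lam``) distribution on the participant trial SD (or on the
  variance, matching the data's ``sigma_mode``), priors ``mu1 ~ N(6, 1/3)`` truncated
  to positive values, ``tau ~ U(0, 15)``, ``lam ~ U(0, 10)``,
  ``delta ~ N(0, 1)`` and the deterministic link ``mu2 = mu1 + delta*tau``;
* the **non-hierarchical model** — the same group level applied directly to
  participant sample means, ``xbar_gi ~ N(mu_g, tau^2)``, ignoring the
  sampling variance of those means.

Sampling is Gibbs with exact conjugate updates for ``theta``, ``mu1`` and
``delta``, slice sampling for the bounded scales ``tau`` and ``lam``, and an
adaptive random-walk Metropolis step (on the log scale, vectorised across
participants) for the participant variances.  Correctness of the posterior,
rather than of any particular sampler, is what the study depends on; the test
suite checks it by simulation-based calibration and against a dense
grid-integration oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
from scipy.special import ndtr, ndtri

from .generate import TrialData, participant_means

__all__ = [
    "McmcSettings",
    "PosteriorDraws",
    "ConvergenceReport",
    "ConvergenceError",
    "fit_hierarchical",
    "fit_nonhierarchical",
    "compute_rhat",
    "posterior_point",
]

# Prior constants (group-level), shared by both models.
MU1_PRIOR_MEAN = 6.0
MU1_PRIOR_SD = 1.0 / 3.0
TAU_UPPER = 15.0
LAM_UPPER = 10.0


@dataclass(frozen=True)
class McmcSettings:
    """Chain layout and convergence policy for one model fit.

    ``retained_per_chain`` is ``(iterations - burn_in) / thin`` and must be a
    positive integer.  ``max_retries`` controls the non-convergence policy:
    each retry doubles the iteration and burn-in counts once before the fit
    is declared failed.
    """

    chains: int = 3
    iterations: int = 20_000
    burn_in: int = 2_000
    thin: int = 4
    rhat_threshold: float = 1.05
    seed: int = 0
    max_retries: int = 1

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")
        if self.burn_in < 0 or self.iterations <= self.burn_in:
            raise ValueError("iterations must exceed burn_in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.iterations - self.burn_in) % self.thin != 0:
            raise ValueError("(iterations - burn_in) must be divisible by thin")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thin

    def doubled(self) -> "McmcSettings":
        return replace(self, iterations=2 * self.iterations, burn_in=2 * self.burn_in)

    @classmethod
    def reference_hierarchical(cls, seed: int = 0) -> "McmcSettings":
        """3 chains x 20,000 draws, 2,000 burn-in, keep 1 in 4 -> 4,500/chain."""
        return cls(chains=3, iterations=20_000, burn_in=2_000, thin=4, seed=seed)

    @classmethod
    def reference_nonhierarchical(cls, seed: int = 0) -> "McmcSettings":
        """3 chains x 5,000 draws, 500 burn-in, no thinning -> 4,500/chain."""
        return cls(chains=3, iterations=5_000, burn_in=500, thin=1, seed=seed)

    @classmethod
    def desk(cls, seed: int = 0) -> "McmcSettings":
        """Shortened chains for replicated desk-scale studies."""
        return cls(chains=3, iterations=2_000, burn_in=500, thin=1, seed=seed)


@dataclass(frozen=True)
class ConvergenceReport:
    """Split-chain potential-scale-reduction factors per parameter."""

    rhat: dict
    threshold: float
    converged: bool

    @classmethod
    def from_rhats(cls, rhat: dict, threshold: float) -> "ConvergenceReport":
        finite = [v for v in rhat.values() if np.isfinite(v)]
        ok = bool(finite) and all(v <= threshold for v in finite)
        ok = ok and all(np.isfinite(v) for v in rhat.values())
        return cls(rhat=dict(rhat), threshold=threshold, converged=ok)

    def to_dict(self) -> dict:
        return {"rhat": {k: float(v) for k, v in self.rhat.items()},
                "threshold": self.threshold, "converged": self.converged}


class ConvergenceError(RuntimeError):
    """Raised when a fit fails the R-hat threshold after the retry policy.

    Carries the draws and report so a harness can count and inspect the
    failure instead of losing it.
    """

    def __init__(self, draws: "PosteriorDraws", report: ConvergenceReport):
        super().__init__(
            f"MCMC did not converge: max R-hat = {max(report.rhat.values()):.4f} "
            f"> {report.threshold}")
        self.draws = draws
        self.report = report


@dataclass
class PosteriorDraws:
    """Retained posterior draws, one array per parameter.

    Scalar parameters have shape ``(chains, draws)``; participant-level
    parameters (``theta``, ``sigma2``, hierarchical model only) have shape
    ``(chains, draws, 2, N)``.  ``mu2`` is stored explicitly and satisfies
    ``mu2 = mu1 + delta * tau`` draw-wise.
    """

    params: dict
    settings: McmcSettings
    model_tag: str = "hierarchical"

    def __contains__(self, name: str) -> bool:
        return name in self.params

    @property
    def names(self) -> list:
        return list(self.params)

    def pooled(self, name: str) -> np.ndarray:
        """Draws for ``name`` pooled across chains (chain axis collapsed)."""
        if name not in self.params:
            raise KeyError(f"unknown parameter {name!r}; have {self.names}")
        a = self.params[name]
        return a.reshape(-1, *a.shape[2:])

    def to_frame(self):
        """Long table (parameter, chain, draw, index, value) for persistence."""
        import pandas as pd

        rows = []
        for name, a in self.params.items():
            C, D = a.shape[:2]
            flat = a.reshape(C, D, -1)
            for idx in range(flat.shape[2]):
                rows.append(pd.DataFrame({
                    "parameter": name,
                    "chain": np.repeat(np.arange(C), D),
                    "draw": np.tile(np.arange(D), C),
                    "index": idx,
                    "value": flat[:, :, idx].ravel(),
                }))
        return pd.concat(rows, ignore_index=True)


def posterior_point(draws: PosteriorDraws, parameter: str, statistic: str = "median"):
    """Point estimate of a parameter: chains pooled, then mean or median.

    For participant-level parameters the statistic is taken draw-wise per
    entry, returning a ``(2, N)`` matrix.
    """
    pooled = draws.pooled(parameter)
    if statistic == "mean":
        return np.mean(pooled, axis=0)
    if statistic == "median":
        return np.median(pooled, axis=0)
    raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")


# ---------------------------------------------------------------------------
# convergence diagnostics


def split_rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one scalar parameter.

    Each chain is split in half and the classic between/within-variance
    ratio is computed over the 2C half-chains.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need a (chains, draws) array with >= 2 chains")
    C, D = chains.shape
    if D < 4:
        raise ValueError("need at least 4 draws per chain")
    half = D // 2
    splits = np.concatenate([chains[:, :half], chains[:, half:2 * half]], axis=0)
    m, n = splits.shape
    means = splits.mean(axis=1)
    W = splits.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    var_hat = (n - 1) / n * W + B / n
    return float(np.sqrt(var_hat / W))


def compute_rhat(draws: PosteriorDraws) -> ConvergenceReport:
    """Split R-hat for every parameter; matrices report their worst entry."""
    out = {}
    for name, a in draws.params.items():
        if a.ndim == 2:
            out[name] = split_rhat(a)
        else:
            C, D = a.shape[:2]
            flat = a.reshape(C, D, -1)
            out[name] = max(split_rhat(flat[:, :, j]) for j in range(flat.shape[2]))
    return ConvergenceReport.from_rhats(out, draws.settings.rhat_threshold)


# ---------------------------------------------------------------------------
# sampling primitives


def _slice_sample(x0: float, logpdf: Callable[[float], float], lo: float, hi: float,
                  rng: np.random.Generator) -> float:
    """One slice-sampling update on a bounded support (shrinkage procedure)."""
    logy = logpdf(x0) + math.log(rng.random())
    left, right = lo, hi
    for _ in range(200):
        x1 = left + rng.random() * (right - left)
        if logpdf(x1) >= logy:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0  # pragma: no cover - pathological shrinkage


def _truncated_normal_positive(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Draw from N(mean, sd^2) truncated to (0, inf) by inverse CDF."""
    a = ndtr(-mean / sd)  # P(X <= 0)
    u = a + (1.0 - a) * rng.random()
    u = min(max(u, 1e-16), 1.0 - 1e-16)
    return mean + sd * ndtri(u)


# ---------------------------------------------------------------------------
# hierarchical model


def _init_hier_state(xbar, ssw, K, rng):
    """Crude data-based initial values, jittered per chain."""
    N = xbar.shape[1]
    theta = xbar + 0.01 * rng.standard_normal(xbar.shape)
    if K >= 2:
        s2 = np.maximum(ssw / (K - 1), 1e-4)
    else:
        s2 = np.full_like(xbar, 0.05)
    sigma2 = s2 * np.exp(0.2 * rng.standard_normal(xbar.shape))
    pooled_sd = np.std(xbar - xbar.mean(axis=1, keepdims=True))
    tau = float(np.clip(pooled_sd * np.exp(0.3 * rng.standard_normal()), 1e-2, TAU_UPPER - 1e-3))
    mu1 = float(max(xbar[0].mean() + 0.05 * rng.standard_normal(), 1e-3))
    delta = float(np.clip((xbar[1].mean() - xbar[0].mean()) / tau
                          + 0.1 * rng.standard_normal(), -5, 5))
    lam = float(np.clip(np.mean(sigma2) / math.sqrt(2 / math.pi)
                        * np.exp(0.3 * rng.standard_normal()), 1e-2, LAM_UPPER - 1e-3))
    return theta, sigma2, mu1, delta, tau, lam


def _run_hier_chain(xbar, ssw, K, settings, rng, sigma_mode):
    """One chain of the hierarchical sampler; returns retained draws."""
    N = xbar.shape[1]
    theta, sigma2, mu1, delta, tau, lam = _init_hier_state(xbar, ssw, K, rng)
    n_keep = settings.retained_per_chain
    keep = {
        "delta": np.empty(n_keep), "mu1": np.empty(n_keep), "tau": np.empty(n_keep),
        "lam": np.empty(n_keep), "theta": np.empty((n_keep, 2, N)),
        "sigma2": np.empty((n_keep, 2, N)),
    }
    # adaptive RW step for log sigma2, per participant
    step = np.full((2, N), 0.8)
    mu1_prior_prec = 1.0 / MU1_PRIOR_SD**2
    half_sd_mode = sigma_mode == "sd"
    k = 0
    for it in range(settings.iterations):
        # --- theta | rest (conjugate normal, vectorised)
        mus = np.array([mu1, mu1 + delta * tau])
        prec = K / sigma2 + 1.0 / tau**2
        mean = (K * xbar / sigma2 + mus[:, None] / tau**2) / prec
        theta = mean + rng.standard_normal((2, N)) / np.sqrt(prec)

        # --- sigma2 | rest (vectorised RW Metropolis on z = log sigma2)
        A = ssw + K * (xbar - theta) ** 2
        z = np.log(sigma2)
        zp = z + step * rng.standard_normal((2, N))
        if half_sd_mode:
            # half-normal prior on the SD: p(sigma) ∝ exp(-sigma^2/(2 lam^2))
            def logpost_z(zz):
                return (-(K / 2.0 - 0.5) * zz - A * np.exp(-zz) / 2.0
                        - np.exp(zz) / (2.0 * lam**2))
        else:
            # half-normal prior on the variance: p(s2) ∝ exp(-s2^2/(2 lam^2))
            def logpost_z(zz):
                return (-(K / 2.0 - 1.0) * zz - A * np.exp(-zz) / 2.0
                        - np.exp(2.0 * zz) / (2.0 * lam**2))
        log_acc = logpost_z(zp) - logpost_z(z)
        accept = np.log(rng.random((2, N))) < log_acc
        z = np.where(accept, zp, z)
        sigma2 = np.exp(z)
        if it < settings.burn_in:  # Robbins-Monro adaptation towards 44%
            step *= np.exp((accept.astype(float) - 0.44) / math.sqrt(1.0 + it))
            step = np.clip(step, 0.05, 10.0)

        # --- tau | rest (slice on (0, TAU_UPPER))
        q1 = float(np.sum((theta[0] - mu1) ** 2))
        d2 = theta[1] - mu1
        s2c = float(d2.sum())
        q2c = float(np.sum(d2**2))
        M = 2 * N

        def logpost_tau(t):
            resid2 = q1 + q2c - 2.0 * delta * t * s2c + N * (delta * t) ** 2
            return -M * math.log(t) - resid2 / (2.0 * t * t)

        tau = _slice_sample(tau, logpost_tau, 1e-12, TAU_UPPER, rng)

        # --- lam | rest (slice on (0, LAM_UPPER))
        Sv = float(np.sum(sigma2)) if half_sd_mode else float(np.sum(sigma2**2))

        def logpost_lam(l):
            return -M * math.log(l) - Sv / (2.0 * l * l)

        lam = _slice_sample(lam, logpost_lam, 1e-12, LAM_UPPER, rng)

        # --- mu1 | rest (conjugate truncated normal)
        prec_mu = M / tau**2 + mu1_prior_prec
        num = (theta[0].sum() + theta[1].sum() - N * delta * tau) / tau**2 \
            + MU1_PRIOR_MEAN * mu1_prior_prec
        mu1 = _truncated_normal_positive(num / prec_mu, 1.0 / math.sqrt(prec_mu), rng)

        # --- delta | rest (conjugate normal; standard-normal prior)
        prec_d = N + 1.0
        mean_d = float(np.sum(theta[1] - mu1)) / tau / prec_d
        delta = mean_d + rng.standard_normal() / math.sqrt(prec_d)

        # --- interweaving step for tau (non-centered parameterization).
        # With eta = (theta - mu_g)/tau held fixed, the trial likelihood
        # depends on tau through xbar_gi ~ N(mu1 + tau*(eta_gi + delta*[g=2]),
        # sigma2_gi/K), so tau has a conjugate normal conditional truncated to
        # its uniform prior support.  Alternating this with the centered
        # update breaks the funnel-shaped tau-theta coupling at small K.
        mus = np.array([mu1, mu1 + delta * tau])
        eta = (theta - mus[:, None]) / tau
        eta_eff = eta + np.array([[0.0], [delta]])
        w = K / sigma2
        prec_t = float(np.sum(w * eta_eff**2))
        if prec_t > 0:
            mean_t = float(np.sum(w * eta_eff * (xbar - mu1))) / prec_t
            sd_t = 1.0 / math.sqrt(prec_t)
            a = ndtr((0.0 - mean_t) / sd_t)
            b = ndtr((TAU_UPPER - mean_t) / sd_t)
            if b - a > 1e-14:
                u = a + (b - a) * rng.random()
                u = min(max(u, 1e-16), 1.0 - 1e-16)
                tau = mean_t + sd_t * ndtri(u)
                theta = np.array([mu1, mu1 + delta * tau])[:, None] + tau * eta

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            keep["delta"][k] = delta
            keep["mu1"][k] = mu1
            keep["tau"][k] = tau
            keep["lam"][k] = lam
            keep["theta"][k] = theta
            keep["sigma2"][k] = sigma2
            k += 1
    return keep


def _finalize(keeps: list, settings: McmcSettings, model_tag: str) -> PosteriorDraws:
    params = {}
    for name in keeps[0]:
        params[name] = np.stack([kc[name] for kc in keeps], axis=0)
    params["mu2"] = params["mu1"] + params["delta"] * params["tau"]
    return PosteriorDraws(params=params, settings=settings, model_tag=model_tag)


def _fit_with_retry(run_one: Callable[[McmcSettings], PosteriorDraws],
                    settings: McmcSettings):
    attempt = settings
    for retry in range(settings.max_retries + 1):
        draws = run_one(attempt)
        report = compute_rhat(draws)
        if report.converged:
            return draws, report
        attempt = attempt.doubled()
    raise ConvergenceError(draws, report)


def fit_hierarchical(data: TrialData, settings: McmcSettings):
    """Sample the full hierarchical model's posterior from trial-level data.

    Returns ``(PosteriorDraws, ConvergenceReport)``; raises
    :class:`ConvergenceError` if any parameter's split R-hat still exceeds
    the threshold after the retry (chain-doubling) policy.
    """
    xbar = participant_means(data)
    ssw = np.sum((data.x - xbar[..., None]) ** 2, axis=2)
    K = data.K
    sigma_mode = data.config.sigma_mode if data.config is not None else "sd"
    root = np.random.SeedSequence(settings.seed)

    def run_one(st: McmcSettings) -> PosteriorDraws:
        children = root.spawn(st.chains)
        keeps = [_run_hier_chain(xbar, ssw, K, st, np.random.default_rng(c), sigma_mode)
                 for c in children]
        return _finalize(keeps, st, "hierarchical")

    return _fit_with_retry(run_one, settings)


# ---------------------------------------------------------------------------
# non-hierarchical model


def _run_nonhier_chain(y, settings, rng):
    """One chain for the participant-means model y_gi ~ N(mu_g, tau^2)."""
    N = y.shape[1]
    M = 2 * N
    s1 = float(y[0].sum())
    mu1 = float(max(y[0].mean() + 0.05 * rng.standard_normal(), 1e-3))
    pooled_sd = float(np.std(y - y.mean(axis=1, keepdims=True)))
    tau = float(np.clip(pooled_sd * np.exp(0.3 * rng.standard_normal()), 1e-2, TAU_UPPER - 1e-3))
    delta = float(np.clip((y[1].mean() - y[0].mean()) / tau
                          + 0.1 * rng.standard_normal(), -5, 5))
    q1_base = float(np.sum(y[0] ** 2))
    mu1_prior_prec = 1.0 / MU1_PRIOR_SD**2
    n_keep = settings.retained_per_chain
    keep = {"delta": np.empty(n_keep), "mu1": np.empty(n_keep), "tau": np.empty(n_keep)}
    k = 0
    for it in range(settings.iterations):
        # --- tau | rest
        q1 = q1_base - 2.0 * mu1 * s1 + N * mu1**2
        d2 = y[1] - mu1
        s2c = float(d2.sum())
        q2c = float(np.sum(d2**2))

        def logpost_tau(t):
            resid2 = q1 + q2c - 2.0 * delta * t * s2c + N * (delta * t) ** 2
            return -M * math.log(t) - resid2 / (2.0 * t * t)

        tau = _slice_sample(tau, logpost_tau, 1e-12, TAU_UPPER, rng)

        # --- mu1 | rest (conjugate truncated normal)
        prec_mu = M / tau**2 + mu1_prior_prec
        num = (s1 + float(y[1].sum()) - N * delta * tau) / tau**2 \
            + MU1_PRIOR_MEAN * mu1_prior_prec
        mu1 = _truncated_normal_positive(num / prec_mu, 1.0 / math.sqrt(prec_mu), rng)

        # --- delta | rest
        prec_d = N + 1.0
        mean_d = float(np.sum(y[1] - mu1)) / tau / prec_d
        delta = mean_d + rng.standard_normal() / math.sqrt(prec_d)

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            keep["delta"][k] = delta
            keep["mu1"][k] = mu1
            keep["tau"][k] = tau
            k += 1
    return keep


def fit_nonhierarchical(means: np.ndarray, settings: McmcSettings):
    """Sample the participant-means model's posterior.

    ``means`` is the ``(2, N)`` matrix of participant sample means; the model
    treats them as exact observations of participants' true means, which is
    precisely the "ignoring the hierarchy" shortcut under study.
    """
    y = np.asarray(means, dtype=float)
    if y.ndim != 2 or y.shape[0] != 2 or y.shape[1] < 2:
        raise ValueError("means must have shape (2, N) with N >= 2")
    root = np.random.SeedSequence(settings.seed)

    def run_one(st: McmcSettings) -> PosteriorDraws:
        children = root.spawn(st.chains)
        keeps = [_run_nonhier_chain(y, st, np.random.default_rng(c)) for c in children]
        return _finalize(keeps, st, "nonhierarchical")

    return _fit_with_retry(run_one, settings)
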