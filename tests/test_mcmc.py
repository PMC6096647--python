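"""Sampler validation: diagnostics, grid-integration oracle, SBC.

The samplers are checked two independent ways: the non-hierarchical
posterior against dense 3-D grid integration over (mu1, delta, tau), and
both samplers by simulation-based calibration (parameters drawn from their
priors, data simulated, posterior rank of the truth recorded; ranks must be
uniform if the sampler targets the correct posterior).
"""

import numpy as np
import pytest
from scipy import stats
from scipy.special import logsumexp

from hierbias import (ConvergenceError, GeneratingConfig, McmcSettings,
                      PosteriorDraws, compute_rhat, fit_hierarchical,
                      fit_nonhierarchical, participant_means, posterior_point,
                      sample_trials, sample_truth)
from hierbias.mcmc import split_rhat

TOY_MEANS = np.array([[6.30, 6.62, 6.51], [6.42, 6.75, 6.88]])
# Frozen from the dense grid oracle below at resolution (601, 601, 801),
# mu1 in [5, 8], delta in [-5, 5], tau in (0, 5]:
TOY_DELTA_MEAN_ORACLE = 0.7266
TOY_DELTA_SD_ORACLE = 0.6300


def grid_oracle_nonhier(y, n_mu=301, n_d=301, n_t=401):
    """Posterior mean/SD of delta by dense grid integration over (mu1, delta, tau)."""
    mu_g = np.linspace(5.0, 8.0, n_mu)
    d_g = np.linspace(-5, 5, n_d)
    t_g = np.linspace(1e-4, 5.0, n_t)
    M, D = np.meshgrid(mu_g, d_g, indexing="ij")
    base = stats.norm.logpdf(M, 6, 1 / 3) + stats.norm.logpdf(D)
    S = np.empty((d_g.size, t_g.size))
    n_per_group = y.shape[1]
    for k, t in enumerate(t_g):
        mu2 = M + D * t
        lp = base - 2 * n_per_group * np.log(t)
        lp = lp - ((y[0][:, None, None] - M) ** 2).sum(axis=0) / (2 * t * t)
        lp = lp - ((y[1][:, None, None] - mu2) ** 2).sum(axis=0) / (2 * t * t)
        S[:, k] = logsumexp(lp, axis=0)
    ld = logsumexp(S, axis=1)
    post = np.exp(ld - logsumexp(ld))
    mean = float((post * d_g).sum())
    sd = float(np.sqrt((post * (d_g - mean) ** 2).sum()))
    return mean, sd


class TestSettings:
    def test_retention_arithmetic_hierarchical(self):
        st_ = McmcSettings.reference_hierarchical()
        assert (st_.chains, st_.retained_per_chain) == (3, 4500)

    def test_retention_arithmetic_nonhierarchical(self):
        st_ = McmcSettings.reference_nonhierarchical()
        assert (st_.chains, st_.retained_per_chain) == (3, 4500)

    @pytest.mark.parametrize("bad", [
        dict(chains=1), dict(iterations=100, burn_in=100),
        dict(thin=0), dict(iterations=103, burn_in=100, thin=2),
    ])
    def test_invalid_settings_rejected(self, bad):
        with pytest.raises(ValueError):
            McmcSettings(**bad)


class TestRhat:
    def test_identical_halves_give_unity(self):
        rng = np.random.default_rng(0)
        stream = rng.normal(size=4000)
        chains = np.stack([stream, stream])
        assert split_rhat(chains) == pytest.approx(1.0, abs=0.01)

    def test_separated_chains_flagged(self):
        """Direct evaluation: chains at 0 and 10 with unit variance."""
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)])
        assert split_rhat(chains) > 5.0

    def test_matches_arviz(self):
        import arviz
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(3, 500)) + np.array([[0.0], [0.1], [0.3]])
        ours = split_rhat(chains)
        theirs = float(arviz.rhat(chains[None, ...].transpose(1, 2, 0)[:, :, 0]))
        assert ours == pytest.approx(theirs, abs=0.02)

    def test_converged_is_conjunction(self):
        settings = McmcSettings(chains=2, iterations=20, burn_in=0, thin=1)
        good = np.random.default_rng(3).normal(size=(2, 20))
        bad = np.stack([good[0], good[1] + 50])
        draws = PosteriorDraws(params={"a": good, "b": bad}, settings=settings)
        report = compute_rhat(draws)
        assert report.rhat["a"] < 1.1 < report.rhat["b"]
        assert not report.converged

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            split_rhat(np.zeros((1, 100)))


class TestPosteriorPoint:
    def test_constant_and_arithmetic(self):
        settings = McmcSettings(chains=2, iterations=6, burn_in=0, thin=1)
        draws = PosteriorDraws(params={
            "c": np.full((2, 2), 3.3), "x": np.array([[1.0, 2.0], [3.0, 4.0]])},
            settings=settings)
        assert posterior_point(draws, "c", "mean") == pytest.approx(3.3)
        assert posterior_point(draws, "c", "median") == pytest.approx(3.3)
        assert posterior_point(draws, "x", "mean") == pytest.approx(2.5)
        assert posterior_point(draws, "x", "median") == pytest.approx(2.5)

    def test_agrees_with_independent_quantile(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(3, 101))
        settings = McmcSettings(chains=3, iterations=101, burn_in=0, thin=1)
        draws = PosteriorDraws(params={"x": a}, settings=settings)
        assert posterior_point(draws, "x", "median") == pytest.approx(
            np.percentile(a.ravel(), 50))

    def test_unknown_parameter(self):
        settings = McmcSettings(chains=2, iterations=4, burn_in=0, thin=1)
        draws = PosteriorDraws(params={"a": np.zeros((2, 4))}, settings=settings)
        with pytest.raises(KeyError):
            posterior_point(draws, "zz", "mean")


class TestNonHierarchicalPosterior:
    def test_matches_grid_integration_oracle(self):
        """Posterior mean/SD of delta within 0.02 of dense grid integration."""
        mean, sd = grid_oracle_nonhier(TOY_MEANS)
        assert mean == pytest.approx(TOY_DELTA_MEAN_ORACLE, abs=0.005)
        assert sd == pytest.approx(TOY_DELTA_SD_ORACLE, abs=0.005)
        draws, _ = fit_nonhierarchical(TOY_MEANS, McmcSettings.reference_nonhierarchical(11))
        d = draws.pooled("delta")
        assert d.mean() == pytest.approx(mean, abs=0.02)
        assert d.std() == pytest.approx(sd, abs=0.02)

    def test_identical_groups_center_delta_at_zero(self):
        rng = np.random.default_rng(5)
        g = 6.5 + 0.2 * rng.normal(size=25)
        draws, _ = fit_nonhierarchical(np.stack([g, g]), McmcSettings.desk(3))
        d = draws.pooled("delta")
        assert abs(d.mean()) < 2 * d.std()

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_nonhierarchical(np.zeros((2, 1)), McmcSettings.desk())


@pytest.fixture(scope="module")
def hier_fit():
    cfg = GeneratingConfig(delta=0.5, N=8, K=5, seed=21)
    rng = np.random.default_rng(21)
    truth = sample_truth(cfg, rng)
    data = sample_trials(truth, cfg.K, rng, config=cfg)
    return fit_hierarchical(data, McmcSettings.desk(22))


class TestPosteriorInvariants:

    def test_mu2_identity_drawwise(self, hier_fit):
        draws, _ = hier_fit
        mu2 = draws.params["mu1"] + draws.params["delta"] * draws.params["tau"]
        assert np.allclose(draws.params["mu2"], mu2, atol=1e-10)

    def test_draws_respect_prior_supports(self, hier_fit):
        draws, _ = hier_fit
        assert np.all((draws.pooled("tau") > 0) & (draws.pooled("tau") < 15))
        assert np.all((draws.pooled("lam") > 0) & (draws.pooled("lam") < 10))
        assert np.all(draws.pooled("mu1") >= 0)
        assert np.all(draws.pooled("sigma2") > 0)

    def test_retained_draw_counts(self, hier_fit):
        draws, report = hier_fit
        st_ = draws.settings
        assert draws.params["delta"].shape == (st_.chains, st_.retained_per_chain)
        assert report.converged


def _sbc_ranks(fit_kind: str, n_reps: int, seed: int, L: int = 63):
    """SBC rank statistics for each group-level parameter."""
    names = ["mu1", "tau", "lam", "delta"] if fit_kind == "hier" else \
        ["mu1", "tau", "delta"]
    ranks = {p: [] for p in names}
    root = np.random.SeedSequence(seed)
    for ss in root.spawn(n_reps):
        rng = np.random.default_rng(ss)
        true = {
            "mu1": stats.truncnorm.rvs(-18, np.inf, loc=6, scale=1 / 3, random_state=rng),
            "tau": rng.uniform(0, 15),
            "lam": rng.uniform(0, 10),
            "delta": rng.normal(),
        }
        cfg = GeneratingConfig(mu1=true["mu1"], delta=true["delta"],
                               tau=true["tau"], lam=true["lam"], N=5, K=5, seed=0)
        truth = sample_truth(cfg, rng)
        data = sample_trials(truth, cfg.K, rng, config=cfg)
        st_ = McmcSettings(chains=2, iterations=1500, burn_in=500, thin=1,
                           seed=int(ss.generate_state(1)[0] % 2**31))
        try:
            if fit_kind == "hier":
                draws, _ = fit_hierarchical(data, st_)
            else:
                # the non-hierarchical model is the true model for the means
                # when the means themselves are the observations
                y = rng.normal([[true["mu1"]], [true["mu1"] + true["delta"] * true["tau"]]],
                               true["tau"], size=(2, 5))
                draws, _ = fit_nonhierarchical(y, st_)
        except ConvergenceError:
            continue
        for p in names:
            pool = draws.pooled(p)
            sub = pool[np.linspace(0, pool.size - 1, L).astype(int)]
            ranks[p].append(int((sub < true[p]).sum()))
    return ranks, L


@pytest.mark.parametrize("fit_kind,seed", [("hier", 710), ("nonhier", 720)])
def test_simulation_based_calibration_uniform(fit_kind, seed):
    """SBC: posterior ranks of prior-drawn truths are uniform for both samplers."""
    ranks, L = _sbc_ranks(fit_kind, n_reps=200, seed=seed)
    for p, r in ranks.items():
        assert len(r) >= 150, f"too many discarded replicates for {p}"
        counts = np.histogram(r, bins=8, range=(0, L + 1))[0]
        _, pval = stats.chisquare(counts)
        assert pval > 0.01, f"SBC ranks non-uniform for {p} (p={pval:.4f})"


def test_overconfidence_nonhierarchical_posterior_narrower(null_cell_n30_k2):
    """Ignoring the hierarchy yields a too-peaked posterior for delta.

    At N=30, K=2 under the null, the mean posterior SD of the effect size
    under the participant-means model is smaller than under the full
    hierarchical model.
    """
    sd_h = np.mean(null_cell_n30_k2.delta_sd["hierarchical"])
    sd_nh = np.mean(null_cell_n30_k2.delta_sd["nonhierarchical"])
    assert sd_nh < sd_h
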