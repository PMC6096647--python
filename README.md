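# hierbias

Monte Carlo machinery for quantifying the statistical biases that arise
when **hierarchical (trials-within-participants) data** from a two-group
experiment are analysed by shortcut strategies — either *ignoring the
hierarchy* (testing participant sample means as if they were true means) or
taking a *two-step approach* (feeding participant-level point estimates
from a hierarchical Bayesian model into a follow-up frequentist test).

It is written for methodologists and cognitive modellers who want to
reproduce, probe, or extend these bias results, or to check a planned
analysis strategy against simulated data from a known truth.

## The model and the five strategies

Data are generated from a two-level normal hierarchy

    x_gij ~ N(theta_gi, sigma2_gi),   theta_gi ~ N(mu_g, tau^2),
    mu_2 = mu_1 + delta * tau,        sigma_gi ~ HalfNormal(lam),

with generating constants `mu1 = 6.52`, `tau = 0.16`, `lam = 0.29` and a
design grid `K, N in {2, 5, 15, 30}`, `delta in {0, 0.1, 0.5, 1}` (64
cells).  Each simulated dataset is analysed by

| tag  | strategy |
|------|----------|
| TR   | t test on the **true** participant means (simulation-only reference) |
| NF   | t test on participant **sample means** (ignores the hierarchy) |
| TF   | t test on **participant-level posterior medians** from the hierarchical Bayesian model (two-step) |
| HF   | t test on **group-level posterior medians** (`mu_g`, `tau`) from the hierarchical model |
| BFH / BFNH | Savage–Dickey Bayes factor `BF10 = p(delta=0|H1) / p(delta=0|x,H1)` under the hierarchical / non-hierarchical model |

All t tests are two-sided equal-n pooled tests,
`t = (mu2_hat - mu1_hat)/sqrt((tau2_1 + tau2_2)/N)` with `2N - 2` degrees
of freedom at `alpha = .05`.  Posterior sampling is a validated Gibbs
scheme (conjugate updates plus slice sampling and an interweaving update
for `tau`); see `docs/methods.md` for the full account.

## Worked example

```python
from hierbias import (DesignCell, GeneratingConfig, McmcSettings,
                      bf_bias_summary, run_cell)

# the cell where the biases peak: many participants, two trials each
summary = run_cell(
    DesignCell(K=2, N=30, delta=0.0, replicates=40),
    GeneratingConfig(seed=20250924),
    strategies=("TR", "NF", "TF", "HF", "BFH", "BFNH"),
    settings_hier=McmcSettings.desk(),
    settings_nonhier=McmcSettings.desk(),
)
print(summary.rejection_rates)
print(bf_bias_summary(summary)["median_difference"])
```

Output from this exact run:

```
{'TR': 0.025, 'NF': 0.05, 'TF': 0.325, 'HF': 0.1}
-0.376
```

Read: with a *true null* (`delta = 0`), the reference test on true means
and the sample-means test reject about 5% of the time as they should,
while the two-step test (TF) rejects 33% of the time — roughly six times
the nominal level — because shrinkage of the posterior medians has
collapsed the between-participant variance and inflated the t values; the
group-estimate test (HF) doubles the nominal rate.  The negative median
difference of absolute log Bayes factors says the non-hierarchical Bayes
factor claims systematically more evidence than the hierarchical one: the
overconfidence bias.  (With `sigma_mode="variance"`, which makes the
sampling variance about three times larger, the same cell gives TF ≈ 0.67
and HF ≈ 0.28.)

A command-line interface wraps the same machinery:

```bash
hierbias generate  --config study.yaml --out data/        # one dataset as CSV
hierbias run-study --config study.yaml --out results/     # grid + manifest
hierbias analyze   --data data/data.csv --strategy NF --out report.json
```

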