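"""Factorial Monte Carlo study over the (K, N, delta) design grid.

The study design crosses trials per participant ``K in {2, 5, 15, 30}``,
participants per group ``N in {2, 5, 15, 30}`` and standardized effect
``delta in {0, 0.1, 0.5, 1}`` — 64 cells, by default 200 replicate datasets
each.  Every replicate is generated from the hierarchical model with the
fixed generating constants and analysed by the requested strategies; the
hierarchical model is fitted at most once per replicate and its draws are
shared by the TF and HF t tests and the hierarchical Bayes factor.

Replicates whose MCMC fails the convergence policy are counted and excluded
from the affected summaries, never silently dropped.  The whole study is a
deterministic function of the root seed: replicate streams are spawned from
``SeedSequence(seed, spawn_key=(cell_index, replicate))``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .generate import GeneratingConfig, generate_dataset, participant_means
from .mcmc import ConvergenceError, McmcSettings, fit_hierarchical, fit_nonhierarchical
from .strategies import (ALPHA_DEFAULT, savage_dickey_bf10, strategy_hf,
                         strategy_nf, strategy_tf, strategy_true)

__all__ = [
    "DesignCell",
    "CellSummary",
    "StudyResult",
    "full_design",
    "run_cell",
    "run_design",
    "rejection_rate",
    "quantile_averaged_posterior",
    "bf_bias_summary",
]

DESIGN_K = (2, 5, 15, 30)
DESIGN_N = (2, 5, 15, 30)
DESIGN_DELTA = (0.0, 0.1, 0.5, 1.0)

FREQUENTIST_STRATEGIES = ("TR", "NF", "TF", "HF")
BAYES_STRATEGIES = ("BFH", "BFNH")
ALL_STRATEGIES = FREQUENTIST_STRATEGIES + BAYES_STRATEGIES

#: Evenly spaced probability grid used for quantile-averaged posteriors.
DEFAULT_PROB_GRID = np.linspace(0.01, 0.99, 99)


@dataclass(frozen=True)
class DesignCell:
    """One cell of the factorial design."""

    K: int
    N: int
    delta: float
    replicates: int = 200

    def __post_init__(self) -> None:
        if self.K < 1 or self.N < 2 or self.replicates < 1:
            raise ValueError("need K >= 1, N >= 2, replicates >= 1")


def full_design(replicates: int = 200) -> list:
    """The full 4 x 4 x 4 design grid (64 cells)."""
    return [DesignCell(K=K, N=N, delta=d, replicates=replicates)
            for K in DESIGN_K for N in DESIGN_N for d in DESIGN_DELTA]


@dataclass
class CellSummary:
    """Per-cell aggregates of strategy results.

    ``tests`` maps a t-test strategy tag to its per-replicate results;
    ``log_bf`` maps a model tag to per-replicate log Bayes factors, paired
    across models replicate by replicate.  ``delta_quantiles`` holds the
    across-replicate average of posterior sample quantiles of delta on
    ``prob_grid`` for each fitted Bayesian model.
    """

    cell: DesignCell
    n_requested: int
    n_converged: int
    n_failed: int
    tests: dict = field(default_factory=dict)
    log_bf: dict = field(default_factory=dict)
    delta_sd: dict = field(default_factory=dict)
    delta_quantiles: dict = field(default_factory=dict)
    prob_grid: Optional[np.ndarray] = None
    rows: list = field(default_factory=list)

    @property
    def rejection_rates(self) -> dict:
        return {tag: rejection_rate(res) for tag, res in self.tests.items() if res}

    def paired_log_bf(self) -> tuple:
        """(hierarchical, non-hierarchical) log BF lists, paired per replicate."""
        h = self.log_bf.get("hierarchical", [])
        nh = self.log_bf.get("nonhierarchical", [])
        if len(h) != len(nh):
            raise ValueError("Bayes-factor lists are not paired")
        return np.asarray(h), np.asarray(nh)


def rejection_rate(results: Sequence) -> float:
    """Fraction of (converged) test results that rejected the null."""
    results = list(results)
    if not results:
        raise ValueError("no results to aggregate")
    return sum(r.reject for r in results) / len(results)


def quantile_averaged_posterior(draw_sets: Sequence, probability_grid=DEFAULT_PROB_GRID) -> np.ndarray:
    """Average, across replicates, of matched sample quantiles.

    For each probability ``p`` in the grid, returns the mean over draw sets
    of that set's ``p``-th sample quantile — an increasing curve that acts as
    the quantile function of the "typical" posterior across replications.
    """
    grid = np.asarray(probability_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(grid <= 0) or np.any(grid >= 1) \
            or np.any(np.diff(grid) <= 0):
        raise ValueError("probability grid must be strictly increasing within (0, 1)")
    draw_sets = list(draw_sets)
    if not draw_sets:
        raise ValueError("need at least one draw set")
    q = np.stack([np.quantile(np.asarray(d, dtype=float).ravel(), grid)
                  for d in draw_sets])
    return q.mean(axis=0)


def bf_bias_summary(summary: CellSummary) -> dict:
    """Per-replicate differences of absolute log Bayes factors, H minus NH.

    Negative differences mean the non-hierarchical model claims *more*
    evidence (in whichever direction) than the hierarchical model — the
    overconfidence signature.
    """
    h, nh = summary.paired_log_bf()
    diff = np.abs(h) - np.abs(nh)
    return {
        "differences": diff,
        "median_difference": float(np.median(diff)) if diff.size else float("nan"),
        "median_log_bf_h": float(np.median(h)) if h.size else float("nan"),
        "median_log_bf_nh": float(np.median(nh)) if nh.size else float("nan"),
    }


def _derived_seed(root_seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(root_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def run_cell(cell: DesignCell, generating: GeneratingConfig,
             strategies: Iterable = ALL_STRATEGIES,
             settings_hier: Optional[McmcSettings] = None,
             settings_nonhier: Optional[McmcSettings] = None,
             alpha: float = ALPHA_DEFAULT, cell_index: int = 0,
             density_method: str = "logspline",
             collect_quantiles: bool = False) -> CellSummary:
    """Run every requested strategy over all replicates of one design cell.

    ``generating`` supplies the truth constants and root seed; the cell's
    ``N``, ``K`` and ``delta`` override its dimensions replicate by
    replicate.  MCMC models are fitted only when a requested strategy needs
    them, each at most once per replicate.
    """
    strategies = tuple(strategies)
    if not strategies:
        raise ValueError("strategies must be nonempty")
    unknown = set(strategies) - set(ALL_STRATEGIES)
    if unknown:
        raise ValueError(f"unknown strategies: {sorted(unknown)}")
    need_hier = bool({"TF", "HF", "BFH"} & set(strategies))
    need_nonhier = "BFNH" in strategies
    if settings_hier is None:
        settings_hier = McmcSettings.desk()
    if settings_nonhier is None:
        settings_nonhier = McmcSettings.reference_nonhierarchical()

    tests = {tag: [] for tag in strategies if tag in FREQUENTIST_STRATEGIES}
    log_bf = {}
    if "BFH" in strategies:
        log_bf["hierarchical"] = []
    if "BFNH" in strategies:
        log_bf["nonhierarchical"] = []
    qsum = {}
    delta_sd = {}
    n_failed = 0
    rows = []

    for rep in range(cell.replicates):
        config = generating.with_cell(N=cell.N, K=cell.K, delta=cell.delta)
        truth, data = generate_dataset(config, spawn_key=(cell_index, rep))
        means = participant_means(data)

        hier = nonhier = None
        try:
            if need_hier:
                st = dataclass_replace_seed(settings_hier,
                                            _derived_seed(config.seed, cell_index, rep, 1))
                hier, _ = fit_hierarchical(data, st)
            if need_nonhier:
                st = dataclass_replace_seed(settings_nonhier,
                                            _derived_seed(config.seed, cell_index, rep, 2))
                nonhier, _ = fit_nonhierarchical(means, st)
        except ConvergenceError:
            n_failed += 1
            continue

        rep_results = []
        if "TR" in tests:
            rep_results.append(strategy_true(truth, alpha))
        if "NF" in tests:
            rep_results.append(strategy_nf(data, alpha))
        if "TF" in tests:
            rep_results.append(strategy_tf(hier, alpha))
        if "HF" in tests:
            rep_results.append(strategy_hf(hier, cell.N, alpha))
        for res in rep_results:
            tests[res.strategy_tag].append(res)
            rows.append({"K": cell.K, "N": cell.N, "delta": cell.delta,
                         "replicate": rep, "strategy": res.strategy_tag,
                         "t": res.t, "df": res.df, "p": res.p,
                         "reject": res.reject, "log_bf10": np.nan})
        for tag, fit, model in (("BFH", hier, "hierarchical"),
                                ("BFNH", nonhier, "nonhierarchical")):
            if tag in strategies:
                pooled_delta = fit.pooled("delta")
                bf = savage_dickey_bf10(pooled_delta, model_tag=model,
                                        method=density_method)
                log_bf[model].append(bf.log_bf10)
                delta_sd.setdefault(model, []).append(float(pooled_delta.std(ddof=1)))
                rows.append({"K": cell.K, "N": cell.N, "delta": cell.delta,
                             "replicate": rep, "strategy": tag,
                             "t": np.nan, "df": np.nan, "p": np.nan,
                             "reject": np.nan, "log_bf10": bf.log_bf10})
                if collect_quantiles:
                    q = np.quantile(fit.pooled("delta"), DEFAULT_PROB_GRID)
                    qsum.setdefault(model, []).append(q)

    delta_quantiles = {m: np.mean(np.stack(qs), axis=0) for m, qs in qsum.items()}
    return CellSummary(cell=cell, n_requested=cell.replicates,
                       n_converged=cell.replicates - n_failed, n_failed=n_failed,
                       tests=tests, log_bf=log_bf, delta_sd=delta_sd,
                       delta_quantiles=delta_quantiles,
                       prob_grid=DEFAULT_PROB_GRID if collect_quantiles else None,
                       rows=rows)


def dataclass_replace_seed(settings: McmcSettings, seed: int) -> McmcSettings:
    from dataclasses import replace
    return replace(settings, seed=seed)


@dataclass
class StudyResult:
    """Results of a full design run plus the information to reproduce it."""

    summaries: list
    root_seed: int
    generating: GeneratingConfig
    settings_hier: Optional[McmcSettings]
    settings_nonhier: Optional[McmcSettings]
    strategies: tuple

    def cell_frame(self) -> pd.DataFrame:
        """One summary row per cell: rejection rates, BF medians, counts."""
        rows = []
        for summ in self.summaries:
            row = {"K": summ.cell.K, "N": summ.cell.N, "delta": summ.cell.delta,
                   "replicates": summ.n_requested, "converged": summ.n_converged,
                   "failed": summ.n_failed}
            for tag, rate in summ.rejection_rates.items():
                row[f"reject_rate_{tag}"] = rate
            for model, bfs in summ.log_bf.items():
                if bfs:
                    row[f"median_log_bf_{model}"] = float(np.median(bfs))
            rows.append(row)
        return pd.DataFrame(rows)

    def replicate_frame(self) -> pd.DataFrame:
        """Tidy per-replicate rows across all cells and strategies."""
        return pd.DataFrame([r for s in self.summaries for r in s.rows])

    def manifest(self) -> dict:
        cfg = {
            "generating": self.generating.to_dict(),
            "strategies": list(self.strategies),
            "settings_hier": None if self.settings_hier is None else vars(self.settings_hier),
            "settings_nonhier": None if self.settings_nonhier is None else vars(self.settings_nonhier),
            "design": [{"K": s.cell.K, "N": s.cell.N, "delta": s.cell.delta,
                        "replicates": s.cell.replicates} for s in self.summaries],
        }
        blob = json.dumps(cfg, sort_keys=True).encode()
        return {
            "config_hash": hashlib.sha256(blob).hexdigest(),
            "root_seed": int(self.root_seed),
            "cell_seed_scheme": "SeedSequence(root, spawn_key=(cell_index, replicate))",
            "cells": [{"cell_index": i, "K": s.cell.K, "N": s.cell.N,
                       "delta": s.cell.delta, "replicates": s.cell.replicates,
                       "failed": s.n_failed} for i, s in enumerate(self.summaries)],
            "config": cfg,
        }


def run_design(design: Sequence, generating: GeneratingConfig,
               strategies: Iterable = ALL_STRATEGIES,
               settings_hier: Optional[McmcSettings] = None,
               settings_nonhier: Optional[McmcSettings] = None,
               alpha: float = ALPHA_DEFAULT, density_method: str = "logspline",
               collect_quantiles: bool = False,
               progress: Optional[callable] = None) -> StudyResult:
    """Run every cell of a design; deterministic given the generating seed."""
    design = list(design)
    if not design:
        raise ValueError("design must contain at least one cell")
    summaries = []
    for idx, cell in enumerate(design):
        summ = run_cell(cell, generating, strategies=strategies,
                        settings_hier=settings_hier,
                        settings_nonhier=settings_nonhier, alpha=alpha,
                        cell_index=idx, density_method=density_method,
                        collect_quantiles=collect_quantiles)
        if progress is not None:
            progress(idx, cell, summ)
        summaries.append(summ)
    return StudyResult(summaries=summaries, root_seed=generating.seed,
                       generating=generating, settings_hier=settings_hier,
                       settings_nonhier=settings_nonhier,
                       strategies=tuple(strategies))
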