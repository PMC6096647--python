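"""Shared fixtures.

The bias phenomena under study are strongest at many participants and few
trials (N = 30, K = 2), so the replicated MCMC runs for that cell are
computed once per session and shared by the tests that examine two-step
inflation, group-estimate conservatism/inflation, Bayes-factor bias and
posterior overconfidence.
"""

import numpy as np
import pytest

from hierbias import (DesignCell, GeneratingConfig, McmcSettings, run_cell)

#: Replicates for the shared MCMC cells: enough for direction and magnitude
#: checks at a few percent Monte Carlo error, small enough for a desk run.
N_REPS_MCMC = 150

DESK = McmcSettings.desk()


@pytest.fixture(scope="session")
def null_cell_n30_k2():
    """All six strategies at N=30, K=2, delta=0 (the worst-case null cell)."""
    return run_cell(DesignCell(K=2, N=30, delta=0.0, replicates=N_REPS_MCMC),
                    GeneratingConfig(seed=60301), strategies=("TR", "NF", "TF", "HF", "BFH", "BFNH"),
                    settings_hier=DESK, settings_nonhier=DESK, cell_index=0)


@pytest.fixture(scope="session")
def alt_cell_n30_k2():
    """Both Bayes factors at N=30, K=2, delta=1 (the worst-case effect cell)."""
    return run_cell(DesignCell(K=2, N=30, delta=1.0, replicates=N_REPS_MCMC),
                    GeneratingConfig(seed=60302), strategies=("BFH", "BFNH"),
                    settings_hier=DESK, settings_nonhier=DESK, cell_index=1)


@pytest.fixture(scope="session")
def hf_cell_n2():
    """Group-estimate t test at N=2, delta=0, K=2 (small-sample conservatism)."""
    return run_cell(DesignCell(K=2, N=2, delta=0.0, replicates=100),
                    GeneratingConfig(seed=60303), strategies=("HF",),
                    settings_hier=DESK, cell_index=2)
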