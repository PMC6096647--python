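"""Synthetic data from the two-group hierarchical normal generating model.

The generating model mirrors a two-group experiment with ``K`` repeated
measurements for each of ``N`` participants per group:

* trial level:        ``x_gij ~ N(theta_gi, sigma2_gi)``
* participant level:  ``theta_gi ~ N(mu_g, tau^2)`` with ``mu2 = mu1 + delta*tau``
* participant variances: a half-normal draw with scale ``lam`` (the absolute
  value of a ``N(0, lam^2)`` draw) supplies the participant's trial SD
  (default) or, via the ``sigma_mode`` switch, the variance itself

The default generating constants (``mu1 = 6.52``, ``tau = 0.16``,
``lam = 0.29``) describe a realistic response-time-like experiment and are
the fixed truth for the whole Monte Carlo study; ``delta`` is the
standardized group difference being tested.

All randomness flows through :class:`numpy.random.SeedSequence` so that any
replicate of any design cell can be regenerated bit-identically from the root
seed alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GeneratingConfig",
    "ParticipantTruth",
    "TrialData",
    "sample_truth",
    "sample_trials",
    "generate_dataset",
    "participant_means",
    "trial_frame",
    "truth_frame",
    "data_from_frame",
]

#: Generating constants for the study (group-1 mean, group-level SD,
#: half-normal scale of the participant-variance distribution).
MU1_DEFAULT = 6.52
TAU_DEFAULT = 0.16
LAM_DEFAULT = 0.29


@dataclass(frozen=True)
class GeneratingConfig:
    """Ground-truth parameters and dimensions for one simulated experiment.

    ``sigma_mode`` selects what the half-normal draw is interpreted as:
    ``"sd"`` (default) draws the participant's trial standard deviation and
    squares it; ``"variance"`` draws the trial variance ``sigma2_gi``
    directly.
    """

    mu1: float = MU1_DEFAULT
    delta: float = 0.0
    tau: float = TAU_DEFAULT
    lam: float = LAM_DEFAULT
    N: int = 15
    K: int = 15
    seed: int = 0
    sigma_mode: str = "sd"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.lam <= 0:
            raise ValueError(f"lam must be > 0, got {self.lam}")
        if int(self.N) != self.N or self.N < 2:
            raise ValueError(f"N must be an integer >= 2, got {self.N}")
        if int(self.K) != self.K or self.K < 1:
            raise ValueError(f"K must be an integer >= 1, got {self.K}")
        if self.sigma_mode not in ("variance", "sd"):
            raise ValueError(f"sigma_mode must be 'variance' or 'sd', got {self.sigma_mode!r}")

    @property
    def mu2(self) -> float:
        """Group-2 mean, always derived as ``mu1 + delta * tau``."""
        return self.mu1 + self.delta * self.tau

    def with_cell(self, *, N: int, K: int, delta: float, seed: Optional[int] = None) -> "GeneratingConfig":
        """Copy of this config with a design cell's dimensions and effect."""
        return replace(self, N=N, K=K, delta=delta, seed=self.seed if seed is None else seed)

    def to_dict(self) -> dict:
        return {
            "mu1": self.mu1, "delta": self.delta, "tau": self.tau, "lam": self.lam,
            "N": int(self.N), "K": int(self.K), "seed": int(self.seed),
            "sigma_mode": self.sigma_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratingConfig":
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GeneratingConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class ParticipantTruth:
    """Latent participant-level truth: true means and trial variances.

    ``theta`` and ``sigma2`` are ``(2, N)`` arrays indexed by (group,
    participant); all ``sigma2`` entries are strictly positive.
    """

    theta: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        sigma2 = np.asarray(self.sigma2, dtype=float)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "sigma2", sigma2)
        if theta.ndim != 2 or theta.shape[0] != 2 or theta.shape != sigma2.shape:
            raise ValueError("theta and sigma2 must both have shape (2, N)")
        if not np.all(sigma2 > 0):
            raise ValueError("all participant variances must be > 0")

    @property
    def N(self) -> int:
        return self.theta.shape[1]


@dataclass(frozen=True)
class TrialData:
    """Observed trials ``x`` with shape ``(2, N, K)`` plus provenance."""

    x: np.ndarray
    config: Optional[GeneratingConfig] = None
    truth: Optional[ParticipantTruth] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if x.ndim != 3 or x.shape[0] != 2:
            raise ValueError("x must have shape (2, N, K)")
        if not np.all(np.isfinite(x)):
            raise ValueError("trial values must be finite")

    @property
    def N(self) -> int:
        return self.x.shape[1]

    @property
    def K(self) -> int:
        return self.x.shape[2]


def sample_truth(config: GeneratingConfig, rng: np.random.Generator) -> ParticipantTruth:
    """Draw participant-level truth for both groups.

    ``theta_gi ~ N(mu_g, tau^2)`` with ``mu2 = mu1 + delta*tau``; the
    participant trial variances come from a half-normal with scale ``lam``
    (interpreted per ``config.sigma_mode``).  Exact zero draws (a
    measure-zero event) are redrawn so every participant has a proper trial
    likelihood.
    """
    mus = np.array([config.mu1, config.mu2])
    theta = rng.normal(loc=mus[:, None], scale=config.tau, size=(2, config.N))
    half = np.abs(rng.normal(0.0, config.lam, size=(2, config.N)))
    while np.any(half == 0.0):  # pragma: no cover - measure-zero redraw
        idx = half == 0.0
        half[idx] = np.abs(rng.normal(0.0, config.lam, size=int(idx.sum())))
    sigma2 = half if config.sigma_mode == "variance" else half**2
    return ParticipantTruth(theta=theta, sigma2=sigma2)


def sample_trials(truth: ParticipantTruth, K: int, rng: np.random.Generator,
                  config: Optional[GeneratingConfig] = None) -> TrialData:
    """Draw ``K`` i.i.d. trials per participant: ``x_gij ~ N(theta_gi, sigma2_gi)``."""
    if int(K) != K or K < 1:
        raise ValueError(f"K must be an integer >= 1, got {K}")
    sd = np.sqrt(truth.sigma2)
    x = rng.normal(loc=truth.theta[..., None], scale=sd[..., None],
                   size=(2, truth.N, int(K)))
    return TrialData(x=x, config=config, truth=truth)


def generate_dataset(config: GeneratingConfig,
                     spawn_key: tuple = ()) -> tuple[ParticipantTruth, TrialData]:
    """Generate one complete dataset; a pure function of (config, spawn_key).

    ``spawn_key`` lets a harness derive independent streams per (cell,
    replicate) from one root seed without collisions.
    """
    ss = np.random.SeedSequence(config.seed, spawn_key=tuple(spawn_key))
    rng = np.random.default_rng(ss)
    truth = sample_truth(config, rng)
    data = sample_trials(truth, config.K, rng, config=config)
    return truth, data


def participant_means(data: TrialData) -> np.ndarray:
    """Participant sample means ``xbar_gi``: mean over the trial axis, shape (2, N)."""
    return data.x.mean(axis=2)


# ---------------------------------------------------------------------------
# long-format CSV interchange


def trial_frame(data: TrialData) -> pd.DataFrame:
    """Long-format table with columns group (1/2), participant, trial, value."""
    g, i, j = np.meshgrid(np.arange(2), np.arange(data.N), np.arange(data.K),
                          indexing="ij")
    return pd.DataFrame({
        "group": g.ravel() + 1,
        "participant": i.ravel() + 1,
        "trial": j.ravel() + 1,
        "value": data.x.ravel(),
    })


def truth_frame(truth: ParticipantTruth) -> pd.DataFrame:
    """Table of latent truth: group, participant, theta, sigma2."""
    g, i = np.meshgrid(np.arange(2), np.arange(truth.N), indexing="ij")
    return pd.DataFrame({
        "group": g.ravel() + 1,
        "participant": i.ravel() + 1,
        "theta": truth.theta.ravel(),
        "sigma2": truth.sigma2.ravel(),
    })


def data_from_frame(df: pd.DataFrame) -> TrialData:
    """Rebuild a balanced :class:`TrialData` from a long-format table.

    Requires columns group/participant/trial/value, groups coded 1 and 2,
    and a complete, balanced crossing of participants and trials.
    """
    required = {"group", "participant", "trial", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    if vals.isna().any():
        row = int(df.index[vals.isna()][0])
        raise ValueError(f"non-numeric value in row {row}")
    groups = sorted(df["group"].unique())
    if groups != [1, 2]:
        raise ValueError(f"group column must contain exactly {{1, 2}}, got {groups}")
    N = df["participant"].nunique()
    K = df["trial"].nunique()
    if len(df) != 2 * N * K:
        raise ValueError("table is not a balanced 2 x N x K design")
    pivot = df.assign(value=vals).sort_values(["group", "participant", "trial"])
    x = pivot["value"].to_numpy().reshape(2, N, K)
    return TrialData(x=x)
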