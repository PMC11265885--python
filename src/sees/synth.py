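"""Synthetic response generation and parameter-recovery experiments.

Responses are drawn from the same generative process the consensus model
assumes: item locations on a latent continuum, team-level scepticism
shifts, item-level dispersion and shared ordered thresholds, with an
independent chance per cell of a "not applicable" (missing) response.
The recovery harness simulates tables at a given number of teams, refits
the model, and scores how well the true item locations are recovered —
the design used to argue that roughly 40+ responding teams give precise
consensus estimates while 20 teams remain usable but noticeably less
precise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .instrument import Instrument, ResponseTable, SurveyItem
from .model import (
    FittedConsensus,
    ModelConfig,
    UnfitError,
    fit_consensus,
    summarize_consensus,
)

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "RecoveryReport",
    "draw_truth",
    "simulate_responses",
    "synthetic_instrument",
    "recovery_experiment",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic-data experiment.

    Defaults emulate a subjective-evidence-style subscale: 8 items rated
    by ``K`` teams on a 4-point scale. Truth distributions are chosen so
    that all four categories occur with non-trivial frequency:
    ``T ~ Normal(0, t_scale)``, ``log lambda ~ Normal(0, loglam_scale)``,
    ``beta ~ Normal(0, beta_scale)`` and fixed thresholds
    ``gamma = (-1.2, 0, 1.2)``. ``na_probability`` masks each cell
    missing-completely-at-random, mirroring the survey's
    "not applicable/I do not know" option.
    """

    K: int = 42
    items: int = 8
    C: int = 4
    t_scale: float = 1.0
    loglam_scale: float = 0.3
    beta_scale: float = 0.5
    gamma: tuple[float, ...] = (-1.2, 0.0, 1.2)
    na_probability: float = 0.1
    seed: int = 0
    replicates: int = 10

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if not 0 <= self.na_probability < 1:
            raise ValueError("na_probability must be in [0, 1)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.gamma) != self.C - 1 or np.any(np.diff(self.gamma) <= 0):
            raise ValueError("gamma must be strictly increasing, length C-1")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth parameters behind one simulated table."""

    T: np.ndarray
    lam: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.gamma) <= 0):
            raise ValueError("gamma must be strictly increasing")
        if np.any(self.lam <= 0):
            raise ValueError("lam must be positive")


def draw_truth(config: SimulationConfig,
               rng: np.random.Generator | None = None) -> TruthRecord:
    """Draw one set of generating parameters from the truth distributions."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = rng.normal(0.0, config.t_scale, size=config.items)
    lam = np.exp(rng.normal(0.0, config.loglam_scale, size=config.items))
    if config.beta_scale > 0:
        beta = rng.normal(0.0, config.beta_scale, size=config.K)
        beta -= beta.mean()      # matches the model's sum-to-zero convention
    else:
        beta = np.zeros(config.K)
    return TruthRecord(
        T=T, lam=lam, beta=beta,
        gamma=np.asarray(config.gamma, dtype=float),
        seed=config.seed,
    )


def simulate_responses(
    truth: TruthRecord,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> ResponseTable:
    """Simulate one teams x items ordinal table from the generative model.

    Each cell's latent appraisal is ``Normal(T_i, lambda_i)``; the response
    is the category of the appraisal relative to the team-shifted
    thresholds ``gamma + beta_k``, exactly the ordered-probit kernel of
    the consensus model. Cells are then masked missing independently with
    probability ``na_probability``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    K, I = config.K, config.items
    appraisal = rng.normal(truth.T[None, :], truth.lam[None, :], size=(K, I))
    # category = 1 + number of shifted thresholds below the appraisal
    shifted = truth.gamma[None, None, :] + truth.beta[:, None, None]
    codes = 1 + (appraisal[:, :, None] > shifted).sum(axis=2)
    values = codes.astype(float)
    if config.na_probability > 0:
        mask = rng.random((K, I)) < config.na_probability
        values[mask] = np.nan
    return ResponseTable(
        team_ids=[f"team_{k+1:03d}" for k in range(K)],
        item_ids=[f"SE_{i+1}" for i in range(I)],
        values=values,
        C=config.C,
        reversed_applied=True,
    )


def synthetic_instrument(config: SimulationConfig) -> Instrument:
    """A minimal instrument matching the simulated item ids (synthetic)."""
    labels = tuple(f"category {c}" for c in range(1, config.C + 1))
    items = tuple(
        SurveyItem(
            id=f"SE_{i+1}",
            subscale="subjective_evidence",
            label=f"Synthetic item {i+1}",
            text="synthetic item",
            example="",
            reverse_coded=False,
            allows_na=True,
            response_labels=labels,
        )
        for i in range(config.items)
    )
    return Instrument(items=items, C=config.C, name="synthetic")


@dataclass
class RecoveryReport:
    """Aggregated parameter-recovery metrics over simulation replicates."""

    config: SimulationConfig
    correlations: list[float] = field(default_factory=list)
    rmse: list[float] = field(default_factory=list)
    coverage: list[float] = field(default_factory=list)
    ci_width: list[float] = field(default_factory=list)
    max_rhat: list[float] = field(default_factory=list)
    failed: list[int] = field(default_factory=list)

    @property
    def n_ok(self) -> int:
        return len(self.correlations)

    @property
    def mean_correlation(self) -> float:
        return float(np.mean(self.correlations))

    @property
    def mean_rmse(self) -> float:
        return float(np.mean(self.rmse))

    @property
    def mean_coverage(self) -> float:
        return float(np.mean(self.coverage))

    @property
    def mean_ci_width(self) -> float:
        return float(np.mean(self.ci_width))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": [i for i in range(self.config.replicates)
                              if i not in self.failed],
                "correlation": self.correlations,
                "rmse": self.rmse,
                "coverage": self.coverage,
                "mean_ci_width": self.ci_width,
                "max_rhat": self.max_rhat,
            }
        )


def recovery_experiment(
    config: SimulationConfig,
    model_config: ModelConfig | None = None,
) -> RecoveryReport:
    """Run replicate simulate-and-refit experiments and score recovery.

    For each replicate: draw truth, simulate a table, fit the consensus
    model and compare the true item locations to their posteriors. The
    whole experiment is a pure function of ``config.seed`` (replicate
    streams are spawned from it); a failing replicate is recorded, not
    fatal.
    """
    model_config = model_config or ModelConfig(C=config.C)
    report = RecoveryReport(config=config)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.replicates)
    instrument = synthetic_instrument(config)
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        truth = draw_truth(replace(config, seed=rep_seed), rng)
        table = simulate_responses(truth, config, rng)
        try:
            fit = fit_consensus(
                table, instrument, "subjective_evidence",
                replace(model_config, seed=rep_seed),
            )
        except UnfitError:
            report.failed.append(rep)
            continue
        summ = summarize_consensus(fit, instrument)
        med = summ.item_median
        lo, hi = summ.item_ci[:, 0], summ.item_ci[:, 1]
        report.correlations.append(
            float(np.corrcoef(truth.T, med)[0, 1])
        )
        report.rmse.append(float(np.sqrt(np.mean((truth.T - med) ** 2))))
        report.coverage.append(
            float(np.mean((truth.T >= lo) & (truth.T <= hi)))
        )
        report.ci_width.append(float(np.mean(hi - lo)))
        report.max_rhat.append(fit.max_rhat)
    return report
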