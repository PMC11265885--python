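"""Belief-updating descriptives.

Compares each team's pre-analysis plausibility rating with the
post-analysis plausibility rating (both on the same 4-point scale):
how many teams became more or less convinced, what fraction agreed with
the hypothesis before versus after, and the plain descriptive statistics
(median, unscaled MAD, mean, sample SD) used for responder versus
non-responder comparisons of effect sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeliefRecord",
    "BeliefSummary",
    "classify_change",
    "agreement_rate",
    "summarize_beliefs",
    "group_descriptives",
    "read_belief_csv",
]


@dataclass(frozen=True)
class BeliefRecord:
    """One team's prior and final plausibility codes (1..C or None)."""

    team_id: str
    prior: int | None
    final: int | None


@dataclass(frozen=True)
class BeliefSummary:
    mean_prior: float
    mean_final: float
    pct_agree_prior: float
    pct_agree_final: float
    prop_increased: float
    prop_decreased: float
    prop_unchanged: float
    n_complete: int

    def to_dict(self) -> dict:
        return {
            "mean_prior": self.mean_prior,
            "mean_final": self.mean_final,
            "pct_agree_prior": self.pct_agree_prior,
            "pct_agree_final": self.pct_agree_final,
            "prop_increased": self.prop_increased,
            "prop_decreased": self.prop_decreased,
            "prop_unchanged": self.prop_unchanged,
            "n_complete": self.n_complete,
        }


def classify_change(prior: int, final: int) -> str:
    """Direction of the belief shift: increased / decreased / unchanged."""
    if prior is None or final is None:
        raise ValueError("classify_change requires both responses")
    diff = final - prior
    if diff > 0:
        return "increased"
    if diff < 0:
        return "decreased"
    return "unchanged"


def agreement_rate(responses: Sequence[float | None], C: int = 4) -> float:
    """Percentage of non-missing responses in the agreeing half of the scale.

    On the 4-point scale a team agrees with the hypothesis when it picks
    one of the top two categories ("yes, mostly" / "yes, definitely").
    Returned as a percentage rounded to two decimals.
    """
    if C != 4:
        raise ValueError("agreement_rate is defined for the 4-point scale")
    vals = np.asarray(
        [np.nan if r is None else float(r) for r in responses], dtype=float
    )
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("agreement rate undefined: all responses missing")
    return round(100.0 * float(np.mean(vals >= 3)), 2)


def summarize_beliefs(records: Iterable[BeliefRecord], C: int = 4) -> BeliefSummary:
    """Aggregate belief updating over teams.

    Means and agreement percentages use every non-missing response at the
    respective timepoint; the change-class proportions use only teams
    with both responses.
    """
    records = list(records)
    priors = [r.prior for r in records if r.prior is not None]
    finals = [r.final for r in records if r.final is not None]
    complete = [r for r in records if r.prior is not None and r.final is not None]
    if not complete:
        raise ValueError("need at least one record with both responses")
    classes = [classify_change(r.prior, r.final) for r in complete]
    n = len(complete)
    return BeliefSummary(
        mean_prior=float(np.mean(priors)),
        mean_final=float(np.mean(finals)),
        pct_agree_prior=agreement_rate(priors, C=C),
        pct_agree_final=agreement_rate(finals, C=C),
        prop_increased=classes.count("increased") / n,
        prop_decreased=classes.count("decreased") / n,
        prop_unchanged=classes.count("unchanged") / n,
        n_complete=n,
    )


def group_descriptives(values: Sequence[float]) -> dict:
    """Median, unscaled MAD, mean and sample SD of a numeric vector.

    MAD is ``median(|x - median(x)|)`` without the 1.4826 normal-
    consistency constant. For a single observation the sample SD is
    undefined; it is reported as 0.0 with ``sd_defined=False``.
    """
    x = np.asarray(list(values), dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("group_descriptives requires at least one finite value")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    out = {
        "median": med,
        "mad": mad,
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "n": int(x.size),
        "sd_defined": x.size > 1,
    }
    return out


def read_belief_csv(path, C: int = 4) -> list[BeliefRecord]:
    """Read a CSV with columns team_id, prior, final (codes or blanks)."""
    df = pd.read_csv(path)

    def _code(v):
        if pd.isna(v):
            return None
        f = float(v)
        if not f.is_integer() or not 1 <= f <= C:
            raise ValueError(f"belief code {v!r} outside 1..{C}")
        return int(f)

    return [
        BeliefRecord(str(row["team_id"]), _code(row["prior"]), _code(row["final"]))
        for _, row in df.iterrows()
    ]
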