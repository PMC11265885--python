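"""Delphi expert-panel item screening.

During instrument development an expert panel rates each candidate item
on a 9-point inclusion scale (1 = definitely not include, 9 = definitely
include). The preregistered screening rule keeps an item when the panel
median is at least 6 *and* the interquartile range is at most 2
(consensus). An item that clears the median bar but fails the IQR bar
can still be flagged for discussion when a large share of experts rate
it 7-9 ("high support"); the flag is advisory, never an automatic
include.

Quantile convention: the IQR uses linearly interpolated quantiles
(NumPy's default, the classic "type 7"). Boundary decisions such as
IQR <= 2 depend on this choice, so it is recorded on every decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DelphiDecision", "delphi_screen", "QUANTILE_METHOD"]

QUANTILE_METHOD = "linear"  # numpy 'linear' == quantile type 7


@dataclass(frozen=True)
class DelphiDecision:
    item_id: str
    median: float
    iqr: float
    pct_high: float
    decision: str           # include | exclude | high_support_flag
    quantile_method: str = QUANTILE_METHOD


def delphi_screen(
    ratings: pd.DataFrame | np.ndarray,
    high_support_cutoff: float = 70.0,
) -> list[DelphiDecision]:
    """Apply the screening rule to an experts x items rating table.

    ``ratings`` holds integer scores 1..9, one column per item (a plain
    array gets positional item names). Rule: include iff median >= 6 and
    IQR <= 2; otherwise, if median >= 6 and at least
    ``high_support_cutoff`` percent of the ratings fall in 7-9, flag the
    item as high-support for the discussion round; otherwise exclude.
    """
    if isinstance(ratings, np.ndarray):
        ratings = pd.DataFrame(
            ratings, columns=[f"item_{j+1}" for j in range(ratings.shape[1])]
        )
    if len(ratings) < 2:
        raise ValueError("need ratings from at least 2 experts")
    decisions: list[DelphiDecision] = []
    for col in ratings.columns:
        x = ratings[col].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 2:
            raise ValueError(f"item {col!r}: fewer than 2 ratings")
        if np.any((x < 1) | (x > 9) | (x != np.round(x))):
            raise ValueError(f"item {col!r}: ratings must be integers in 1..9")
        med = float(np.median(x))
        q1, q3 = np.percentile(x, [25, 75], method=QUANTILE_METHOD)
        iqr = float(q3 - q1)
        pct_high = 100.0 * float(np.mean(x >= 7))
        if med >= 6 and iqr <= 2:
            decision = "include"
        elif med >= 6 and pct_high >= high_support_cutoff:
            decision = "high_support_flag"
        else:
            decision = "exclude"
        decisions.append(
            DelphiDecision(
                item_id=str(col),
                median=med,
                iqr=iqr,
                pct_high=pct_high,
                decision=decision,
            )
        )
    return decisions
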