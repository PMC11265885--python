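"""End-to-end analysis pipeline for a deposited pilot dataset.

Reproduces the full survey analysis on an externally obtained dataset —
the intended use case is the 42-team pilot of the Many-Analysts Religion
Project deposited on OSF (project ``jk674``), which is *not* shipped with
this package and must be downloaded separately.

Expected layout of ``data_dir`` (plain CSV, see ``docs/methods.md``):

* ``responses.csv`` — wide response table: first column ``team_id``, one
  column per scored item (``SE_1..SE_8``, ``MA_1..MA_10``) holding Likert
  labels or integer codes; NA label or blank for not applicable.
* ``beliefs.csv`` — columns ``team_id, prior, final`` with plausibility
  codes 1..4.
* ``effect_sizes.csv`` — columns ``team_id, effect_size`` with each
  team's reported standardized effect size.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .bayescorr import pearson_bf, spearman_bf
from .beliefs import group_descriptives, read_belief_csv, summarize_beliefs
from .instrument import load_instrument, read_response_csv
from .model import ModelConfig, fit_consensus, summarize_consensus

__all__ = ["reproduce_pilot_analysis"]


def reproduce_pilot_analysis(
    data_dir: str | Path,
    model_config: ModelConfig | None = None,
    seed: int = 0,
) -> dict:
    """Run the complete pilot analysis and return all headline quantities.

    Fits the consensus model per subscale, summarizes belief updating,
    and computes the three directional correlation tests (prior beliefs
    vs effect size and final beliefs vs effect size, both rank-based and
    tested for a positive relation; estimated scepticism vs effect size,
    Pearson and tested for a negative relation).
    """
    data_dir = Path(data_dir)
    for fname in ("responses.csv", "beliefs.csv", "effect_sizes.csv"):
        if not (data_dir / fname).exists():
            raise FileNotFoundError(
                f"pilot data file {data_dir / fname} not found; the pilot "
                "dataset is an external deposit and is not packaged"
            )
    instrument = load_instrument()
    table = read_response_csv(data_dir / "responses.csv", instrument)
    cfg = model_config or ModelConfig(C=instrument.C, seed=seed)

    results: dict = {"n_teams": table.n_teams}
    fits = {}
    for subscale, key in (
        ("subjective_evidence", "se"),
        ("methodological_appropriateness", "ma"),
    ):
        fit = fit_consensus(table, instrument, subscale, cfg)
        summ = summarize_consensus(fit, instrument)
        fits[key] = fit
        results[f"{key}_overall_median"] = summ.overall_median
        results[f"{key}_overall_ci"] = summ.overall_ci
        results[f"{key}_sd_across_items"] = summ.sd_across_items
        results[f"{key}_labels"] = summ.labels

    records = read_belief_csv(data_dir / "beliefs.csv", C=instrument.C)
    bs = summarize_beliefs(records)
    results["beliefs"] = bs.to_dict()

    es = pd.read_csv(data_dir / "effect_sizes.csv")
    es["team_id"] = es["team_id"].astype(str)
    es = es.set_index("team_id")["effect_size"]
    results["effect_size_descriptives"] = group_descriptives(es.to_numpy())

    by_team = {r.team_id: r for r in records}
    teams = [t for t in es.index if t in by_team]
    eff = es.loc[teams].to_numpy(dtype=float)
    prior = np.array(
        [np.nan if by_team[t].prior is None else by_team[t].prior for t in teams]
    )
    final = np.array(
        [np.nan if by_team[t].final is None else by_team[t].final for t in teams]
    )
    results["corr_prior_effect"] = spearman_bf(
        prior, eff, direction="positive", seed=seed
    ).to_dict()
    results["corr_final_effect"] = spearman_bf(
        final, eff, direction="positive", seed=seed + 1
    ).to_dict()

    scept = fits["se"]
    beta_by_team = dict(
        zip(scept.team_ids, np.median(scept.beta, axis=0))
    )
    common = [t for t in es.index if t in beta_by_team]
    results["corr_scepticism_effect"] = pearson_bf(
        np.array([beta_by_team[t] for t in common]),
        es.loc[common].to_numpy(dtype=float),
        direction="negative",
    ).to_dict()
    return results
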