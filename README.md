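# sees — Subjective Evidence Evaluation Survey toolkit

In a many-analysts study, dozens of independent teams analyse the same
dataset and research question, and the project is usually summarised by
the spread of a single outcome metric (an effect size per team). That
summary misses how the teams themselves judge the evidence: whether they
found the hypothesis plausible, whether their result was robust, and
whether they trust the study's design and data at all. The Subjective
Evidence Evaluation Survey (SEES) is an 18-item instrument — an
8-item *subjective evidence* subscale and a 10-item *methodological
appropriateness* subscale, plus a pre-analysis prior-plausibility item —
that each analysis team fills out once, on a 4-point Likert scale with a
"not applicable/I do not know" option.

This package is for project leaders of many-analysts studies. It ships
the SEES as a machine-readable instrument and implements the full
analysis pipeline for its responses:

* **Instrument & ingestion** (`sees.instrument`) — the packaged SEES
  schema, label recoding (counter-indicative items SE_4–SE_7 are
  reverse-coded as `x → C+1−x`), NA handling and validation reports.
* **Consensus model** (`sees.model`) — a Bayesian cultural-consensus
  (latent truth rater) model for ordinal responses. Each item *i* has a
  latent consensus location `T_i`, each team *k* a scepticism shift
  `β_k`, each item a dispersion ("difficulty") `λ_i`, and the subscale
  shares ordered category thresholds `γ_1 < … < γ_{C−1}`:

  `P(X_ki = c) = Φ((γ_c + β_k − T_i)/λ_i) − Φ((γ_{c−1} + β_k − T_i)/λ_i)`

  with a hierarchical prior `T_i ~ Normal(μ_s, σ_s)` per subscale.
  Posteriors are sampled by ensemble MCMC; summaries report per-item and
  overall consensus with 95% credible intervals, interpreted against the
  category thresholds.
* **Simulation & recovery** (`sees.synth`) — generate synthetic response
  tables from the same generative model and run simulate-and-refit
  recovery studies (e.g. 42 versus 20 teams).
* **Belief updating** (`sees.beliefs`) — prior-versus-final plausibility:
  means, agreement percentages, increased/decreased/unchanged shares.
* **Correlations** (`sees.bayescorr`) — Bayesian Pearson and rank-based
  Spearman correlations with directional Bayes factors (`BF_+0`,
  `BF_0+`) under a stretched-beta prior on the correlation.
* **Delphi screening** (`sees.delphi`) — the preregistered expert-panel
  rule: include an item iff its median rating ≥ 6 and IQR ≤ 2, with a
  high-support flag for discussion-round overrides.

## Worked example

Simulate a 42-team survey and fit the subjective-evidence consensus:

```bash
sees simulate --teams 42 --items 8 --seed 11 --outdir sim
sees fit --responses sim/responses.csv --subscale subjective_evidence \
         --outdir fit --seed 11
```

`fit/summary_subjective_evidence.csv` then starts:

```
item_id,consensus_median,ci_lower,ci_upper,difficulty_median,label
SE_1,-0.2573,-0.5575,0.0189,0.9547,"no, mostly not"
SE_2,1.8744,1.3727,2.5512,0.9672,"yes, definitely"
SE_3,1.4297,0.8147,2.2787,1.9963,"yes, definitely"
```

and `fit/overall_subjective_evidence.json` reports the overall subscale
consensus (the posterior of the per-draw mean of the item locations)

```
overall_median 0.358   95% CI [0.217, 0.538]   sd_across_items 0.857
thresholds [-1.128, -0.051, 1.179]
```

Reading: each `consensus_median` is the teams' collective answer for
that item on the latent continuum; it only has meaning relative to the
thresholds, so SE_1's −0.26 falls between γ_1 = −1.13 and γ_2 = −0.05
("no, mostly not"), while the overall 0.36 [0.22, 0.54] sits in the
"yes, mostly" band — the panel as a whole mostly endorses the evidence.
The same run writes a forest plot per subscale, and `sees beliefs`,
`sees corr`, `sees delphi` and `sees report` cover the remaining
analyses (`sees --help` lists everything).

Equivalent library calls: `sees.load_instrument()`,
`sees.read_response_csv()`, `sees.fit_consensus()`,
`sees.summarize_consensus()`.

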