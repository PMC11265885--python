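# Methods

## The consensus model

Responses to a subscale form a teams × items matrix `X` of ordinal codes
in `1..C` (C = 4 for the SEES) with explicit missingness for the
"not applicable/I do not know" option. The model is a latent truth rater
model from the cultural-consensus-theory family: there is no ground
truth to score answers against, and the estimand is the panel's
collective answer per item.

Generative story: item *i* has a latent location `T_i` on a shared
evaluation continuum; team *k* forms a noisy appraisal
`a_ki ~ Normal(T_i, λ_i)` and reports the category of `a_ki` relative to
the ordered thresholds `γ_1 < … < γ_{C−1}` shifted by the team's
scepticism `β_k` (positive β shifts all thresholds up, pushing responses
toward lower categories). This yields an ordered probit,

    P(X_ki = c) = Φ((γ_c + β_k − T_i)/λ_i) − Φ((γ_{c−1} + β_k − T_i)/λ_i),

with `γ_0 = −∞`, `γ_C = +∞`. `λ_i` ("difficulty") widens the appraisal
distribution for items that elicit polarized answers. Item locations are
hierarchical within a subscale, `T_i ~ Normal(μ_s, σ_s)`; each subscale
is fitted separately (subscales have distinct label sets and thresholds;
scepticism is therefore estimated per subscale).

**Identification.** The likelihood only involves `γ_c + β_k − T_i`, so a
joint shift of locations and thresholds (with any β shift absorbable
into γ) is unidentified, as is a common rescaling of `(T, γ, β, λ)`.
We enforce `mean(γ) = 0` and `mean(β) = 0` exactly in every draw — γ is
built from positive increments and centred; β is parameterised with K−1
free coordinates and a balancing last element — and the scale is
anchored softly by the dispersion prior, whose median is `λ = 1`.

**Priors** (defaults, all overridable through `ModelConfig`):
`μ_s ~ Normal(0, 1)`; `σ_s ~ half-Normal(1)`;
`β_k = σ_β η_k` with `η ~ Normal(0, 1)` (sum-to-zero) and
`σ_β ~ half-Normal(1)`; `log λ_i ~ Normal(0, 0.5)`; log threshold
increments `~ Normal(0, 1)`. The item and scepticism hierarchies use the
non-centred parameterisation: sampling `(ζ, η, log σ)` rather than
`(T, β, σ)` keeps the posterior free of the `σ → 0` funnel, whose
unbounded density otherwise captures mode-finding and cripples mixing
(we observed exactly this failure with the centred form: the optimiser
collapsed `σ_β` to ~1e−7 and dragged thresholds and dispersions with it).

**Missingness.** NA cells contribute no likelihood term. The survey
presents "not applicable" and "I do not know" as one escape option; we
treat it as missing completely at random, which is what an NA option for
inapplicable analyses is meant to capture. Items answered by few teams
simply get wide credible intervals.

**Estimation.** Posterior-mode initialisation (L-BFGS on the penalised
log posterior) followed by affine-invariant ensemble MCMC (`emcee`,
80% differential-evolution moves + 20% snooker moves, ≥ 2·dim walkers).
Defaults: 500 warmup sweeps, 500 retained sweeps thinned by 2 — for a
42-team, 8-item subscale that is ~130 walkers × 250 sweeps ≈ 30k stored
draws in a few seconds on one core. Diagnostics treat walker subgroups
(default 4) as chains for split-R̂ and bulk ESS; because walkers
interact, these are approximate health checks rather than exact chain
diagnostics, and a run warns (never silently passes) when max R̂ exceeds
1.01. The ensemble sampler has no divergent-transition concept, so the
reported divergence count is identically 0 and the mean move-acceptance
fraction is carried alongside; `target_accept` exists in the
configuration only for compatibility with gradient-based backends.
A fixed seed makes runs draw-identical on a platform.

**Summaries.** Per item: posterior median of `T_i` and central 95%
credible interval. The *overall* subscale consensus is the posterior of
the per-draw mean of the subscale's `T_i` — a quantity that inherits
between-item agreement — rather than the hyper-mean `μ_s`; the two agree
closely when items are exchangeable, but the item mean is what the
reported per-item figures aggregate, so it is the default.
`sd_across_items` is the sample SD of the item-level posterior medians.
Category labels assign each item the band (delimited by the posterior
medians of γ) containing its consensus median; a median exactly on a
threshold goes to the higher category. For reverse-coded items the label
is read from the coded (flipped) label order, so it reads in the
favourable direction.

## Synthetic data and the recovery study

`sees.synth` draws truth from `T_i ~ Normal(0, 1)`,
`log λ_i ~ Normal(0, 0.3)`, `β_k ~ Normal(0, 0.5)` (centred), fixed
`γ = (−1.2, 0, 1.2)`, then simulates responses through exactly the
ordered-probit kernel above and masks cells missing independently with
probability 0.1 by default. These choices make all four categories occur
with non-trivial frequency and produce realistic team-level variation;
the default NA rate reflects that most survey items are applicable to
most teams, while individual items in real deployments can run far
higher (the model tolerates this, at the price of wide intervals).

The recovery experiment replicates (default 10×): draw truth → simulate
K teams × 8 items → refit → score. Reported metrics: correlation between
true and posterior-median `T`, RMSE, 95% CI coverage of the truth, and
mean CI width. Everything is a pure function of the experiment seed
(replicate streams are spawned from it), and a failed replicate is
recorded rather than fatal. At K = 42 the harness attains
truth-correlation ≈ 0.97 with coverage ≈ 0.9; at K = 20 estimates remain
usable but intervals are systematically wider (width ratio ≈ 1.3),
which is the basis for recommending ≥ 40 responding teams. Recovery runs
use 600 warmup / 500 retained sweeps per fit — enough for stable medians
and intervals at these problem sizes while keeping a full two-sample,
10-replicate study within a few minutes on one core.

What the generator does *not* emulate: non-ignorable missingness (teams
skipping items *because* of their appraisal), within-team dependence
when several analysts share a team, response styles beyond a location
shift (e.g. extreme-responding), and item wording effects. Passing
recovery therefore shows the estimator is calibrated under the model's
own assumptions, not that those assumptions hold in any given study.

## Belief updating

Simple descriptives on the prior- and post-analysis plausibility item:
means over available responses at each timepoint; "agreement" is the top
half of the 4-point scale (codes 3–4), reported as a percentage to two
decimals; change classes (increased / decreased / unchanged) are the
sign of final − prior over teams with both responses — teams missing
either response are excluded from change classes but kept in
single-timepoint statistics. Group descriptives report median, unscaled
MAD (no 1.4826 consistency factor), mean, and sample SD (n−1); a single
observation reports SD 0 with an explicit `sd_defined=False` flag.

## Bayesian correlations

Both tests put a stretched beta(1/κ, 1/κ) prior on the correlation over
(−1, 1); the default κ = 1 is the uniform prior, the common default for
Bayesian correlation tests, and is configurable. Directional Bayes
factors restrict the prior to the tested half-line; by symmetry
`BF_10 = (BF_+0 + BF_−0)/2` and `BF_0+ = 1/BF_+0` exactly.

*Pearson:* the likelihood is reduced to the exact sampling density of
the observed correlation coefficient `r` (hypergeometric form), and
marginal likelihoods are computed by adaptive quadrature — the result is
deterministic. Posterior quantiles come from an 8001-point grid CDF.
The unit tests cross-check against an independent 200k-point trapezoid
oracle at 1% tolerance (observed agreement is ~1e−14, the two routes
differing only in integration rule).

*Spearman:* rank-based inference via latent-normal data augmentation.
Latent Gaussian scores consistent with each variable's ordering are
Gibbs-sampled from truncated normals (tied values impose no mutual
ordering, reproducing average-rank behaviour; location/scale are
standardised each sweep since ranks do not identify them), with a
Fisher-z random-walk Metropolis step for ρ (step size adapted toward
~40% acceptance during burn-in only). Draws of ρ map to
`ρ_s = (6/π) arcsin(ρ/2)`. `BF_10` is the Savage–Dickey ratio at ρ = 0
with the posterior density estimated by a Gaussian KDE on the Fisher-z
draws (Jacobian 1 at 0); one-sided factors multiply by twice the
posterior mass on the tested side. Defaults: 5000 retained sweeps after
500 burn-in; a batch-means Monte-Carlo standard error of `BF_+0` is
reported. The sampler sees only orderings, so results are exactly
invariant under strictly increasing transforms of either input.

## Delphi screening

Include an item iff the expert median ≥ 6 *and* IQR ≤ 2 on the 9-point
inclusion scale; an item clearing the median bar but failing the IQR bar
is flagged (never auto-included) when ≥ 70% of experts rate it 7–9,
mirroring the discussion-round override used during instrument
development. Quantiles use linear interpolation (type 7) — the paper
trail for any boundary decision depends on this convention, so it is
pinned in tests and recorded in every decision row.

## Numerical and design notes

* Probabilities in the ordered-probit likelihood are clipped at 1e−300
  before logging; threshold strict ordering is guaranteed by the
  increment parameterisation rather than rejection.
* Integer survey input is accepted as *already coded*: reverse coding is
  applied only when decoding labels, so coded tables round-trip through
  CSV without double reversal. Label matching is case-, punctuation- and
  whitespace-insensitive.
* `fit_consensus` requires ≥ 2 items and ≥ 5 responding teams; teams
  with no response on the subscale are dropped from that fit (their
  scepticism is not estimable there).
* The pilot-deposit pipeline (`sees.pilot`) expects externally obtained
  CSVs (`responses.csv`, `beliefs.csv`, `effect_sizes.csv`) and is the
  one part of the package whose reference outputs cannot be validated
  without that external dataset.

## Known limitations

Single-culture model only (no mixture of rater cultures, no model
comparison between consensus variants); one response per team (no
within-team nesting); ignorable missingness assumed; ensemble-MCMC
diagnostics are approximate as noted above; the Spearman Bayes factor is
Monte-Carlo (report `mc_se`, increase `n_samples` where precision
matters).
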