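"""Bayesian cultural-consensus model for ordinal survey responses.

The model is a latent truth rater model: each item *i* of a subscale has a
latent consensus location ``T_i`` on a shared evaluation continuum, each
team *k* draws a noisy latent appraisal ``a ~ Normal(T_i, lambda_i)`` and
reports the ordinal category in which the appraisal falls relative to
ordered population thresholds ``gamma_1 < ... < gamma_{C-1}`` shifted by the
team's scepticism ``beta_k`` (positive beta pushes responses toward lower
categories). The probability of team *k* answering category *c* on item *i*
is therefore an ordered probit::

    P(X_ki = c) = Phi((gamma_c + beta_k - T_i) / lambda_i)
                - Phi((gamma_{c-1} + beta_k - T_i) / lambda_i)

with ``gamma_0 = -inf`` and ``gamma_C = +inf``. Item locations are
hierarchical within a subscale, ``T_i ~ Normal(mu_s, sigma_s)``, so the
model borrows strength across items and yields an overall consensus.

Identification: the likelihood is invariant under a common shift of
``(T, gamma, beta)`` and a common rescaling of ``(T, gamma, beta, lambda)``.
We remove the shift by hard sum-to-zero constraints on the thresholds and
on the scepticism vector (enforced in the parameterization, so they hold in
every draw), and anchor the scale through the item-dispersion prior, whose
median is ``lambda = 1``.

Estimation is fully Bayesian: posterior-mode initialisation followed by
affine-invariant ensemble MCMC (differential-evolution moves), with
split-R-hat / effective-sample-size diagnostics computed by treating walker
subgroups as chains. Missing (not-applicable) cells contribute no
likelihood term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import arviz as az
import emcee
import numpy as np
from scipy import optimize
from scipy.special import ndtr

from .instrument import Instrument, ResponseTable

__all__ = [
    "ModelConfig",
    "FittedConsensus",
    "ConsensusSummary",
    "UnfitError",
    "ConvergenceWarning",
    "category_probability",
    "fit_consensus",
    "summarize_consensus",
    "label_consensus",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class UnfitError(RuntimeError):
    """Raised when a subscale has no usable data to fit."""


class ConvergenceWarning(UserWarning):
    """Sampler diagnostics exceeded their thresholds; inspect before use."""


@dataclass(frozen=True)
class ModelConfig:
    """Sampler and prior settings for :func:`fit_consensus`.

    ``chains`` is the number of walker subgroups used for split-R-hat;
    ``draws_per_chain`` the number of post-warmup ensemble sweeps retained
    (thinned by ``thin`` before storage). Prior scales follow the default
    weakly-informative choices documented in ``docs/methods.md``.
    ``target_accept`` is kept for configuration compatibility with
    gradient-based backends; the ensemble sampler has no step-size tuning.
    """

    C: int = 4
    chains: int = 4
    draws_per_chain: int = 500
    warmup: int = 500
    thin: int = 2
    seed: int = 0
    hyper_mean_scale: float = 1.0      # mu_s ~ Normal(0, .)
    hyper_sd_scale: float = 1.0        # sigma_s ~ half-Normal(.)
    difficulty_scale: float = 0.5      # log lambda_i ~ Normal(0, .)
    scepticism_scale: float = 1.0      # sigma_beta ~ half-Normal(.)
    threshold_scale: float = 1.0       # log threshold increments ~ Normal(0, .)
    target_accept: float = 0.9
    nwalkers: int | None = None
    rhat_threshold: float = 1.01

    def __post_init__(self) -> None:
        if self.C < 2:
            raise ValueError("C must be >= 2")
        if self.chains < 2:
            raise ValueError("chains must be >= 2")
        if self.draws_per_chain < 1 or self.warmup < 0 or self.thin < 1:
            raise ValueError("invalid sampling lengths")
        for name in ("hyper_mean_scale", "hyper_sd_scale", "difficulty_scale",
                     "scepticism_scale", "threshold_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def category_probability(T, lam, beta, gamma, c=None):
    """Ordered-probit response probability.

    Parameters
    ----------
    T, lam, beta : float
        Item location, item dispersion (> 0) and rater scepticism shift.
    gamma : array-like
        Strictly increasing thresholds, length C-1.
    c : int or None
        Category index in ``1..C``; with ``None`` the full probability
        vector over all C categories is returned.
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 1 or gamma.size < 1:
        raise ValueError("gamma must be a 1-D array of length C-1")
    if np.any(np.diff(gamma) <= 0):
        raise ValueError("gamma must be strictly increasing")
    if not np.all(np.asarray(lam) > 0):
        raise ValueError("lam must be > 0")
    C = gamma.size + 1
    edges = np.concatenate(([-np.inf], gamma, [np.inf]))
    z = (edges + beta - T) / lam
    cdf = ndtr(z)
    probs = np.diff(cdf)
    if c is None:
        return probs
    c = int(c)
    if not 1 <= c <= C:
        raise ValueError(f"category index {c} outside 1..{C}")
    return float(probs[c - 1])


# ---------------------------------------------------------------------------
# parameter packing:  theta = [zeta (I), log lambda (I), eta_free (K-1),
#                              log d (C-2), mu, log sigma, log sigma_beta]
# non-centred hierarchies:  T = mu + sigma * zeta,  beta = sigma_beta * eta
# (eta constrained to sum to zero), which keeps the posterior free of the
# sigma -> 0 funnel singularity that a centred parameterisation exhibits
# ---------------------------------------------------------------------------

class _Posterior:
    """Vectorised log-posterior over the packed parameter vector."""

    def __init__(self, x: np.ndarray, mask: np.ndarray, C: int,
                 cfg: ModelConfig):
        self.K, self.I = x.shape
        self.C = C
        self.cfg = cfg
        obs = np.nonzero(mask)
        self.k_idx = obs[0]
        self.i_idx = obs[1]
        self.x_obs = x[obs].astype(int)
        self.n_obs = self.x_obs.size
        self.ndim = 2 * self.I + (self.K - 1) + (C - 2) + 3
        s = 0
        self.sl_zeta = slice(s, s + self.I); s += self.I
        self.sl_loglam = slice(s, s + self.I); s += self.I
        self.sl_eta = slice(s, s + self.K - 1); s += self.K - 1
        self.sl_logd = slice(s, s + C - 2); s += C - 2
        self.i_mu, self.i_logsig, self.i_logsigb = s, s + 1, s + 2

    def unpack(self, theta: np.ndarray):
        """theta (..., ndim) -> dict of natural-scale parameter arrays."""
        mu = theta[..., self.i_mu]
        sigma = np.exp(theta[..., self.i_logsig])
        sigma_beta = np.exp(theta[..., self.i_logsigb])
        T = mu[..., None] + sigma[..., None] * theta[..., self.sl_zeta]
        lam = np.exp(theta[..., self.sl_loglam])
        efree = theta[..., self.sl_eta]
        eta = np.concatenate(
            [efree, -efree.sum(axis=-1, keepdims=True)], axis=-1
        )
        beta = sigma_beta[..., None] * eta
        d = np.exp(theta[..., self.sl_logd])
        # raw thresholds (0, d1, d1+d2, ...) centred to mean zero
        zeros = np.zeros(d.shape[:-1] + (1,))
        g = np.concatenate([zeros, np.cumsum(d, axis=-1)], axis=-1)
        gamma = g - g.mean(axis=-1, keepdims=True)
        return {
            "T": T, "lam": lam, "beta": beta, "gamma": gamma,
            "mu": mu, "sigma": sigma, "sigma_beta": sigma_beta,
        }

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        p = self.unpack(theta)
        T, lam, beta, gamma = p["T"], p["lam"], p["beta"], p["gamma"]
        mu, sigma, sigma_b = p["mu"], p["sigma"], p["sigma_beta"]
        W = theta.shape[0]

        inf = np.full((W, 1), np.inf)
        edges = np.concatenate([-inf, gamma, inf], axis=1)     # (W, C+1)
        loc = beta[:, self.k_idx] - T[:, self.i_idx]           # (W, n_obs)
        scale = lam[:, self.i_idx]
        zu = (np.take_along_axis(edges, self.x_obs[None, :].repeat(W, 0),
                                 axis=1) + loc) / scale
        zl = (np.take_along_axis(edges, (self.x_obs - 1)[None, :].repeat(W, 0),
                                 axis=1) + loc) / scale
        prob = ndtr(zu) - ndtr(zl)
        loglik = np.log(np.clip(prob, 1e-300, None)).sum(axis=1)

        cfg = self.cfg
        lp = loglik
        # non-centred item effects: zeta_i ~ Normal(0, 1)
        lp = lp - 0.5 * (theta[:, self.sl_zeta] ** 2).sum(axis=1)
        # mu ~ Normal(0, hyper_mean_scale)
        lp = lp - 0.5 * (mu / cfg.hyper_mean_scale) ** 2
        # sigma ~ half-Normal(hyper_sd_scale), sampled on the log scale
        lp = lp - 0.5 * (sigma / cfg.hyper_sd_scale) ** 2 + np.log(sigma)
        # non-centred scepticism: eta ~ Normal(0, 1) on the sum-to-zero vector
        eta = beta / sigma_b[:, None]
        lp = lp - 0.5 * (eta ** 2).sum(axis=1)
        # sigma_beta ~ half-Normal(scepticism_scale), log scale
        lp = lp - 0.5 * (sigma_b / cfg.scepticism_scale) ** 2 + np.log(sigma_b)
        # log lambda_i ~ Normal(0, difficulty_scale): prior median lambda = 1
        lp = lp - 0.5 * ((theta[:, self.sl_loglam] /
                          cfg.difficulty_scale) ** 2).sum(axis=1)
        # log threshold increments ~ Normal(0, threshold_scale)
        lp = lp - 0.5 * ((theta[:, self.sl_logd] /
                          cfg.threshold_scale) ** 2).sum(axis=1)
        return lp

    def initial_guess(self) -> np.ndarray:
        theta0 = np.zeros(self.ndim)
        theta0[self.i_logsigb] = -0.5
        # crude item-location moments to shorten optimisation
        means = np.zeros(self.I)
        for i in range(self.I):
            vals = self.x_obs[self.i_idx == i]
            if vals.size:
                means[i] = (vals.mean() - (self.C + 1) / 2.0)
        theta0[self.sl_zeta] = means
        return theta0

    def map_estimate(self) -> np.ndarray:
        fun = lambda t: -float(self.log_prob(t)[0])
        res = optimize.minimize(fun, self.initial_guess(), method="L-BFGS-B",
                                options={"maxiter": 500})
        return res.x


@dataclass
class FittedConsensus:
    """Posterior draws and diagnostics for one subscale fit.

    Draw arrays are flattened over walkers and retained sweeps;
    ``chain_shape`` records the (chains, draws) layout used for
    diagnostics. ``divergences`` is identically 0 for the ensemble
    backend (it has no divergent-transition concept); the mean move
    acceptance fraction is the backend's native health signal.
    """

    subscale: str
    item_ids: list[str]
    team_ids: list[str]
    C: int
    config: ModelConfig
    T: np.ndarray              # (n_draws, I)
    lam: np.ndarray            # (n_draws, I)
    beta: np.ndarray           # (n_draws, K)
    gamma: np.ndarray          # (n_draws, C-1)
    mu: np.ndarray             # (n_draws,)
    sigma: np.ndarray
    sigma_beta: np.ndarray
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    divergences: int = 0
    acceptance_fraction: float = float("nan")
    chain_shape: tuple[int, int] = (0, 0)

    @property
    def n_draws(self) -> int:
        return self.T.shape[0]

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")


def _diagnostics(fit: FittedConsensus, chains: int,
                 per_chain: int) -> None:
    """Split-R-hat and bulk ESS with walker groups treated as chains."""
    def reshape(a: np.ndarray) -> np.ndarray:
        tail = a.shape[1:]
        return a.reshape((chains, per_chain) + tail)

    for name in ("T", "lam", "beta", "gamma", "mu", "sigma", "sigma_beta"):
        ds = az.convert_to_dataset(reshape(getattr(fit, name)))
        fit.rhat[name] = float(np.max(az.rhat(ds).to_array().values))
        fit.ess[name] = float(np.min(az.ess(ds).to_array().values))


def fit_consensus(
    table: ResponseTable,
    instrument: Instrument,
    subscale: str,
    config: ModelConfig | None = None,
) -> FittedConsensus:
    """Fit the consensus model to one subscale of a response table.

    Requires at least two items in the subscale and at least five teams
    with a non-missing response on it; reverse coding must already have
    been applied (``table.reversed_applied``). Missing cells are dropped
    from the likelihood. A fixed ``config.seed`` reproduces the draws
    exactly on the same platform. Emits :class:`ConvergenceWarning` when
    split-R-hat exceeds the configured threshold.
    """
    config = config or ModelConfig(C=table.C)
    if config.C != table.C:
        raise ValueError(f"config C={config.C} but table C={table.C}")
    if not table.reversed_applied:
        raise ValueError("reverse coding must be applied before fitting")

    items = [it.id for it in instrument.subscale_items(subscale)]
    items = [i for i in items if i in table.item_ids]
    if len(items) < 2:
        raise UnfitError(
            f"subscale {subscale!r} has {len(items)} item(s) in the table; "
            "need at least 2"
        )
    sub = table.subset(items)
    mask = np.isfinite(sub.values)
    responding = mask.any(axis=1)
    if mask.sum() == 0:
        raise UnfitError(f"subscale {subscale!r} has no non-missing responses")
    if responding.sum() < 5:
        raise UnfitError(
            f"subscale {subscale!r} has {int(responding.sum())} responding "
            "teams; need at least 5"
        )
    x = sub.values[responding]
    team_ids = [t for t, r in zip(sub.team_ids, responding) if r]
    mask = mask[responding]

    post = _Posterior(np.nan_to_num(x, nan=1.0), mask, config.C, config)
    theta_map = post.map_estimate()

    ndim = post.ndim
    nwalkers = config.nwalkers or max(2 * ndim + 2, 48)
    # round up so walkers split evenly into halves and diagnostic groups
    m = config.chains if config.chains % 2 == 0 else 2 * config.chains
    nwalkers = ((nwalkers + m - 1) // m) * m
    rng = np.random.RandomState(config.seed % (2 ** 32))
    p0 = theta_map[None, :] + 0.05 * rng.standard_normal((nwalkers, ndim))

    sampler = emcee.EnsembleSampler(
        nwalkers, ndim, post.log_prob, vectorize=True,
        moves=[(emcee.moves.DEMove(), 0.8),
               (emcee.moves.DESnookerMove(), 0.2)],
    )
    state = emcee.State(p0, random_state=rng.get_state())
    state = sampler.run_mcmc(state, config.warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, config.draws_per_chain, progress=False)

    chain = sampler.get_chain()[:: config.thin]      # (steps, walkers, ndim)
    nsteps = chain.shape[0]
    # walker-major flattening keeps contiguous walker groups for split-R-hat
    flat = np.swapaxes(chain, 0, 1).reshape(-1, ndim)
    params = post.unpack(flat)

    fit = FittedConsensus(
        subscale=subscale,
        item_ids=items,
        team_ids=team_ids,
        C=config.C,
        config=config,
        T=params["T"],
        lam=params["lam"],
        beta=params["beta"],
        gamma=params["gamma"],
        mu=params["mu"],
        sigma=params["sigma"],
        sigma_beta=params["sigma_beta"],
        acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
        chain_shape=(config.chains, (nwalkers // config.chains) * nsteps),
    )
    groups = config.chains
    per_chain = (nwalkers // groups) * nsteps
    _diagnostics(fit, groups, per_chain)
    if fit.max_rhat > config.rhat_threshold:
        warnings.warn(
            f"subscale {subscale!r}: max split-R-hat {fit.max_rhat:.3f} "
            f"exceeds {config.rhat_threshold}; min bulk ESS "
            f"{min(fit.ess.values()):.0f}; mean acceptance "
            f"{fit.acceptance_fraction:.2f}",
            ConvergenceWarning,
            stacklevel=2,
        )
    return fit


@dataclass
class ConsensusSummary:
    """Posterior summaries of one subscale fit.

    The overall consensus is the posterior of the per-draw mean of the
    subscale's item locations; ``sd_across_items`` is the standard
    deviation of the item-level posterior medians.
    """

    subscale: str
    item_ids: list[str]
    item_median: np.ndarray
    item_ci: np.ndarray                 # (I, 2) central 95%
    overall_median: float
    overall_ci: tuple[float, float]
    sd_across_items: float
    thresholds: np.ndarray              # posterior medians of gamma (C-1)
    scepticism_median: dict[str, float]
    difficulty_median: dict[str, float]
    labels: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {
                "item_id": self.item_ids,
                "consensus_median": self.item_median,
                "ci_lower": self.item_ci[:, 0],
                "ci_upper": self.item_ci[:, 1],
                "difficulty_median": [
                    self.difficulty_median[i] for i in self.item_ids
                ],
                "label": [self.labels.get(i, "") for i in self.item_ids],
            }
        )


def summarize_consensus(
    fit: FittedConsensus, instrument: Instrument
) -> ConsensusSummary:
    """Posterior medians, 95% credible intervals and consensus labels."""
    if fit.n_draws < 100:
        raise ValueError(
            f"need at least 100 posterior draws, got {fit.n_draws}"
        )
    q = np.percentile(fit.T, [2.5, 50, 97.5], axis=0)
    item_median = q[1]
    item_ci = q[[0, 2]].T
    overall_draws = fit.T.mean(axis=1)
    o = np.percentile(overall_draws, [2.5, 50, 97.5])
    sd_items = float(np.std(item_median, ddof=1)) if len(fit.item_ids) > 1 else 0.0
    summary = ConsensusSummary(
        subscale=fit.subscale,
        item_ids=list(fit.item_ids),
        item_median=item_median,
        item_ci=item_ci,
        overall_median=float(o[1]),
        overall_ci=(float(o[0]), float(o[2])),
        sd_across_items=sd_items,
        thresholds=np.median(fit.gamma, axis=0),
        scepticism_median={
            t: float(m) for t, m in zip(fit.team_ids, np.median(fit.beta, axis=0))
        },
        difficulty_median={
            i: float(m) for i, m in zip(fit.item_ids, np.median(fit.lam, axis=0))
        },
    )
    summary.labels = label_consensus(summary, instrument)
    return summary


def label_consensus(
    summary: ConsensusSummary, instrument: Instrument
) -> dict[str, str]:
    """Map each item's consensus median to a response-category label.

    The label is the category whose threshold interval (using the
    posterior medians of the thresholds) contains the consensus median; a
    median falling exactly on a threshold goes to the higher category.
    Labels come from the item's coded (post-reversal) ordering, so for
    counter-indicative items the reported label reads in the favourable
    direction.
    """
    thr = np.asarray(summary.thresholds)
    out: dict[str, str] = {}
    for iid, m in zip(summary.item_ids, summary.item_median):
        cat = int(np.searchsorted(thr, m, side="right"))  # 0-based category
        labels = instrument[iid].coded_labels()
        out[iid] = labels[cat]
    return out
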