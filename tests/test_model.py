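"""Consensus-model likelihood, fitting, summaries and labels."""

import warnings

import numpy as np
import pytest
from scipy.special import ndtr

import sees
from sees.model import (
    ConsensusSummary,
    FittedConsensus,
    ModelConfig,
    UnfitError,
    category_probability,
    fit_consensus,
    label_consensus,
    summarize_consensus,
)

GAMMA = np.array([-1.0, 0.0, 1.0])


class TestCategoryProbability:
    def test_probabilities_partition_unit(self):
        p = category_probability(0.0, 1.0, 0.0, GAMMA)
        assert p.shape == (4,)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(p > 0)

    def test_lowest_category_is_normal_tail(self):
        # P(X=1) = Phi((gamma_1 - T)/lambda) = Phi(-1)
        assert category_probability(0.0, 1.0, 0.0, GAMMA, c=1) == pytest.approx(
            0.158655, abs=1e-6
        )

    def test_symmetry_about_centre(self):
        p = category_probability(0.0, 1.0, 0.0, GAMMA)
        assert p[0] == pytest.approx(p[3], abs=1e-12)
        assert p[1] == pytest.approx(p[2], abs=1e-12)

    def test_translation_invariance(self):
        # the likelihood depends only on gamma_c + beta - T: shifting the
        # locations and thresholds together (the rater shift folds into the
        # thresholds) leaves probabilities unchanged, which is why the model
        # needs the sum-to-zero identification constraints
        base = category_probability(0.3, 0.8, -0.2, GAMMA)
        for shift in (-2.0, 0.7, 5.0):
            moved = category_probability(0.3 + shift, 0.8, -0.2, GAMMA + shift)
            np.testing.assert_allclose(moved, base, atol=1e-12)
            folded = category_probability(0.3 + shift, 0.8, -0.2 + shift, GAMMA)
            np.testing.assert_allclose(folded, base, atol=1e-12)

    def test_scepticism_decreases_top_category(self):
        betas = np.linspace(-1.5, 1.5, 11)
        ptop = [category_probability(0.4, 0.9, b, GAMMA, c=4) for b in betas]
        assert np.all(np.diff(ptop) < 0)

    def test_monte_carlo_oracle(self):
        # bin latent appraisals by the shifted thresholds and compare
        rng = np.random.default_rng(2024)
        T, lam, beta = 0.35, 0.75, -0.4
        n = 100_000
        a = rng.normal(T, lam, size=n)
        counts = np.array([
            np.mean((a > lo) & (a <= hi))
            for lo, hi in zip(
                np.concatenate(([-np.inf], GAMMA + beta)),
                np.concatenate((GAMMA + beta, [np.inf])),
            )
        ])
        p = category_probability(T, lam, beta, GAMMA)
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(counts - p) < 3 * se)

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(gamma=[1.0, 0.0, -1.0]), "increasing"),
            (dict(gamma=[0.0, 0.0, 1.0]), "increasing"),
            (dict(lam=0.0), "lam"),
            (dict(lam=-1.0), "lam"),
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs, msg):
        args = dict(T=0.0, lam=1.0, beta=0.0, gamma=GAMMA)
        args.update(kwargs)
        with pytest.raises(ValueError, match=msg):
            category_probability(**args)

    def test_out_of_range_category_index(self):
        with pytest.raises(ValueError, match="category"):
            category_probability(0.0, 1.0, 0.0, GAMMA, c=5)


def _fake_fit(n_draws=400, I=3, K=6, seed=0):
    """A FittedConsensus with hand-made draws, bypassing MCMC."""
    rng = np.random.default_rng(seed)
    gam = np.sort(rng.normal(0, 1, size=(n_draws, 3)), axis=1)
    gam += np.linspace(0, 0.5, 3)  # guarantee strict ordering
    return FittedConsensus(
        subscale="subjective_evidence",
        item_ids=[f"SE_{i+1}" for i in range(I)],
        team_ids=[f"t{k}" for k in range(K)],
        C=4,
        config=ModelConfig(),
        T=rng.normal(0, 1, size=(n_draws, I)),
        lam=np.exp(rng.normal(0, 0.3, size=(n_draws, I))),
        beta=rng.normal(0, 0.5, size=(n_draws, K)),
        gamma=gam,
        mu=rng.normal(size=n_draws),
        sigma=np.exp(rng.normal(size=n_draws)),
        sigma_beta=np.exp(rng.normal(size=n_draws)),
    )


class TestSummaries:
    def test_overall_matches_direct_pass_over_draws(self):
        fit = _fake_fit()
        inst = sees.synthetic_instrument(sees.SimulationConfig(items=3))
        summ = summarize_consensus(fit, inst)
        # independent recomputation straight from the stored draws
        per_draw_mean = fit.T.mean(axis=1)
        assert summ.overall_median == pytest.approx(np.median(per_draw_mean))
        lo, hi = np.percentile(per_draw_mean, [2.5, 97.5])
        assert summ.overall_ci == pytest.approx((lo, hi))
        assert summ.sd_across_items == pytest.approx(
            np.std(np.median(fit.T, axis=0), ddof=1)
        )

    def test_ci_brackets_median(self):
        fit = _fake_fit(seed=3)
        inst = sees.synthetic_instrument(sees.SimulationConfig(items=3))
        summ = summarize_consensus(fit, inst)
        assert np.all(summ.item_ci[:, 0] <= summ.item_median)
        assert np.all(summ.item_median <= summ.item_ci[:, 1])

    def test_single_item_sd_is_zero(self):
        fit = _fake_fit(I=1)
        inst = sees.synthetic_instrument(sees.SimulationConfig(items=1))
        summ = summarize_consensus(fit, inst)
        assert summ.sd_across_items == 0.0

    def test_too_few_draws_rejected(self):
        fit = _fake_fit(n_draws=50)
        inst = sees.synthetic_instrument(sees.SimulationConfig(items=3))
        with pytest.raises(ValueError, match="100"):
            summarize_consensus(fit, inst)


class TestLabels:
    def _summary(self, medians, thresholds):
        I = len(medians)
        return ConsensusSummary(
            subscale="subjective_evidence",
            item_ids=[f"SE_{i+1}" for i in range(I)],
            item_median=np.asarray(medians, dtype=float),
            item_ci=np.column_stack([medians, medians]).astype(float),
            overall_median=0.0,
            overall_ci=(0.0, 0.0),
            sd_across_items=0.0,
            thresholds=np.asarray(thresholds, dtype=float),
            scepticism_median={},
            difficulty_median={},
        )

    def test_extreme_and_tied_medians(self):
        inst = sees.synthetic_instrument(sees.SimulationConfig(items=3))
        summ = self._summary([-5.0, 0.0, 5.0], [-1.0, 0.0, 1.0])
        labels = label_consensus(summ, inst)
        assert labels["SE_1"] == "category 1"     # below every threshold
        assert labels["SE_2"] == "category 3"     # exactly on a threshold -> higher
        assert labels["SE_3"] == "category 4"

    def test_reverse_coded_items_use_coded_order(self, instrument):
        summ = self._summary([-5.0], [-1.0, 0.0, 1.0])
        summ.item_ids = ["SE_4"]
        labels = label_consensus(summ, instrument)
        # lowest coded category on a counter-indicative item is the
        # respondent's strongest endorsement of evidence *against*
        assert labels["SE_4"] == "yes, definitely"


class TestFit:
    def test_recovers_truth_direction(self, small_sim, small_fit):
        _, truth, _ = small_sim
        inst, _, fit = small_fit
        summ = summarize_consensus(fit, inst)
        r = np.corrcoef(truth.T, summ.item_median)[0, 1]
        assert r > 0.7

    def test_fixed_seed_is_draw_identical(self, small_sim, small_fit):
        cfg, _, table = small_sim
        inst, mc, fit = small_fit
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            again = fit_consensus(table, inst, "subjective_evidence", mc)
        np.testing.assert_array_equal(fit.T, again.T)
        np.testing.assert_array_equal(fit.gamma, again.gamma)

    def test_thresholds_ordered_and_scales_positive_in_every_draw(self, small_fit):
        _, _, fit = small_fit
        assert np.all(np.diff(fit.gamma, axis=1) > 0)
        assert np.all(fit.lam > 0)
        assert np.all(fit.sigma > 0)

    def test_identification_constraints_hold_per_draw(self, small_fit):
        _, _, fit = small_fit
        np.testing.assert_allclose(fit.gamma.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(fit.beta.mean(axis=1), 0.0, atol=1e-10)

    def test_unanimous_top_category_pushes_consensus_above_last_threshold(self):
        K = 10
        table = sees.ResponseTable(
            team_ids=[f"t{k}" for k in range(K)],
            item_ids=["SE_1", "SE_2", "SE_3"],
            values=np.full((K, 3), 4.0),
            C=4,
        )
        inst = sees.synthetic_instrument(sees.SimulationConfig(K=K, items=3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_consensus(table, inst, "subjective_evidence",
                                ModelConfig(seed=1, warmup=300, draws_per_chain=200))
        summ = summarize_consensus(fit, inst)
        assert np.all(summ.item_median > summ.thresholds[-1])

    def test_missing_cells_are_ignorable(self, small_sim):
        # blanking one team's row must not crash and removes its influence
        cfg, _, table = small_sim
        inst = sees.synthetic_instrument(cfg)
        vals = table.values.copy()
        vals[0, :] = np.nan
        t2 = sees.ResponseTable(table.team_ids, table.item_ids, vals, C=4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = fit_consensus(t2, inst, "subjective_evidence",
                                ModelConfig(seed=2, warmup=200, draws_per_chain=150))
        assert len(fit.team_ids) == cfg.K - 1

    def test_single_item_subscale_unfit(self, instrument):
        table = sees.ResponseTable(
            team_ids=[f"t{k}" for k in range(6)],
            item_ids=["SE_1"],
            values=np.full((6, 1), 2.0),
            C=4,
        )
        with pytest.raises(UnfitError, match="at least 2"):
            fit_consensus(table, instrument, "subjective_evidence", ModelConfig())

    def test_no_data_unfit(self, instrument):
        table = sees.ResponseTable(
            team_ids=[f"t{k}" for k in range(6)],
            item_ids=["SE_1", "SE_2"],
            values=np.full((6, 2), np.nan),
            C=4,
        )
        with pytest.raises(UnfitError, match="no non-missing"):
            fit_consensus(table, instrument, "subjective_evidence", ModelConfig())

    def test_too_few_teams_unfit(self, instrument):
        table = sees.ResponseTable(
            team_ids=["a", "b", "c"],
            item_ids=["SE_1", "SE_2"],
            values=np.full((3, 2), 3.0),
            C=4,
        )
        with pytest.raises(UnfitError, match="responding"):
            fit_consensus(table, instrument, "subjective_evidence", ModelConfig())
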