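"""Hierarchical Bayesian inference: recovery, comparison, contrasts, checks.

MCMC-based tests run on deliberately small cohorts and shortened chains so
the whole suite stays within a single-CPU budget; tolerances were fixed
from pilot simulations at these exact settings.
"""

import numpy as np
import pandas as pd
import pytest

import prlkit as pk
from prlkit.metrics import posterior_predictive_check


@pytest.fixture(scope="module")
def model1_recovery_fit():
    """Model 1 fit to model-1 data: 12 subjects, two blocks each."""
    cohort = pk.CohortSpec(group_sizes={"control": 6, "gambling": 6},
                           generating_model=pk.MODEL_REGISTRY[1], rng_seed=21)
    trials, truth = pk.generate_cohort(cohort, pk.TaskConfig(n_blocks=2))
    fit = pk.HierarchicalRLModel(
        model_id=1, mcmc=pk.McmcConfig(chains=2, warmup=400, samples=400,
                                       seed=3)).fit(trials)
    return fit, truth


class TestFitModel:
    def test_learning_rate_recovered_within_tolerance(self, model1_recovery_fit):
        fit, truth = model1_recovery_fit
        est = fit.subject_params_.set_index("subject_id")
        tru = truth.set_index("subject_id")
        err = (est.loc[tru.index, "alpha_rew"] - tru["alpha_rew"]).abs()
        assert err.max() < 0.15
        assert fit.max_rhat_ < 1.1

    def test_single_alpha_model_ties_learning_rates(self, model1_recovery_fit):
        fit, _ = model1_recovery_fit
        pd.testing.assert_series_equal(fit.subject_params_["alpha_rew"],
                                       fit.subject_params_["alpha_pun"],
                                       check_names=False)

    def test_natural_scale_constraints_hold_for_every_draw(self, winning_model_fit):
        post = winning_model_fit.posterior_.posterior
        sp = post["subject_param"]
        for rate in ("alpha_rew", "alpha_pun"):
            vals = sp.sel(param=rate).values
            assert vals.min() >= 0.0 and vals.max() <= 1.0
        assert sp.sel(param="beta").values.min() > 0.0
        assert np.isfinite(post["mu"].values).all()

    def test_degenerate_hierarchy_concentrates_on_shared_truth(self):
        cohort = pk.CohortSpec(
            group_sizes={"control": 4, "gambling": 4},
            generating_model=pk.MODEL_REGISTRY[1],
            group_means={g: (-0.4055, 1.0986) for g in ("control", "gambling")},
            group_sds={g: (0.0, 0.0) for g in ("control", "gambling")},
            rng_seed=8)
        trials, truth = pk.generate_cohort(cohort, pk.TaskConfig(n_blocks=2))
        fit = pk.HierarchicalRLModel(
            model_id=1, mcmc=pk.McmcConfig(chains=2, warmup=300, samples=300,
                                           seed=9)).fit(trials)
        alpha_true = truth["alpha_rew"].iloc[0]
        est = fit.subject_params_["alpha_rew"]
        assert np.all(np.abs(est - alpha_true) < 0.12)

    def test_requires_two_subjects_per_group(self, winning_model_cohort):
        trials, _ = winning_model_cohort
        lone = trials[trials["subject_id"].isin(["control01", "gambling01",
                                                 "gambling02"])]
        with pytest.raises(ValueError, match="2 subjects"):
            pk.HierarchicalRLModel(
                model_id=1, mcmc=pk.McmcConfig(chains=1, warmup=10,
                                               samples=10)).fit(lone)


class TestGroupContrast:
    def test_self_contrast_is_identically_zero(self, winning_model_fit):
        c = winning_model_fit.group_contrast("beta", "control", "control")
        assert np.all(c.draws == 0.0)
        assert c.hdi_75 == (0.0, 0.0) and not c.excludes_zero_75

    def test_hdi_nesting(self, winning_model_fit):
        c = winning_model_fit.group_contrast("kappa_stim", "gambling", "control")
        assert c.hdi_95[0] <= c.hdi_75[0] and c.hdi_75[1] <= c.hdi_95[1]

    def test_chain_permutation_invariance(self, winning_model_fit):
        gm = winning_model_fit.posterior_.posterior["group_mean_natural"]
        diff = (gm.sel(group="control", param="beta")
                - gm.sel(group="cud", param="beta")).values
        forward = pk.hdi(diff.ravel(), 0.75)
        permuted = pk.hdi(diff[::-1].ravel(), 0.75)
        assert forward == permuted

    def test_unknown_parameter_or_group(self, winning_model_fit):
        with pytest.raises(KeyError, match="parameter"):
            winning_model_fit.group_contrast("gamma", "control", "cud")
        with pytest.raises(KeyError, match="group"):
            winning_model_fit.group_contrast("beta", "control", "patients")


@pytest.fixture(scope="module")
def sticky_data_fits():
    """Models 1 and 6 fitted to data with strong stickiness (model 6)."""
    means = list(pk.task.DEFAULT_GROUP_MEANS)
    means[3], means[4] = 0.8, 0.5  # |kappa| >= 0.5 in the generator
    cohort = pk.CohortSpec(
        group_sizes={"control": 5, "gambling": 5},
        group_means={g: tuple(means) for g in ("control", "gambling")},
        rng_seed=31)
    trials, _ = pk.generate_cohort(cohort, pk.TaskConfig(n_blocks=2))
    mcmc = pk.McmcConfig(chains=2, warmup=400, samples=400, seed=5)
    return {f"model{mid}": pk.HierarchicalRLModel(model_id=mid, mcmc=mcmc)
            .fit(trials) for mid in (1, 6)}


class TestCompareModels:
    def test_generating_model_ranked_first(self, sticky_data_fits):
        table = pk.compare_models(sticky_data_fits)
        assert table.index[0] == "model6"
        assert table.loc["model6", "winner"]
        # advantage is decisive, not within criterion uncertainty
        assert table.loc["model1", "elpd_diff"] > 2 * table.loc["model1", "dse"]

    def test_simpler_generator_not_beaten_beyond_uncertainty(self):
        cohort = pk.CohortSpec(group_sizes={"control": 5, "gambling": 5},
                               generating_model=pk.MODEL_REGISTRY[1],
                               rng_seed=41)
        trials, _ = pk.generate_cohort(cohort, pk.TaskConfig(n_blocks=2))
        mcmc = pk.McmcConfig(chains=2, warmup=400, samples=400, seed=6)
        fits = {f"model{mid}": pk.HierarchicalRLModel(model_id=mid, mcmc=mcmc)
                .fit(trials) for mid in (1, 6)}
        table = pk.compare_models(fits)
        runner_up = table.index[1]
        assert table.loc[runner_up, "elpd_diff"] <= \
            2 * max(table.loc[runner_up, "dse"], 1.0)

    def test_self_comparison_has_zero_difference(self, sticky_data_fits):
        fit = sticky_data_fits["model6"]
        table = pk.compare_models({"a": fit, "b": fit})
        assert table["elpd_diff"].iloc[1] == pytest.approx(0.0, abs=1e-9)

    def test_rejects_fits_of_different_data(self, sticky_data_fits,
                                            model1_recovery_fit):
        with pytest.raises(ValueError, match="same data"):
            pk.compare_models({"a": sticky_data_fits["model6"],
                               "b": model1_recovery_fit[0]})


class TestPosteriorPredictiveCheck:
    def test_self_consistency_and_null_groups(self, winning_model_cohort,
                                              winning_model_fit):
        trials, _ = winning_model_cohort
        report = posterior_predictive_check(winning_model_fit, trials,
                                            pk.TaskConfig(), n_reps=12, seed=4)
        # data were generated by the fitted model itself: observed group
        # means should sit inside the central 95% simulation intervals
        assert report["outside_interval"].mean() <= 0.2
        # groups share a generator: simulated group means should not differ
        # more than simulation noise across groups
        sims = report.pivot(index="measure", columns="group",
                            values="simulated_mean")
        spread = (sims.max(axis=1) - sims.min(axis=1)) / sims.mean(axis=1).abs()
        assert (spread < 0.35).all()

    def test_single_replicate_degenerate_interval(self, winning_model_cohort,
                                                  winning_model_fit):
        trials, _ = winning_model_cohort
        report = posterior_predictive_check(winning_model_fit, trials,
                                            pk.TaskConfig(), n_reps=1, seed=1)
        assert (report["sim_lo_2.5"] == report["sim_hi_97.5"]).all()
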