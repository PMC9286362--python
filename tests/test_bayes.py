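"""Hierarchical Bayesian models: summaries, recovery, contrasts, properties."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import aglearn as ag
from aglearn.bayes import (
    ModelSpec,
    SamplerConfig,
    fit_consistency_model,
    fit_property_model,
    grammar_logodds_contrast,
    group_probability_draws,
    individual_probabilities,
    latent_cohens_d,
    summarize,
)
from aglearn.coding import annotate_trials, build_consistency_table

FAST = ModelSpec(sampler=SamplerConfig(n_walkers=16, n_steps=600, n_burn=600,
                                       thin=4, gh_nodes=21, seed=0))


class TestSummarize:
    def test_symmetric_draws_split_pp(self, rng):
        s = summarize(rng.normal(0, 1, 20000))
        assert abs(s.pp_positive - 0.5) < 0.02
        assert abs(s.median) < 0.03

    def test_all_positive_draws(self, rng):
        s = summarize(rng.uniform(0.1, 1.0, 2000))
        assert s.pp_positive == 1.0
        assert s.ci90[0] > 0

    def test_constant_draws(self):
        s = summarize(np.full(1500, 0.7), null=0.7)
        assert s.median == 0.7 and s.mad == 0.0
        assert s.pp_positive == 0.5          # ties count half

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            summarize(np.ones(10))

    def test_transform_applied_before_summary(self, rng):
        draws = rng.normal(1.5, 0.1, 2000)
        s = summarize(draws, transform=expit, null=0.5)
        assert 0.7 < s.median < 0.9


class TestConsistencyModel:
    def test_two_group_recovery_and_diagnostics(self, coded_study):
        fit = fit_consistency_model(coded_study, "ABNA", FAST)
        assert fit.diagnostics["rhat"] < 1.03
        assert fit.diagnostics["n_draws"] >= 1000
        probs = group_probability_draws(fit)
        s_deaf = summarize(probs["deaf"], null=0.5)
        s_hear = summarize(probs["hearing"], null=0.5)
        # generating probabilities .87 / .97 up to offset-sampling noise
        assert abs(s_deaf.median - 0.87) < 0.08
        assert abs(s_hear.median - 0.97) < 0.03
        assert s_deaf.pp_positive == 1.0 and s_hear.pp_positive == 1.0
        d = summarize(latent_cohens_d(fit))
        assert d.median > 0   # hearing simulated above deaf

    def test_monotone_in_generating_logit(self, abna_test_set):
        """Posterior median group probability strictly increases with the
        generating base logit."""
        medians = []
        for i, p in enumerate((0.6, 0.75, 0.9)):
            prof = {"g": ag.StrategyProfile(base_logit=float(logit(p)),
                                            individual_sd=0.3)}
            study = ag.simulate_study(prof, n_per_group=15,
                                      grammars=("ABNA",),
                                      stimsets={"ABNA": abna_test_set}, seed=40 + i)
            tab = build_consistency_table(study.trials, [ag.grammar("ABNA")])
            fit = fit_consistency_model(tab, "ABNA", FAST, participant_effects=False)
            medians.append(summarize(group_probability_draws(fit)["g"]).median)
        assert medians[0] < medians[1] < medians[2]

    def test_degenerate_outcome_warns_but_stays_finite(self, abna_test_set, rng):
        prof = ag.StrategyProfile(base_logit=20.0, individual_sd=0.0)
        trials = ag.simulate_trials(abna_test_set, np.zeros(5), prof, rng)
        tab = build_consistency_table(trials, [ag.grammar("ABNA")])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            fit = fit_consistency_model(tab, "ABNA", FAST, participant_effects=False)
        assert np.isfinite(fit.alpha).all()

    def test_missing_column_rejected(self, coded_study):
        with pytest.raises(KeyError):
            fit_consistency_model(coded_study, "NOT_CODED", FAST)


class TestIndividualProbabilities:
    @pytest.mark.parametrize("label,lgt,expect_flag", [
        ("sharp", 3.5, True), ("chance", 0.0, False),
    ])
    def test_flags_separate_perfect_from_chance(self, abna_test_set, rng,
                                                label, lgt, expect_flag):
        prof = ag.StrategyProfile(base_logit=lgt, individual_sd=0.0)
        trials = ag.simulate_trials(abna_test_set, np.zeros(10), prof, rng, group="g")
        tab = build_consistency_table(trials, [ag.grammar("ABNA")])
        fit = fit_consistency_model(tab, "ABNA", FAST)
        ip = individual_probabilities(fit)
        if expect_flag:
            assert ip["above_chance"].all()
        else:
            assert not ip["above_chance"].any()

    def test_requires_participant_effects(self, coded_study):
        fit = fit_consistency_model(coded_study, "ABNA", FAST,
                                    participant_effects=False)
        with pytest.raises(ValueError):
            individual_probabilities(fit)


class TestLogORContrast:
    def test_rule_against_itself_is_exactly_zero(self, coded_study):
        t = coded_study.copy()
        t["ABNA_COPY2"] = t["ABNA"]
        with pytest.warns(RuntimeWarning, match="identical"):
            con = grammar_logodds_contrast(t, "ABNA", "ABNA_COPY2", FAST)
        for g, draws in con.draws.items():
            assert np.all(draws == 0)

    def test_target_followers_favour_target_over_shortcut(self, abna_test_set, rng):
        prof = ag.StrategyProfile(rule="target", base_logit=2.2, individual_sd=0.3)
        trials = ag.simulate_trials(abna_test_set,
                                    ag.sample_participants(15, prof, rng), prof, rng)
        tab = build_consistency_table(trials)
        con = grammar_logodds_contrast(tab, "ABNA", "ENDS_A", FAST)
        s = con.by_group["synthetic"]
        assert s.median > 0
        assert s.pp_positive >= 0.95

    def test_joint_and_perrule_modes_agree_in_sign(self, coded_study):
        joint = grammar_logodds_contrast(coded_study, "ABNA", "ENDS_A", FAST)
        per = grammar_logodds_contrast(coded_study, "ABNA", "ENDS_A", FAST,
                                       mode="perrule")
        for g in joint.by_group:
            assert np.sign(joint.by_group[g].median) == np.sign(per.by_group[g].median)
            assert abs(joint.by_group[g].median - per.by_group[g].median) < 0.5


def _property_table(rng, deficit_on_dissimilar=0.0, n_per_group=8):
    """Synthetic annotated accuracy table with a group effect confined to
    dissimilar stimuli; cell sizes follow the published test design."""
    cells = [(1, 0, 20), (1, 1, 16), (0, 0, 30), (0, 1, 21)]  # (sim, gen, n)
    rows = []
    for grp, bonus in (("deaf", 0.0), ("hearing", deficit_on_dissimilar)):
        for i in range(n_per_group):
            off = rng.normal(0, 0.3)
            for sim, gen, n in cells:
                lgt = 1.2 + off + (bonus if sim == 0 else 0.0)
                kk = rng.binomial(n, expit(lgt))
                rows += [{"participant_id": f"{grp}_{i}", "group": grp,
                          "similar": sim, "generalization": gen,
                          "accuracy": 1}] * kk
                rows += [{"participant_id": f"{grp}_{i}", "group": grp,
                          "similar": sim, "generalization": gen,
                          "accuracy": 0}] * (n - kk)
    return pd.DataFrame(rows)


class TestPropertyModel:
    def test_group_by_similarity_interaction_recovered(self, rng):
        """A group advantage confined to dissimilar stimuli shows up in the
        dissimilar-stimulus group contrast but not the similar one."""
        tab = _property_table(rng, deficit_on_dissimilar=1.2)
        fit = fit_property_model(tab, FAST)
        dis = fit.contrast({"group": "hearing", "similar": 0},
                           {"group": "deaf", "similar": 0})
        sim = fit.contrast({"group": "hearing", "similar": 1},
                           {"group": "deaf", "similar": 1})
        assert dis.median > 0 and dis.pp_positive >= 0.95
        assert sim.ci90[0] < 0 < sim.ci90[1]
        # interaction: hearing similarity effect is negative (worse on similar)
        inter = fit.contrast({"group": "hearing", "similar": 1},
                             {"group": "hearing", "similar": 0})
        assert inter.median < 0

    def test_latent_cohens_d_scaling(self, rng):
        tab = _property_table(rng, deficit_on_dissimilar=1.2)
        fit = fit_property_model(tab, FAST)
        raw = fit.contrast({"group": "hearing", "similar": 0},
                           {"group": "deaf", "similar": 0})
        d = fit.contrast_d({"group": "hearing", "similar": 0},
                           {"group": "deaf", "similar": 0})
        # dividing by sqrt(sigma_u^2 + pi^2/3) > 1 shrinks the magnitude
        assert 0 < d.median < raw.median

    def test_missing_annotation_rejected(self, coded_study):
        with pytest.raises(KeyError):
            fit_property_model(coded_study.drop(columns=["similar"]), FAST)
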