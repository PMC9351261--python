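import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from ungated.gating import apply_gating_tree, GateNode
from ungated.synthetic import (EVENT_CLEAN, ChannelModel, CohortConfig,
                               OutcomeSpec, default_channel_models,
                               derive_latent, generate_cohort,
                               generate_events_for_individual,
                               ground_truth_gated_counts,
                               intensity_shift_channel_models)


class TestConfigValidation:
    def test_proportions_must_sum_below_one(self):
        with pytest.raises(ValueError, match="sum below 1"):
            CohortConfig(debris_fraction=0.5, doublet_fraction=0.3,
                         dead_fraction=0.3)

    def test_out_of_range_proportion_rejected(self):
        with pytest.raises(ValueError, match="outlier_rate"):
            CohortConfig(outlier_rate=1.5)

    def test_minimum_cohort_size(self):
        with pytest.raises(ValueError, match="n_individuals"):
            CohortConfig(n_individuals=1)


class TestDeterminism:
    def test_equal_seeds_give_bit_identical_cohorts(self):
        config = CohortConfig(n_individuals=3, n_events_per_individual=500, seed=1)
        t1, o1, g1 = generate_cohort(config)
        t2, o2, g2 = generate_cohort(config)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.values, b.values)
        pd.testing.assert_frame_equal(o1.data, o2.data)
        pd.testing.assert_series_equal(g1.z, g2.z)

    def test_different_seeds_differ(self):
        base = dict(n_individuals=3, n_events_per_individual=500)
        t1, _, _ = generate_cohort(CohortConfig(seed=1, **base))
        t2, _, _ = generate_cohort(CohortConfig(seed=2, **base))
        assert not np.array_equal(t1[0].values, t2[0].values)


class TestEventGeneration:
    def test_outlier_rate_zero_means_no_values_below_floor(self, panel):
        config = CohortConfig(n_individuals=2, n_events_per_individual=5000,
                              outlier_rate=0.0, seed=3)
        tables, _, _ = generate_cohort(config)
        for ev in tables:
            fluor = [ev.channels.index(c) for c in panel.fluorescence_channels]
            assert (ev.values[:, fluor] >= -50_000).all()

    def test_single_event_table(self, panel):
        config = CohortConfig(n_individuals=2, n_events_per_individual=1, seed=4)
        latent = derive_latent("S1", 0.0, default_channel_models(panel))
        ev = generate_events_for_individual(latent, config, np.random.default_rng(4))
        assert ev.n_events == 1

    def test_sample_moments_converge_to_mixture_moments(self, clean_events, panel):
        """With no nuisance events, per-channel sample mean/variance approach
        the analytic two-component mixture moments (CLT tolerance)."""
        latent, ev = clean_events
        n = ev.n_events
        for ch in panel.fluorescence_channels[:6]:
            w, means, sds = latent.mixtures[ch]
            mix_mean = float(w @ means)
            mix_var = float(w @ (sds ** 2 + means ** 2) - mix_mean ** 2)
            values = ev.column(ch)
            # 4th moment bound: SE of the sample mean is sqrt(var/n)
            assert abs(values.mean() - mix_mean) <= 5 * np.sqrt(mix_var / n)
            assert abs(values.var() - mix_var) <= 0.1 * mix_var

    def test_positive_component_fraction_matches_weights(self, clean_events, panel):
        latent, ev = clean_events
        ch = panel.channel_of("CD3")
        w_pos = latent.mixtures[ch][0][1]
        n_clean = int((ev.meta["event_class"] == EVENT_CLEAN).sum())
        observed = ev.meta["positive_counts"][ch] / n_clean
        se = np.sqrt(w_pos * (1 - w_pos) / n_clean)
        assert abs(observed - w_pos) <= 3 * se

    def test_mixture_weight_recovered_by_valley_gate(self, clean_events, panel):
        """A one-threshold gate at the valley of a well-separated bimodal
        channel recovers the mixing weight within 3 binomial SEs."""
        latent, ev = clean_events
        ch = panel.channel_of("CD3")
        w_pos = latent.mixtures[ch][0][1]
        tree = GateNode("root", channel=ch, thresholds=(10_000.0,),
                        children=[GateNode("neg"), GateNode("pos")])
        counts = apply_gating_tree(ev, tree)
        observed = counts.counts[1] / ev.n_events
        se = np.sqrt(w_pos * (1 - w_pos) / ev.n_events)
        assert abs(observed - w_pos) <= 3 * se

    def test_latent_missing_channel_rejected(self, panel):
        config = CohortConfig(n_individuals=2, n_events_per_individual=10)
        latent = derive_latent("S1", 0.0, default_channel_models(panel))
        latent.mixtures.pop(panel.channel_of("CD3"))
        with pytest.raises(ValueError, match="lacks channels"):
            generate_events_for_individual(latent, config)


class TestOutcomes:
    def test_cohort_of_567_has_567_outcome_rows(self):
        config = CohortConfig(n_individuals=567, n_events_per_individual=1, seed=5)
        _, outcomes, _ = generate_cohort(config)
        assert len(outcomes.data) == 567

    def test_noiseless_monotone_link_has_rank_correlation_one(self):
        spec = OutcomeSpec("pure", "continuous", coef=2.0, noise_sd=0.0)
        config = CohortConfig(n_individuals=100, n_events_per_individual=1,
                              seed=6, outcome_specs=(spec,))
        _, outcomes, truth = generate_cohort(config)
        rho = spearmanr(truth.z.to_numpy(), outcomes.data["pure"].to_numpy()).statistic
        assert rho == pytest.approx(1.0)

    def test_negative_control_is_independent_of_latent_state(self):
        config = CohortConfig(n_individuals=500, n_events_per_individual=1, seed=7)
        _, outcomes, truth = generate_cohort(config)
        rho = spearmanr(truth.z.to_numpy(),
                        outcomes.data["Religion"].to_numpy()).statistic
        assert abs(rho) < 3 / np.sqrt(500)

    def test_binary_outcomes_take_zero_one_values(self):
        config = CohortConfig(n_individuals=50, n_events_per_individual=1, seed=8)
        _, outcomes, _ = generate_cohort(config)
        values = set(outcomes.data["Diabetes"].unique())
        assert values <= {0.0, 1.0}

    def test_binary_prevalence_near_target(self):
        spec = OutcomeSpec("flag", "binary", coef=0.6, noise_sd=1.0, prevalence=0.3)
        config = CohortConfig(n_individuals=2000, n_events_per_individual=1,
                              seed=9, outcome_specs=(spec,))
        _, outcomes, _ = generate_cohort(config)
        p = outcomes.data["flag"].mean()
        assert abs(p - 0.3) <= 3 * np.sqrt(0.3 * 0.7 / 2000)

    def test_ordinal_outcomes_respect_declared_range(self):
        config = CohortConfig(n_individuals=300, n_events_per_individual=1, seed=10)
        _, outcomes, _ = generate_cohort(config)
        ssa = outcomes.data["Self-assessed Health"]
        assert ssa.between(1, 5).all()


class TestGroundTruthCounts:
    def test_equivalence_with_gating_module(self, small_cohort, panel):
        _, tables, _, _ = small_cohort
        ch = panel.channel_of("CD3")
        tree = GateNode("root", channel=ch, thresholds=(10_000.0,),
                        children=[GateNode("neg"), GateNode("pos")])
        a = ground_truth_gated_counts(tables[0], tree)
        b = apply_gating_tree(tables[0], tree)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_counts_partition_gated_events(self, small_cohort, panel):
        _, tables, _, _ = small_cohort
        ch = panel.channel_of("CD4")
        tree = GateNode("root", channel=ch, thresholds=(0.0, 10_000.0),
                        children=[GateNode("lo"), GateNode("mid"), GateNode("hi")])
        counts = ground_truth_gated_counts(tables[1], tree)
        assert counts.counts.sum() == tables[1].n_events


class TestScenarios:
    def test_intensity_shift_scenario_freezes_weights(self, panel):
        models = intensity_shift_channel_models(panel)
        for model in models.values():
            assert model.signal in ("none", "mean")
        w_lo = models[panel.fluorescence_channels[0]].mixture_for(-2.0)[0]
        w_hi = models[panel.fluorescence_channels[0]].mixture_for(2.0)[0]
        np.testing.assert_allclose(w_lo, w_hi)

    def test_weight_signal_moves_mixing_weight(self):
        model = ChannelModel(signal="weight", effect=0.3)
        w_lo = model.mixture_for(-2.0)[0][1]
        w_hi = model.mixture_for(2.0)[0][1]
        assert w_hi > w_lo
        assert np.isclose(model.mixture_for(1.0)[0].sum(), 1.0)
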