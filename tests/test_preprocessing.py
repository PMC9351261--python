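import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ungated.io import EventTable
from ungated.preprocessing import (BinnedDistribution, PreprocessConfig,
                                   bin_channel, bins_to_long, bins_to_wide,
                                   preprocess_cohort, preprocess_individual,
                                   remove_outlier_cells, subsample_events,
                                   trim_events)


def table(values, channels=None, iid="S1"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    channels = channels or [f"c{j}" for j in range(values.shape[1])]
    return EventTable(iid, channels, values)


def brute_force_clip_counts(values, lower_pct, upper_pct):
    """Independent oracle: count values strictly outside the type-7 percentiles."""
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)

    def type7(p):
        h = (n - 1) * p / 100.0
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return values[lo] + (h - lo) * (values[hi] - values[lo])

    lo, hi = type7(lower_pct), type7(upper_pct)
    return int((values < lo).sum()), int((values > hi).sum())


class TestTrim:
    def test_ten_percent_of_5000_leaves_middle_4000(self):
        ev = table(np.arange(5000.0)[:, None])
        out = trim_events(ev, 0.10)
        assert out.n_events == 4000
        assert out.values[0, 0] == 500.0 and out.values[-1, 0] == 4499.0

    def test_small_n_floor_rounding_removes_nothing(self):
        out = trim_events(table(np.arange(9.0)[:, None]), 0.10)
        assert out.n_events == 9  # floor(0.9) = 0 per end

    def test_zero_fraction_is_identity(self):
        ev = table(np.arange(7.0)[:, None])
        np.testing.assert_array_equal(trim_events(ev, 0.0).values, ev.values)

    def test_half_or_more_rejected(self):
        with pytest.raises(ValueError):
            trim_events(table([[1.0]]), 0.5)


class TestOutlierRemoval:
    def test_single_bad_channel_removes_whole_event(self):
        ev = table([[100.0, -60_000.0], [100.0, 100.0]])
        out = remove_outlier_cells(ev, -50_000.0)
        assert out.n_events == 1
        assert out.meta["outliers_removed"] == 1

    def test_boundary_value_kept(self):
        ev = table([[-50_000.0, 0.0]])
        assert remove_outlier_cells(ev, -50_000.0).n_events == 1

    def test_screening_respects_channel_subset(self):
        ev = table([[-60_000.0, 1.0]], channels=["FSC-A", "CD3"])
        out = remove_outlier_cells(ev, -50_000.0, fluorescence_channels=["CD3"])
        assert out.n_events == 1  # scatter channel not screened

    def test_removed_count_matches_binomial_expectation(self, panel):
        from ungated.synthetic import CohortConfig, default_channel_models, \
            derive_latent, generate_events_for_individual
        rate, n = 0.001, 20_000
        config = CohortConfig(n_individuals=2, n_events_per_individual=n,
                              outlier_rate=rate, seed=5)
        latent = derive_latent("S1", 0.0, default_channel_models(panel))
        ev = generate_events_for_individual(latent, config, np.random.default_rng(5))
        out = remove_outlier_cells(ev, -50_000.0, panel.fluorescence_channels)
        removed = n - out.n_events
        se = np.sqrt(n * rate * (1 - rate))
        assert abs(removed - n * rate) <= 3 * se


class TestSubsample:
    def test_shortfall_keeps_all_and_flags(self):
        ev = table(np.arange(4000.0)[:, None])
        out = subsample_events(ev, 5000, seed=0)
        assert out.n_events == 4000 and out.meta["shortfall"] is True

    def test_fixed_seed_reproduces_indices(self):
        ev = table(np.random.default_rng(3).normal(size=(100_000, 1)))
        a = subsample_events(ev, 5000, seed=11)
        b = subsample_events(ev, 5000, seed=11)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.n_events == 5000 and a.meta["shortfall"] is False

    def test_sample_is_an_ordered_subset(self):
        ev = table(np.arange(1000.0)[:, None])
        out = subsample_events(ev, 100, seed=2)
        picked = out.values[:, 0]
        assert np.all(np.diff(picked) > 0)  # acquisition order preserved
        assert set(picked) <= set(ev.values[:, 0])


class TestBinChannel:
    config = PreprocessConfig()

    def test_clip_sections_match_brute_force_oracle(self):
        rng = np.random.default_rng(17)
        values = rng.normal(10_000, 3_000, size=5000)  # distinct a.s.
        d = bin_channel(values, self.config)
        lo_expect, hi_expect = brute_force_clip_counts(values, 2.5, 97.5)
        assert d.counts[0] == lo_expect == 125
        assert d.counts[-1] == hi_expect == 125

    def test_uniform_grid_interior_widths_forced(self):
        # clip points at 25 and 975 -> interior width (975-25)/100 = 9.5
        values = np.linspace(0.0, 1000.0, 1001)
        d = bin_channel(values, self.config)
        widths = np.diff(d.edges)
        np.testing.assert_allclose(widths, 9.5, rtol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 4000), st.integers(0, 2**31 - 1))
    def test_counts_conserved_for_random_inputs(self, n, seed):
        values = np.random.default_rng(seed).normal(0, 1000, size=n)
        d = bin_channel(values, self.config)
        assert d.n_sections == 102
        assert d.total == n

    def test_shift_equivariance(self):
        rng = np.random.default_rng(23)
        values = rng.normal(500, 100, size=3000)
        c = 12_345.678
        a = bin_channel(values, self.config)
        b = bin_channel(values + c, self.config)
        np.testing.assert_array_equal(a.counts, b.counts)
        np.testing.assert_allclose(b.edges, a.edges + c, atol=1e-6)

    def test_degenerate_channel_collapses_with_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            d = bin_channel(np.full(100, 7.0), self.config)
        assert d.degenerate and d.total == 100
        assert d.counts[1] == 100  # all mass in one interior section

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            bin_channel(np.array([]), self.config)


class TestPreprocessIndividual:
    def test_default_panel_yields_23_distributions_of_102(self, small_cohort, panel):
        _, tables, _, _ = small_cohort
        dists = preprocess_individual(tables[0], panel, PreprocessConfig(seed=1))
        assert len(dists) == 23
        assert all(d.n_sections == 102 for d in dists)
        assert all(d.total == dists[0].total for d in dists)

    @pytest.mark.parametrize("n_interior", [10, 100])
    def test_section_count_follows_config(self, small_cohort, panel, n_interior):
        _, tables, _, _ = small_cohort
        cfg = PreprocessConfig(seed=1, n_interior_sections=n_interior)
        dists = preprocess_individual(tables[0], panel, cfg)
        assert all(d.n_sections == n_interior + 2 for d in dists)

    def test_rerun_with_same_seed_is_bit_identical(self, small_cohort, panel):
        _, tables, _, _ = small_cohort
        cfg = PreprocessConfig(seed=9)
        a = preprocess_individual(tables[1], panel, cfg)
        b = preprocess_individual(tables[1], panel, cfg)
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.counts, db.counts)
            np.testing.assert_array_equal(da.edges, db.edges)

    def test_missing_channel_rejected(self, panel):
        ev = table(np.zeros((10, 2)), channels=["CD3", "CD4"])
        with pytest.raises(KeyError, match="lacks panel channels"):
            preprocess_individual(ev, panel, PreprocessConfig())


class TestExports:
    def test_wide_and_long_are_consistent(self, small_cohort, panel):
        _, tables, _, _ = small_cohort
        binned = preprocess_cohort(tables[:3], panel, PreprocessConfig(seed=1))
        wide = bins_to_wide(binned)
        long = bins_to_long(binned)
        assert wide.shape == (3, 23 * 102)
        assert len(long) == 3 * 23 * 102
        iid = tables[0].individual_id
        total_wide = wide.loc[iid].sum()
        total_long = long[long.individual_id == iid]["count"].sum()
        assert total_wide == total_long
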