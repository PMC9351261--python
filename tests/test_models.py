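import numpy as np
import pytest

from ungated.models import (ModelSpecError, NetworkSpec, build_model,
                            continuous_spec, desk_profile,
                            extract_informative_values, gated_spec,
                            make_split, run_replicates, scaled_gated_layers,
                            train)


def tiny_continuous(n_branches=3, **kw):
    return continuous_spec(n_branches=n_branches, branch_input_size=8,
                           branch_layer_sizes=(6, 4, 1), **kw)


def make_data(spec, n=40, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, size=(n, spec.total_input_size))
    y = rng.normal(0, 1, size=n)
    return X, y


class TestArchitecture:
    def test_continuous_parameter_count_closed_form(self):
        spec = continuous_spec()
        # 23 branches of (102->75->50->25->1) plus the 23->1 combiner
        branch = 102 * 75 + 75 + 75 * 50 + 50 + 50 * 25 + 25 + 25 * 1 + 1
        assert spec.parameter_count() == 23 * branch + 23 + 1 == 295_022
        assert build_model(spec, seed=0).n_parameters == 295_022

    def test_gated_parameter_count_closed_form(self):
        spec = gated_spec()
        expected = 67 * 50 + 50 + 50 * 30 + 30 + 30 * 15 + 15 + 15 * 1 + 1
        assert spec.parameter_count() == expected == 5_411
        assert build_model(spec, seed=0).n_parameters == expected

    def test_layer_shapes_match_spec(self):
        model = build_model(continuous_spec(), seed=1)
        assert len(model.branches) == 23
        shapes = [layer.W.shape for layer in model.branches[0]]
        assert shapes == [(102, 75), (75, 50), (50, 25), (25, 1)]
        assert model.combiner.W.shape == (23, 1)
        gated = build_model(gated_spec(), seed=1)
        assert [l.W.shape for l in gated.layers] == \
            [(67, 50), (50, 30), (30, 15), (15, 1)]

    def test_increasing_layer_sizes_rejected(self):
        with pytest.raises(ModelSpecError, match="decreasing"):
            NetworkSpec(kind="gated", input_size=10, layer_sizes=(20, 5, 1))

    def test_same_seed_identical_initialization(self):
        spec = tiny_continuous()
        a, b = build_model(spec, seed=5), build_model(spec, seed=5)
        for pa, pb in zip(a.get_parameters(), b.get_parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_scaled_gated_layers_keep_decreasing_gradient(self):
        assert scaled_gated_layers(67) == (50, 30, 15, 1)
        for size in (2, 5, 16, 64, 200):
            sizes = (size,) + scaled_gated_layers(size)
            assert all(a > b for a, b in zip(sizes, sizes[1:]))
            gated_spec(input_size=size, layer_sizes=scaled_gated_layers(size))


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """The analytic gradient of the MSE loss agrees with central
        finite differences through branches, ELU and combiner."""
        spec = tiny_continuous(n_branches=2)
        model = build_model(spec, seed=3)
        rng = np.random.default_rng(3)
        X = rng.normal(size=(5, spec.total_input_size))
        y = rng.normal(size=5)

        pred = model.forward(X)
        model.backward(2.0 * (pred - y) / len(y))
        layer = model.branches[0][1]
        analytic = layer._gW.copy()

        eps = 1e-6
        for idx in [(0, 0), (2, 3), (5, 1)]:
            orig = layer.W[idx]
            layer.W[idx] = orig + eps
            up = np.mean((model.forward(X) - y) ** 2)
            layer.W[idx] = orig - eps
            down = np.mean((model.forward(X) - y) ** 2)
            layer.W[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert analytic[idx] == pytest.approx(numeric, rel=1e-4, abs=1e-8)


class TestTraining:
    def test_constant_target_is_learned(self):
        spec = tiny_continuous(epochs=2000, batch_size=20)
        X, _ = make_data(spec, n=40)
        y = np.full(40, 3.5)
        rep = train(build_model(spec, seed=0), X, y, spec, seed=0, X_val=X, y_val=y)
        assert rep.rmse_val < 0.05

    def test_zero_epochs_leaves_parameters_untouched(self):
        spec = tiny_continuous(epochs=0)
        X, y = make_data(spec)
        model = build_model(spec, seed=1)
        before = model.get_parameters()
        train(model, X, y, spec, seed=1)
        for pa, pb in zip(before, model.get_parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_mismatched_rows_rejected(self):
        spec = tiny_continuous()
        X, y = make_data(spec)
        with pytest.raises(ValueError, match="row count"):
            train(build_model(spec, seed=0), X, y[:-1], spec, seed=0)

    def test_validation_rmse_shrinks_with_more_epochs(self):
        """On a noiseless outcome linear in one section count, rmse falls
        monotonically over increasing epoch budgets."""
        spec0 = tiny_continuous(epochs=0)
        rng = np.random.default_rng(4)
        X = rng.poisson(40, size=(60, spec0.total_input_size)).astype(float)
        y = 0.5 * X[:, 3]
        rmses = []
        for epochs in (0, 60, 600):
            spec = tiny_continuous(epochs=epochs, batch_size=20)
            rep = train(build_model(spec, seed=2), X[:40], y[:40], spec,
                        seed=2, X_val=X[40:], y_val=y[40:])
            rmses.append(rep.rmse_val)
        assert rmses[0] > rmses[1] > rmses[2]

    def test_standardization_switch_round_trips_predictions(self):
        spec = tiny_continuous(epochs=30, standardize_inputs=True)
        X, y = make_data(spec, n=30, seed=6)
        rep = train(build_model(spec, seed=6), X, y, spec, seed=6,
                    X_val=X, y_val=y)
        assert rep.input_mean is not None
        assert np.isfinite(rep.rmse_val)


class TestInformativeLayer:
    def trained_replicate(self, epochs=40):
        spec = tiny_continuous(epochs=epochs, batch_size=10)
        X, y = make_data(spec, n=30, seed=5)
        return train(build_model(spec, seed=5), X, y, spec, seed=5,
                     X_val=X, y_val=y), X

    def test_affine_decomposition_of_predictions(self):
        rep, X = self.trained_replicate()
        informative, w, b = extract_informative_values(rep, X)
        reconstructed = informative @ w + b
        np.testing.assert_allclose(reconstructed, rep.predictions_val, rtol=1e-10)

    def test_zeroing_one_branch_shifts_prediction_by_its_share(self):
        rep, X = self.trained_replicate()
        informative, w, b = extract_informative_values(rep, X)
        dropped = informative.copy()
        dropped[:, 1] = 0.0
        delta = (informative @ w + b) - (dropped @ w + b)
        np.testing.assert_allclose(delta, w[1] * informative[:, 1], rtol=1e-10)

    def test_contribution_summary_aggregates_over_replicates(self):
        spec = tiny_continuous(epochs=10, batch_size=10)
        X, y = make_data(spec, n=30, seed=8)
        reps = run_replicates(X[:20], y[:20], X[20:], y[20:], spec,
                              n_replicates=3, base_seed=50)
        from ungated.models import contribution_summary
        summary = contribution_summary(reps, ["a", "b", "c"])
        assert list(summary.channel) == ["a", "b", "c"]
        assert (summary.n_replicates == 3).all()
        # weighted contribution of replicate r, channel m is
        # w_m * mean_i informative[i, m]
        expected = np.mean([r.informative_values.mean(axis=0) * r.combiner_w
                            for r in reps], axis=0)
        np.testing.assert_allclose(summary.mean_contribution, expected)

    def test_gated_model_has_no_informative_layer(self):
        spec = gated_spec(input_size=12, layer_sizes=scaled_gated_layers(12),
                          epochs=5)
        X = np.random.default_rng(0).normal(size=(20, 12))
        rep = train(build_model(spec, seed=0), X, X[:, 0], spec, seed=0)
        with pytest.raises(ModelSpecError, match="informative"):
            extract_informative_values(rep, X)


class TestSplitsAndReplicates:
    def test_default_split_is_300_267(self):
        ids = [f"S{i:04d}" for i in range(567)]
        split = make_split(ids, seed=0)
        assert len(split.calibration_ids) == 300
        assert len(split.validation_ids) == 267
        assert not set(split.calibration_ids) & set(split.validation_ids)
        assert set(split.calibration_ids) | set(split.validation_ids) == set(ids)

    def test_split_requires_leftover_validation_ids(self):
        with pytest.raises(ValueError, match="no validation"):
            make_split(["a", "b"], n_calibration=2, seed=0)

    def test_replicates_are_deterministic_and_distinct(self):
        spec = tiny_continuous(epochs=20, batch_size=10)
        X, y = make_data(spec, n=30, seed=7)
        reps1 = run_replicates(X[:20], y[:20], X[20:], y[20:], spec,
                               n_replicates=2, base_seed=100)
        reps2 = run_replicates(X[:20], y[:20], X[20:], y[20:], spec,
                               n_replicates=2, base_seed=100)
        np.testing.assert_array_equal(reps1[0].predictions_val,
                                      reps2[0].predictions_val)
        assert not np.array_equal(reps1[0].predictions_val,
                                  reps1[1].predictions_val)

    def test_desk_profile_reduces_epochs_only(self):
        cont = continuous_spec()
        desk = desk_profile(cont)
        assert desk.epochs < cont.epochs
        assert desk.branch_layer_sizes == cont.branch_layer_sizes
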