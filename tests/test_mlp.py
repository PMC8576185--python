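"""Tests of the MLP estimator: splitting, scaling, training, prediction."""

import numpy as np
import pytest

from lvadest.mlp import (LabelScaler, MLPSpec, TrainConfig, fit_label_scaler,
                         load_model, predict, save_model, select_architecture,
                         split_dataset, train_mlp)


class TestSplit:
    def test_full_scale_bookkeeping(self):
        speeds = np.repeat(np.linspace(4000, 6000, 21), 10_000)
        itr, iva, ite = split_dataset(210_000, TrainConfig(seed=0), speeds)
        assert ite.size == 10_500
        assert itr.size == 159_600
        assert iva.size == 39_900

    def test_partition_is_disjoint_and_exhaustive(self):
        speeds = np.repeat([4000.0, 5000.0], 50)
        itr, iva, ite = split_dataset(100, TrainConfig(seed=1), speeds)
        all_idx = np.concatenate([itr, iva, ite])
        assert np.array_equal(np.sort(all_idx), np.arange(100))

    def test_split_is_stratified_by_speed(self):
        speeds = np.repeat([4000.0, 5000.0], 500)
        itr, iva, ite = split_dataset(1000, TrainConfig(seed=2), speeds)
        for subset in (itr, iva, ite):
            counts = np.unique(speeds[subset], return_counts=True)[1]
            assert counts[0] == counts[1]

    def test_seed_reproducible(self):
        a = split_dataset(1000, TrainConfig(seed=3))
        b = split_dataset(1000, TrainConfig(seed=3))
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(10, TrainConfig())


class TestLabelScaler:
    def test_endpoints_map_to_unit_interval(self):
        s = LabelScaler([0.2, 0.011], [2.95, 0.014])
        assert np.allclose(s.scale([0.2, 0.011]), [0.0, 0.0])
        assert np.allclose(s.scale([2.95, 0.014]), [1.0, 1.0])

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        s = LabelScaler([0.2, 0.2, 0.2, 0.011], [2.95, 2.39, 0.475, 0.014])
        y = rng.uniform(0.2, 0.4, (50, 4))
        assert np.max(np.abs(s.unscale(s.scale(y)) - y)) < 1e-12

    def test_out_of_range_values_pass_through_unclipped(self):
        s = LabelScaler([0.0], [1.0])
        assert s.scale([1.5])[0] == pytest.approx(1.5)  # no error, no clip

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            LabelScaler([1.0, 0.0], [1.0, 1.0])

    def test_fit_from_data(self):
        y = np.array([[1.0, 5.0], [3.0, 7.0]])
        s = fit_label_scaler(y)
        assert np.allclose(s.mins, [1.0, 5.0])
        assert np.allclose(s.maxs, [3.0, 7.0])


def _linear_problem(n=600, d=8, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    A = rng.normal(size=(d, 3)) * 0.3
    Y = X @ A + rng.normal(scale=1e-3, size=(n, 3))
    return X[: n // 2], Y[: n // 2], X[n // 2:], Y[n // 2:]


class TestTraining:
    def test_learns_linear_map(self):
        # an MLP contains linear maps; with targets kept inside the
        # sigmoid's linear zone the validation loss collapses
        Xtr, Ytr, Xva, Yva = _linear_problem()
        scaler = LabelScaler(Ytr.min(axis=0) - 1.0, Ytr.max(axis=0) + 1.0)
        model = train_mlp(Xtr, Ytr, Xva, Yva,
                          MLPSpec(input_size=8, hidden=(32,), output_size=3),
                          TrainConfig(seed=0, max_epochs=800, patience=150,
                                      learning_rate=0.003),
                          scaler=scaler)
        h = model.history
        assert h.val_loss.min() < 1e-3 * h.val_loss.iloc[0]

    def test_matches_sklearn_reference_on_linear_map(self):
        # independent cross-check against an established implementation
        from sklearn.neural_network import MLPRegressor
        Xtr, Ytr, Xva, Yva = _linear_problem(seed=1)
        model = train_mlp(Xtr, Ytr, Xva, Yva,
                          MLPSpec(input_size=8, hidden=(32,), output_size=3),
                          TrainConfig(seed=0, max_epochs=200, patience=30))
        ours = float(np.mean((predict(model, Xva) - Yva) ** 2))
        ref = MLPRegressor(hidden_layer_sizes=(32,), max_iter=2000,
                           random_state=0).fit(Xtr, Ytr)
        theirs = float(np.mean((ref.predict(Xva) - Yva) ** 2))
        assert ours < max(5.0 * theirs, 1e-3)

    def test_best_epoch_checkpoint_minimizes_validation_loss(self):
        Xtr, Ytr, Xva, Yva = _linear_problem(seed=2)
        model = train_mlp(Xtr, Ytr, Xva, Yva,
                          MLPSpec(input_size=8, hidden=(16,), output_size=3),
                          TrainConfig(seed=0, max_epochs=60, patience=10))
        h = model.history
        assert h.val_loss.idxmin() == model.best_epoch

    def test_history_records_both_metrics(self):
        Xtr, Ytr, Xva, Yva = _linear_problem(seed=3)
        model = train_mlp(Xtr, Ytr, Xva, Yva,
                          MLPSpec(input_size=8, hidden=(8,), output_size=3),
                          TrainConfig(seed=0, max_epochs=5, patience=5))
        for col in ("train_loss", "val_loss", "train_mae", "val_mae"):
            assert col in model.history.columns


class TestArchitectureSelection:
    def test_single_candidate_returned(self):
        Xtr, Ytr, Xva, Yva = _linear_problem(seed=4)
        model, tab = select_architecture([(16,)], Xtr, Ytr, Xva, Yva,
                                         TrainConfig(seed=0, max_epochs=10,
                                                     patience=5))
        assert model.spec.hidden == (16,)
        assert len(tab) == 1

    def test_smaller_model_wins_ties(self):
        Xtr, Ytr, Xva, Yva = _linear_problem(seed=5)
        cfg = TrainConfig(seed=0, max_epochs=30, patience=10)
        model, tab = select_architecture([(64, 64), (8,)], Xtr, Ytr, Xva, Yva,
                                         cfg, tolerance=10.0)
        # enormous tolerance makes every candidate admissible -> smallest wins
        assert model.spec.hidden == (8,)
        assert set(tab.columns) >= {"hidden", "n_parameters", "val_loss",
                                    "val_mae"}
        assert len(tab) == 2


class TestPredict:
    def _toy_model(self):
        Xtr, Ytr, Xva, Yva = _linear_problem(seed=6)
        scaler = LabelScaler(Ytr.min(axis=0) - 0.1, Ytr.max(axis=0) + 0.1)
        return train_mlp(Xtr, Ytr, Xva, Yva,
                         MLPSpec(input_size=8, hidden=(16,), output_size=3),
                         TrainConfig(seed=0, max_epochs=20, patience=10),
                         scaler=scaler), Xva

    def test_outputs_lie_within_configured_ranges(self):
        model, Xva = self._toy_model()
        Y = predict(model, Xva)
        assert np.all(Y >= model.scaler.mins) and np.all(Y <= model.scaler.maxs)

    def test_prediction_is_deterministic_and_fast(self):
        import time
        model, Xva = self._toy_model()
        a = predict(model, Xva[0])
        t0 = time.time()
        b = predict(model, Xva[0])
        assert time.time() - t0 < 1.0
        assert np.array_equal(a, b)

    def test_shape_mismatch_rejected(self):
        model, _ = self._toy_model()
        with pytest.raises(ValueError):
            predict(model, np.zeros(5))

    def test_serialization_round_trip(self, tmp_path):
        model, Xva = self._toy_model()
        save_model(model, tmp_path / "m")
        back = load_model(tmp_path / "m")
        assert np.max(np.abs(predict(back, Xva) - predict(model, Xva))) < 1e-8
        assert back.spec == model.spec
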