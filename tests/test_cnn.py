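"""CNN classifier: shape arithmetic, weight round-trips, objectives, trainers."""

import numpy as np
import pytest

import flamingo_ecg as fe
from flamingo_ecg.cnn import cross_entropy, forward, softmax


def _arch(window=64, n_classes=5, **kw):
    defaults = dict(n_conv_blocks=1, filters_per_block=(8,), kernel_size=7,
                    pool_size=2, dense_units=16)
    defaults.update(kw)
    return fe.CNNArchitecture(fe.CNNHyperparams(**defaults), window, n_classes)


class TestArchitecture:
    def test_documented_shape_example(self):
        # window 186, kernel 7 valid conv -> 180, pool 2 -> 90, 8 filters -> 720
        arch = _arch(window=186)
        assert arch.flat_features == 8 * 90

    def test_output_dimension_matches_classes(self):
        logits, _ = forward(_arch(n_classes=5), _arch(n_classes=5).init_params(
            np.random.default_rng(0)), np.zeros((3, 64)))
        assert logits.shape == (3, 5)

    def test_two_blocks_shape_chain(self):
        arch = _arch(window=64, n_conv_blocks=2, filters_per_block=(4, 6))
        # 64 -> 58 -> 29 ; 29 -> 23 -> 11 ; flat = 6 * 11
        assert arch.flat_features == 66

    def test_pooling_collapse_raises(self):
        with pytest.raises(fe.ArchitectureError, match="conv block"):
            _arch(window=16, n_conv_blocks=3, filters_per_block=(4, 4, 4),
                  kernel_size=9, pool_size=4)

    def test_checkpoint_round_trip(self, tmp_path):
        arch = _arch()
        params = arch.init_params(np.random.default_rng(1))
        model = fe.TrainedModel(arch, params, np.zeros(1), "adam_baseline",
                                fe.AAMI_CLASSES)
        model.save(str(tmp_path / "ck"))
        back = fe.TrainedModel.load(str(tmp_path / "ck"))
        X = np.random.default_rng(2).normal(size=(5, 64))
        assert np.allclose(model.predict_proba(X), back.predict_proba(X))


class TestWeightVector:
    @pytest.mark.parametrize("kw", [
        {}, {"n_conv_blocks": 2, "filters_per_block": (4, 6)},
        {"dense_units": 3, "kernel_size": 3},
    ])
    def test_flatten_unflatten_exact(self, kw):
        arch = _arch(**kw)
        params = arch.init_params(np.random.default_rng(0))
        w = fe.flatten_weights(params, arch.manifest)
        assert w.size == arch.n_weights
        back = fe.unflatten_weights(w, arch.manifest)
        for name, _ in arch.manifest:
            assert np.array_equal(params[name], back[name])

    def test_length_mismatch_rejected(self):
        arch = _arch()
        with pytest.raises(ValueError, match="manifest"):
            fe.unflatten_weights(np.zeros(arch.n_weights - 1), arch.manifest)


class TestObjectives:
    def test_softmax_rows_sum_to_one(self):
        logits = np.random.default_rng(0).normal(scale=8.0, size=(40, 5))
        assert np.abs(softmax(logits).sum(axis=1) - 1.0).max() < 1e-9

    def test_zero_weights_uniform_loss_five_class(self, scaled_small):
        arch = _arch()
        loss = fe.weight_objective(np.zeros(arch.n_weights), arch, scaled_small)
        assert loss == pytest.approx(np.log(5), abs=1e-9)

    def test_zero_weights_uniform_loss_binary(self):
        ds = fe.BeatDataset(
            np.random.default_rng(0).normal(size=(10, 20)),
            np.array(["N"] * 5 + ["V"] * 5, dtype=object),
            class_names=("N", "V"),
        )
        arch = fe.CNNArchitecture(
            fe.CNNHyperparams(kernel_size=3, filters_per_block=(2,), dense_units=4),
            20, 2,
        )
        loss = fe.weight_objective(np.zeros(arch.n_weights), arch, ds)
        assert loss == pytest.approx(np.log(2), abs=1e-9)

    def test_separating_weights_drive_loss_down(self):
        # one-feature toy problem: dense net reads the sign of the single input
        ds = fe.BeatDataset(
            np.array([[1.0, 1.0], [-1.0, -1.0]] * 5),
            np.array(["N", "V"] * 5, dtype=object),
            class_names=("N", "V"),
        )
        arch = fe.CNNArchitecture(
            fe.CNNHyperparams(n_conv_blocks=1, filters_per_block=(1,),
                              kernel_size=1, pool_size=2, dense_units=2),
            2, 2,
        )
        # conv is identity (kernel [1]); dense routes +/- to two units; output
        # layer maps them to the two classes, scaled hard
        params = {
            "conv0_W": np.array([[[1.0]]]), "conv0_b": np.zeros(1),
            "dense_W": np.array([[1.0, -1.0]]), "dense_b": np.array([0.0, 1.0]),
            "out_W": np.array([[1.0, -1.0], [-1.0, 1.0]]) * 50.0,
            "out_b": np.zeros(2),
        }
        w = fe.flatten_weights(params, arch.manifest)
        assert fe.weight_objective(w, arch, ds) <= 0.01

    def test_gradients_match_finite_differences(self):
        # spot-check the hand backprop on a tiny architecture
        from flamingo_ecg.cnn import _backward

        rng = np.random.default_rng(3)
        arch = _arch(window=12, kernel_size=3, filters_per_block=(2,),
                     dense_units=3, n_classes=3)
        params = arch.init_params(rng)
        X = rng.normal(size=(6, 12))
        y = rng.integers(0, 3, size=6)
        logits, cache = forward(arch, params, X)
        grads = _backward(arch, params, cache, softmax(logits), y)
        w = fe.flatten_weights(params, arch.manifest)
        g = fe.flatten_weights(grads, arch.manifest)
        eps = 1e-6
        idx = rng.choice(w.size, size=25, replace=False)
        for i in idx:
            wp, wm = w.copy(), w.copy()
            wp[i] += eps
            wm[i] -= eps
            lp = cross_entropy(forward(arch, fe.unflatten_weights(wp, arch.manifest), X)[0], y)
            lm = cross_entropy(forward(arch, fe.unflatten_weights(wm, arch.manifest), X)[0], y)
            assert g[i] == pytest.approx((lp - lm) / (2 * eps), abs=1e-4)


class TestAdamBaseline:
    def test_reaches_99_percent_on_clean_data(self, clean_dataset):
        params = fe.fit_scaler(clean_dataset)
        ds = fe.apply_scaler(clean_dataset, params)
        arch = fe.CNNArchitecture(
            fe.CNNHyperparams(epochs=30, dense_units=16), ds.window_length, 5
        )
        model = fe.train_with_adam(arch, ds, seed=0)
        assert model.accuracy(ds) >= 0.99
        assert model.history.size == 30

    def test_seeded_determinism(self, scaled_small):
        arch = _arch()
        a = fe.train_with_adam(arch, scaled_small, seed=4, epochs=3)
        b = fe.train_with_adam(arch, scaled_small, seed=4, epochs=3)
        for name, _ in arch.manifest:
            assert np.array_equal(a.params[name], b.params[name])


@pytest.fixture(scope="module")
def tiny_task():
    ds = fe.generate_dataset(
        fe.SyntheticConfig(n_per_class={"N": 30, "V": 30}, window_length=32,
                           noise_sd=0.0, seed=0)
    )
    return fe.apply_scaler(ds, fe.fit_scaler(ds))


class TestWeightModeFSA:
    def tiny_arch(self):
        return fe.CNNArchitecture(
            fe.CNNHyperparams(n_conv_blocks=1, filters_per_block=(1,),
                              kernel_size=3, pool_size=2, dense_units=4),
            32, 5,
        )

    def test_trains_separable_task(self, tiny_task):
        model = fe.train_weights_with_fsa(
            self.tiny_arch(), tiny_task,
            fe.FSAConfig(seed=0, population_size=30, max_iterations=300),
        )
        assert model.accuracy(tiny_task) >= 0.95
        assert (np.diff(model.history) <= 0).all()

    def test_seeded_determinism(self, tiny_task):
        cfg = fe.FSAConfig(seed=8, population_size=10, max_iterations=20)
        a = fe.train_weights_with_fsa(self.tiny_arch(), tiny_task, cfg)
        b = fe.train_weights_with_fsa(self.tiny_arch(), tiny_task, cfg)
        for name, _ in a.arch.manifest:
            assert np.array_equal(a.params[name], b.params[name])

    def test_refuses_oversized_network(self, scaled_small):
        big = fe.CNNArchitecture(
            fe.CNNHyperparams(filters_per_block=(32,), dense_units=64),
            scaled_small.window_length, 5,
        )
        assert big.n_weights > 5000
        with pytest.raises(ValueError, match="ceiling"):
            fe.train_weights_with_fsa(big, scaled_small, fe.FSAConfig(seed=0))


class TestSearchSpace:
    def test_encode_decode_round_trip(self):
        space = fe.default_search_space()
        h = fe.CNNHyperparams(n_conv_blocks=1, filters_per_block=(8,),
                              kernel_size=5, dense_units=12, dropout_rate=0.25,
                              learning_rate=1e-3)
        back = space.decode(space.encode(h))
        assert back.filters_per_block == (8,)
        assert back.kernel_size == 5
        assert back.dense_units == 12
        assert back.dropout_rate == pytest.approx(0.25)
        assert back.learning_rate == pytest.approx(1e-3)

    def test_decode_snaps_out_of_grid_positions(self):
        space = fe.default_search_space()
        far = space.upper_bounds + 10.0
        h = space.decode(far)
        assert h.filters_per_block == (16,)
        assert h.kernel_size == 9
        assert h.dropout_rate == pytest.approx(0.5)
        assert h.learning_rate == pytest.approx(3e-2)

    def test_identical_snapped_positions_share_objective_value(self, noisy_dataset):
        train, val = fe.split_by_training_percentage(noisy_dataset, 70, seed=0)
        sc = fe.fit_scaler(train)
        train_s, val_s = fe.apply_scaler(train, sc), fe.apply_scaler(val, sc)
        space = fe.default_search_space()
        pos = space.encode(fe.CNNHyperparams(filters_per_block=(4,), dense_units=8))
        jittered = pos.copy()
        jittered[0] += 0.3  # rounds back to the same filter count
        a = fe.hyper_objective(pos, space, train_s, val_s, budget_epochs=2)
        b = fe.hyper_objective(jittered, space, train_s, val_s, budget_epochs=2)
        assert a == b
        assert 0.0 <= a <= 1.0


class TestTuning:
    def test_default_config_beats_degenerate(self, noisy_dataset):
        train, val = fe.split_by_training_percentage(noisy_dataset, 70, seed=0)
        sc = fe.fit_scaler(train)
        train_s, val_s = fe.apply_scaler(train, sc), fe.apply_scaler(val, sc)
        space = fe.default_search_space()
        sensible = space.encode(fe.CNNHyperparams(
            filters_per_block=(8,), kernel_size=7, dense_units=16,
            dropout_rate=0.1, learning_rate=3e-3))
        degenerate = space.encode(fe.CNNHyperparams(
            filters_per_block=(2,), kernel_size=3, dense_units=4,
            dropout_rate=0.49, learning_rate=1e-4))
        errs = {name: [] for name in ("sensible", "degenerate")}
        for s in range(5):
            errs["sensible"].append(fe.hyper_objective(
                sensible, space, train_s, val_s, budget_epochs=4, inner_seed=s))
            errs["degenerate"].append(fe.hyper_objective(
                degenerate, space, train_s, val_s, budget_epochs=4, inner_seed=s))
        assert np.median(errs["sensible"]) <= np.median(errs["degenerate"])

    def test_tuner_reproducible_and_in_space(self, noisy_dataset):
        train, val = fe.split_by_training_percentage(noisy_dataset, 70, seed=1)
        sc = fe.fit_scaler(train)
        train_s, val_s = fe.apply_scaler(train, sc), fe.apply_scaler(val, sc)
        space = fe.default_search_space()
        cfg = fe.FSAConfig(seed=2, population_size=4, max_iterations=2)
        h1, m1, r1 = fe.tune_hyperparams_with_fsa(
            space, train_s, val_s, cfg, budget_epochs=2, final_epochs=3)
        h2, _, r2 = fe.tune_hyperparams_with_fsa(
            space, train_s, val_s, cfg, budget_epochs=2, final_epochs=3)
        assert h1 == h2
        assert r1.best_fitness == r2.best_fitness
        assert 2 <= h1.filters_per_block[0] <= 16
        assert 3 <= h1.kernel_size <= 9
        assert 1e-4 <= h1.learning_rate <= 3e-2
        assert m1.mode == "hyper_fsa"

    def test_budget_ceiling_refusal(self, noisy_dataset):
        train, val = fe.split_by_training_percentage(noisy_dataset, 70, seed=0)
        space = fe.default_search_space()
        with pytest.raises(ValueError, match="ceiling"):
            fe.tune_hyperparams_with_fsa(
                space, train, val, fe.FSAConfig(seed=0, population_size=30,
                                                max_iterations=500),
                budget_epochs=10,
            )
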