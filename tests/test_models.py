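import numpy as np
import pytest

from landsdm.models import (
    ModelError,
    SpeciesClassifier,
    SpeciesHead,
    TrainConfig,
    cross_entropy,
    fit_bt_baseline,
    fit_rf_baseline,
    load_checkpoint,
    lr_schedule,
    reference_train_config,
    predict,
    save_checkpoint,
    softmax,
    softmax_head,
    train,
)
from landsdm.synthetic import generate_world


def brute_force_softmax(logits):
    """Direct evaluation without max-subtraction."""
    e = np.exp(np.asarray(logits, dtype=float))
    return e / e.sum()


class TestSoftmaxHead:
    def test_equal_logits_uniform(self):
        head = SpeciesHead(np.zeros((3, 4)), np.zeros(4))
        probs = softmax_head(np.ones(3), head)
        np.testing.assert_allclose(probs, 0.25)

    def test_closed_form_two_species(self):
        probs = softmax(np.array([[0.0, np.log(3.0)]]))
        np.testing.assert_allclose(probs[0], [0.25, 0.75])

    def test_shift_invariance(self, rng):
        logits = rng.standard_normal((5, 7))
        np.testing.assert_allclose(
            softmax(logits), softmax(logits + 123.4), atol=1e-12
        )

    def test_agrees_with_brute_force(self, rng):
        for _ in range(50):
            logits = rng.standard_normal(6) * 3
            np.testing.assert_allclose(
                softmax(logits[None])[0], brute_force_softmax(logits), atol=1e-10
            )

    def test_overflow_safe(self):
        probs = softmax(np.array([[1000.0, 0.0]]))
        np.testing.assert_allclose(probs[0], [1.0, 0.0], atol=1e-12)

    def test_nonfinite_logits_raise(self):
        with pytest.raises(ModelError):
            softmax(np.array([[np.nan, 0.0]]))

    def test_feature_dim_mismatch_raises(self):
        head = SpeciesHead(np.zeros((3, 4)), np.zeros(4))
        with pytest.raises(ModelError):
            softmax_head(np.ones(5), head)


class TestCrossEntropy:
    def test_certain_prediction_zero_loss(self):
        assert cross_entropy(np.array([[0.0, 1.0]]), [1]) == pytest.approx(0.0)

    def test_uniform_over_4520_species(self):
        m = 4520
        probs = np.full((1, m), 1.0 / m)
        assert cross_entropy(probs, [17]) == pytest.approx(np.log(m))
        assert cross_entropy(probs, [17]) == pytest.approx(8.4164, abs=1e-3)

    def test_monotone_in_true_probability(self):
        losses = []
        for p in (0.1, 0.3, 0.6, 0.9):
            probs = np.array([[p, 1 - p]])
            losses.append(cross_entropy(probs, [0]))
        assert losses == sorted(losses, reverse=True)

    def test_zero_probability_clamped(self):
        loss = cross_entropy(np.array([[1.0, 0.0]]), [1])
        assert np.isfinite(loss)
        assert loss == pytest.approx(-np.log(1e-12))

    def test_gradient_check_with_softmax(self, rng):
        """Analytic gradient of CE(softmax(logits)) vs finite differences."""
        logits = rng.standard_normal(5)
        truth = 2
        probs = softmax(logits[None])[0]
        analytic = probs.copy()
        analytic[truth] -= 1.0
        eps = 1e-6
        for j in range(5):
            up, down = logits.copy(), logits.copy()
            up[j] += eps
            down[j] -= eps
            num = (
                cross_entropy(softmax(up[None]), [truth])
                - cross_entropy(softmax(down[None]), [truth])
            ) / (2 * eps)
            assert num == pytest.approx(analytic[j], abs=1e-5)


class TestLrSchedule:
    def test_reference_schedule_values(self):
        cfg = reference_train_config()
        assert lr_schedule(0, cfg) == pytest.approx(0.1)
        assert lr_schedule(100, cfg) == pytest.approx(0.01)
        assert lr_schedule(170, cfg) == pytest.approx(1e-5)

    def test_reference_defaults(self):
        cfg = reference_train_config()
        assert cfg.dropout == 0.7
        assert cfg.momentum == 0.9
        assert cfg.validation_period == 5
        assert cfg.lr_drop_epochs == (90, 130, 150, 170)

    def test_drop_epochs_must_increase(self):
        with pytest.raises(ModelError):
            TrainConfig(lr_drop_epochs=(10, 10))


@pytest.fixture(scope="module")
def tiny_world():
    return generate_world(
        seed=21, grid_size=64, n_species=6, n_occurrences=400,
        structure_fraction=0.5, tail_exponent=0.3, window=3,
    )


@pytest.fixture(scope="module")
def tiny_trained(tiny_world):
    w = tiny_world
    model = SpeciesClassifier(
        n_layers=len(w.stack), patch_size=8, channels=(6, 12), pool="gap"
    )
    cfg = TrainConfig(
        initial_lr=0.05, lr_drop_epochs=(8,), dropout=0.1,
        max_epochs=10, validation_period=5, seed=0,
    )
    _, history = train(model, w.occurrences, w.stack, cfg, transform="none")
    return w, model, history


class TestTraining:
    def test_validation_every_five_epochs(self, tiny_trained):
        _, _, history = tiny_trained
        for entry in history:
            assert ("val_msa" in entry) == (entry["epoch"] % 5 == 0)

    def test_loss_decreases(self, tiny_trained):
        _, _, history = tiny_trained
        assert history[-1]["loss"] < history[0]["loss"]

    def test_checkpoint_is_validation_argmax(self, tiny_world):
        w = tiny_world
        model = SpeciesClassifier(
            n_layers=len(w.stack), patch_size=8, channels=(6, 12), pool="gap"
        )
        cfg = TrainConfig(
            initial_lr=0.05, lr_drop_epochs=(8,), dropout=0.1,
            max_epochs=10, validation_period=5, seed=1,
        )
        _, history = train(model, w.occurrences, w.stack, cfg, transform="none")
        best = max(h["val_msa"] for h in history if "val_msa" in h)
        # recompute the returned model's validation score (transform-free
        # path is deterministic)
        from landsdm.evaluation import compute_ranks, mean_species_topk

        val = w.occurrences.subset("validation")
        bundle = predict(model, val[["lon", "lat"]].to_numpy(), w.stack)
        idx = {s: i for i, s in enumerate(bundle.label_space)}
        truths = np.array([idx[s] for s in val["species_id"]])
        ranks = compute_ranks(bundle.probabilities, truths)
        k = min(30, len(bundle.label_space))
        _, msa = mean_species_topk(ranks, truths, k)
        assert msa == pytest.approx(best, abs=1e-9)

    def test_single_species_degenerate_loss_zero(self, tiny_world):
        w = tiny_world
        records = w.occurrences.records.copy()
        records["species_id"] = 0
        from landsdm.synthetic import OccurrenceSet

        occ = OccurrenceSet(records)
        model = SpeciesClassifier(
            n_layers=len(w.stack), patch_size=8, channels=(4, 8), pool="gap"
        )
        cfg = TrainConfig(
            initial_lr=0.01, lr_drop_epochs=(5,), dropout=0.0,
            max_epochs=5, validation_period=5, seed=0,
        )
        _, history = train(model, occ, w.stack, cfg)
        assert history[-1]["loss"] < 1e-6

    def test_deterministic_under_seed(self, tiny_world):
        w = tiny_world
        cfg = TrainConfig(
            initial_lr=0.05, lr_drop_epochs=(4,), dropout=0.2,
            max_epochs=4, validation_period=2, seed=9,
        )
        histories = []
        for _ in range(2):
            model = SpeciesClassifier(
                n_layers=len(w.stack), patch_size=8, channels=(4, 8), pool="gap"
            )
            _, history = train(model, w.occurrences, w.stack, cfg, "rotation")
            histories.append(history)
        assert histories[0] == histories[1]

    def test_empty_validation_raises(self, tiny_world):
        from landsdm.synthetic import OccurrenceSet

        w = tiny_world
        records = w.occurrences.records.copy()
        records["partition"] = "train"
        model = SpeciesClassifier(n_layers=len(w.stack), patch_size=8,
                                  channels=(4, 8))
        with pytest.raises(ModelError):
            train(model, OccurrenceSet(records), w.stack, TrainConfig())


class TestPredict:
    def test_probabilities_sum_to_one(self, tiny_trained):
        w, model, _ = tiny_trained
        test = w.occurrences.subset("test")
        bundle = predict(model, test[["lon", "lat"]].to_numpy(), w.stack)
        np.testing.assert_allclose(bundle.probabilities.sum(axis=1), 1.0)

    def test_identical_points_identical_predictions(self, tiny_trained):
        w, model, _ = tiny_trained
        pts = np.array([[30.0, 30.0], [30.0, 30.0]])
        bundle = predict(model, pts, w.stack)
        np.testing.assert_array_equal(
            bundle.probabilities[0], bundle.probabilities[1]
        )

    def test_unfitted_model_raises(self, tiny_world):
        w = tiny_world
        model = SpeciesClassifier(n_layers=len(w.stack), patch_size=8,
                                  channels=(4, 8))
        with pytest.raises(ModelError):
            predict(model, np.array([[30.0, 30.0]]), w.stack)

    def test_punctual_model_blind_to_neighborhood(self, tiny_world):
        """The constant-tensor construction makes predictions depend only on
        the center-pixel vector, whatever surrounds it."""
        w = tiny_world
        model = SpeciesClassifier(
            n_layers=len(w.stack), patch_size=8, channels=(4, 8),
            input_mode="punctual", pool="gap",
        )
        cfg = TrainConfig(initial_lr=0.05, lr_drop_epochs=(4,), dropout=0.1,
                          max_epochs=5, validation_period=5, seed=2)
        train(model, w.occurrences, w.stack, cfg)
        from landsdm.models import _materialize, _predict_probs, extract_dataset
        from landsdm.ablation import as_spec

        pts = w.occurrences.subset("test")[["lon", "lat"]].to_numpy()[:4]
        vecs = extract_dataset(pts, w.stack, 8, "punctual")
        probs = _predict_probs(model, vecs, as_spec("none"), (0, 3))
        # permuting non-center pixels of the constant tensors changes nothing
        tensors = _materialize(vecs, 8)
        rng = np.random.default_rng(0)
        scrambled = tensors + 0.0
        scrambled[:, :, 0, 0], scrambled[:, :, 3, 3] = (
            tensors[:, :, 3, 3], tensors[:, :, 0, 0],
        )
        probs2 = _predict_probs(model, scrambled, as_spec("none"), (0, 3))
        np.testing.assert_allclose(probs, probs2, atol=1e-12)


class TestCheckpoint:
    def test_round_trip(self, tiny_trained, tmp_path):
        w, model, _ = tiny_trained
        path = str(tmp_path / "model.npz")
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        test = w.occurrences.subset("test")[["lon", "lat"]].to_numpy()
        a = predict(model, test, w.stack)
        b = predict(back, test, w.stack)
        np.testing.assert_allclose(a.probabilities, b.probabilities, atol=1e-12)
        assert back.transform_kind == model.transform_kind
        assert back.history == model.history


class TestBaselines:
    def test_documented_hyperparameters_are_defaults(self, rng):
        x = rng.standard_normal((30, 4))
        y = rng.integers(0, 3, size=30)
        rf = fit_rf_baseline(x, y)
        assert rf.estimator.n_estimators == 100
        assert rf.estimator.max_depth == 16
        bt = fit_bt_baseline(x, y)
        assert bt.estimator.max_depth == 2

    def test_separable_toy_data_perfect_training_accuracy(self, rng):
        x = np.vstack([rng.normal(-5, 0.1, (20, 2)), rng.normal(5, 0.1, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        for fit in (fit_rf_baseline, fit_bt_baseline):
            model = fit(x, y)
            preds = model.predict_bundle(x).probabilities.argmax(axis=1)
            assert (preds == y).all()

    def test_rows_are_distributions(self, rng):
        x = rng.standard_normal((40, 3))
        y = rng.integers(0, 4, size=40)
        bundle = fit_rf_baseline(x, y).predict_bundle(rng.standard_normal((10, 3)))
        assert (bundle.probabilities >= 0).all()
        np.testing.assert_allclose(bundle.probabilities.sum(axis=1), 1.0)

    def test_single_class_raises(self, rng):
        x = rng.standard_normal((10, 3))
        with pytest.raises(ModelError):
            fit_rf_baseline(x, np.zeros(10, dtype=int))

    def test_label_space_padding(self, rng):
        x = rng.standard_normal((20, 3))
        y = rng.integers(0, 2, size=20)
        bundle = fit_rf_baseline(x, y, label_space=[0, 1, 2, 3]).predict_bundle(x[:5])
        assert bundle.probabilities.shape == (5, 4)
        np.testing.assert_array_equal(bundle.probabilities[:, 2:], 0.0)


class TestEndToEndLearnability:
    def test_both_networks_exceed_chance_fivefold_on_punctual_world(self):
        """On a world of purely punctual species (one layer per species,
        thresholded niches), both the tensor model and its punctual twin
        reach MSA_1 at least 5x the 1/m chance level."""
        from landsdm.raster import RasterStack
        from landsdm.synthetic import (
            SpeciesNiche,
            generate_grf_layer,
            sample_occurrences,
            split_occurrences,
        )

        layers = [
            generate_grf_layer((128, 128), 8.0, seed=100 + i, name=f"env_{i}")
            for i in range(6)
        ]
        stack = RasterStack(layers, expanded=True)
        niches = [
            SpeciesNiche(
                i, "punctual",
                {f"env_{i % 6}": 4.0 * (1.0 if i < 6 else -1.0)},
                intercept=-6.0,
            )
            for i in range(12)
        ]
        occ = sample_occurrences(stack, niches, 2000, 0.0, seed=1)
        occ = split_occurrences(occ, seed=2)
        m = len(occ.species_ids)
        test = occ.subset("test")
        pts = test[["lon", "lat"]].to_numpy()
        truths = test["species_id"].to_numpy()
        from landsdm.evaluation import compute_ranks, mean_species_topk

        cfg = TrainConfig(
            initial_lr=0.1, lr_drop_epochs=(12,), dropout=0.1,
            max_epochs=15, validation_period=5, seed=0,
        )
        for input_mode in ("tensor", "punctual"):
            model = SpeciesClassifier(
                n_layers=len(stack), patch_size=8, channels=(8, 16),
                input_mode=input_mode,
            )
            train(model, occ, stack, cfg)
            bundle = predict(model, pts, stack)
            ranks = compute_ranks(bundle.probabilities, truths)
            _, msa1 = mean_species_topk(ranks, truths, 1)
            assert msa1 >= 5.0 / m, f"{input_mode}: MSA_1={msa1:.3f} < {5 / m:.3f}"
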