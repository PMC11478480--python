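"""Model construction, the training protocols, and the serial pipeline.

Networks here use reduced widths/sequence lengths so the tests exercise the
full code paths quickly; architecture defaults are asserted separately.
"""

import copy

import numpy as np
import pytest

import gaitphase as gp
from gaitphase import models as gm
from gaitphase._recurrent import mse, softmax_xent
from gaitphase.signal_io import DataError


TINY_WC = dict(hidden1=12, hidden2=8, dense=8, seq_len=20, hop=20,
               max_epochs=6, folds=1, batch_size=64, seed=5)
TINY_PH = dict(hidden1=16, hidden2=8, seq_len=15, hop=8,
               max_epochs=25, batch_size=100, seed=5)


@pytest.fixture(scope="module")
def quiet_dataset():
    """One-subject noiseless dataset: easiest possible learning target."""
    cohort = gp.make_cohort(1, 13)
    p = copy.deepcopy(cohort[0])
    p.noise_sd = 0.0
    p.jitter_sd_ms = 0.0
    return gp.simulate_protocol([p], gp.default_scripts(8, 4), 3)


@pytest.fixture(scope="module")
def quiet_split(quiet_dataset):
    return gp.make_split(quiet_dataset, test_trial_index=3, val_fraction=0.2)


@pytest.fixture(scope="module")
def tiny_wc_model(tiny_split):
    return gm.train_wc_classifier(tiny_split, gm.WcClassifierConfig(**TINY_WC))


@pytest.fixture(scope="module")
def quiet_phase_model(quiet_split):
    cfg = gm.PhaseEstimatorConfig(variant=2, **TINY_PH)
    return gm.train_phase_estimator(quiet_split, cfg)


class TestBuilders:
    def test_default_output_dimensions(self):
        wc = gm.build_wc_classifier(gm.WcClassifierConfig())
        x = np.zeros((2, 100, 10))
        assert wc.forward(x).shape == (2, 5)
        ph = gm.build_phase_estimator(gm.PhaseEstimatorConfig())
        assert ph.forward(np.zeros((2, 25, 19))).shape == (2, 2)

    def test_parameter_counts_match_stack(self):
        cfg = gm.WcClassifierConfig()
        net = gm.build_wc_classifier(cfg)

        def bilstm(d, h):
            return 2 * 4 * h * (d + h + 1)

        expected = (
            bilstm(10, 128) + bilstm(256, 64)
            + (128 + 1) * 64 + (64 + 1) * 5
        )
        assert net.n_params() == expected

    def test_same_seed_same_initial_weights(self):
        a = gm.build_phase_estimator(gm.PhaseEstimatorConfig(seed=3))
        b = gm.build_phase_estimator(gm.PhaseEstimatorConfig(seed=3))
        for pa, pb in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa, pb)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            gm.WcClassifierConfig(hidden1=0)
        with pytest.raises(ValueError):
            gm.WcClassifierConfig(dropout=(1.5, 0.2))
        with pytest.raises(ValueError):
            gm.PhaseEstimatorConfig(output=3)

    def test_variant_sets_input_width(self):
        assert gm.PhaseEstimatorConfig(variant=4).input_width == 9


class TestEarlyStopping:
    def test_worsening_validation_stops_after_patience(self, monkeypatch):
        calls = {"n": 0}

        def fake_eval(net, X, y, loss_fn, batch):
            calls["n"] += 1
            return float(calls["n"])  # strictly worsening

        monkeypatch.setattr(gm, "_eval_loss", fake_eval)
        rng = np.random.default_rng(0)
        net = gm.build_wc_classifier(
            gm.WcClassifierConfig(hidden1=4, hidden2=4, dense=4, seq_len=5)
        )
        X = rng.normal(size=(20, 5, 10))
        y = rng.integers(0, 5, 20)
        hist = gm.fit_network(
            net, softmax_xent, X, y, X[:4], y[:4],
            max_epochs=50, patience=5, rng=rng,
        )
        assert len(hist) == 6  # first epoch sets the best, then 5 bad epochs

    def test_restores_parameters_of_best_epoch(self, monkeypatch):
        losses = iter([1.0, 0.1, 5.0, 6.0])
        snapshots = []

        def fake_eval(net, X, y, loss_fn, batch):
            snapshots.append(net.get_state())
            return next(losses)

        monkeypatch.setattr(gm, "_eval_loss", fake_eval)
        rng = np.random.default_rng(0)
        net = gm.build_phase_estimator(
            gm.PhaseEstimatorConfig(hidden1=4, hidden2=4, seq_len=5, variant=4)
        )
        X = rng.normal(size=(12, 5, 9))
        y = rng.normal(size=(12, 2))
        gm.fit_network(net, mse, X, y, X, y, max_epochs=4, patience=2, rng=rng)
        # epoch 2 had the best validation loss; its parameters must be live
        for p, s in zip(net.params(), snapshots[1]):
            np.testing.assert_array_equal(p, s)

    def test_history_loss_decreases_on_separable_data(self, tiny_wc_model):
        hist = tiny_wc_model.history
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]


class TestWcClassifierProtocol:
    def test_missing_class_raises(self, quiet_dataset):
        lw_only = [r for r in quiet_dataset if r.scenario_id == "sc1"]
        split = gp.make_split(lw_only, test_trial_index=3)
        with pytest.raises(DataError, match="SA"):
            gm.train_wc_classifier(split, gm.WcClassifierConfig(**TINY_WC))

    def test_cv_produces_fold_histories(self, tiny_split):
        cfg = gm.WcClassifierConfig(**{**TINY_WC, "folds": 3, "max_epochs": 2})
        model = gm.train_wc_classifier(tiny_split, cfg)
        assert len(model.fold_histories) == 3
        assert all(len(h) >= 1 for h in model.fold_histories)

    def test_training_deterministic_given_seed(self, tiny_split):
        cfg = gm.WcClassifierConfig(**{**TINY_WC, "max_epochs": 2})
        a = gm.train_wc_classifier(tiny_split, cfg)
        b = gm.train_wc_classifier(tiny_split, cfg)
        assert a.history == b.history
        for pa, pb in zip(a.network.params(), b.network.params()):
            np.testing.assert_array_equal(pa, pb)


class TestPredictWc:
    def test_probabilities_and_argmax(self, tiny_wc_model, tiny_split, tiny_stats):
        X, y = gm._classifier_windows(
            tiny_split.test, tiny_stats, tiny_wc_model.config.seq_len, 40
        )
        probs, labels = gm.predict_wc(tiny_wc_model, X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(labels, probs.argmax(axis=1))

    def test_shape_mismatch_raises(self, tiny_wc_model):
        with pytest.raises(ValueError, match="shape"):
            gm.predict_wc(tiny_wc_model, np.zeros((3, 7, 10)))

    def test_separable_fixture_high_accuracy(self):
        # class index encoded as a constant signal level: trivially separable
        rng = np.random.default_rng(0)
        cfg = gm.WcClassifierConfig(
            hidden1=12, hidden2=8, dense=8, seq_len=10, max_epochs=60,
            batch_size=50, folds=1, seed=1,
        )
        y = rng.integers(0, 5, 400)
        X = np.zeros((400, 10, 10))
        X[:, :, :3] = y[:, None, None] / 4.0
        X += rng.normal(0, 0.01, X.shape)
        net = gm.build_wc_classifier(cfg)
        gm.fit_network(net, softmax_xent, X[:300], y[:300], X[300:], y[300:],
                       batch_size=50, max_epochs=60, patience=8,
                       rng=np.random.default_rng(2))
        model = gm.TrainedModel(network=net, config=cfg, kind="wc")
        _, labels = gm.predict_wc(model, X[300:])
        assert np.mean(labels == y[300:]) > 0.95


class TestPhaseEstimatorProtocol:
    def test_easy_task_reaches_low_validation_mse(self, quiet_phase_model):
        assert quiet_phase_model.history[-1]["val_loss"] < 0.05

    def test_variant_stored_in_metadata(self, quiet_phase_model):
        assert quiet_phase_model.feature_variant == 2

    def test_deterministic_given_seed(self, quiet_split):
        cfg = gm.PhaseEstimatorConfig(variant=4, **{**TINY_PH, "max_epochs": 2})
        a = gm.train_phase_estimator(quiet_split, cfg)
        b = gm.train_phase_estimator(quiet_split, cfg)
        assert a.history == b.history


class TestSaveLoad:
    def test_roundtrip(self, quiet_phase_model, tmp_path):
        path = tmp_path / "model.npz"
        quiet_phase_model.save(path)
        back = gm.TrainedModel.load(path)
        for pa, pb in zip(quiet_phase_model.network.params(), back.network.params()):
            np.testing.assert_array_equal(pa, pb)
        assert back.config == quiet_phase_model.config
        assert back.history == quiet_phase_model.history
        np.testing.assert_array_equal(
            back.norm_stats.channel_min, quiet_phase_model.norm_stats.channel_min
        )


class TestPipeline:
    def test_phase_in_range_and_validity(self, quiet_split, quiet_phase_model):
        rec = quiet_split.test_recordings[0]
        res = gm.run_pipeline(rec, quiet_phase_model, hop=5)
        est = res.phase_pred[res.valid]
        assert np.all((est >= 0) & (est < 100))
        # warm-up samples are never extrapolated
        assert not res.valid[: quiet_phase_model.config.seq_len - 1].any()
        assert np.isnan(res.phase_pred[~res.valid]).all()

    def test_variant2_ignores_classifier(self, quiet_split, quiet_phase_model, tiny_wc_model):
        rec = quiet_split.test_recordings[0]
        with pytest.warns(UserWarning, match="ignores"):
            with_wc = gm.run_pipeline(rec, quiet_phase_model, tiny_wc_model, hop=7)
        without = gm.run_pipeline(rec, quiet_phase_model, None, hop=7)
        np.testing.assert_array_equal(
            with_wc.phase_pred[with_wc.valid], without.phase_pred[without.valid]
        )

    def test_variant_needing_wc_without_model_raises(self, quiet_split):
        cfg = gm.PhaseEstimatorConfig(variant=1, **{**TINY_PH, "max_epochs": 1})
        model = gm.train_phase_estimator(quiet_split, cfg)
        with pytest.raises(ValueError, match="classifier"):
            gm.run_pipeline(quiet_split.test_recordings[0], model, None)

    def test_noiseless_median_error_small(self, quiet_split, quiet_phase_model):
        errs = []
        for rec in quiet_split.test_recordings:
            res = gm.run_pipeline(rec, quiet_phase_model, hop=3)
            idx = res.eval_indices
            e = gp.circular_phase_error(res.phase_pred[idx], np.asarray(rec.phase)[idx])
            errs.append(np.abs(e))
        assert np.median(np.concatenate(errs)) < 5.0
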