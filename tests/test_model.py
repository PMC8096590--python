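"""Network assembly, gradients, training contract, metrics."""

import numpy as np
import pandas as pd
import pytest

from kecnet import nn
from kecnet.model import (
    KecNetConfig,
    TrainConfig,
    build_baseline_cnn,
    build_kecnet,
    count_parameters,
    evaluate,
    predict,
    train,
)
from kecnet.sinc import sinc_param_gain
from kecnet.synth import synth_dataset

TINY = KecNetConfig(
    input_length=64, sample_rate=360, n_sinc_filters=4, sinc_kernel_length=15,
    baseline_kernel_length=8, conv_filters=6, n_classes=3, cv_fusion=True,
    class_order=("N", "S", "V"),
)


def _tiny_batch(n=6, length=64, n_classes=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, length))
    cv = rng.random(n) * 0.4
    y = np.eye(n_classes)[rng.integers(0, n_classes, n)]
    return X, cv, y


class TestArchitecture:
    def test_softmax_rows_sum_to_one(self):
        model = build_kecnet(TINY, seed=0, dtype=np.float64)
        X, cv, _ = _tiny_batch()
        probs = model.predict_proba(X, cv)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.shape == (6, 3)

    def test_cv_fusion_changes_head_width(self):
        from dataclasses import replace

        fused = build_kecnet(TINY, seed=0)
        plain = build_kecnet(replace(TINY, cv_fusion=False), seed=0)
        assert fused.head_layers[0].params["W"].shape[0] == TINY.conv_filters + 1
        assert plain.head_layers[0].params["W"].shape[0] == TINY.conv_filters

    def test_sinc_layer_param_count_is_2f(self):
        for L in (65, 129, 251):
            from dataclasses import replace

            cfg = replace(TINY, sinc_kernel_length=L, n_sinc_filters=32)
            model = build_kecnet(cfg, seed=0)
            assert model.sinc_layer.n_params == 64

    def test_baseline_first_layer_weight_count(self):
        model = build_baseline_cnn(KecNetConfig(), seed=0)
        first = model.feature_layers[0]
        assert first.params["W"].size == 32 * 32
        assert first.params["b"].size == 32

    def test_baseline_tail_matches_kecnet(self):
        kec = build_kecnet(TINY, seed=0)
        base = build_baseline_cnn(TINY, seed=0)
        for a, b in zip(kec.feature_layers[1:], base.feature_layers[1:]):
            assert type(a) is type(b)
            for name in a.params:
                assert a.params[name].shape == b.params[name].shape

    def test_incompatible_input_length_rejected(self):
        with pytest.raises(ValueError, match="multiple of 4"):
            KecNetConfig(input_length=3602)
        model = build_kecnet(TINY, seed=0)
        with pytest.raises(ValueError, match="length"):
            model.forward(np.zeros((2, 100)), np.zeros(2))

    def test_kecnet_total_below_matched_baseline(self):
        """Sinc first layer undercuts a free-tap layer of the same length."""
        from dataclasses import replace

        cfg = replace(KecNetConfig(), baseline_kernel_length=251)
        _, kec_total = count_parameters(build_kecnet(cfg, seed=0))
        _, base_total = count_parameters(build_baseline_cnn(cfg, seed=0))
        assert kec_total < base_total
        assert base_total - kec_total == 32 * 251 + 32 - 64


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Every layer's backward agrees with central differences."""
        for builder in (build_kecnet, build_baseline_cnn):
            model = builder(TINY, seed=3, dtype=np.float64)
            for layer in model.layers:
                if isinstance(layer, nn.Dropout):
                    layer.rate = 0.0
            X, cv, y = _tiny_batch()

            def loss():
                logits = model.forward(X, cv, training=True)
                return nn.cross_entropy_with_grad(logits, y)[0]

            logits = model.forward(X, cv, training=True)
            _, dlog, _ = nn.cross_entropy_with_grad(logits, y)
            model.backward(dlog)
            for li, layer in enumerate(model.layers):
                for name, p in layer.params.items():
                    flat = p.ravel()
                    picks = np.random.default_rng(li).choice(
                        flat.size, size=min(4, flat.size), replace=False)
                    for i in picks:
                        eps, old = 1e-6, flat[i]
                        flat[i] = old + eps
                        lp = loss()
                        flat[i] = old - eps
                        lm = loss()
                        flat[i] = old
                        num = (lp - lm) / (2 * eps)
                        ana = layer.grads[name].ravel()[i]
                        scale = max(abs(num), abs(ana), 1e-8)
                        assert abs(num - ana) / scale < 1e-4, \
                            f"{type(layer).__name__}.{name}[{i}]"

    def test_sinc_cutoffs_stay_valid_under_training(self):
        ds = synth_dataset(n_per_class=10, duration_s=10, seed=0)
        from dataclasses import replace

        cfg = replace(KecNetConfig(), n_sinc_filters=8, sinc_kernel_length=65)
        model = build_kecnet(cfg, seed=0)
        trained = train(model, ds, TrainConfig(epochs=2, learning_rate=1e-2, seed=0))
        cut = trained.model.sinc_layer.current_cutoffs()
        assert np.all(cut[:, 0] >= 0)
        assert np.all(cut[:, 0] < cut[:, 1])
        assert np.all(cut[:, 1] <= 180.0)


class TestTraining:
    def test_history_contract_and_determinism(self):
        ds = synth_dataset(n_per_class=10, seed=1)
        from dataclasses import replace

        cfg = replace(TINY, input_length=3600, n_classes=5,
                      class_order=("N", "S", "V", "F", "Q"))
        tc = TrainConfig(epochs=2, seed=4)
        t1 = train(build_kecnet(cfg, seed=4), ds, tc)
        t2 = train(build_kecnet(cfg, seed=4), ds, tc)
        assert list(t1.history.columns) == ["epoch", "train_loss", "train_acc",
                                            "val_loss", "val_acc"]
        assert len(t1.history) == 2
        assert np.isfinite(t1.history.train_loss).all()
        for l1, l2 in zip(t1.model.layers, t2.model.layers):
            for name in l1.params:
                np.testing.assert_array_equal(l1.params[name], l2.params[name])

    def test_missing_split_rejected(self):
        ds = synth_dataset(n_per_class=10, seed=1)
        ds.split[:] = "train"  # wipe out the validation split
        with pytest.raises(ValueError, match="split"):
            train(build_kecnet(KecNetConfig(), seed=0), ds, TrainConfig(epochs=1))


class TestPredict:
    def test_probability_contract(self):
        model = build_kecnet(TINY, seed=1)
        X, cv, _ = _tiny_batch(n=4)
        probs, labels = predict(model, X, cv)
        assert probs.shape == (4, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert set(labels) <= {"N", "S", "V"}

    def test_pure_function_on_duplicates(self):
        model = build_kecnet(TINY, seed=1)
        X, cv, _ = _tiny_batch(n=1)
        X2 = np.repeat(X, 3, axis=0)
        cv2 = np.repeat(cv, 3)
        probs, _ = predict(model, X2, cv2)
        np.testing.assert_array_equal(probs[0], probs[1])
        np.testing.assert_array_equal(probs[0], probs[2])

    def test_argmax_tie_toward_lower_class_index(self):
        probs = np.array([[0.4, 0.4, 0.2]])
        assert probs.argmax(axis=1)[0] == 0  # documented tie rule


class TestEvaluate:
    def test_perfect_predictions(self):
        y = ["N", "S", "V", "F", "Q"] * 3
        m = evaluate(y, y)
        assert m.acc == m.sen == m.pre == 1.0
        assert m.confusion.sum() == 15

    def test_two_class_hand_computed(self):
        """Confusion [[8,2],[1,9]]: ACC .85, SEN .85, PRE ~.8535."""
        y_true = ["N"] * 10 + ["S"] * 10
        y_pred = ["N"] * 8 + ["S"] * 2 + ["N"] * 1 + ["S"] * 9
        m = evaluate(y_true, y_pred, class_order=("N", "S"))
        assert m.acc == pytest.approx(17 / 20)
        assert m.sen == pytest.approx((0.8 + 0.9) / 2)
        assert m.pre == pytest.approx((8 / 9 + 9 / 11) / 2, abs=1e-4)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        y_true = rng.choice(list("NSVFQ"), 60)
        y_pred = rng.choice(list("NSVFQ"), 60)
        perm = rng.permutation(60)
        a = evaluate(y_true, y_pred)
        b = evaluate(y_true[perm], y_pred[perm])
        assert a.acc == b.acc and a.sen == b.sen and a.pre == b.pre

    def test_absent_class_skipped_with_warning(self):
        y_true = ["N", "S", "N", "S"]
        y_pred = ["N", "S", "S", "S"]
        with pytest.warns(UserWarning, match="absent"):
            m = evaluate(y_true, y_pred)
        assert 0 < m.acc < 1

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            evaluate(["N"], ["N", "S"])


class TestCountParameters:
    def test_table_reports_sinc_gain(self):
        table, total = count_parameters(build_kecnet(KecNetConfig(), seed=0))
        sinc_row = table[table.layer == "SincConv1d"].iloc[0]
        assert sinc_row.n_params == 64
        assert sinc_row.gain_vs_standard_pct == pytest.approx(sinc_param_gain(251))
        assert total == sum(r.n_params for r in table.itertuples())

    def test_standard_first_layer_taps(self):
        from dataclasses import replace

        cfg = replace(KecNetConfig(), baseline_kernel_length=251)
        model = build_baseline_cnn(cfg, seed=0)
        assert model.feature_layers[0].params["W"].size == 32 * 251
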