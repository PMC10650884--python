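"""Variant grid, BCE, transfer semantics, fine-tuning schemes."""

import numpy as np
import pytest

from motorgrade.masking import MaskSpec
from motorgrade.network import build_model
from motorgrade.pretrain import MaskedPretrainer, PretrainedWeights
from motorgrade.supervised import (
    VariantSpec,
    XceptionTimeClassifier,
    bce_loss,
    enumerate_variants,
    parameter_hash,
    transfer_weights,
)


class TestEnumerateVariants:
    def test_exactly_ten_variants(self):
        assert len(enumerate_variants(1)) == 10

    def test_two_random_inits(self):
        variants = enumerate_variants(2)
        assert sum(v.init == "RandInit" for v in variants) == 2

    def test_four_ftl_variants(self):
        variants = enumerate_variants(3)
        assert sum(v.scheme == "FTL" for v in variants) == 4

    def test_grid_structure(self):
        variants = enumerate_variants(1)
        assert len(set(variants)) == 10
        for train_set in ("PD", "PD_HOA"):
            sub = [v for v in variants if v.train_set == train_set]
            assert len(sub) == 5

    def test_randinit_scheme_coupling_enforced(self):
        with pytest.raises(ValueError):
            VariantSpec("PD", "RandInit", "FTA", 1)
        with pytest.raises(ValueError):
            VariantSpec("PD", "W_PD", "none", 1)


class TestBceLoss:
    def test_perfect_prediction_near_zero(self):
        assert bce_loss([1.0], [1.0 - 1e-9]) < 1e-5

    def test_uninformative_prediction_is_ln2(self):
        assert bce_loss([1.0], [0.5]) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            y = (rng.random(20) < 0.5).astype(float)
            p = rng.uniform(0.01, 0.99, 20)
            expected = -np.mean(
                [yi * np.log(pi) + (1 - yi) * np.log(1 - pi) for yi, pi in zip(y, p)]
            )
            assert bce_loss(y, p) == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss([1.0, 0.0], [0.5])


@pytest.fixture(scope="module")
def pretrained(tiny_model_config, small_segments):
    est = MaskedPretrainer(
        model_config=tiny_model_config,
        mask_spec=MaskSpec(),
        epochs=1,
        batch_size=32,
        seed=4,
    )
    est.fit(small_segments.X[:60])
    return PretrainedWeights(state=est.backbone_state_, tag="W_PD", fold=1)


class TestTransferWeights:
    def test_backbone_copied_bit_for_bit(self, tiny_model_config, pretrained):
        model = build_model(tiny_model_config)
        transfer_weights(model, pretrained)
        state = model.backbone_state()
        for k, v in pretrained.state.items():
            np.testing.assert_array_equal(state[k], v)

    def test_head_keeps_fresh_initialization(self, tiny_model_config, pretrained):
        from dataclasses import replace

        fresh = build_model(replace(tiny_model_config, seed=tiny_model_config.seed))
        model = build_model(tiny_model_config)
        transfer_weights(model, pretrained)
        fresh_head = fresh.head.named_parameters("head.")
        moved_head = model.head.named_parameters("head.")
        for k in fresh_head:
            np.testing.assert_array_equal(fresh_head[k].data, moved_head[k].data)


@pytest.fixture(scope="module")
def separable():
    # two sinusoid families differing in frequency, standardized
    rng = np.random.default_rng(1)
    n, L = 80, 400
    t = np.arange(L) / 80.0
    X = np.empty((n, L, 2))
    y = np.arange(n) % 2
    for i in range(n):
        f = 2.0 if y[i] == 0 else 4.5
        sig = np.sin(2 * np.pi * f * t + rng.uniform(0, 6))
        X[i, :, 0] = sig + 0.1 * rng.normal(size=L)
        X[i, :, 1] = 0.9 * sig + 0.1 * rng.normal(size=L)
    X = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
    return X, y


class TestClassifier:
    def test_learns_separable_data(self, tiny_model_config, separable):
        X, y = separable
        clf = XceptionTimeClassifier(
            model_config=tiny_model_config, epochs=15, batch_size=16, seed=0
        )
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_string_labels_round_trip(self, tiny_model_config, separable):
        X, y = separable
        labels = np.where(y == 1, "high", "low")
        clf = XceptionTimeClassifier(
            model_config=tiny_model_config, epochs=2, batch_size=16, seed=0
        )
        clf.fit(X[:20], labels[:20])
        pred = clf.predict(X[:4])
        assert set(pred) <= {"low", "high"}
        proba = clf.predict_proba(X[:4])
        assert proba.shape == (4, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)

    def test_ftl_phase_one_freezes_backbone(
        self, tiny_model_config, pretrained, separable
    ):
        # head-only epochs must leave every backbone parameter untouched
        X, y = separable
        clf = XceptionTimeClassifier(
            model_config=tiny_model_config,
            epochs=0,
            head_epochs=3,
            scheme="FTL",
            init_weights=pretrained,
            batch_size=16,
            seed=2,
        )
        clf.fit(X[:32], y[:32])
        before = parameter_hash(
            {k: v for k, v in pretrained.state.items() if not k.endswith("running_mean") and not k.endswith("running_var")}
        )
        after_state = {
            f"backbone.{k}": v.data
            for k, v in clf.model_.backbone.named_parameters().items()
        }
        assert parameter_hash(after_state) == before

    def test_fta_moves_backbone(self, tiny_model_config, pretrained, separable):
        X, y = separable
        clf = XceptionTimeClassifier(
            model_config=tiny_model_config,
            epochs=2,
            scheme="FTA",
            init_weights=pretrained,
            batch_size=16,
            seed=2,
        )
        clf.fit(X[:32], y[:32])
        after = {
            f"backbone.{k}": v.data
            for k, v in clf.model_.backbone.named_parameters().items()
        }
        before = {
            k: v
            for k, v in pretrained.state.items()
            if "running_" not in k
        }
        assert parameter_hash(after) != parameter_hash(before)

    def test_scheme_requires_weights(self, tiny_model_config, separable):
        X, y = separable
        clf = XceptionTimeClassifier(
            model_config=tiny_model_config, epochs=1, scheme="FTA"
        )
        with pytest.raises(ValueError):
            clf.fit(X[:8], y[:8])

    def test_deterministic_validation_curve(self, tiny_model_config, separable):
        X, y = separable
        curves = []
        for _ in range(2):
            clf = XceptionTimeClassifier(
                model_config=tiny_model_config, epochs=3, batch_size=16, seed=7
            )
            clf.fit(X[:32], y[:32], validation_data=(X[32:48], y[32:48]))
            curves.append([row["val_loss"] for row in clf.history_])
        assert curves[0] == curves[1]

    def test_sklearn_params_round_trip(self, tiny_model_config):
        clf = XceptionTimeClassifier(model_config=tiny_model_config, epochs=5)
        params = clf.get_params()
        assert params["epochs"] == 5
        clf.set_params(epochs=7)
        assert clf.epochs == 7
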