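"""Fusion algebra, loss, attention semantics and training behavior."""

import numpy as np
import pytest

from medcnn.model import (
    MedcnnClassifier,
    ModelConfig,
    attention_weights,
    bce_loss,
    build_model,
    fuse_tensors,
    predict,
    train,
)
from medcnn.sequence_io import LabeledDataset, SequenceRecord, SplitSpec, split_dataset
from medcnn.synthetic_data import motif_preset

TINY = dict(conv_channels=(4, 8), embed_dim=3, fc_width=8, kernel_size=3,
            spatial_kernel_size=3, batch_size=16, dropout=0.0)


class TestFuseTensors:
    def test_zero_vectors_single_corner_one(self):
        ft = fuse_tensors([0.0], [0.0], [0.0])
        expected = np.zeros((2, 2, 2))
        expected[1, 1, 1] = 1.0
        np.testing.assert_array_equal(ft.values, expected)

    def test_scalar_product_corner(self):
        ft = fuse_tensors([2.0], [3.0], [5.0])
        assert ft.values[0, 0, 0] == 30.0

    def test_fiber_recovers_first_vector(self):
        z1 = np.array([1.5, -2.0, 0.25])
        ft = fuse_tensors(z1, [4.0], [7.0, 8.0])
        d1, d2, d3 = ft.component_dims
        np.testing.assert_array_equal(ft.values[:, d2, d3], np.r_[z1, 1.0])

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fuse_tensors([], [1.0], [1.0])

    def test_slice_recovery_on_random_triples(self):
        """All three corner-fiber identities, 100 random triples, 1e-12."""
        rng = np.random.default_rng(2)
        for _ in range(100):
            dims = rng.integers(1, 6, size=3)
            z = [rng.normal(size=d) for d in dims]
            ft = fuse_tensors(*z)
            d1, d2, d3 = ft.component_dims
            assert ft.values.shape == (d1 + 1, d2 + 1, d3 + 1)
            assert ft.values[d1, d2, d3] == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(ft.values[:, d2, d3], np.r_[z[0], 1],
                                       atol=1e-12)
            np.testing.assert_allclose(ft.values[d1, :, d3], np.r_[z[1], 1],
                                       atol=1e-12)
            np.testing.assert_allclose(ft.values[d1, d2, :], np.r_[z[2], 1],
                                       atol=1e-12)


class TestBceLoss:
    def test_perfect_prediction_limit(self):
        assert bce_loss([1 - 1e-7], [1]) == pytest.approx(0.0, abs=1e-6)

    def test_coin_flip_is_ln2(self):
        assert bce_loss([0.5], [1]) == pytest.approx(np.log(2))
        assert bce_loss([0.5, 0.5], [1, 0]) == pytest.approx(np.log(2))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bce_loss([0.5], [1, 0])

    def test_matches_per_sample_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            n = int(rng.integers(1, 30))
            p = rng.uniform(0.01, 0.99, size=n)
            y = rng.integers(0, 2, size=n)
            expected = -np.mean(
                [yi * np.log(pi) + (1 - yi) * np.log(1 - pi)
                 for pi, yi in zip(p, y)]
            )
            assert bce_loss(p, y) == pytest.approx(expected, abs=1e-10)


class TestAttention:
    @staticmethod
    def identity_params(C):
        k = 3
        sa = np.zeros((1, 1, k))
        return {
            "ca_W1": np.eye(C), "ca_b1": np.zeros(C),
            "ca_W2": np.eye(C), "ca_b2": np.zeros(C),
            "sa_Wa": sa, "sa_Wm": sa.copy(), "sa_b": np.zeros(1),
        }

    def test_reweighting_is_elementwise_product(self):
        rng = np.random.default_rng(1)
        fm = rng.normal(size=(3, 7))
        cw, sw, out = attention_weights(fm, self.identity_params(3))
        np.testing.assert_allclose(out, fm * cw[:, None] * sw[None, :],
                                   atol=1e-12)
        assert ((cw > 0) & (cw < 1)).all() and ((sw > 0) & (sw < 1)).all()

    def test_zero_spatial_weights_give_half(self):
        """Zero conv kernels make every position weight sigmoid(0) = 1/2."""
        fm = np.random.default_rng(2).normal(size=(3, 5))
        _, sw, _ = attention_weights(fm, self.identity_params(3))
        np.testing.assert_allclose(sw, 0.5)

    def test_dominant_channel_gets_max_weight(self):
        """With an identity bottleneck, the high-magnitude channel wins."""
        fm = np.vstack([np.full(6, 5.0), np.full(6, 0.01), np.full(6, -0.02)])
        cw, _, _ = attention_weights(fm, self.identity_params(3))
        assert np.argmax(cw) == 0

    def test_near_zero_channel_weight_zeroes_row(self):
        params = self.identity_params(2)
        params["ca_b2"] = np.array([-60.0, 0.0])  # drive channel 0 to ~0
        fm = np.ones((2, 4))
        cw, _, out = attention_weights(fm, params)
        assert cw[0] < 1e-20
        np.testing.assert_allclose(out[0], 0.0, atol=1e-15)


def small_dataset(n=40, seed=0):
    return motif_preset(n_pos=n, n_neg=n, L=21, seed=seed)


class TestBuildModel:
    def test_fusion_input_dimension(self):
        cfg = ModelConfig(embed_dim=4, **{k: v for k, v in TINY.items()
                                          if k != "embed_dim"})
        model = build_model(cfg, L=21)
        assert model.params_["fc1_W"].shape[0] == 125  # (4+1)^3

    def test_same_seed_identical_initial_parameters(self):
        cfg = ModelConfig(seed=5, **TINY)
        m1, m2 = build_model(cfg, L=21), build_model(cfg, L=21)
        for k in m1.params_:
            np.testing.assert_array_equal(m1.params_[k].data,
                                          m2.params_[k].data)

    def test_kernel_larger_than_window_rejected(self):
        with pytest.raises(ValueError, match="kernel"):
            build_model(ModelConfig(**TINY), L=2)

    def test_attention_disabled_has_no_attention_parameters(self):
        cfg = ModelConfig(attention=False, **TINY)
        model = build_model(cfg, L=21)
        assert not any("ca_" in k or "sa_" in k for k in model.params_)


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        ds = small_dataset()
        tr, va, te = split_dataset(ds, SplitSpec(seed=0))
        est = MedcnnClassifier(max_epochs=8, random_state=0, **TINY)
        est.fit(tr, validation_data=(va, None))
        h = est.history_
        assert h.train_loss[-1] < h.train_loss[0]
        assert h.best_epoch is not None

    def test_max_epochs_zero_keeps_initial_weights(self):
        cfg = ModelConfig(max_epochs=0, seed=1, **TINY)
        ds = small_dataset()
        model = build_model(cfg, L=21)
        initial = {k: p.data.copy() for k, p in model.params_.items()}
        tr, va, _ = split_dataset(ds, SplitSpec(seed=0))
        state = train(model, tr, va)
        assert state.n_epochs == 0 and state.train_loss == []
        # fit re-initializes from the same seed, so weights equal the build
        for k, v in initial.items():
            np.testing.assert_array_equal(model.params_[k].data, v)

    def test_single_class_train_rejected(self):
        records = [SequenceRecord(f"p{i}", "ACGTACGTACGTACGTACGTA", label=1)
                   for i in range(10)]
        est = MedcnnClassifier(**TINY)
        with pytest.raises(ValueError, match="both classes"):
            est.fit(LabeledDataset(records))

    def test_predict_deterministic_and_bounded(self):
        ds = small_dataset()
        tr, va, te = split_dataset(ds, SplitSpec(seed=0))
        est = MedcnnClassifier(max_epochs=3, random_state=0, **TINY)
        est.fit(tr, validation_data=(va, None))
        p1 = est.predict_proba(te)[:, 1]
        p2 = est.predict_proba(te)[:, 1]
        np.testing.assert_array_equal(p1, p2)
        assert ((p1 >= 0) & (p1 <= 1)).all()

    def test_threshold_zero_predicts_all_positive(self):
        ds = small_dataset()
        tr, va, te = split_dataset(ds, SplitSpec(seed=0))
        est = MedcnnClassifier(max_epochs=2, random_state=0, **TINY)
        est.fit(tr, validation_data=(va, None))
        results = predict(est, te, threshold=0.0)
        assert all(r.label == 1 for r in results)
        assert [r.id for r in results] == [r.id for r in te.records]

    def test_length_mismatch_at_predict_rejected(self):
        ds = small_dataset()
        tr, va, _ = split_dataset(ds, SplitSpec(seed=0))
        est = MedcnnClassifier(max_epochs=1, random_state=0, **TINY)
        est.fit(tr, validation_data=(va, None))
        with pytest.raises(ValueError, match="does not match fitted length"):
            est.predict_proba(["ACGT"])

    def test_checkpoint_roundtrip_bit_identical(self, tmp_path):
        ds = small_dataset()
        tr, va, te = split_dataset(ds, SplitSpec(seed=0))
        est = MedcnnClassifier(max_epochs=3, random_state=0, **TINY)
        est.fit(tr, validation_data=(va, None))
        path = tmp_path / "ckpt.npz"
        est.save(path)
        loaded = MedcnnClassifier.load(path)
        np.testing.assert_array_equal(
            est.predict_proba(te), loaded.predict_proba(te)
        )

    def test_attention_maps_exported_per_input(self):
        ds = small_dataset()
        tr, va, te = split_dataset(ds, SplitSpec(seed=0))
        est = MedcnnClassifier(max_epochs=1, random_state=0, **TINY)
        est.fit(tr, validation_data=(va, None))
        maps = est.attention_maps(te)
        assert set(maps) == {f"branch{i}_{kind}" for i in range(3)
                             for kind in ("channel", "spatial")}
        assert maps["branch0_spatial"].shape == (len(te), 21)
        assert all((0 < m).all() and (m < 1).all() for m in maps.values())

    def test_sklearn_get_set_params_roundtrip(self):
        est = MedcnnClassifier(**TINY)
        params = est.get_params()
        assert params["embed_dim"] == TINY["embed_dim"]
        est.set_params(embed_dim=5)
        assert est.embed_dim == 5
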