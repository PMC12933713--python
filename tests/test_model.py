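import numpy as np
import pytest

import surfibs._autodiff as ad
from surfibs._autodiff import Tensor
from surfibs.geodesy import extract_all_patches
from surfibs.model import (
    FEATURE_PRESETS,
    ModelConfig,
    ProteinData,
    SoftGridModel,
    TrainConfig,
    mask_features,
    pack_patches,
    train,
    transfer_surgery,
)


def _tiny_data(n_vertices=30, seed=0, n_members=12):
    """Hand-built packed patches: ring geometry, random features."""
    rng = np.random.default_rng(seed)
    rho = rng.uniform(0, 9, size=(n_vertices, n_members)).astype(np.float32)
    rho[:, 0] = 0.0
    theta = rng.uniform(0, 2 * np.pi, size=(n_vertices, n_members)).astype(np.float32)
    mask = np.ones((n_vertices, n_members), dtype=np.float32)
    mask[:, -3:] = 0.0  # padded tail
    members = rng.integers(0, n_vertices, size=(n_vertices, n_members))
    members[:, 0] = np.arange(n_vertices)
    feats = rng.normal(0, 0.4, size=(n_vertices, n_members, 5)).astype(np.float32)
    feats[mask == 0] = 0.0
    labels = rng.integers(0, 2, size=n_vertices)
    return ProteinData("tiny", rho, theta, mask, members, feats, labels)


class TestSoftGridMap:
    def test_zero_features_give_zero_bins(self):
        data = _tiny_data()
        data.features[:] = 0.0
        model = SoftGridModel(ModelConfig(seed=0))
        bins = model.soft_grid_map(data)
        np.testing.assert_array_equal(bins, 0.0)

    def test_member_at_kernel_center_saturates_its_bin(self):
        model = SoftGridModel(ModelConfig(seed=0))
        mu_rho = model.params["conv0.mu_rho"].data
        mu_theta = model.params["conv0.mu_theta"].data
        # one real member parked exactly on kernel 0, unit first feature
        rho = np.full((1, 4), 9.0, dtype=np.float32)
        theta = np.zeros((1, 4), dtype=np.float32)
        rho[0, 0], theta[0, 0] = mu_rho[0], mu_theta[0]
        mask = np.zeros((1, 4), dtype=np.float32)
        mask[0, 0] = 1.0
        feats = np.zeros((1, 4, 5), dtype=np.float32)
        feats[0, 0, 0] = 1.0
        data = ProteinData("x", rho, theta, mask, np.zeros((1, 4), int), feats)
        bins = model.soft_grid_map(data)
        assert bins[0, 0, 0] == pytest.approx(1.0, abs=1e-6)
        assert np.all(bins[0, 1:, 0] <= bins[0, 0, 0])

    def test_full_turn_offset_is_identity(self):
        data = _tiny_data(seed=3)
        model = SoftGridModel(ModelConfig(seed=1))
        b0 = model.soft_grid_map(data, rotation_offset=0.0)
        b1 = model.soft_grid_map(data, rotation_offset=2 * np.pi)
        np.testing.assert_allclose(b0, b1, atol=1e-6)


class TestForward:
    def test_scores_in_unit_interval_and_deterministic(self):
        data = _tiny_data()
        model = SoftGridModel(ModelConfig(seed=0))
        s1 = model.predict(data)
        s2 = model.predict(data)
        assert np.all((s1 > 0) & (s1 < 1))
        np.testing.assert_array_equal(s1, s2)

    def test_rotation_count_convergence(self, planted_packed):
        data = planted_packed[0]
        s8 = SoftGridModel(ModelConfig(seed=0, n_rotations=8)).predict(data)
        s16 = SoftGridModel(ModelConfig(seed=0, n_rotations=16)).predict(data)
        assert np.abs(s8 - s16).max() < 0.02

    def test_padded_member_features_have_zero_gradient(self):
        data = _tiny_data(seed=5)
        model = SoftGridModel(ModelConfig(seed=0))
        ft = Tensor(data.features.astype(np.float64), requires_grad=True)
        logits = model.forward_t(data, features_tensor=ft)
        loss = ad.mean(ad.sigmoid_cross_entropy(logits, data.labels))
        loss.backward()
        padded = data.mask == 0.0
        assert np.any(padded)
        np.testing.assert_array_equal(ft.grad[padded], 0.0)
        assert np.abs(ft.grad[~padded]).max() > 0  # real members do get gradient


class TestGridWeightGradients:
    @pytest.mark.parametrize(
        "name", ["mu_rho", "sigma_rho_raw", "mu_theta", "sigma_theta_raw"]
    )
    def test_fused_kernel_gradients_match_finite_differences(self, name):
        rng = np.random.default_rng(0)
        model = SoftGridModel(ModelConfig(seed=0, n_rotations=3))
        for t in model.params.values():
            t.data = t.data.astype(np.float64)
        V, M = 5, 7
        rho = rng.uniform(0, 9, (V, M))
        theta = rng.uniform(0, 2 * np.pi, (V, M))
        mask = (rng.uniform(size=(V, M)) > 0.2).astype(float)
        proj = rng.normal(size=(3, V, M, 12))

        def loss():
            return ad.tsum(model._grid_weights(0, rho, theta, mask) * proj)

        p = model.params[f"conv0.{name}"]
        for t in model.params.values():
            t.grad = None
        loss().backward()
        analytic = p.grad.copy()
        numeric = np.zeros_like(p.data)
        eps = 1e-6
        for i in range(len(p.data)):
            orig = p.data[i]
            p.data[i] = orig + eps
            up = float(loss().data)
            p.data[i] = orig - eps
            down = float(loss().data)
            p.data[i] = orig
            numeric[i] = (up - down) / (2 * eps)
        np.testing.assert_allclose(analytic, numeric, atol=1e-7)


class TestMaskFeatures:
    def test_keep_all_is_identity(self):
        data = _tiny_data()
        out = mask_features([data], "all")[0]
        np.testing.assert_array_equal(out.features, data.features)

    def test_geom_zeroes_chemical_columns(self):
        data = _tiny_data()
        out = mask_features([data], "geom")[0]
        np.testing.assert_array_equal(out.features[:, :, 2:], 0.0)
        np.testing.assert_array_equal(out.features[:, :, :2], data.features[:, :, :2])

    def test_masked_model_ignores_chemical_perturbation(self):
        data = _tiny_data(seed=9)
        model = SoftGridModel(ModelConfig(seed=2))
        base = model.predict(mask_features([data], "geom")[0])
        perturbed = ProteinData(
            data.protein_id, data.rho, data.theta, data.mask, data.members,
            data.features + np.array([0, 0, 0.5, -0.3, 0.8], dtype=np.float32),
            data.labels,
        )
        after = model.predict(mask_features([perturbed], "geom")[0])
        np.testing.assert_array_equal(base, after)

    def test_empty_or_unknown_keep_rejected(self):
        data = _tiny_data()
        with pytest.raises(ValueError):
            mask_features([data], ())
        with pytest.raises(ValueError, match="unknown"):
            mask_features([data], {"voltage"})


class TestTraining:
    def test_seeded_determinism(self, planted_packed):
        subset = planted_packed[:4]
        cfg = TrainConfig(epochs=2, seed=11, patience=None)
        _, h1 = train(subset, cfg)
        _, h2 = train(subset, cfg)
        assert h1 == h2

    def test_single_class_protein_excluded(self, planted_packed):
        bad = ProteinData(
            "allneg", *(getattr(planted_packed[0], f) for f in
                        ("rho", "theta", "mask", "members", "features")),
            labels=np.zeros(planted_packed[0].n_vertices, dtype=int),
        )
        with pytest.warns(UserWarning, match="single-class"):
            train([bad] + list(planted_packed[:3]), TrainConfig(epochs=1, seed=0))


class TestTransferSurgery:
    def test_opt1_manifest_and_head_widths(self):
        pre = SoftGridModel(ModelConfig(seed=0))
        model = transfer_surgery(pre, "opt1")
        manifest = model.frozen_manifest()
        assert all(v for k, v in manifest.items() if k.startswith("conv"))
        assert not any(v for k, v in manifest.items() if k.startswith("head"))
        assert model.head_widths == (128, 64, 4, 2)
        widths = [model.params[f"head{j}.W"].data.shape for j in range(5)]
        assert widths == [(16, 128), (128, 64), (64, 4), (4, 2), (2, 1)]

    def test_opt1_conv_parameters_bit_identical_after_training_step(self, planted_packed):
        pre = SoftGridModel(ModelConfig(seed=0))
        before = {k: v.data.copy() for k, v in pre.params.items() if k.startswith("conv")}
        model = transfer_surgery(pre, "opt1")
        train(planted_packed[:3], TrainConfig(epochs=1, seed=1, patience=None), model=model)
        for k, v in before.items():
            assert np.array_equal(model.params[k].data, v), k

    def test_opt2_six_conv_layers_first_three_frozen(self):
        pre = SoftGridModel(ModelConfig(seed=0))
        model = transfer_surgery(pre, "opt2")
        assert model.n_conv_layers == 6
        manifest = model.frozen_manifest()
        for i in range(3):
            assert manifest[f"conv{i}.W"]
        for i in range(3, 6):
            assert not manifest[f"conv{i}.W"]

    def test_unknown_strategy(self):
        with pytest.raises(ValueError, match="unknown transfer strategy"):
            transfer_surgery(SoftGridModel(), "opt3")


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        model = transfer_surgery(SoftGridModel(ModelConfig(seed=4)), "opt1")
        path = tmp_path / "ckpt.npz"
        model.save(path)
        back = SoftGridModel.load(path)
        assert back.frozen == model.frozen
        assert back.head_widths == model.head_widths
        data = _tiny_data()
        np.testing.assert_array_equal(back.predict(data), model.predict(data))
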