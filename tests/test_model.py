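import math
from dataclasses import replace

import numpy as np
import pytest

from scmeth import ImputationModel, ModelConfig, fine_tune, masked_loss, train
from scmeth import nn
from scmeth.baselines import cnn_baseline_config
from scmeth.encoding import ExampleSet, SENTINEL
from scmeth.io import SiteCatalog
from scmeth.model import TrainingDiverged


def _batch(cfg: ModelConfig, n: int, rng, observed_frac=0.6):
    dna = np.zeros((n, cfg.L, 4))
    idx = rng.integers(0, 4, size=(n, cfg.L))
    for b in range(n):
        dna[b, np.arange(cfg.L), idx[b]] = 1.0
    neighbors = rng.random(size=(n, cfg.K, cfg.n_clusters))
    labels = rng.integers(0, 2, size=(n, cfg.n_cells)).astype(float)
    mask = rng.random(size=(n, cfg.n_cells)) < observed_frac
    return dna, neighbors, labels, mask


def _example_set(cfg: ModelConfig, n: int, rng, cells=None):
    dna, neighbors, labels, mask = _batch(cfg, n, rng)
    cells = cells or [f"c{i}" for i in range(cfg.n_cells)]
    cat = SiteCatalog(np.array(["s1"] * n, dtype=object),
                      (np.arange(n) + 1) * 10,
                      np.array(["+"] * n, dtype=object))
    return ExampleSet(np.arange(n), cat, cells, dna, neighbors, cfg.K // 2,
                      labels, mask)


class TestForward:
    def test_output_shape_and_range(self, tiny_model_config, rng):
        model = ImputationModel(tiny_model_config)
        dna, nb, _, _ = _batch(tiny_model_config, 5, rng)
        out = model.forward(dna, nb, tiny_model_config.K // 2)
        assert out.shape == (5, tiny_model_config.n_cells)
        assert np.all(out.data > 0) and np.all(out.data < 1)

    def test_inference_deterministic(self, tiny_model_config, rng):
        model = ImputationModel(tiny_model_config)
        dna, nb, _, _ = _batch(tiny_model_config, 3, rng)
        a = model.forward(dna, nb, 4, training=False).data
        b = model.forward(dna, nb, 4, training=False).data
        np.testing.assert_array_equal(a, b)

    def test_all_zero_window_and_all_sentinel_tensor_finite(
            self, tiny_model_config):
        model = ImputationModel(tiny_model_config)
        dna = np.zeros((2, tiny_model_config.L, 4))
        nb = np.full((2, tiny_model_config.K, tiny_model_config.n_clusters),
                     SENTINEL)
        out = model.forward(dna, nb, 4).data
        assert np.all(np.isfinite(out))

    def test_single_cluster_degenerate(self, tiny_model_config, rng):
        cfg = replace(tiny_model_config, n_clusters=1)
        model = ImputationModel(cfg)
        dna, nb, _, _ = _batch(cfg, 2, rng)
        assert model.forward(dna, nb, 4).shape == (2, cfg.n_cells)

    def test_cluster_order_invariance_of_mean_path(self, tiny_model_config, rng):
        """The shared-CNN mean over clusters is symmetric, so permuting
        clusters leaves the position-wise branch input unchanged."""
        model = ImputationModel(tiny_model_config)
        enc = model.network.cpg
        dna, nb, _, _ = _batch(tiny_model_config, 2, rng)
        x = nn.Tensor(nb)
        xp = nn.Tensor(nb[:, :, ::-1].copy())
        def mean_feats(t):
            bsz, k, n = t.shape
            z = nn.reshape(nn.transpose(t, (0, 2, 1)), (bsz * n, k, 1))
            defined = nn.Tensor((z.data >= 0).astype(z.data.dtype))
            z = nn.concat([z, defined], axis=-1)
            for conv in enc.convs:
                z = nn.relu(conv(z))
            return nn.reshape(z, (bsz, n, k, -1)).mean(axis=1).data
        np.testing.assert_allclose(mean_feats(x), mean_feats(xp), atol=1e-6)

    def test_shape_mismatch_rejected(self, tiny_model_config, rng):
        model = ImputationModel(tiny_model_config)
        dna, nb, _, _ = _batch(tiny_model_config, 2, rng)
        with pytest.raises(ValueError):
            model.forward(dna[:, :-2], nb, 4)
        with pytest.raises(ValueError):
            model.forward(dna, nb[:, :, :1], 4)


class TestAblations:
    def test_dna_only_ignores_neighbors(self, tiny_model_config, rng):
        cfg = replace(tiny_model_config, module_mode="dna_only")
        model = ImputationModel(cfg)
        dna, nb, _, _ = _batch(cfg, 3, rng)
        a = model.forward(dna, nb, 4, training=False).data
        b = model.forward(dna, rng.random(nb.shape), 4, training=False).data
        np.testing.assert_array_equal(a, b)

    def test_cpg_only_ignores_dna(self, tiny_model_config, rng):
        cfg = replace(tiny_model_config, module_mode="cpg_only")
        model = ImputationModel(cfg)
        dna, nb, _, _ = _batch(cfg, 3, rng)
        dna2, _, _, _ = _batch(cfg, 3, rng)
        a = model.forward(dna, nb, 4, training=False).data
        b = model.forward(dna2, nb, 4, training=False).data
        np.testing.assert_array_equal(a, b)


class TestCnnBaseline:
    def test_config_swap_only_encoder(self, tiny_model_config):
        cnn_cfg = cnn_baseline_config(tiny_model_config)
        assert cnn_cfg.encoder_kind == "cnn_only"
        assert replace(cnn_cfg, encoder_kind="transformer") == tiny_model_config

    def test_output_shape_unchanged(self, tiny_model_config, rng):
        model = ImputationModel(cnn_baseline_config(tiny_model_config))
        dna, nb, _, _ = _batch(tiny_model_config, 4, rng)
        assert model.forward(dna, nb, 4).shape == (4, tiny_model_config.n_cells)

    def test_receptive_field_locality(self, rng):
        """Perturbing window content beyond the CNN receptive field leaves
        CNN-only DNA features unchanged but changes transformer features."""
        cfg = ModelConfig(n_cells=4, n_clusters=2, L=128, K=8, conv_layers=2,
                          conv_kernels=8, kernel_size=5, pool_step=16,
                          n_transformer_layers=1, n_heads=2, model_dim=16,
                          ffn_dim=32, head_hidden=16, seed=3)
        dna, _, _, _ = _batch(cfg, 1, rng)
        far = dna.copy()
        far[0, :4] = 0.0  # flip bases at the distal window edge
        far[0, np.arange(4), (np.argmax(dna[0, :4], axis=1) + 2) % 4] = 1.0

        cnn = ImputationModel(cnn_baseline_config(cfg))
        cnn.network.set_training(False)
        with nn.no_grad():
            a = cnn.network.dna(nn.Tensor(dna)).data
            b = cnn.network.dna(nn.Tensor(far)).data
        np.testing.assert_array_equal(a, b)

        trans = ImputationModel(cfg)
        trans.network.set_training(False)
        with nn.no_grad():
            ta = trans.network.dna(nn.Tensor(dna)).data
            tb = trans.network.dna(nn.Tensor(far)).data
        assert np.abs(ta - tb).max() > 0

    def test_checkpoint_roundtrip(self, tiny_model_config, tmp_path, rng):
        model = ImputationModel(cnn_baseline_config(tiny_model_config))
        path = tmp_path / "cnn.ckpt.npz"
        model.save(path)
        back = ImputationModel.load(path)
        assert back.config == cnn_baseline_config(tiny_model_config)
        dna, nb, _, _ = _batch(tiny_model_config, 2, rng)
        np.testing.assert_array_equal(
            model.forward(dna, nb, 4, training=False).data,
            back.forward(dna, nb, 4, training=False).data)


class TestMaskedLoss:
    def test_closed_form_ln2(self):
        probs = nn.Tensor(np.array([[0.5]]))
        loss = masked_loss(probs, np.array([[1.0]]), np.array([[True]]))
        assert float(loss.data) == pytest.approx(math.log(2), abs=1e-6)

    def test_empty_mask_is_zero(self, rng):
        probs = nn.Tensor(rng.random((3, 4)))
        loss = masked_loss(probs, np.zeros((3, 4)), np.zeros((3, 4), bool))
        assert float(loss.data) == 0.0

    def test_unobserved_labels_cannot_move_loss_or_gradients(
            self, tiny_model_config, rng):
        cfg = tiny_model_config
        model = ImputationModel(cfg)
        dna, nb, labels, mask = _batch(cfg, 4, rng)

        def loss_and_grads(lab):
            model.network.zero_grad()
            # dropout must be off so the two passes are comparable
            probs = model.forward(dna, nb, 4, training=False)
            loss = masked_loss(probs, lab, mask)
            loss.backward()
            return (float(loss.data),
                    [p.grad.copy() for p in model.network.parameters()])

        base_loss, base_grads = loss_and_grads(labels)
        perturbed = labels.copy()
        perturbed[~mask] = rng.integers(0, 2, size=(~mask).sum())
        new_loss, new_grads = loss_and_grads(perturbed)
        assert new_loss == base_loss
        for g0, g1 in zip(base_grads, new_grads):
            np.testing.assert_array_equal(g0, g1)

    def test_bad_observed_label_rejected(self, rng):
        probs = nn.Tensor(rng.random((1, 3)))
        labels = np.array([[0.5, 1.0, 0.0]])
        with pytest.raises(ValueError):
            masked_loss(probs, labels, np.ones((1, 3), bool))


class TestTraining:
    def test_loss_decreases_and_history_reproducible(self, tiny_model_config,
                                                     rng):
        cfg = replace(tiny_model_config, max_epochs=6, learning_rate=3e-3)
        train_set = _example_set(cfg, 50, np.random.default_rng(5))
        model, hist = train(cfg, train_set)
        losses = [h["train_loss"] for h in hist]
        assert np.mean(losses[-2:]) < np.mean(losses[:2])
        _model2, hist2 = train(cfg, train_set)
        assert hist2 == hist

    def test_early_stopping_restores_best(self, tiny_model_config):
        cfg = replace(tiny_model_config, max_epochs=4, patience=1)
        train_set = _example_set(cfg, 30, np.random.default_rng(6))
        val_set = _example_set(cfg, 10, np.random.default_rng(7))
        model, hist = train(cfg, train_set, val_set)
        best = np.nanmax([h.get("val_auprc", np.nan) for h in hist])
        assert model.metadata["best_val_auprc"] == pytest.approx(best)

    def test_nan_divergence_aborts(self, tiny_model_config):
        cfg = replace(tiny_model_config, max_epochs=3)
        train_set = _example_set(cfg, 30, np.random.default_rng(8))
        model = ImputationModel(cfg)
        model.network.hidden.weight.data[0, 0] = np.nan
        with pytest.raises(TrainingDiverged):
            model.fit(train_set)

    def test_predict_all_contract(self, tiny_model_config):
        cfg = tiny_model_config
        examples = _example_set(cfg, 20, np.random.default_rng(9))
        model = ImputationModel(cfg)
        pred = model.predict_all(examples)
        assert pred.probs.shape == (cfg.n_cells, 20)
        assert np.all((pred.probs >= 0) & (pred.probs <= 1))
        np.testing.assert_array_equal(pred.observed, examples.mask.T)


class TestFineTune:
    def test_zero_epochs_preserves_transferable_weights(self,
                                                        tiny_model_config):
        pre = ImputationModel(tiny_model_config)
        new_cfg = replace(tiny_model_config, n_cells=20, max_epochs=0, seed=9)
        model, hist = fine_tune(pre, new_cfg)
        assert hist == []
        assert model.network.out.weight.shape == (tiny_model_config.head_hidden
                                                  if False else 16, 20)
        src = pre.network.state_dict()
        dst = model.network.state_dict()
        for key, value in src.items():
            name = key.split("buffer:")[-1]
            if name.startswith("out."):
                continue
            np.testing.assert_array_equal(dst[key], value)

    def test_resized_cluster_width(self, tiny_model_config):
        pre = ImputationModel(tiny_model_config)
        new_cfg = replace(tiny_model_config, n_clusters=3, max_epochs=0)
        model, _ = fine_tune(pre, new_cfg)
        # cluster positional embedding resized, transformer weights copied
        assert model.network.cpg.cluster_encoder.pos.shape[0] == 3
        np.testing.assert_array_equal(
            model.network.cpg.convs[0].weight.data,
            pre.network.cpg.convs[0].weight.data)

    def test_mismatched_geometry_rejected(self, tiny_model_config):
        pre = ImputationModel(tiny_model_config)
        with pytest.raises(ValueError):
            fine_tune(pre, replace(tiny_model_config, L=64))

    def test_fine_tuned_at_least_as_good_as_fresh(self, tiny_model_config):
        cfg = replace(tiny_model_config, max_epochs=4)
        train_set = _example_set(cfg, 60, np.random.default_rng(10))
        val_set = _example_set(cfg, 20, np.random.default_rng(11))
        pre, _ = train(cfg, train_set, val_set)
        tuned, _ = fine_tune(pre, replace(cfg, max_epochs=2, seed=1),
                             train_set, val_set)
        fresh, _ = train(replace(cfg, max_epochs=2, seed=1), train_set,
                         val_set)
        assert (tuned.metadata["best_val_auprc"]
                >= fresh.metadata["best_val_auprc"] - 0.05)
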