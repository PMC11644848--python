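"""Architecture geometry, block semantics, attention, and training behavior."""

import numpy as np
import pytest

from gidfe import _nn
from gidfe.arch import (
    ArchitectureSpec,
    TrainConfig,
    build_model,
    pooling_attention,
    resnet_star_block,
    train_model,
)


class TestSpec:
    def test_default_geometry(self):
        spec = ArchitectureSpec()
        assert spec.stage_spatial_sizes == (56, 28, 14, 7)
        assert spec.attention_pool_sizes == (8, 4, 2, 1)
        assert tuple(n for n, _ in spec.stages) == (3, 4, 6, 3)
        assert spec.channel_match == 2048

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(variant="resnet101")

    def test_roundtrip_through_dict(self):
        spec = ArchitectureSpec.tiny(96, variant="case1_attention_only")
        assert ArchitectureSpec.from_dict(spec.to_dict()) == spec


class TestStarBlock:
    def test_output_channels(self, rng):
        block = resnet_star_block(64, 256, seed=0)
        x = _nn.Tensor(rng.standard_normal((1, 64, 56, 56)).astype(np.float32))
        assert block(x, training=False).data.shape == (1, 256, 56, 56)

    def test_downsampling_halves_spatial_size(self, rng):
        block = resnet_star_block(256, 512, downsample=True, seed=0)
        x = _nn.Tensor(rng.standard_normal((1, 256, 56, 56)).astype(np.float32))
        assert block(x, training=False).data.shape == (1, 512, 28, 28)

    def test_shortcut_is_always_a_convolution(self):
        # even a same-shape, stride-1 star block projects its shortcut
        block = resnet_star_block(256, 256, seed=0)
        assert block.has_projection

    def test_zero_main_path_reduces_to_shortcut(self, rng):
        """With the main path zeroed, output = ReLU(BN(conv_shortcut(x)))."""
        block = resnet_star_block(8, 8, seed=0)
        block.conv3.weight.data[...] = 0.0
        x = _nn.Tensor(rng.standard_normal((2, 8, 6, 6)).astype(np.float32))
        out = block(x, training=False)
        shortcut = _nn.relu(
            block.shortcut_bn(block.shortcut_conv(x), training=False)
        )
        np.testing.assert_allclose(out.data, shortcut.data, atol=1e-6)


class TestPoolingAttention:
    def test_all_pooled_maps_share_the_final_grid(self, full_star_model, rng):
        x = rng.random((1, 224, 224, 3), dtype=np.float32)
        out = full_star_model.forward(x)
        gates = full_star_model.net.attention.gates(out["stage_outputs"],
                                                    training=False)
        for g in gates:
            assert g.data.shape == (1, 2048, 7, 7)

    def test_gate_values_strictly_inside_unit_interval(self, full_star_model, rng):
        x = rng.random((1, 224, 224, 3), dtype=np.float32)
        out = full_star_model.forward(x)
        gates = full_star_model.net.attention.gates(out["stage_outputs"],
                                                    training=False)
        for g in gates:
            assert (g.data > 0).all() and (g.data < 1).all()

    def test_zero_weight_gates_give_half_everywhere(self, rng):
        """Zero gate convolutions: each gate is sigmoid(0)=0.5, so multiply
        mode returns the stage-4 map scaled by 0.5^4."""
        maps = [rng.standard_normal((1, 2 ** (i + 2), s, s)).astype(np.float32)
                for i, s in enumerate((16, 8, 4, 2))]
        from gidfe.arch import PoolingAttention

        head = PoolingAttention((4, 8, 16, 32), (8, 4, 2, 1), 32, "multiply",
                                np.random.default_rng(0))
        for conv in head.gate_convs:
            conv.weight.data[...] = 0.0
            conv.bias.data[...] = 0.0
        tensors = [_nn.Tensor(m) for m in maps]
        out = head(tensors, training=False)
        np.testing.assert_allclose(out.data, maps[-1] * 0.5**4, rtol=1e-5)

    def test_convenience_wrapper_preserves_stage4_shape(self, rng):
        maps = [rng.standard_normal((1, 2 ** (i + 2), s, s)).astype(np.float32)
                for i, s in enumerate((16, 8, 4, 2))]
        out = pooling_attention(maps, combine_mode="multiply", channel_match=32)
        assert out.shape == (1, 32, 2, 2)


class TestBuildModel:
    def test_full_stage_shapes(self, full_star_model, rng):
        x = rng.random((1, 224, 224, 3), dtype=np.float32)
        out = full_star_model.forward(x)
        shapes = [s.data.shape for s in out["stage_outputs"]]
        assert shapes == [(1, 256, 56, 56), (1, 512, 28, 28),
                          (1, 1024, 14, 14), (1, 2048, 7, 7)]
        assert out["pre_gap"].data.shape == (1, 2048, 7, 7)
        assert out["gap"].data.shape == (1, 2048)

    def test_block_counts(self, full_star_model):
        counts = [stop - start for start, stop in full_star_model.net.stage_slices]
        assert counts == [3, 4, 6, 3]

    def test_star_variant_has_strictly_more_parameters(self, full_star_model,
                                                       full_plain_model):
        n_star = full_star_model.net.n_parameters()
        n_plain = full_plain_model.net.n_parameters()
        assert n_star > n_plain
        # the conv shortcuts + attention convolutions add tens of millions
        assert (n_star - n_plain) > 10_000_000

    def test_softmax_probabilities_sum_to_one(self, rng):
        model = build_model(ArchitectureSpec.tiny(64), 5, seed=0)
        x = rng.random((3, 64, 64, 3), dtype=np.float32)
        p = model.predict_proba(x)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-5)

    def test_variant_attention_presence(self):
        has_attn = {
            "resnet50_star": True,
            "resnet50": False,
            "case1_attention_only": True,
            "case2_block_only": False,
        }
        for variant, expected in has_attn.items():
            m = build_model(ArchitectureSpec.tiny(64, variant=variant), 2)
            assert (m.net.attention is not None) is expected, variant

    def test_plain_variant_uses_identity_shortcuts_where_possible(self):
        spec = ArchitectureSpec(
            input_size=(64, 64, 3), stem_filters=8,
            stages=((2, 32), (2, 64), (2, 128), (2, 256)), variant="resnet50",
        )
        m = build_model(spec, 2)
        projections = [b.has_projection for b in m.net.blocks]
        # first block of each stage projects (channel/stride change), rest not
        assert projections == [True, False] * 4


class TestTraining:
    def test_beats_chance_on_eight_classes(self, images_8class):
        """A small network fitted for a few epochs exceeds the 1/8 chance
        level on its own training images."""
        model = build_model(ArchitectureSpec.tiny(64), 8, seed=1)
        train_model(model, images_8class,
                    cfg=TrainConfig(max_epochs=5, batch_size=32, seed=0))
        assert model.history[-1]["train_acc"] > 1.0 / 8.0

    def test_zero_learning_rate_freezes_weights_and_loss(self, images_8class):
        model = build_model(ArchitectureSpec.tiny(64), 8, seed=1)
        before = {k: v.copy() for k, v in model.net.state_arrays().items()
                  if not k.endswith(("running_mean", "running_var"))}
        train_model(model, images_8class,
                    cfg=TrainConfig(initial_lr=0.0, max_epochs=2, batch_size=40,
                                    seed=0, val_fraction=0.0))
        after = model.net.state_arrays()
        for k, v in before.items():
            np.testing.assert_array_equal(after[k], v, err_msg=k)
        losses = [h["train_loss"] for h in model.history]
        assert abs(losses[0] - losses[1]) < 1e-4

    def test_same_seed_reproduces_first_epoch_loss(self, images_8class):
        runs = []
        for _ in range(2):
            model = build_model(ArchitectureSpec.tiny(64), 8, seed=1)
            train_model(model, images_8class,
                        cfg=TrainConfig(max_epochs=1, batch_size=32, seed=0))
            runs.append(model.history[0]["train_loss"])
        assert runs[0] == runs[1]

    def test_gradient_reaches_the_stem(self, rng):
        """The convolutional shortcuts keep a nonzero gradient path from the
        loss all the way down to the stem convolution."""
        model = build_model(ArchitectureSpec.tiny(64), 4, seed=1)
        x = rng.random((4, 64, 64, 3), dtype=np.float32)
        y = np.array([0, 1, 2, 3])
        out = model.forward(x, training=True)
        _nn.softmax_cross_entropy(out["logits"], y).backward()
        g = model.net.stem_conv.weight.grad
        assert g is not None and np.abs(g).max() > 0

    def test_too_few_classes_rejected(self, images_8class):
        model = build_model(ArchitectureSpec.tiny(64), 8, seed=1)
        with pytest.raises(ValueError):
            train_model(model, images_8class.images[:5], np.zeros(5, dtype=int),
                        TrainConfig(max_epochs=1))


class TestCheckpointRoundTrip:
    def test_save_load_preserves_predictions(self, tmp_path, images_8class):
        model = build_model(ArchitectureSpec.tiny(64), 8, seed=1)
        train_model(model, images_8class,
                    cfg=TrainConfig(max_epochs=1, batch_size=32, seed=0))
        p1 = model.predict_proba(images_8class.images[:4])
        model.save(tmp_path / "ckpt.npz")
        from gidfe import load_model

        restored = load_model(tmp_path / "ckpt.npz")
        p2 = restored.predict_proba(images_8class.images[:4])
        np.testing.assert_array_equal(p1, p2)
        assert restored.history == model.history
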