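"""Architecture contracts: shapes, identities, parameter accounting."""

import numpy as np
import pytest

from resmtunet import ModelConfig, count_macs, count_parameters, tiny_config
from resmtunet.model import (FeaturePyramid, PatchEmbed, ResMTUNet,
                             patch_embed_output_size)
from resmtunet.model.decoder import ClassificationHead, SegmentationHead
from resmtunet.model.encoder import FusionModule, ResidualBranch
from resmtunet.nn import Conv2d, Tensor, no_grad


class TestPatchEmbed:
    @pytest.mark.parametrize("size,k,s,p,expected", [
        (512, 7, 4, 3, 128),       # stage-1 embedding
        (128, 3, 2, 1, 64),        # stages 2-4 embedding
        (1, 1, 1, 0, 1),           # degenerate identity window
    ])
    def test_output_size_formula(self, size, k, s, p, expected):
        assert patch_embed_output_size(size, k, s, p) == expected

    def test_rejects_nonpositive_output(self):
        with pytest.raises(ValueError):
            patch_embed_output_size(2, 7, 4, 0)

    def test_degenerate_window_is_linear_in_input(self):
        rng = np.random.default_rng(0)
        pe = PatchEmbed(3, 4, 1, 1, 0, rng)
        x1 = rng.normal(size=(1, 3, 1, 1))
        x2 = rng.normal(size=(1, 3, 1, 1))
        y1 = pe(Tensor(x1)).data
        y2 = pe(Tensor(x2)).data
        y12 = pe(Tensor(x1 + x2)).data
        b = pe.proj.bias.data.reshape(1, 4, 1, 1)
        assert np.allclose(y12 - b, (y1 - b) + (y2 - b))


class TestPyramidShapes:
    def test_shape_ledger_64px(self, tiny_net):
        x = Tensor(np.random.default_rng(0).random((1, 3, 64, 64)))
        with no_grad():
            pyr = tiny_net.encode(x)
        assert [lv.shape[2] for lv in pyr.levels] == [16, 8, 4, 2]
        assert pyr.fused_top.shape[2:] == pyr.levels[3].shape[2:]

    def test_pyramid_rejects_swapped_levels(self, tiny_net):
        x = Tensor(np.random.default_rng(0).random((1, 3, 64, 64)))
        with no_grad():
            pyr = tiny_net.encode(x)
        bad = [pyr.levels[1], pyr.levels[0], pyr.levels[2], pyr.levels[3]]
        with pytest.raises(ValueError, match="halve"):
            FeaturePyramid(levels=bad, fused_top=pyr.fused_top)

    def test_forward_is_deterministic(self, tiny_net):
        x = Tensor(np.random.default_rng(1).random((1, 3, 64, 64)))
        tiny_net.eval()
        with no_grad():
            a = tiny_net(x).seg_logits.data
            b = tiny_net(x).seg_logits.data
        assert np.array_equal(a, b)


class TestResidualBranch:
    def test_stride_32_contract(self):
        cfg = tiny_config(input_size=64)
        branch = ResidualBranch(cfg, np.random.default_rng(0))
        with no_grad():
            out = branch(Tensor(np.random.default_rng(0).random((1, 3, 64, 64))))
        assert out.shape[2:] == (2, 2)
        assert out.shape[1] == branch.out_channels

    def test_stage_stride_table(self):
        """Per-stage spatial sizes follow the 2/4/4/8/16/32 stride ladder."""
        cfg = tiny_config(input_size=64)
        branch = ResidualBranch(cfg, np.random.default_rng(0))
        x = Tensor(np.random.default_rng(0).random((1, 3, 64, 64)))
        with no_grad():
            s = branch.stem(x)
            assert s.shape[2] == 32
            s = branch.pool(s)
            sizes = []
            for stage in branch.stages:
                s = stage(s)
                sizes.append(s.shape[2])
        assert sizes == [16, 8, 4, 2]

    def test_zeroed_residual_paths_reduce_to_projected_stem(self):
        """With all residual-path weights zero, each bottleneck passes its
        shortcut through a final ReLU, so the branch output equals the
        (projected, BN-scaled) stem signal propagated by shortcuts alone."""
        cfg = tiny_config(input_size=32)
        rng = np.random.default_rng(0)
        branch = ResidualBranch(cfg, rng)
        branch.eval()
        for stage in branch.stages:
            for block in stage.layers:
                block.conv3.weight.data[...] = 0.0
                block.bn3.bias.data[...] = 0.0
        x = Tensor(np.random.default_rng(1).random((1, 3, 32, 32)))
        with no_grad():
            ref = branch.pool(branch.stem(x))
            for stage in branch.stages:
                for block in stage.layers:
                    ref = block.shortcut(ref).relu()
            out = branch(x)
        assert np.allclose(out.data, ref.data)


class TestFusion:
    def test_shape_and_mismatch(self):
        rng = np.random.default_rng(0)
        fuse = FusionModule(4, 6, 8, rng)
        a = Tensor(rng.random((1, 4, 2, 2)))
        b = Tensor(rng.random((1, 6, 2, 2)))
        with no_grad():
            assert fuse(a, b).shape == (1, 8, 2, 2)
        with pytest.raises(ValueError, match="spatial"):
            fuse(a, Tensor(rng.random((1, 6, 4, 4))))

    def test_identity_slice_weights_recover_first_input(self):
        """Zero second input + identity-slice conv weights -> projection of
        the first input (BN frozen to identity)."""
        rng = np.random.default_rng(0)
        fuse = FusionModule(3, 2, 3, rng)
        fuse.eval()
        fuse.conv.weight.data[...] = 0.0
        for c in range(3):
            fuse.conv.weight.data[c, c, 1, 1] = 1.0
        a = Tensor(np.abs(rng.random((1, 3, 2, 2))))
        b = Tensor(np.zeros((1, 2, 2, 2)))
        with no_grad():
            out = fuse(a, b)
        assert np.allclose(out.data, a.data, atol=1e-4)

    def test_gradient_reaches_both_branches(self):
        rng = np.random.default_rng(0)
        fuse = FusionModule(3, 2, 4, rng)
        a = Tensor(rng.normal(size=(2, 3, 2, 2)), requires_grad=True)
        b = Tensor(rng.normal(size=(2, 2, 2, 2)), requires_grad=True)
        (fuse(a, b) ** 2).sum().backward()
        assert np.abs(a.grad).max() > 0
        assert np.abs(b.grad).max() > 0


class TestDecoder:
    def test_decoder_levels_and_output_size(self, tiny_net):
        x = Tensor(np.random.default_rng(0).random((1, 3, 64, 64)))
        with no_grad():
            pyr = tiny_net.encode(x)
            out = tiny_net.decoder(pyr)
        assert out.shape[2:] == (16, 16)          # stride 4

    def test_constant_propagation_oracle(self):
        """Channel-mean convolutions + constant inputs: the decoder output
        equals the nested mean computable by hand."""
        rng = np.random.default_rng(0)
        from resmtunet.model.decoder import DecoderBlock
        blk = DecoderBlock(2, 3, 4, rng)
        blk.eval()
        cin = 2 + 3
        blk.conv.weight.data[...] = 0.0
        blk.conv.weight.data[:, :, 1, 1] = 1.0 / cin    # channel mean
        skip = Tensor(np.full((1, 2, 4, 4), 2.0))
        below = Tensor(np.full((1, 3, 2, 2), 8.0))
        with no_grad():
            out = blk(skip, below)
        # mean over channels of concat(2,2, 8,8,8) = (2*2 + 3*8)/5
        assert np.allclose(out.data, (2 * 2 + 3 * 8) / 5)

    def test_missing_fused_top_raises(self, tiny_net):
        x = Tensor(np.random.default_rng(0).random((1, 3, 64, 64)))
        with no_grad():
            pyr = tiny_net.encode(x)
            pyr.fused_top = None
            with pytest.raises(ValueError, match="fused"):
                tiny_net.decoder(pyr)


class TestHeads:
    def test_classification_closed_form_on_constant_input(self):
        rng = np.random.default_rng(0)
        head = ClassificationHead(3, 4, rng)
        c = np.array([0.3, -1.2, 2.0])
        x = Tensor(np.broadcast_to(c[None, :, None, None], (1, 3, 5, 5)).copy())
        with no_grad():
            probs = head(x).data[0]
        z = head.fc.weight.data @ c + head.fc.bias.data
        want = np.exp(z - z.max())
        want /= want.sum()
        assert np.allclose(probs, want)

    def test_zero_weights_give_uniform_distribution(self):
        rng = np.random.default_rng(0)
        head = ClassificationHead(3, 4, rng)
        head.fc.weight.data[...] = 0.0
        head.fc.bias.data[...] = 0.0
        with no_grad():
            probs = head(Tensor(rng.random((2, 3, 4, 4)))).data
        assert np.allclose(probs, 0.25)

    @pytest.mark.parametrize("n_class", [2, 4, 6])
    def test_segmentation_channels_and_upsampling(self, n_class):
        rng = np.random.default_rng(0)
        head = SegmentationHead(6, 3, n_class, rng)
        with no_grad():
            out = head(Tensor(rng.random((1, 6, 8, 8))))
        assert out.shape == (1, n_class + 1, 32, 32)

    def test_upsampling_against_interpolation_oracle(self):
        """The x4 bilinear path reproduces an independently coded
        interpolation of a ramp."""
        from resmtunet.nn import interpolate_bilinear
        ramp = np.arange(16, dtype=float).reshape(1, 1, 4, 4)
        got = interpolate_bilinear(Tensor(ramp), (8, 8)).data[0, 0]

        def oracle(img, ho, wo):
            h, w = img.shape
            out = np.empty((ho, wo))
            for i in range(ho):
                for j in range(wo):
                    y = np.clip((i + 0.5) * h / ho - 0.5, 0, h - 1)
                    x = np.clip((j + 0.5) * w / wo - 0.5, 0, w - 1)
                    y0, x0 = int(np.floor(y)), int(np.floor(x))
                    y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
                    fy, fx = y - y0, x - x0
                    out[i, j] = (img[y0, x0] * (1 - fy) * (1 - fx)
                                 + img[y0, x1] * (1 - fy) * fx
                                 + img[y1, x0] * fy * (1 - fx)
                                 + img[y1, x1] * fy * fx)
            return out

        assert np.abs(got - oracle(ramp[0, 0], 8, 8)).max() < 1e-12


class TestForward:
    def test_output_contracts(self, tiny_net):
        rng = np.random.default_rng(0)
        with no_grad():
            out = tiny_net(Tensor(rng.random((2, 3, 64, 64))))
        assert out.class_probs.shape == (2, 4)
        assert out.seg_logits.shape == (2, 5, 64, 64)
        assert np.allclose(out.class_probs.data.sum(axis=1), 1.0, atol=1e-5)
        assert (out.class_probs.data >= 0).all()
        assert np.isfinite(out.seg_logits.data).all()

    def test_batch_permutation_equivariance(self, tiny_net):
        rng = np.random.default_rng(3)
        x = rng.random((3, 3, 64, 64))
        perm = [2, 0, 1]
        tiny_net.eval()
        with no_grad():
            a = tiny_net(Tensor(x)).seg_logits.data
            b = tiny_net(Tensor(x[perm])).seg_logits.data
        assert np.allclose(a[perm], b, atol=1e-10)

    def test_rejects_bad_input_shape(self, tiny_net):
        with pytest.raises(ValueError, match="NCHW"):
            tiny_net(Tensor(np.zeros((1, 64, 64))))


class TestComplexity:
    def test_single_conv_closed_form(self):
        rng = np.random.default_rng(0)
        conv = Conv2d(3, 8, 3, rng=rng)
        assert sum(p.size for p in conv.parameters()) == 3 * 3 * 3 * 8 + 8

    def test_analytic_count_matches_constructed_model(self, tiny_net):
        assert tiny_net.num_parameters() == count_parameters(tiny_net.cfg)

    def test_width_scaling_law(self):
        """Doubling every width roughly quadruples the parameter count of the
        convolution-dominated model."""
        lo = count_parameters(tiny_config(input_size=64))
        hi = count_parameters(ModelConfig(
            input_size=64, width_multiplier=0.25, stage_depths=(1, 1, 2, 1)))
        assert 3.0 < hi / lo < 4.5

    def test_macs_scale_with_input_area(self):
        cfg = tiny_config(input_size=64)
        m64 = count_macs(cfg, 64)
        m128 = count_macs(cfg, 128)
        assert 3.5 < m128 / m64 < 4.5

    def test_config_validation(self):
        with pytest.raises(ValueError, match="divisible by 32"):
            ModelConfig(input_size=500)
        with pytest.raises(ValueError, match="n_class"):
            ModelConfig(n_class=1)
        with pytest.raises(ValueError, match="reduction"):
            ModelConfig(reduction_ratios=(0, 4, 2, 1))


def test_checkpoint_roundtrip(tmp_path, tiny_net):
    path = tmp_path / "ckpt.npz"
    tiny_net.save(path)
    clone = ResMTUNet.from_checkpoint(path)
    x = Tensor(np.random.default_rng(0).random((1, 3, 64, 64)))
    tiny_net.eval()
    clone.eval()
    with no_grad():
        a = tiny_net(x).seg_logits.data
        b = clone(x).seg_logits.data
    assert np.array_equal(a, b)
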