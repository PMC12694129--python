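"""Local-global attention unit and holistic attention block head."""

import numpy as np
import pytest

from reefblocks.hab import (ECA, HAB, LGA, SAM, HABHead, LGAConfig,
                            lga_relevance_mask)
from reefblocks.nn import Tensor


@pytest.fixture
def lga2(rng):
    return LGA(LGAConfig(patch_size=2, channels=6), rng=rng)


class TestPatchEncoding:
    def test_constant_input_channel_mean_is_constant(self, lga2):
        """Mean pooling a constant map across channels keeps the value."""
        x = Tensor(np.full((1, 6, 4, 4), 7.0, dtype=np.float32))
        p = lga2.cfg.patch_size
        xm = x.mean(axis=1)
        patches = (xm.reshape(1, 2, p, 2, p).transpose(0, 1, 3, 2, 4)
                   .reshape(1, 4, p * p))
        np.testing.assert_allclose(patches.data, 7.0, atol=1e-6)

    def test_single_channel_mean_is_identity(self, rng):
        lga = LGA(LGAConfig(patch_size=2, channels=1), rng=rng)
        x_arr = rng.normal(size=(1, 1, 2, 2)).astype(np.float32)
        xm = Tensor(x_arr).mean(axis=1)
        np.testing.assert_allclose(xm.data[0], x_arr[0, 0], atol=1e-7)

    def test_four_by_four_patch_order_is_row_major(self, lga2, rng):
        """4x4 input with p=2 tokenizes to exactly 4 patches ordered
        top-left, top-right, bottom-left, bottom-right (enumeration oracle)."""
        x_arr = rng.normal(size=(1, 6, 4, 4)).astype(np.float32)
        xm = x_arr.mean(axis=1)[0]  # (4, 4)
        expected = [xm[0:2, 0:2], xm[0:2, 2:4], xm[2:4, 0:2], xm[2:4, 2:4]]
        p = 2
        patches = (Tensor(x_arr).mean(axis=1).reshape(1, 2, p, 2, p)
                   .transpose(0, 1, 3, 2, 4).reshape(1, 4, p * p)).data[0]
        for k in range(4):
            np.testing.assert_allclose(patches[k], expected[k].ravel(),
                                       atol=1e-7)
        enc = lga2.encode_patches(Tensor(x_arr))
        assert enc.shape == (1, 4, 6)


class TestRelevanceMask:
    def test_identical_vectors_approach_one_as_epsilon_vanishes(self):
        pg = Tensor(np.array([1.0, 2.0, 2.0], dtype=np.float32))
        for eps, tol in [(1e-2, 0.01), (1e-8, 1e-7)]:
            m = lga_relevance_mask(pg, pg, eps).data
            norm2 = 9.0
            assert m == pytest.approx(norm2 / (norm2 + eps), rel=1e-5)
            assert m <= 1.0

    def test_orthogonal_vectors_give_zero(self):
        a = Tensor(np.array([1.0, 0.0], dtype=np.float32))
        b = Tensor(np.array([0.0, 3.0], dtype=np.float32))
        assert lga_relevance_mask(a, b, 1e-6).data == pytest.approx(0.0)

    def test_antiparallel_clamps_to_zero(self):
        a = Tensor(np.array([1.0, -2.0], dtype=np.float32))
        m = lga_relevance_mask(a, -1.0 * a, 1e-6).data
        assert m == 0.0

    def test_mask_in_unit_interval_for_arbitrary_inputs(self, rng):
        for _ in range(50):
            a = Tensor(rng.normal(size=8).astype(np.float32) * 100)
            b = Tensor(rng.normal(size=8).astype(np.float32) * 100)
            m = lga_relevance_mask(a, b, 1e-6).data
            assert 0.0 <= m <= 1.0

    def test_zero_vector_safe(self):
        z = Tensor(np.zeros(4, dtype=np.float32))
        p = Tensor(np.ones(4, dtype=np.float32))
        assert np.isfinite(lga_relevance_mask(z, p, 1e-6).data)


class TestLGAForward:
    @pytest.mark.parametrize("hw", [(8, 8), (7, 5), (4, 4)])
    def test_output_spatial_shape_equals_input(self, lga2, rng, hw):
        x = Tensor(rng.normal(size=(2, 6, *hw)).astype(np.float32))
        assert lga2(x).shape == (2, 6, *hw)

    def test_orthogonal_prompt_zeroes_the_preconv_map(self, rng):
        """If the prompt is orthogonal to every gated patch encoding, all
        relevance masks are zero and the pre-convolution map vanishes."""
        lga = LGA(LGAConfig(patch_size=2, channels=8), rng=rng)
        x = Tensor(rng.normal(size=(1, 8, 4, 4)).astype(np.float32))
        l = lga.encode_patches(x)
        from reefblocks.nn import functional as F
        l_prime = (l * F.softmax(l, axis=-1)).data[0]  # (N, C)
        # build a prompt orthogonal to the span of all gated encodings
        _, _, vt = np.linalg.svd(l_prime)
        null = vt[-1]
        assert np.abs(l_prime @ null).max() < 1e-5
        lga.prompt.data = null.astype(np.float32)
        pre = lga(x, return_premap=True).data
        np.testing.assert_allclose(pre, 0.0, atol=1e-5)

    def test_degenerate_single_pixel_grid(self, rng):
        lga = LGA(LGAConfig(patch_size=1, channels=3), rng=rng)
        x = Tensor(rng.normal(size=(1, 3, 1, 1)).astype(np.float32))
        assert lga(x).shape == (1, 3, 1, 1)


class TestHAB:
    def test_output_channels_match_config(self, rng):
        hab = HAB(5, 9, rng=rng)
        x = Tensor(rng.normal(size=(2, 5, 8, 8)).astype(np.float32))
        assert hab(x).shape == (2, 9, 8, 8)

    def test_zeroed_branches_reduce_to_refined_skip(self, rng):
        """With the deep-conv and LGA branch outputs forced to zero, the
        fusion is exactly the skip path through ECA/SAM/BN/ReLU."""
        from reefblocks.nn import functional as F

        hab = HAB(4, 4, rng=rng)
        hab.eval()
        for blk in (hab.c1, hab.c2, hab.c3):
            blk.conv.weight.data[:] = 0
        for lga in hab.lgas:
            lga.proj.weight.data[:] = 0
            lga.proj.bias.data[:] = 0
        # zeroed conv + BN still adds the BN bias; zero those too
        for blk in (hab.c1, hab.c2, hab.c3):
            blk.bn.beta.data[:] = 0
        x = Tensor(np.abs(rng.normal(size=(1, 4, 8, 8))).astype(np.float32))
        out = hab(x).data
        x_skip = hab.c_skip(x)
        expected = F.relu(hab.bn(hab.sam(hab.eca(x_skip)))).data
        np.testing.assert_allclose(out, expected, atol=1e-5)

    def test_batch_permutation_equivariance_in_eval(self, rng):
        hab = HAB(3, 6, rng=rng)
        hab.eval()
        x = rng.normal(size=(4, 3, 8, 8)).astype(np.float32)
        out = hab(Tensor(x)).data
        perm = np.array([2, 0, 3, 1])
        out_perm = hab(Tensor(x[perm])).data
        np.testing.assert_allclose(out_perm, out[perm], atol=1e-5)

    def test_gradient_reaches_input_through_skip_with_frozen_deep_path(self, rng):
        hab = HAB(3, 3, rng=rng)
        hab.eval()
        for blk in (hab.c1, hab.c2, hab.c3):
            blk.conv.weight.data[:] = 0
        x = Tensor(rng.normal(size=(1, 3, 4, 4)).astype(np.float32),
                   requires_grad=True)
        hab(x).sum().backward()
        assert x.grad is not None
        assert np.abs(x.grad).max() > 0

    def test_fusion_is_additive_in_each_branch(self, rng):
        """Doubling one branch's pre-fusion output shifts the aggregate by
        exactly that branch's contribution (attention stages bypassed)."""
        from reefblocks.nn import functional as F

        hab = HAB(3, 5, rng=rng)
        hab.eval()
        x = Tensor(rng.normal(size=(1, 3, 8, 8)).astype(np.float32))
        x_skip = hab.c_skip(x)
        x1 = hab.c1(x)
        x2 = hab.c2(x1)
        x_deep = hab.c3(x2)
        lga_outs = [lga(x_skip) for lga in hab.lgas]
        base = (x_skip + x1 + x2 + x_deep + lga_outs[0] + lga_outs[1]).data
        doubled = (x_skip + x1 * 2.0 + x2 + x_deep + lga_outs[0] + lga_outs[1]).data
        np.testing.assert_allclose(doubled - base, x1.data, atol=1e-5)


class TestHABHead:
    def test_pyramid_grids_and_class_channels(self, rng):
        head = HABHead((4, 6, 8), n_classes=4, rng=rng)
        p3 = Tensor(rng.normal(size=(1, 4, 80, 80)).astype(np.float32))
        p4 = Tensor(rng.normal(size=(1, 6, 40, 40)).astype(np.float32))
        p5 = Tensor(rng.normal(size=(1, 8, 20, 20)).astype(np.float32))
        out = head([p3, p4, p5])
        sizes = [(80, 80), (40, 40), (20, 20)]
        for (cls, reg), (h, w) in zip(out, sizes):
            assert cls.shape[1] == 4 and reg.shape[1] == 4
            assert cls.shape[2:] == (h, w) and reg.shape[2:] == (h, w)

    def test_two_stacks_have_more_parameters_than_one(self, rng):
        two = HABHead((4, 4, 4), 4, stacks=2, rng=np.random.default_rng(0))
        one = HABHead((4, 4, 4), 4, stacks=1, rng=np.random.default_rng(0))
        assert two.n_parameters() > one.n_parameters()

    def test_wrong_level_count_rejected(self, rng):
        from reefblocks.errors import ConfigurationError
        with pytest.raises(ConfigurationError):
            HABHead((4, 4), 4, rng=rng)
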