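"""Exactness of the diverse-branch-block fusion algebra.

Every transform is checked against a literal forward computation: the
fused kernel must reproduce the multi-branch (or sequential) forward to
floating-point precision, not approximately.
"""

import numpy as np
import pytest

from conftest import randomize_bn, randomize_dbb
from veinid.autodiff import Tensor, conv2d
from veinid.nn import BatchNorm2d
from veinid.optim import AdamW
from veinid.reparam import (BNStats, DiverseBranchBlock, FusedKernel,
                            avgpool_as_conv, fuse_conv_bn,
                            merge_parallel_branches,
                            merge_sequential_1x1_kxk, reparameterize_dbb)


def random_kernel(rng, cout, cin, k):
    return FusedKernel(rng.normal(0, 0.5, (cout, cin, k, k)),
                       rng.normal(0, 0.5, cout))


def random_bn_stats(rng, c):
    return BNStats(gamma=rng.normal(1, 0.3, c), beta=rng.normal(0, 0.3, c),
                   mean=rng.normal(0, 0.5, c), var=rng.uniform(0.5, 2.0, c))


class TestFuseConvBn:
    def test_identity_bn_leaves_kernel_unchanged(self, rng):
        k = random_kernel(rng, 3, 2, 3)
        bn = BNStats(np.ones(3), np.zeros(3), np.zeros(3), np.ones(3), eps=0.0)
        fused = fuse_conv_bn(k, bn)
        assert np.allclose(fused.weight, k.weight)
        assert np.allclose(fused.bias, k.bias)

    def test_zero_kernel_folds_to_constant_beta_channel(self, rng):
        k = FusedKernel(np.zeros((3, 2, 3, 3)), np.zeros(3))
        bn = random_bn_stats(rng, 3)
        bn.mean = np.zeros(3)
        fused = fuse_conv_bn(k, bn)
        assert np.allclose(fused.weight, 0)
        assert np.allclose(fused.bias, bn.beta)

    def test_fused_forward_equals_sequential_conv_then_bn(self, rng):
        k = random_kernel(rng, 2, 2, 3)
        bn = random_bn_stats(rng, 2)
        x = rng.random((1, 2, 5, 5))
        seq = conv2d(Tensor(x), Tensor(k.weight), Tensor(k.bias), padding=1).data
        scale = bn.gamma / np.sqrt(bn.var + bn.eps)
        seq = seq * scale[None, :, None, None] \
            + (bn.beta - bn.mean * scale)[None, :, None, None]
        fused = fuse_conv_bn(k, bn).forward(x)
        assert np.abs(fused - seq).max() < 1e-6

    def test_channel_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="channel"):
            fuse_conv_bn(random_kernel(rng, 3, 2, 3), random_bn_stats(rng, 4))

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            BNStats(np.ones(2), np.zeros(2), np.zeros(2),
                    np.array([-1.0, 1.0]), eps=1e-7)


class TestMergeParallel:
    def test_merging_kernel_with_itself_doubles_everything(self, rng):
        k = random_kernel(rng, 3, 2, 3)
        merged = merge_parallel_branches([k, k], 3)
        x = rng.random((1, 2, 7, 7))
        assert np.allclose(merged.weight, 2 * k.weight)
        assert np.abs(merged.forward(x) - 2 * k.forward(x)).max() < 1e-10

    def test_zero_kernel_is_additive_identity(self, rng):
        k = random_kernel(rng, 3, 2, 3)
        zero = FusedKernel(np.zeros_like(k.weight), np.zeros(3))
        merged = merge_parallel_branches([k, zero], 3)
        assert np.allclose(merged.weight, k.weight)
        assert np.allclose(merged.bias, k.bias)

    def test_mixed_sizes_forward_equals_sum_of_branches(self, rng):
        k3 = random_kernel(rng, 3, 2, 3)
        k1 = random_kernel(rng, 3, 2, 1)
        merged = merge_parallel_branches([k3, k1], 3)
        x = rng.random((2, 2, 7, 7))
        separate = k3.forward(x, padding=1) + k1.forward(x, padding=0)
        assert np.abs(merged.forward(x, padding=1) - separate).max() < 1e-6

    @pytest.mark.parametrize("bad_k", [2, 5])
    def test_even_or_oversized_kernels_rejected(self, rng, bad_k):
        good = random_kernel(rng, 2, 2, 3)
        bad = FusedKernel(np.zeros((2, 2, bad_k, bad_k)), np.zeros(2))
        with pytest.raises(ValueError):
            merge_parallel_branches([good, bad], 3)

    def test_merge_is_linear_in_each_branch(self, rng):
        """Scaling one branch's kernel scales its contribution."""
        k3 = random_kernel(rng, 3, 2, 3)
        k1 = random_kernel(rng, 3, 2, 1)
        alpha = 2.75
        scaled = FusedKernel(alpha * k1.weight, alpha * k1.bias)
        m1 = merge_parallel_branches([k3, scaled], 3)
        m0 = merge_parallel_branches([k3, FusedKernel(0 * k1.weight,
                                                      0 * k1.bias)], 3)
        mk = merge_parallel_branches([k3, k1], 3)
        assert np.allclose(m1.weight, m0.weight + alpha * (mk.weight - m0.weight))
        assert np.allclose(m1.bias, m0.bias + alpha * (mk.bias - m0.bias))


class TestMergeSequential:
    def _composite_forward(self, x, k1, k2, pad):
        """Oracle: pad input, 1×1 (valid) — so the border carries the
        1×1 bias — then K×K valid."""
        xp = np.pad(x, [(0, 0), (0, 0), (pad, pad), (pad, pad)])
        y = k1.forward(xp, padding=0)
        return k2.forward(y, padding=0)

    def test_identity_1x1_returns_second_kernel(self, rng):
        c = 4
        eye = FusedKernel(np.eye(c)[:, :, None, None], np.zeros(c))
        k2 = random_kernel(rng, 3, c, 3)
        merged = merge_sequential_1x1_kxk(eye, k2)
        assert np.allclose(merged.weight, k2.weight)
        assert np.allclose(merged.bias, k2.bias)

    def test_zero_1x1_leaves_only_bias_response(self, rng):
        k1 = FusedKernel(np.zeros((4, 2, 1, 1)), rng.normal(0, 1, 4))
        k2 = random_kernel(rng, 3, 4, 3)
        merged = merge_sequential_1x1_kxk(k1, k2)
        assert np.allclose(merged.weight, 0)
        expected = k2.bias + np.einsum("omhw,m->o", k2.weight, k1.bias)
        assert np.allclose(merged.bias, expected)

    def test_merged_forward_equals_sequential_forward(self, rng):
        k1 = random_kernel(rng, 4, 2, 1)
        k2 = random_kernel(rng, 3, 4, 3)
        merged = merge_sequential_1x1_kxk(k1, k2)
        x = rng.random((1, 2, 8, 8))
        assert np.abs(merged.forward(x, padding=1)
                      - self._composite_forward(x, k1, k2, 1)).max() < 1e-6

    def test_channel_chain_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="chain"):
            merge_sequential_1x1_kxk(random_kernel(rng, 4, 2, 1),
                                     random_kernel(rng, 3, 5, 3))


class TestAvgPoolAsConv:
    def test_k1_is_channel_identity(self):
        fk = avgpool_as_conv(1, 3)
        assert np.allclose(fk.weight[:, :, 0, 0], np.eye(3))

    def test_k3_diagonal_taps_are_one_ninth(self):
        fk = avgpool_as_conv(3, 4)
        for c in range(4):
            assert np.allclose(fk.weight[c, c], 1.0 / 9)
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(fk.weight[off], 0)

    def test_forward_equals_direct_average_pooling(self, rng):
        fk = avgpool_as_conv(3, 4)
        x = rng.random((2, 4, 8, 8))
        direct = np.zeros((2, 4, 6, 6))
        for i in range(3):
            for j in range(3):
                direct += x[:, :, i:i + 6, j:j + 6]
        direct /= 9
        assert np.abs(fk.forward(x, padding=0) - direct).max() < 1e-7


class TestReparameterizeDbb:
    def test_zeroed_side_branches_recover_kxk_kernel(self, rng):
        dbb = DiverseBranchBlock(3, 5, 3, rng=rng, dtype=np.float64)
        dbb.eval()
        for conv in (dbb.conv_1x1, dbb.seq_1x1, dbb.avg_1x1):
            conv.weight.data[:] = 0.0
        fk = dbb.fuse()
        assert np.allclose(fk.weight, dbb.conv_kxk.weight.data)
        assert np.allclose(fk.bias, 0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_fused_forward_matches_branch_sum_across_configs(self, seed):
        """Fusion exactness over randomized configurations (double
        precision, tolerance 1e-10)."""
        rng = np.random.default_rng(seed)
        cin = int(rng.integers(1, 6))
        cout = int(rng.integers(1, 8))
        k = int(rng.choice([1, 3, 5]))
        dbb = DiverseBranchBlock(cin, cout, k, rng=rng, dtype=np.float64)
        randomize_dbb(dbb, rng)
        dbb.eval()
        x = rng.random((2, cin, 11, 11))
        train_out = dbb(Tensor(x)).data
        deploy_out = dbb.fuse().forward(x)
        assert np.abs(train_out - deploy_out).max() < 1e-10

    def test_single_precision_block_fuses_within_1e4(self, rng):
        dbb = DiverseBranchBlock(4, 8, 3, rng=rng, dtype=np.float32)
        randomize_dbb(dbb, rng)
        dbb.eval()
        x = rng.random((2, 4, 28, 28)).astype(np.float32)
        train_out = dbb(Tensor(x)).data
        fk = dbb.fuse()
        deploy_out = FusedKernel(fk.weight.astype(np.float32),
                                 fk.bias.astype(np.float32)).forward(x)
        assert np.abs(train_out - deploy_out).max() < 1e-4

    def test_equivalence_survives_gradient_steps(self, rng):
        """Train the block briefly on a toy regression, then fuse."""
        dbb = DiverseBranchBlock(2, 3, 3, rng=rng, dtype=np.float64)
        opt = AdamW(dbb.parameters(), lr=1e-2)
        x = rng.random((4, 2, 9, 9))
        target = rng.random((4, 3, 9, 9))
        dbb.train()
        for _ in range(5):
            out = dbb(Tensor(x))
            loss = ((out - Tensor(target)) ** 2).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
        dbb.eval()
        train_out = dbb(Tensor(x)).data
        assert np.abs(train_out - dbb.fuse().forward(x)).max() < 1e-10

    def test_fusion_requires_eval_mode(self, rng):
        dbb = DiverseBranchBlock(2, 3, 3, rng=rng)
        dbb.train()
        with pytest.raises(RuntimeError, match="eval"):
            reparameterize_dbb(dbb)

    def test_deploy_parameters_fewer_than_train_structure(self, rng):
        for k in (3, 5):
            dbb = DiverseBranchBlock(4, 6, k, rng=rng)
            deploy = 6 * 4 * k * k + 6  # fused conv weight + bias
            assert deploy < dbb.param_count()
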