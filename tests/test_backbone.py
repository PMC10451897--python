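"""Cross-scale transformer: embeddings, attention, encoder blocks, fusion."""

import numpy as np
import pytest

from milct.autodiff import Tensor
from milct.backbone import (CrossAttention, CrossScaleTransformer,
                            EncoderBlock, MHSA, PatchEmbed, _CTRepetition)
from milct.nn import LayerNorm
from milct.specs import BranchSpec, ModelSpec


def _rng():
    return np.random.default_rng(42)


# ----------------------------------------------------------------------
# patch embedding
# ----------------------------------------------------------------------

class TestPatchEmbed:
    @pytest.mark.parametrize("s,p,n", [(224, 16, 196), (240, 12, 400)])
    def test_token_counts(self, s, p, n):
        spec = BranchSpec(p, s, 32, 1, 1)
        embed = PatchEmbed(spec, _rng())
        out = embed(np.zeros((1, s, s, 3)))
        assert out.shape == (1, n + 1, 32)

    def test_invalid_divisibility_errors(self):
        with pytest.raises(ValueError):
            BranchSpec(12, 224, 96, 1, 3)

    def test_zero_weights_give_zero_patches_and_init_cls(self):
        spec = BranchSpec(16, 32, 8, 1, 1)
        embed = PatchEmbed(spec, _rng())
        embed.proj.weight.data[:] = 0
        embed.proj.bias.data[:] = 0
        embed.pos.data[:] = 0
        out = embed(np.zeros((2, 32, 32, 3)))
        np.testing.assert_allclose(out.data[:, 1:, :], 0.0)
        np.testing.assert_allclose(
            out.data[:, 0, :], np.broadcast_to(embed.cls.data[0, 0], (2, 8)))


# ----------------------------------------------------------------------
# layer normalization
# ----------------------------------------------------------------------

class TestLayerNorm:
    def test_constant_token_maps_to_zero(self):
        ln = LayerNorm(4, eps=1e-6)
        out = ln(Tensor(np.full((1, 4), 3.7)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-3)

    def test_zero_gamma_gives_beta(self):
        ln = LayerNorm(4)
        ln.gamma.data[:] = 0
        ln.beta.data[:] = 2.5
        out = ln(Tensor(np.random.default_rng(0).normal(size=(5, 4))))
        np.testing.assert_allclose(out.data, 2.5)

    def test_matches_formula_oracle_on_random_vector(self):
        rng = _rng()
        x = rng.normal(size=4)
        gamma, beta, eps = rng.normal(size=4), rng.normal(size=4), 1e-6
        ln = LayerNorm(4, eps=eps)
        ln.gamma.data[:] = gamma
        ln.beta.data[:] = beta
        # oracle: direct evaluation of (x - E x)/sqrt(Var x + eps) * g + b
        expected = (x - x.mean()) / np.sqrt(x.var() + eps) * gamma + beta
        np.testing.assert_allclose(ln(Tensor(x[None])).data[0], expected,
                                   rtol=1e-12)


# ----------------------------------------------------------------------
# self-attention
# ----------------------------------------------------------------------

class TestMHSA:
    def test_single_token_attends_to_itself(self):
        attn = MHSA(8, 2, _rng())
        attn(Tensor(np.random.default_rng(3).normal(size=(1, 1, 8))))
        np.testing.assert_allclose(attn.last_attention, 1.0)

    def test_identical_tokens_give_uniform_attention(self):
        attn = MHSA(8, 2, _rng())
        x = np.tile(np.random.default_rng(4).normal(size=(1, 1, 8)), (1, 5, 1))
        attn(Tensor(x))
        np.testing.assert_allclose(attn.last_attention, 0.2, atol=1e-12)

    def test_two_token_single_head_matches_matrix_oracle(self):
        rng = _rng()
        attn = MHSA(2, 1, rng)
        x = rng.normal(size=(1, 2, 2))
        out = attn(Tensor(x)).data[0]
        # oracle: enumerate Q, K, V arithmetic directly
        w = attn.qkv.weight.data
        b = attn.qkv.bias.data
        qkv = x[0] @ w.T + b
        q, k, v = qkv[:, :2], qkv[:, 2:4], qkv[:, 4:]
        scores = q @ k.T / np.sqrt(2.0)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        expected = (a @ v) @ attn.out.weight.data.T + attn.out.bias.data
        np.testing.assert_allclose(out, expected, rtol=1e-10)
        np.testing.assert_allclose(attn.last_attention[0, 0], a, rtol=1e-10)

    def test_rows_sum_to_one(self):
        attn = MHSA(12, 3, _rng())
        attn(Tensor(np.random.default_rng(5).normal(size=(2, 7, 12))))
        sums = attn.last_attention.sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-6)

    def test_indivisible_heads_error(self):
        with pytest.raises(ValueError):
            MHSA(10, 3, _rng())


# ----------------------------------------------------------------------
# encoder block
# ----------------------------------------------------------------------

class TestEncoderBlock:
    def test_identity_when_residual_outputs_zeroed(self):
        spec = BranchSpec(16, 32, 8, 1, 2)
        blk = EncoderBlock(spec, _rng())
        blk.attn.out.weight.data[:] = 0
        blk.attn.out.bias.data[:] = 0
        blk.ffn.fc2.weight.data[:] = 0
        blk.ffn.fc2.bias.data[:] = 0
        x = np.random.default_rng(6).normal(size=(2, 5, 8))
        np.testing.assert_allclose(blk(Tensor(x)).data, x)

    def test_shape_preserved(self):
        spec = BranchSpec(16, 224, 192, 1, 6)
        blk = EncoderBlock(spec, _rng())
        out = blk(Tensor(np.zeros((1, 197, 192))))
        assert out.shape == (1, 197, 192)

    def test_composition_matches_suboperation_oracle(self):
        spec = BranchSpec(16, 32, 4, 1, 1)
        blk = EncoderBlock(spec, _rng())
        x = np.random.default_rng(7).normal(size=(1, 3, 4))
        got = blk(Tensor(x)).data
        y = x + blk.attn(blk.ln1(Tensor(x))).data
        expected = y + blk.ffn(blk.ln2(Tensor(y))).data
        np.testing.assert_allclose(got, expected, rtol=1e-12)


# ----------------------------------------------------------------------
# cross-scale attention fusion
# ----------------------------------------------------------------------

class TestCrossAttentionFuse:
    def test_zero_other_patches_degenerates_to_self_attention(self):
        ca = CrossAttention(4, 6, 2, _rng())
        cls_own = Tensor(np.random.default_rng(8).normal(size=(1, 1, 4)))
        ca(cls_own, Tensor(np.zeros((1, 0, 6))))
        np.testing.assert_allclose(ca.last_attention, 1.0)

    def test_attention_map_has_single_query_row(self):
        ca = CrossAttention(4, 6, 2, _rng())
        ca(Tensor(np.zeros((3, 1, 4))),
           Tensor(np.random.default_rng(9).normal(size=(3, 11, 6))))
        assert ca.last_attention.shape == (3, 2, 1, 12)
        np.testing.assert_allclose(ca.last_attention.sum(axis=-1), 1.0,
                                   atol=1e-6)

    def test_patch_tokens_pass_through_unchanged(self):
        spec = ModelSpec(f_branch=BranchSpec(8, 16, 4, 1, 1),
                         c_branch=BranchSpec(16, 32, 6, 1, 2), T=1)
        rep = _CTRepetition(spec, _rng())
        rng = np.random.default_rng(10)
        xf = Tensor(rng.normal(size=(2, 5, 4)))
        xc = Tensor(rng.normal(size=(2, 5, 6)))
        # isolate the fusion step: zero-depth branches
        rep.blocks_f, rep.blocks_c = [], []
        zf, zc = rep(xf, xc)
        np.testing.assert_array_equal(zf.data[:, 1:], xf.data[:, 1:])
        np.testing.assert_array_equal(zc.data[:, 1:], xc.data[:, 1:])

    def test_matches_stepwise_equation_oracle(self):
        # dims 2/2, one patch per branch, full brute-force of the fusion
        ca = CrossAttention(2, 2, 1, _rng())
        rng = np.random.default_rng(11)
        cls_own = rng.normal(size=(1, 1, 2))
        patches = rng.normal(size=(1, 1, 2))
        got = ca(Tensor(cls_own), Tensor(patches)).data

        def ln(v, mod):
            mu, var = v.mean(), v.var()
            return (v - mu) / np.sqrt(var + mod.eps) * mod.gamma.data \
                + mod.beta.data

        p = ln(cls_own[0, 0], ca.ln_proj) @ ca.proj.weight.data.T \
            + ca.proj.bias.data
        xhat = np.vstack([p, patches[0]])
        xn = np.vstack([ln(r, ca.ln_in) for r in xhat])
        q = xn[0:1] @ ca.wq.weight.data.T
        k = xn @ ca.wk.weight.data.T
        v = xn @ ca.wv.weight.data.T
        scores = q @ k.T / np.sqrt(2.0)
        e = np.exp(scores - scores.max())
        a = e / e.sum()
        fused = (a @ v) @ ca.wo.weight.data.T + ca.wo.bias.data
        u = p + fused[0]
        expected = ln(u, ca.ln_back) @ ca.back.weight.data.T \
            + ca.back.bias.data
        np.testing.assert_allclose(got[0, 0], expected, rtol=1e-10)


# ----------------------------------------------------------------------
# full backbone forward
# ----------------------------------------------------------------------

def _tiny_spec(T=1):
    return ModelSpec(f_branch=BranchSpec(8, 32, 4, 1, 1),
                     c_branch=BranchSpec(16, 32, 6, 1, 2), T=T)


class TestCTForward:
    def test_T_zero_equals_normalized_embeddings(self):
        ct = CrossScaleTransformer(_tiny_spec(T=0), _rng())
        imgs = np.random.default_rng(12).normal(size=(1, 32, 32, 3))
        sf, sc = ct(imgs, imgs)
        np.testing.assert_allclose(sf.data, ct.norm_f(ct.embed_f(imgs)).data)
        np.testing.assert_allclose(sc.data, ct.norm_c(ct.embed_c(imgs)).data)

    def test_deterministic_under_fixed_seed(self):
        imgs = np.random.default_rng(13).normal(size=(1, 32, 32, 3))
        outs = []
        for _ in range(2):
            ct = CrossScaleTransformer(_tiny_spec(), np.random.default_rng(99))
            sf, _ = ct(imgs, imgs)
            outs.append(sf.data)
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_gradient_reaches_both_embeddings(self):
        ct = CrossScaleTransformer(_tiny_spec(), _rng())
        imgs = np.random.default_rng(14).normal(size=(1, 32, 32, 3))
        sf, sc = ct(imgs, imgs)
        loss = (sf * sf).sum() + (sc * sc).sum()
        loss.backward()
        for embed in (ct.embed_f, ct.embed_c):
            g = embed.proj.weight.grad
            assert g is not None and np.abs(g).max() > 0
        # finite-difference check on one embedding weight
        w = ct.embed_f.proj.weight
        eps = 1e-6
        orig = w.data[0, 0]
        vals = []
        for d in (eps, -eps):
            w.data[0, 0] = orig + d
            sf2, sc2 = ct(imgs, imgs)
            vals.append(((sf2 * sf2).sum() + (sc2 * sc2).sum()).data.item())
        w.data[0, 0] = orig
        num = (vals[0] - vals[1]) / (2 * eps)
        np.testing.assert_allclose(w.grad[0, 0], num, rtol=1e-4, atol=1e-8)

    def test_tied_identical_branches_give_identical_cls(self):
        spec = ModelSpec(f_branch=BranchSpec(8, 32, 4, 1, 1),
                         c_branch=BranchSpec(8, 32, 4, 1, 1), T=2)
        ct = CrossScaleTransformer(spec, _rng())
        ct.embed_c.load_state_dict(ct.embed_f.state_dict())
        ct.norm_c.load_state_dict(ct.norm_f.state_dict())
        for rep in ct.reps:
            for bc, bf in zip(rep.blocks_c, rep.blocks_f):
                bc.load_state_dict(bf.state_dict())
            rep.fuse_c.load_state_dict(rep.fuse_f.state_dict())
        imgs = np.random.default_rng(15).normal(size=(2, 32, 32, 3))
        sf, sc = ct(imgs, imgs)
        np.testing.assert_allclose(sf.data, sc.data, rtol=1e-12)
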