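"""Dual-branch cross-scale transformer feature extractor.

Two vision-transformer branches see the same fundus image at different
patch granularities: a fine branch (small patches, shallow, narrow) and
a coarse branch (large patches, deeper, wider).  Each cross-scale
encoder repetition runs the per-branch encoder stacks and then fuses
the branches with multi-head cross-scale attention (MHCA): each
branch's classification token — as the *sole* query — attends to the
other branch's patch tokens, so the fusion cost is linear in token
count and patch tokens pass through the fusion unchanged.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .autodiff import Tensor, concat
from .nn import LayerNorm, Linear, Module, trunc_normal
from .specs import BranchSpec, ModelSpec

__all__ = [
    "PatchEmbed",
    "MHSA",
    "FeedForward",
    "EncoderBlock",
    "CrossAttention",
    "CrossScaleTransformer",
    "patchify",
    "prepare_branch_input",
]


def patchify(imgs: np.ndarray, patch_size: int) -> np.ndarray:
    """(B, s, s, 3) -> (B, n, p*p*3) row-major non-overlapping patches."""
    b, h, w, c = imgs.shape
    if h % patch_size or w % patch_size:
        raise ValueError("image size not divisible by patch size")
    gh, gw = h // patch_size, w // patch_size
    x = imgs.reshape(b, gh, patch_size, gw, patch_size, c)
    return x.transpose(0, 1, 3, 2, 4, 5).reshape(b, gh * gw,
                                                 patch_size * patch_size * c)


def prepare_branch_input(img: np.ndarray, spec: BranchSpec) -> np.ndarray:
    """Resize one uint8 RGB image to the branch input size, scale to [-1, 1]."""
    s = spec.input_size
    out = resize(img.astype(np.float64) / 255.0, (s, s, 3), order=1,
                 mode="reflect", anti_aliasing=True)
    return out * 2.0 - 1.0


class PatchEmbed(Module):
    """Linear patch projection + learned cls token + learned position embedding."""

    def __init__(self, spec: BranchSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        p, q = spec.patch_size, spec.embed_dim
        self.proj = Linear(p * p * 3, q, rng)
        self.cls = self.param("cls", trunc_normal(rng, (1, 1, q)))
        self.pos = self.param("pos", trunc_normal(rng, (1, spec.n_patches + 1, q)))

    def forward(self, imgs: np.ndarray) -> Tensor:
        if imgs.shape[1] != self.spec.input_size:
            raise ValueError(
                f"expected {self.spec.input_size}-px input, got {imgs.shape[1]}"
            )
        patches = self.proj(Tensor(patchify(imgs, self.spec.patch_size)))
        b = imgs.shape[0]
        cls = self.cls + Tensor(np.zeros((b, 1, self.spec.embed_dim)))
        return concat([cls, patches], axis=1) + self.pos


class MHSA(Module):
    """Multi-head self-attention; stores the last attention map for inspection."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if dim % n_heads:
            raise ValueError("dim must be divisible by n_heads")
        self.dim, self.n_heads = dim, n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)
        self.last_attention: np.ndarray | None = None

    def forward(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        h, dh = self.n_heads, self.dim // self.n_heads
        qkv = self.qkv(x).reshape(b, n, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (b, h, n, dh)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        self.last_attention = attn.data.copy()
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.out(out)


class FeedForward(Module):
    """Two linear layers with GELU, hidden width = expansion * dim."""

    def __init__(self, dim: int, expansion: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(dim, expansion * dim, rng)
        self.fc2 = Linear(expansion * dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class EncoderBlock(Module):
    """Pre-norm transformer block: x + MHSA(LN(x)), then y + FFN(LN(y))."""

    def __init__(self, spec: BranchSpec, rng: np.random.Generator):
        super().__init__()
        q = spec.embed_dim
        self.ln1 = LayerNorm(q)
        self.attn = MHSA(q, spec.n_heads, rng)
        self.ln2 = LayerNorm(q)
        self.ffn = FeedForward(q, spec.ffn_expansion, rng)

    def forward(self, x: Tensor) -> Tensor:
        y = x + self.attn(self.ln1(x))
        return y + self.ffn(self.ln2(y))


class CrossAttention(Module):
    """One direction of MHCA fusion for the branch owning the cls token.

    The own-branch cls token is projected into the other branch's width
    (LN then linear), concatenated in front of the other branch's patch
    tokens, and used as the single attention query over that sequence.
    The updated token is back-projected (LN then linear) to the owning
    branch's width.  The attention map therefore has exactly one row.
    """

    def __init__(self, dim_own: int, dim_other: int, n_heads: int,
                 rng: np.random.Generator):
        super().__init__()
        if dim_other % n_heads:
            raise ValueError("other-branch dim must be divisible by n_heads")
        self.dim_own, self.dim_other, self.n_heads = dim_own, dim_other, n_heads
        self.ln_proj = LayerNorm(dim_own)
        self.proj = Linear(dim_own, dim_other, rng)
        self.ln_in = LayerNorm(dim_other)
        self.wq = Linear(dim_other, dim_other, rng, bias=False)
        self.wk = Linear(dim_other, dim_other, rng, bias=False)
        self.wv = Linear(dim_other, dim_other, rng, bias=False)
        self.wo = Linear(dim_other, dim_other, rng)
        self.ln_back = LayerNorm(dim_other)
        self.back = Linear(dim_other, dim_own, rng)
        self.last_attention: np.ndarray | None = None

    def forward(self, cls_own: Tensor, patches_other: Tensor) -> Tensor:
        if cls_own.shape[-1] != self.dim_own:
            raise ValueError("cls token width does not match projection input")
        if patches_other.shape[-1] != self.dim_other:
            raise ValueError("patch token width mismatch after projection")
        b = cls_own.shape[0]
        h, dh = self.n_heads, self.dim_other // self.n_heads
        p = self.proj(self.ln_proj(cls_own))  # (b, 1, dim_other)
        xhat = concat([p, patches_other], axis=1)  # (b, n_o + 1, dim_other)
        xn = self.ln_in(xhat)
        q = self.wq(xn[:, 0:1, :]).reshape(b, 1, h, dh).transpose(0, 2, 1, 3)
        m = xn.shape[1]
        k = self.wk(xn).reshape(b, m, h, dh).transpose(0, 2, 1, 3)
        v = self.wv(xn).reshape(b, m, h, dh).transpose(0, 2, 1, 3)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)  # (b, h, 1, n_o + 1): one query row
        self.last_attention = attn.data.copy()
        fused = (attn @ v).transpose(0, 2, 1, 3).reshape(b, 1, self.dim_other)
        u = p + self.wo(fused)
        return self.back(self.ln_back(u))  # updated cls in own width


class _CTRepetition(Module):
    """Per-branch encoder stacks followed by a single-layer MHCA fusion."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__()
        f, c = spec.f_branch, spec.c_branch
        self.blocks_f = [EncoderBlock(f, rng) for _ in range(f.depth)]
        self.blocks_c = [EncoderBlock(c, rng) for _ in range(c.depth)]
        self.fuse_f = CrossAttention(f.embed_dim, c.embed_dim, c.n_heads, rng)
        self.fuse_c = CrossAttention(c.embed_dim, f.embed_dim, f.n_heads, rng)

    def forward(self, xf: Tensor, xc: Tensor) -> tuple[Tensor, Tensor]:
        for blk in self.blocks_f:
            xf = blk(xf)
        for blk in self.blocks_c:
            xc = blk(xc)
        new_cls_f = self.fuse_f(xf[:, 0:1, :], xc[:, 1:, :])
        new_cls_c = self.fuse_c(xc[:, 0:1, :], xf[:, 1:, :])
        zf = concat([new_cls_f, xf[:, 1:, :]], axis=1)
        zc = concat([new_cls_c, xc[:, 1:, :]], axis=1)
        return zf, zc


class CrossScaleTransformer(Module):
    """Patch embedding, T cross-scale repetitions, final per-branch LN.

    Position embeddings are added once at embedding time, before the
    first repetition.  ``forward`` caches the pre-final-LN token
    sequences per branch (``cam_tokens``) for activation mapping.
    """

    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.embed_f = PatchEmbed(spec.f_branch, rng)
        self.embed_c = PatchEmbed(spec.c_branch, rng)
        self.reps = [_CTRepetition(spec, rng) for _ in range(spec.T)]
        self.norm_f = LayerNorm(spec.f_branch.embed_dim)
        self.norm_c = LayerNorm(spec.c_branch.embed_dim)
        self.cam_tokens: dict[str, Tensor] = {}

    def forward(self, imgs_f: np.ndarray, imgs_c: np.ndarray
                ) -> tuple[Tensor, Tensor]:
        xf = self.embed_f(imgs_f)
        xc = self.embed_c(imgs_c)
        for rep in self.reps:
            xf, xc = rep(xf, xc)
        self.cam_tokens = {"F": xf, "C": xc}
        return self.norm_f(xf), self.norm_c(xc)
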