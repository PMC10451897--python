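"""Attention-based multiple-instance-learning head.

The image is the bag, the branch's final patch tokens are the
instances.  Per instance: a low-dimensional embedding h = relu(LN(W z));
a gated two-layer attention scores each instance, softmax over the bag
gives weights alpha; the bag representation A = sum_i alpha_i h_i is
classified by a single linear layer.  The head is permutation-invariant
in the instances and plugs onto each transformer branch independently;
the final bag output concatenates the two branches (coarse first).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .nn import LayerNorm, Linear, Module
from .specs import MILHeadSpec

__all__ = ["MILBranchHead", "MILHead"]


class MILBranchHead(Module):
    """MIL head for one branch: embed -> attention-aggregate -> classify."""

    def __init__(self, d: int, spec: MILHeadSpec, rng: np.random.Generator):
        super().__init__()
        self.d, self.spec = d, spec
        self.embed = Linear(d, spec.m, rng, bias=False)
        self.ln_embed = LayerNorm(spec.m)
        self.att1 = Linear(spec.m, spec.l, rng, bias=False)
        self.ln_att = LayerNorm(spec.l)
        self.att2 = Linear(spec.l, 1, rng, bias=False)
        self.bag = Linear(spec.m, spec.n_classes, rng, bias=False)

    def instance_embed(self, z: Tensor) -> Tensor:
        """h_i = relu(LN(W_linear z_i)); nonnegative by construction."""
        if z.shape[-1] != self.d:
            raise ValueError(f"instances must have dim {self.d}")
        return self.ln_embed(self.embed(z)).relu()

    def attention_aggregate(self, h: Tensor) -> tuple[Tensor, Tensor]:
        """Per-instance gated scores -> softmax weights alpha -> A = sum alpha h."""
        if h.shape[-2] == 0:
            raise ValueError("cannot aggregate an empty bag")
        e = self.att2(self.ln_att(self.att1(h)).relu())  # (..., n, 1)
        alpha = e.swapaxes(-1, -2).softmax(axis=-1)  # (..., 1, n)
        a = (alpha @ h).sum(axis=-2)  # (..., m)
        return alpha.sum(axis=-2), a

    def bag_classify(self, a: Tensor) -> Tensor:
        """Linear bag-level class scores (no hidden layer)."""
        if a.shape[-1] != self.spec.m:
            raise ValueError(f"aggregate must have dim {self.spec.m}")
        return self.bag(a)

    def forward(self, z: Tensor) -> dict:
        h = self.instance_embed(z)
        alpha, a = self.attention_aggregate(h)
        scores = self.bag_classify(a)
        return {"H": h, "alpha": alpha, "A": a, "scores": scores}


class MILHead(Module):
    """Both branches' MIL heads; bag scores concatenated coarse-first."""

    def __init__(self, d_f: int, d_c: int, spec: MILHeadSpec,
                 rng: np.random.Generator):
        super().__init__()
        self.branch_c = MILBranchHead(d_c, spec, rng)
        self.branch_f = MILBranchHead(d_f, spec, rng)

    def forward(self, patches_f: Tensor, patches_c: Tensor) -> dict:
        out_c = self.branch_c(patches_c)
        out_f = self.branch_f(patches_f)
        p_mil = concat([out_c["scores"], out_f["scores"]], axis=-1)
        return {"C": out_c, "F": out_f, "P_mil": p_mil}
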