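"""Full model assembly, joint loss, and inference-time fusion.

Each branch contributes two probability estimates for an image: the
MLP head on its classification token and the MIL head on its patch
tokens.  Training minimizes, per branch, the eta-weighted sum of the
two cross-entropies (summed over branches); inference fuses the four
probability vectors with the same eta weighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .backbone import CrossScaleTransformer, prepare_branch_input
from .mil import MILHead
from .nn import LayerNorm, Linear, Module
from .specs import BranchSpec, MILHeadSpec, ModelSpec

__all__ = ["MILCT", "Prediction", "build_model", "joint_loss", "predict_fused",
           "save_checkpoint", "load_checkpoint"]

_LOG_FLOOR = 1e-12


@dataclass
class Prediction:
    """Per-head class probabilities and the fused 2-class output."""

    y_mlp: dict[str, np.ndarray]
    y_mil: dict[str, np.ndarray]
    y_fused: np.ndarray


class MILCT(Module):
    """Cross-scale transformer backbone + per-branch MLP and MIL heads."""

    def __init__(self, spec: ModelSpec, mil_spec: MILHeadSpec,
                 rng: np.random.Generator):
        super().__init__()
        if mil_spec.n_classes != spec.n_classes:
            raise ValueError("head and model class counts disagree")
        self.spec, self.mil_spec = spec, mil_spec
        self.ct = CrossScaleTransformer(spec, rng)
        qf, qc = spec.f_branch.embed_dim, spec.c_branch.embed_dim
        self.mlp_ln_f = LayerNorm(qf)
        self.mlp_f = Linear(qf, spec.n_classes, rng)
        self.mlp_ln_c = LayerNorm(qc)
        self.mlp_c = Linear(qc, spec.n_classes, rng)
        self.mil = MILHead(qf, qc, mil_spec, rng)

    def forward(self, imgs_f: np.ndarray, imgs_c: np.ndarray) -> dict:
        seq_f, seq_c = self.ct(imgs_f, imgs_c)
        out = {
            "seq_F": seq_f,
            "seq_C": seq_c,
            "mlp_probs": {
                "F": self.mlp_f(self.mlp_ln_f(seq_f[:, 0, :])).softmax(axis=-1),
                "C": self.mlp_c(self.mlp_ln_c(seq_c[:, 0, :])).softmax(axis=-1),
            },
        }
        mil_out = self.mil(seq_f[:, 1:, :], seq_c[:, 1:, :])
        out["mil"] = mil_out
        out["mil_probs"] = {
            "F": mil_out["F"]["scores"].softmax(axis=-1),
            "C": mil_out["C"]["scores"].softmax(axis=-1),
        }
        return out

    def prepare_inputs(self, imgs: list[np.ndarray] | np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
        """Resize uint8 RGB images to both branch input sizes, scale to [-1, 1]."""
        if isinstance(imgs, np.ndarray) and imgs.ndim == 3:
            imgs = [imgs]
        xf = np.stack([prepare_branch_input(im, self.spec.f_branch)
                       for im in imgs])
        xc = np.stack([prepare_branch_input(im, self.spec.c_branch)
                       for im in imgs])
        return xf, xc


def build_model(spec: ModelSpec | None = None,
                mil_spec: MILHeadSpec | None = None,
                seed: int = 0) -> tuple[MILCT, int]:
    """Construct the network; returns (model, trainable parameter count)."""
    spec = spec or ModelSpec()
    mil_spec = mil_spec or MILHeadSpec(n_classes=spec.n_classes)
    model = MILCT(spec, mil_spec, np.random.default_rng(seed))
    return model, model.n_parameters()


def _floor_clip(p: Tensor, floor: float) -> Tensor:
    # max(p, floor) with gradient passing only where p > floor
    return p + (floor - p).relu()


def _check_probs(p: np.ndarray, name: str):
    if (p < -1e-9).any() or (p > 1 + 1e-9).any():
        raise ValueError(f"{name} entries must lie in [0, 1]")
    if np.abs(p.sum(axis=-1) - 1.0).max() > 1e-6:
        raise ValueError(f"{name} rows must sum to 1")


def joint_loss(y_gt: np.ndarray, y_mlp: dict[str, Tensor],
               y_mil: dict[str, Tensor], eta: float) -> Tensor:
    """Summed-over-branches eta-weighted double cross-entropy.

    Per branch b: -eta * sum_j y_gt_j log y_mlp_bj
                  - (1 - eta) * sum_j y_gt_j log y_mil_bj,
    averaged over the batch.  Probabilities are floored at 1e-12 inside
    the log.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must lie in [0, 1]")
    y = np.asarray(y_gt, dtype=np.float64)
    total = None
    for branch in sorted(y_mlp):
        pm, pb = y_mlp[branch], y_mil[branch]
        _check_probs(pm.data, f"y_mlp[{branch}]")
        _check_probs(pb.data, f"y_mil[{branch}]")
        # zero-weight terms are dropped from the graph entirely, so the
        # unused head receives no gradient at all at eta = 0 or 1
        terms = []
        if eta > 0.0:
            ce_mlp = -(Tensor(y) * _floor_clip(pm, _LOG_FLOOR).log()).sum(axis=-1)
            terms.append(eta * ce_mlp)
        if eta < 1.0:
            ce_mil = -(Tensor(y) * _floor_clip(pb, _LOG_FLOOR).log()).sum(axis=-1)
            terms.append((1.0 - eta) * ce_mil)
        branch_loss = terms[0] if len(terms) == 1 else terms[0] + terms[1]
        branch_loss = branch_loss.mean()
        total = branch_loss if total is None else total + branch_loss
    return total


def predict_fused(model: MILCT, img: np.ndarray) -> Prediction:
    """Eta-weighted fusion of the four head probabilities for one image.

    y_fused = normalize(eta * mean_b y_mlp_b + (1 - eta) * mean_b y_mil_b).
    """
    xf, xc = model.prepare_inputs(img)
    out = model(xf, xc)
    eta = model.spec.eta
    y_mlp = {b: out["mlp_probs"][b].data[0] for b in ("C", "F")}
    y_mil = {b: out["mil_probs"][b].data[0] for b in ("C", "F")}
    mlp_mean = (y_mlp["C"] + y_mlp["F"]) / 2.0
    mil_mean = (y_mil["C"] + y_mil["F"]) / 2.0
    fused = eta * mlp_mean + (1.0 - eta) * mil_mean
    fused = fused / fused.sum()
    return Prediction(y_mlp=y_mlp, y_mil=y_mil, y_fused=fused)


def fused_probabilities(out: dict, eta: float) -> np.ndarray:
    """Batch version of the fusion rule on a forward-pass output dict."""
    mlp = (out["mlp_probs"]["C"].data + out["mlp_probs"]["F"].data) / 2.0
    mil = (out["mil_probs"]["C"].data + out["mil_probs"]["F"].data) / 2.0
    fused = eta * mlp + (1.0 - eta) * mil
    return fused / fused.sum(axis=-1, keepdims=True)


# ----------------------------------------------------------------------
# checkpointing: weights (npz) + specs (json sidecar inside the npz)
# ----------------------------------------------------------------------

def save_checkpoint(model: MILCT, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({
        "f_branch": vars(model.spec.f_branch),
        "c_branch": vars(model.spec.c_branch),
        "T": model.spec.T,
        "n_classes": model.spec.n_classes,
        "eta": model.spec.eta,
        "mil": {"m": model.mil_spec.m, "l": model.mil_spec.l,
                "n_classes": model.mil_spec.n_classes},
    })
    arrays = {k.replace(".", "/"): v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> MILCT:
    with np.load(Path(path)) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k.replace("/", "."): z[k] for k in z.files if k != "__meta__"}
    spec = ModelSpec(
        f_branch=BranchSpec(**meta["f_branch"]),
        c_branch=BranchSpec(**meta["c_branch"]),
        T=meta["T"], n_classes=meta["n_classes"], eta=meta["eta"],
    )
    mil_spec = MILHeadSpec(**meta["mil"])
    model = MILCT(spec, mil_spec, np.random.default_rng(0))
    model.load_state_dict(state)
    return model
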