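"""Gradient-weighted class activation maps on the patch-token grid.

The hook point is the chosen branch's final layer-normalized token
sequence — the exact features the classification heads consume (the
fusion leaves patch tokens unchanged, so up to the final LN this is
the branch's last encoder-block output).  Channel weights are the
global average over the token grid of the target-class score's
gradient; the map is the ReLU of the weighted channel sum, normalized
to [0, 1] and bilinearly upsampled to image size.  The classification
token is excluded from the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .model import MILCT, fused_probabilities

__all__ = ["Heatmap", "grad_cam_map"]


@dataclass
class Heatmap:
    grid: np.ndarray  # sqrt(n) x sqrt(n), in [0, 1]
    upsampled: np.ndarray  # image-size map, in [0, 1]
    branch: str
    target_class: int


def grad_cam_map(model: MILCT, img: np.ndarray, target_class: int,
                 branch: str, out_size: int | None = None,
                 context_images: list[np.ndarray] | None = None) -> Heatmap:
    """Class activation map for one image; the map is batch-invariant.

    ``context_images`` can be appended to the forward batch to check
    that invariance; the map is always computed for ``img`` (index 0).
    """
    if branch not in ("C", "F"):
        raise ValueError("branch must be 'C' or 'F'")
    if target_class not in range(model.spec.n_classes):
        raise ValueError("invalid target class")
    batch = [img] + list(context_images or [])
    xf, xc = model.prepare_inputs(batch)
    out = model(xf, xc)
    eta = model.spec.eta
    # target score: log fused probability of the target class, image 0
    mlp = (out["mlp_probs"]["C"] + out["mlp_probs"]["F"]) * 0.5
    mil = (out["mil_probs"]["C"] + out["mil_probs"]["F"]) * 0.5
    fused = eta * mlp + (1.0 - eta) * mil
    score = fused[0, target_class].log()
    model.zero_grad()
    score.backward()

    tokens = out["seq_F"] if branch == "F" else out["seq_C"]
    feats = tokens.data[0, 1:, :]  # cls token excluded
    grads = tokens.grad[0, 1:, :] if tokens.grad is not None \
        else np.zeros_like(feats)
    n, q = feats.shape
    side = int(round(np.sqrt(n)))
    if side * side != n:
        raise ValueError("token count is not a perfect square")
    weights = grads.mean(axis=0)
    cam = np.maximum(feats @ weights, 0.0).reshape(side, side)
    if cam.max() > 0:
        cam = cam / cam.max()
    spec = model.spec.c_branch if branch == "C" else model.spec.f_branch
    size = out_size or spec.input_size
    upsampled = resize(cam, (size, size), order=1, mode="reflect",
                       anti_aliasing=False)
    upsampled = np.clip(upsampled, 0.0, 1.0)
    return Heatmap(grid=cam, upsampled=upsampled, branch=branch,
                   target_class=target_class)
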