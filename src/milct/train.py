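"""Training and cross-validated evaluation.

Optimizer defaults follow the reference protocol: Adam with initial
learning rate 1e-3, weight decay 5e-4, beta1 (momentum) 0.9, batch
size 32, 200 epochs; five-fold stratified cross-validation with
minority-class balancing applied to the training folds only.  Epoch
counts are configurable for desk-scale runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .data import FundusSample, load_image
from .metrics import MetricsReport, compute_metrics, confusion_matrix, roc_auc
from .model import MILCT, build_model, fused_probabilities, joint_loss, \
    save_checkpoint
from .nn import Adam
from .preprocess import augment_minority
from .specs import MILHeadSpec, ModelSpec, SynthConfig, tiny_model_spec
from .synth import generate_arrays, generate_sample

__all__ = ["Hyperparams", "stratified_kfold", "fit", "evaluate",
           "train_model", "learning_sanity_run"]


@dataclass
class Hyperparams:
    epochs: int = 200
    lr: float = 1e-3  # initial rate; decays to 0 under the cosine schedule
    weight_decay: float = 5e-4
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 32
    lr_schedule: str = "cosine"  # or "constant"


def stratified_kfold(manifest: pd.DataFrame, k: int = 5, seed: int = 0
                     ) -> np.ndarray:
    """Fold id per manifest row; class-stratified, deterministic under seed."""
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = manifest["label"].to_numpy()
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= {k} members for {k} folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(manifest), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)),
                                                   labels)):
        folds[test_idx] = fold
    return folds


def _one_hot(y: np.ndarray, n_classes: int = 2) -> np.ndarray:
    return np.eye(n_classes)[np.asarray(y, dtype=int)]


def fit(model: MILCT, xf: np.ndarray, xc: np.ndarray, y: np.ndarray,
        hyper: Hyperparams, seed: int = 0,
        log: list | None = None, epoch_data_fn=None) -> list[float]:
    """Mini-batch Adam training on pre-resized branch inputs.

    ``epoch_data_fn(epoch, rng)``, if given, supplies fresh
    ``(xf, xc, y)`` arrays each epoch (online augmentation).  Returns
    per-epoch mean losses.  Aborts on a non-finite loss.
    """
    opt = Adam(model.parameters(), lr=hyper.lr,
               betas=(hyper.beta1, hyper.beta2),
               weight_decay=hyper.weight_decay)
    rng = np.random.default_rng(seed)
    history: list[float] = []
    for epoch in range(hyper.epochs):
        if epoch_data_fn is not None:
            xf, xc, y = epoch_data_fn(epoch, rng)
        n = len(y)
        y1h = _one_hot(y, model.spec.n_classes)
        if hyper.lr_schedule == "cosine":
            opt.lr = hyper.lr * 0.5 * (1 + np.cos(np.pi * epoch /
                                                  max(1, hyper.epochs)))
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, hyper.batch_size):
            idx = order[start:start + hyper.batch_size]
            out = model(xf[idx], xc[idx])
            loss = joint_loss(y1h[idx], out["mlp_probs"], out["mil_probs"],
                              model.spec.eta)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        if log is not None:
            log.append({"epoch": epoch, "loss": history[-1]})
    return history


def evaluate(model: MILCT, xf: np.ndarray, xc: np.ndarray, y: np.ndarray,
             batch_size: int = 32, fold: int | None = None) -> MetricsReport:
    """Fused-probability predictions -> confusion matrix, metrics, ROC/AUC."""
    probs = []
    for start in range(0, len(y), batch_size):
        out = model(xf[start:start + batch_size], xc[start:start + batch_size])
        probs.append(fused_probabilities(out, model.spec.eta))
    p = np.concatenate(probs)
    y_pred = p.argmax(axis=1)
    report = compute_metrics(confusion_matrix(y, y_pred), fold=fold)
    if len(np.unique(y)) == 2:
        fpr, tpr, auc = roc_auc(p[:, 1], y)
        report.roc, report.auc = (fpr, tpr), auc
    return report


def _prepare(model: MILCT, images: list[np.ndarray]):
    return model.prepare_inputs(images)


def train_model(manifest: pd.DataFrame, folds: np.ndarray,
                model_spec: ModelSpec, mil_spec: MILHeadSpec,
                hyper: Hyperparams, seed: int = 0,
                out_dir: str | Path | None = None,
                balance: bool = True) -> list[MetricsReport]:
    """k-fold cross-validated training from a manifest of image paths.

    Balancing augmentation is applied to the training folds only; the
    held-out fold is never augmented and never overlaps the training
    paths (asserted every fold).
    """
    reports: list[MetricsReport] = []
    paths = manifest["path"].to_numpy()
    labels = manifest["label"].to_numpy()
    images = [load_image(p) for p in paths]
    for fold in np.unique(folds):
        test_mask = folds == fold
        train_paths = set(paths[~test_mask])
        assert not train_paths & set(paths[test_mask]), "fold leakage"
        train_samples = [FundusSample(images[i], int(labels[i]), paths[i])
                         for i in np.flatnonzero(~test_mask)]
        if balance:
            train_samples = augment_minority(train_samples, seed=seed)
        model, _ = build_model(model_spec, mil_spec, seed=seed + int(fold))
        xf, xc = _prepare(model, [s.image for s in train_samples])
        y_train = np.array([s.label for s in train_samples])
        log: list = []
        fit(model, xf, xc, y_train, hyper, seed=seed + int(fold), log=log)
        xf_t, xc_t = _prepare(model, [images[i]
                                      for i in np.flatnonzero(test_mask)])
        report = evaluate(model, xf_t, xc_t, labels[test_mask],
                          fold=int(fold))
        reports.append(report)
        if out_dir is not None:
            out_dir = Path(out_dir)
            save_checkpoint(model, out_dir / f"fold{int(fold)}.npz")
            pd.DataFrame(log).to_csv(out_dir / f"fold{int(fold)}_log.csv",
                                     index=False)
            payload = {"fold": int(fold), "accuracy_pct": report.accuracy,
                       "per_class": report.per_class, "macro": report.macro,
                       "auc": report.auc,
                       "confusion_matrix": report.cm.tolist()}
            (out_dir / f"fold{int(fold)}_metrics.json").write_text(
                json.dumps(payload, indent=2))
    return reports


def dihedral_expand(images: list[np.ndarray], labels: np.ndarray
                    ) -> tuple[list[np.ndarray], np.ndarray]:
    """Deterministic 4x expansion: identity, h-flip, v-flip, 180-degree
    rotation.  Exact pixel permutations, so no interpolation artifacts."""
    out_imgs, out_labels = [], []
    for img, lab in zip(images, labels):
        out_imgs += [img, img[:, ::-1].copy(), img[::-1, :].copy(),
                     img[::-1, ::-1].copy()]
        out_labels += [lab] * 4
    return out_imgs, np.asarray(out_labels)


def learning_sanity_run(seed: int = 0, n_per_class: int = 100,
                        image_size: int = 96, epochs: int = 50,
                        n_test_per_class: int = 50
                        ) -> tuple[MILCT, MetricsReport]:
    """Train the desk-scale model on generated images, report held-out metrics.

    Trains on ``n_per_class`` generated images per class (expanded 4x by
    deterministic dihedral augmentation — the sample count is far below
    what a transformer trained from scratch normally sees, and the
    reflex phenotype is orientation-free) with the reference optimizer
    settings, then evaluates on a freshly generated held-out set drawn
    from the same process with disjoint sample seeds.
    """
    cfg = SynthConfig(image_size=image_size, n_per_class=n_per_class,
                      seed=seed)
    train_images, train_labels = generate_arrays(cfg)
    test_images, test_labels = [], []
    for c in (0, 1):
        for i in range(n_test_per_class):
            # sample-seed block disjoint from the training block
            s = generate_sample(c, cfg, 100000 + c * n_test_per_class + i)
            test_images.append(s.image)
            test_labels.append(c)
    test_labels = np.array(test_labels)
    spec = tiny_model_spec(image_size)
    model, _ = build_model(spec, MILHeadSpec(m=32, l=16), seed=seed)
    train_imgs, train_y = dihedral_expand(train_images, train_labels)
    xf, xc = model.prepare_inputs(train_imgs)
    fit(model, xf, xc, train_y, Hyperparams(epochs=epochs), seed=seed)
    xf_t, xc_t = model.prepare_inputs(test_images)
    report = evaluate(model, xf_t, xc_t, test_labels)
    return model, report
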