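"""Samples and manifests.

A manifest is a CSV with columns ``path,label`` plus optional ``split``,
``fold`` and ``seed`` columns; labels are binary (0 = normal, 1 = lesion
present).  Images are 8-bit RGB PNG/JPEG, loaded as H x W x 3 uint8 in
RGB channel order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = ["FundusSample", "load_image", "save_image", "read_manifest",
           "write_manifest"]


@dataclass
class FundusSample:
    """One fundus image with its binary label and provenance."""

    image: np.ndarray  # H x W x 3 uint8, RGB
    label: int
    path: str | None = None
    seed: int | None = None

    def __post_init__(self):
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("image must be H x W x 3")
        if img.dtype != np.uint8:
            raise ValueError("image must be uint8")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        self.image = img


def load_image(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def save_image(img: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="RGB").save(path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "path" not in df.columns or "label" not in df.columns:
        raise ValueError("manifest must have 'path' and 'label' columns")
    if not set(df["label"].unique()) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    if df["path"].duplicated().any():
        raise ValueError("manifest paths must be unique")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
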