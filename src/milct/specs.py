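"""Configuration dataclasses: architecture, preprocessing and generator knobs.

Defaults follow the reference configuration of the dual-branch
cross-scale transformer: fine branch patch 12 at 240 px input with
96-dim embeddings and depth 1, coarse branch patch 16 at 224 px with
192-dim embeddings and depth 4, three cross-scale encoder repetitions,
and a loss weight eta balancing the cls-token (MLP) and MIL-head
cross-entropies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = [
    "BranchSpec",
    "ModelSpec",
    "MILHeadSpec",
    "PreprocessConfig",
    "SynthConfig",
    "tiny_model_spec",
]


@dataclass
class BranchSpec:
    """One transformer branch: patch size, input size, width, depth, heads."""

    patch_size: int
    input_size: int
    embed_dim: int
    depth: int
    n_heads: int
    ffn_expansion: int = 4

    def __post_init__(self):
        if self.input_size % self.patch_size != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by patch_size "
                f"{self.patch_size}"
            )
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")

    @property
    def n_patches(self) -> int:
        return (self.input_size // self.patch_size) ** 2


@dataclass
class ModelSpec:
    """Full dual-branch model: F (fine) and C (coarse) branches, T repetitions."""

    f_branch: BranchSpec = field(
        default_factory=lambda: BranchSpec(12, 240, 96, 1, 3)
    )
    c_branch: BranchSpec = field(
        default_factory=lambda: BranchSpec(16, 224, 192, 4, 6)
    )
    T: int = 3
    n_classes: int = 2
    eta: float = 0.5

    def __post_init__(self):
        if self.T < 0:
            raise ValueError("T must be >= 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass
class MILHeadSpec:
    """MIL head sizes: instance-embedding dim m and attention hidden dim l."""

    m: int = 128
    l: int = 64
    n_classes: int = 2

    def __post_init__(self):
        if self.m < 1 or self.l < 1:
            raise ValueError("m and l must be >= 1")


@dataclass
class PreprocessConfig:
    """Preprocessing chain knobs (border removal, CLAHE, unsharp enhancement)."""

    clip_limit: float = 7.0
    tile_grid: int = 6
    kappa: float = 4.0
    sigma_divisor: float = 30.0
    delta: float = 128.0
    background_threshold: int = 10

    def __post_init__(self):
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive")
        if self.tile_grid < 1:
            raise ValueError("tile_grid must be >= 1")
        if self.sigma_divisor <= 0:
            raise ValueError("sigma_divisor must be positive")
        if not 0 <= self.delta <= 255:
            raise ValueError("delta must lie in [0, 255]")


@dataclass
class SynthConfig:
    """Synthetic fundus generator settings.

    Class 1 images carry a bright central reflex stripe along a subset of
    vessels; ``reflex_width_fraction`` is the stripe width as a fraction of
    the vessel width and ``reflex_brightness`` the added intensity.  Both
    classes get a per-image global brightness jitter larger than the mean
    shift the stripes induce, so a global-intensity rule cannot separate
    the classes.
    """

    image_size: int = 96
    n_per_class: int = 100
    seed: int = 0
    n_vessels: tuple[int, int] = (6, 10)
    vessel_width: tuple[float, float] = (2.0, 4.5)
    reflex_width_fraction: float = 0.5
    reflex_brightness: float = 90.0
    brightness_jitter: float = 18.0

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0.0 < self.reflex_width_fraction <= 1.0:
            raise ValueError("reflex_width_fraction must lie in (0, 1]")


def tiny_model_spec(image_size: int = 96) -> ModelSpec:
    """Desk-scale model (32/64 dims, T=1) used for smoke training runs."""
    if image_size % 48 != 0:
        raise ValueError("image_size must be divisible by both 12 and 16")
    return ModelSpec(
        f_branch=BranchSpec(12, image_size, 32, 1, 1),
        c_branch=BranchSpec(16, image_size, 64, 2, 2),
        T=1,
    )


def spec_to_dict(spec) -> dict:
    return asdict(spec)


_CONFIG_KEYS = {
    "f_patch_size", "f_input_size", "f_embed_dim", "f_depth", "f_n_heads",
    "f_ffn_expansion", "c_patch_size", "c_input_size", "c_embed_dim",
    "c_depth", "c_n_heads", "c_ffn_expansion", "T", "n_classes", "eta",
    "mil_m", "mil_l",
}


def load_model_config(path) -> tuple[ModelSpec, MILHeadSpec]:
    """Read a flat ``key: value`` text file into model + MIL-head specs.

    Recognized keys (all optional, defaults otherwise): ``f_patch_size``,
    ``f_input_size``, ``f_embed_dim``, ``f_depth``, ``f_n_heads``,
    ``f_ffn_expansion`` and the ``c_``-prefixed coarse-branch versions;
    ``T``, ``n_classes``, ``eta``; ``mil_m``, ``mil_l``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    def branch(prefix: str, default: BranchSpec) -> BranchSpec:
        return BranchSpec(
            patch_size=raw.get(f"{prefix}_patch_size", default.patch_size),
            input_size=raw.get(f"{prefix}_input_size", default.input_size),
            embed_dim=raw.get(f"{prefix}_embed_dim", default.embed_dim),
            depth=raw.get(f"{prefix}_depth", default.depth),
            n_heads=raw.get(f"{prefix}_n_heads", default.n_heads),
            ffn_expansion=raw.get(f"{prefix}_ffn_expansion",
                                  default.ffn_expansion),
        )

    base = ModelSpec()
    spec = ModelSpec(
        f_branch=branch("f", base.f_branch),
        c_branch=branch("c", base.c_branch),
        T=raw.get("T", base.T),
        n_classes=raw.get("n_classes", base.n_classes),
        eta=raw.get("eta", base.eta),
    )
    mil = MILHeadSpec(m=raw.get("mil_m", 128), l=raw.get("mil_l", 64),
                      n_classes=spec.n_classes)
    return spec, mil
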