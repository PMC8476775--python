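"""Configuration objects and named presets.

The cell-type vocabulary is ordered: its order defines label-vector index
0..C-1 everywhere in the package (tables, prediction matrices, thresholds).
The eight defaults are the testicular cell types distinguishable in an IHC
section: five germ-cell stages from the seminiferous tubule periphery inward
(spermatogonia, preleptotene spermatocytes, pachytene spermatocytes,
round/early spermatids, elongated/late spermatids) and three somatic types
(Sertoli, Leydig, peritubular).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError

#: Ordered default cell-type vocabulary; index = label-vector position.
CELL_TYPES: tuple[str, ...] = (
    "spermatogonia",
    "preleptotene_spermatocytes",
    "pachytene_spermatocytes",
    "round_early_spermatids",
    "elongated_late_spermatids",
    "sertoli",
    "leydig",
    "peritubular",
)

#: Admissible subcellular locations in the annotation vocabulary.
LOCATIONS: tuple[str, ...] = ("cytoplasm", "nucleus", "membrane")

#: Published per-cell-type DHC cutoffs for the HPA testis model
#: (normalized-score scale; the two 1e-10 entries mean "retain everything").
DHC_CUTOFF_PRESETS: dict[str, dict[str, float]] = {
    "hpa_testis_v1": {
        "spermatogonia": 0.11,
        "preleptotene_spermatocytes": 0.11,
        "pachytene_spermatocytes": 0.22,
        "round_early_spermatids": 0.78,
        "elongated_late_spermatids": 0.22,
        "sertoli": 1.00e-10,
        "leydig": 0.11,
        "peritubular": 1.00e-10,
    }
}


@dataclass
class ModelConfig:
    """Architecture and training hyper-parameters for the hybrid network.

    The defaults reproduce the published full-scale training recipe
    (VGG19-like trunk, 1024 px input, base learning rate 1e-6, minibatch 32,
    250 epochs, weight decay 0.2, drop-weights rate 0.3, he-uniform init,
    adaptive-moment optimizer with maximum-of-past-variance correction).
    Use :func:`desk_config` for a configuration that trains in minutes on a
    single CPU.
    """

    backbone: str = "vgg19_like"          # "vgg19_like" | "small_cnn"
    image_side: int = 1024
    cnn_feature_dim: int = 256
    fc_layer_sizes: tuple[int, ...] = (512, 512)
    drop_weight_rate: float = 0.3
    n_labels: int = 8
    learning_rate: float = 1e-6
    batch_size: int = 32
    epochs: int = 250
    weight_decay: float = 0.2
    weight_decay_mode: str = "l2"         # "l2" | "lr_decay"
    optimizer: str = "amsgrad"
    init: str = "he-uniform"
    augment: bool = False       # random dihedral transforms of training batches
    seed: int = 0
    # feature-extraction side
    handcrafted_channel: str = "luminance"  # "luminance" | "dab"
    pca_dim: int = 3732
    hog_orientations: int = 8
    hog_cell_px: int = 8
    hog_cells_per_block: int = 8
    haralick_levels: int = 256
    haralick_distance: int = 1
    # uncertainty side
    mc_samples: int = 1000
    cppd_mode: str = "per_label"          # "per_label" | "across_labels"
    threshold_policy: str = "mcc"         # "mcc" | "fixed_half"

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_weight_rate < 1.0:
            raise ConfigError(
                f"drop_weight_rate must be in [0, 1), got {self.drop_weight_rate}"
            )
        if self.n_labels < 1:
            raise ConfigError(f"n_labels must be >= 1, got {self.n_labels}")
        if self.backbone not in ("vgg19_like", "small_cnn"):
            raise ConfigError(f"unknown backbone {self.backbone!r}")
        if self.cppd_mode not in ("per_label", "across_labels"):
            raise ConfigError(f"unknown cppd_mode {self.cppd_mode!r}")
        self.fc_layer_sizes = tuple(int(s) for s in self.fc_layer_sizes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fc_layer_sizes"] = list(self.fc_layer_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown ModelConfig keys: {sorted(unknown)}")
        return cls(**d)


def desk_config(**overrides) -> ModelConfig:
    """Out-of-the-box profile that trains in minutes on one CPU.

    64 px images, a 3-block convolutional trunk, a learning rate and weight
    decay sized for the small network, and 100 MC samples at inference.
    """
    base = dict(
        backbone="small_cnn",
        image_side=64,
        cnn_feature_dim=256,
        fc_layer_sizes=(256, 256),
        learning_rate=1e-3,
        epochs=50,
        weight_decay=1e-3,
        pca_dim=128,
        handcrafted_channel="dab",
        augment=True,
        mc_samples=100,
    )
    base.update(overrides)
    return ModelConfig(**base)


def paper_scale_config(**overrides) -> ModelConfig:
    """The published full-scale recipe (needs the real image corpus)."""
    return ModelConfig(**overrides)


PROFILES = {"desk": desk_config, "paper_scale": paper_scale_config}


@dataclass
class RunConfig:
    """End-to-end run description used by the CLI (provenance record)."""

    model: ModelConfig = field(default_factory=desk_config)
    cell_types: tuple[str, ...] = CELL_TYPES
    dhc_preset: str | None = None
    seed: int = 0
    mc_samples: int | None = None  # overrides model.mc_samples when set

    def to_dict(self) -> dict:
        return {
            "model": self.model.to_dict(),
            "cell_types": list(self.cell_types),
            "dhc_preset": self.dhc_preset,
            "seed": self.seed,
            "mc_samples": self.mc_samples,
        }


def load_config(path) -> RunConfig:
    """Read a declarative YAML run configuration.

    Recognized top-level keys: ``profile`` (desk | paper_scale), ``model``
    (ModelConfig overrides), ``cell_types``, ``dhc_preset``, ``seed``,
    ``mc_samples``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    profile = raw.pop("profile", "desk")
    if profile not in PROFILES:
        raise ConfigError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
    model_overrides = raw.pop("model", {}) or {}
    try:
        model = PROFILES[profile](**model_overrides)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    cell_types = tuple(raw.pop("cell_types", CELL_TYPES))
    preset = raw.pop("dhc_preset", None)
    if preset is not None and preset not in DHC_CUTOFF_PRESETS:
        raise ConfigError(f"unknown DHC preset {preset!r}")
    seed = int(raw.pop("seed", 0))
    mc = raw.pop("mc_samples", None)
    if raw:
        raise ConfigError(f"unknown config keys: {sorted(raw)}")
    model.n_labels = len(cell_types)
    return RunConfig(model=model, cell_types=cell_types, dhc_preset=preset,
                     seed=seed, mc_samples=None if mc is None else int(mc))


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
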