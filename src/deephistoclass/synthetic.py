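"""Synthetic IHC-like images and synthetic MC prediction sets.

The image generator emulates the geometry of a testis section: each image
holds 1-3 circular seminiferous-tubule cross-sections whose concentric
layers, outermost to innermost, house spermatogonia, preleptotene
spermatocytes, pachytene spermatocytes, round/early spermatids and
elongated/late spermatids; a thin peritubular rim wraps each tubule,
Sertoli cells appear as intratubular wisps, and Leydig cells as
interstitial blobs between tubules.  Compartments whose label is positive
are painted DAB-brown with a strength scaled by the annotated intensity
(weak staining is deliberately faint); everything else carries the
hematoxylin-blue counterstain, plus Gaussian pixel noise.

Labels are drawn from a Gaussian-copula model with three biological
co-expression clusters (somatic, premeiotic, meiotic/postmeiotic), so the
generated label matrix reproduces both the requested marginal prevalences
and positive within-cluster correlation.  The generator exercises the
pipeline's statistics; it makes no attempt at histological realism.

``generate_mc_samples`` fabricates drop-weights-style MC probability
samples with a controlled difficulty ladder, standing in for network output
when testing the uncertainty and triage machinery in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CELL_TYPES
from .errors import ConfigError
from .io import AnnotationEntry, LabeledImage
from .uncertainty import MCPredictionSet

GERM_LAYERS = ("spermatogonia", "preleptotene_spermatocytes",
               "pachytene_spermatocytes", "round_early_spermatids",
               "elongated_late_spermatids")

#: Co-expression clusters (somatic / premeiotic / meiotic-postmeiotic).
LABEL_CLUSTERS = {
    "somatic": ("sertoli", "leydig", "peritubular"),
    "premeiotic": ("spermatogonia", "preleptotene_spermatocytes"),
    "meiotic": ("pachytene_spermatocytes", "round_early_spermatids",
                "elongated_late_spermatids"),
}

#: Marginal positivity rates, qualitatively mirroring the real corpus
#: (Leydig most frequent ~0.66, peritubular rarest ~0.10).
DEFAULT_PREVALENCE = {
    "spermatogonia": 0.35,
    "preleptotene_spermatocytes": 0.30,
    "pachytene_spermatocytes": 0.45,
    "round_early_spermatids": 0.35,
    "elongated_late_spermatids": 0.40,
    "sertoli": 0.20,
    "leydig": 0.66,
    "peritubular": 0.10,
}

DAB_BROWN = (110, 70, 40)
HEMATOXYLIN_BLUE = (70, 80, 150)
#: Mixing strength toward full DAB per intensity grade (weak is faint).
INTENSITY_STRENGTH = {1: 0.35, 2: 0.65, 3: 1.0}


@dataclass
class SyntheticImageSpec:
    """Study conditions for the image generator."""

    n_images: int = 100
    image_side: int = 64
    cell_types: tuple = CELL_TYPES
    prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    cluster_rho: float = 0.5               # within-cluster copula correlation
    intensity_probs: tuple = (0.25, 0.40, 0.35)   # weak/moderate/strong | positive
    stain_brown: tuple = DAB_BROWN
    stain_blue: tuple = HEMATOXYLIN_BLUE
    noise_sd: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_side < 48:
            raise ConfigError(
                f"image_side {self.image_side} too small to draw the "
                "concentric tubule layers (minimum 48)")
        for ct in self.cell_types:
            p = self.prevalence.get(ct)
            if p is None or not 0.0 < p < 1.0:
                raise ConfigError(f"prevalence for {ct!r} must be in (0, 1)")
        if not np.isclose(sum(self.intensity_probs), 1.0):
            raise ConfigError("intensity_probs must sum to 1")
        for ch in tuple(self.stain_brown) + tuple(self.stain_blue):
            if not 0 <= ch <= 255:
                raise ConfigError("palette channels must be in [0, 255]")


def sample_label_matrix(spec: SyntheticImageSpec,
                        rng: np.random.Generator) -> np.ndarray:
    """Correlated multilabel draws via a Gaussian copula.

    Each cluster shares a latent factor with loading sqrt(rho); thresholding
    the latent at the normal quantile of each label's prevalence gives exact
    marginals with positive within-cluster association.
    """
    from scipy.stats import norm

    C = len(spec.cell_types)
    cluster_of = {}
    for k, (name, members) in enumerate(LABEL_CLUSTERS.items()):
        for m in members:
            cluster_of[m] = k
    n = spec.n_images
    factors = rng.standard_normal((n, len(LABEL_CLUSTERS)))
    eps = rng.standard_normal((n, C))
    rho = spec.cluster_rho
    Y = np.zeros((n, C), dtype=np.int8)
    for c, ct in enumerate(spec.cell_types):
        k = cluster_of.get(ct)
        latent = (np.sqrt(rho) * factors[:, k] + np.sqrt(1 - rho) * eps[:, c]
                  if k is not None else eps[:, c])
        Y[:, c] = latent < norm.ppf(spec.prevalence[ct])
    return Y


def _disk(side: int, cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


def _compartment_masks(side: int, rng: np.random.Generator,
                       cell_types=CELL_TYPES) -> dict:
    """Boolean mask per cell type for one image's geometry."""
    # 1-2 large tubules: each of the five germ layers must stay >= ~2.5 px
    # wide so the compartments are resolvable at the working resolution, and
    # tubules must not overlap (overlap would mix compartment identities)
    n_tubules = int(rng.integers(1, 3))
    r_lo, r_hi = (0.32, 0.44) if n_tubules == 1 else (0.25, 0.31)
    masks = {ct: np.zeros((side, side), dtype=bool) for ct in cell_types}
    tubule_union = np.zeros((side, side), dtype=bool)
    centers = []
    for _ in range(n_tubules):
        placed = False
        for _attempt in range(40):
            r = rng.uniform(r_lo, r_hi) * side
            cy = rng.uniform(r, side - r)
            cx = rng.uniform(r, side - r)
            if all((cy - y) ** 2 + (cx - x) ** 2 > (r + rr + 1.0) ** 2
                   for y, x, rr in centers):
                placed = True
                break
        if not placed:
            continue  # keep fewer tubules rather than overlap
        centers.append((cy, cx, r))
        outer = _disk(side, cy, cx, r)
        tubule_union |= outer
        # thin peritubular rim
        rim_inner = _disk(side, cy, cx, r * 0.92)
        masks["peritubular"] |= outer & ~rim_inner
        # five germ layers from the rim toward the lumen
        lumen_frac = 0.18
        radii = np.linspace(0.92, lumen_frac, len(GERM_LAYERS) + 1) * r
        for layer, (ro, ri) in zip(GERM_LAYERS, zip(radii[:-1], radii[1:])):
            ring = _disk(side, cy, cx, ro) & ~_disk(side, cy, cx, ri)
            masks[layer] |= ring
        # Sertoli: radial wisps crossing the germ layers
        interior = rim_inner & ~_disk(side, cy, cx, lumen_frac * r)
        yy, xx = np.mgrid[0:side, 0:side]
        theta = np.arctan2(yy - cy, xx - cx)
        n_wisps = int(rng.integers(4, 7))
        phases = rng.uniform(0, 2 * np.pi, n_wisps)
        wisp = np.zeros((side, side), dtype=bool)
        for ph in phases:
            ang = np.angle(np.exp(1j * (theta - ph)))
            wisp |= np.abs(ang) < (0.05 + 4.0 / side)
        masks["sertoli"] |= interior & wisp
    # Leydig: interstitial blobs outside the tubules
    interstitium = ~tubule_union
    n_blobs = int(rng.integers(3, 7))
    leydig = np.zeros((side, side), dtype=bool)
    for _ in range(n_blobs):
        br = rng.uniform(0.03, 0.07) * side
        by = rng.uniform(0, side)
        bx = rng.uniform(0, side)
        leydig |= _disk(side, by, bx, br)
    masks["leydig"] = leydig & interstitium
    # Sertoli wisps must not claim germ-layer pixels exclusively: Sertoli
    # overrides, germ layers keep the rest
    for layer in GERM_LAYERS:
        masks[layer] &= ~masks["sertoli"]
    # guarantee non-empty compartments (resample-free fallback: tiny patch)
    for ct in cell_types:
        if not masks[ct].any():
            cy, cx, r = centers[0]
            masks[ct] = _disk(side, cy, cx, max(2.0, 0.05 * side)) \
                if ct != "leydig" else _disk(side, 1.5, 1.5, 2.0)
    return masks


def render_image(masks: dict, annotations: dict, spec: SyntheticImageSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """Paint compartments by annotation over the counterstain, add noise."""
    side = spec.image_side
    blue = np.array(spec.stain_blue, dtype=np.float64)
    brown = np.array(spec.stain_brown, dtype=np.float64)
    img = np.tile(blue, (side, side, 1))
    for ct, entry in annotations.items():
        if entry.intensity > 0:
            strength = INTENSITY_STRENGTH[entry.intensity]
            img[masks[ct]] = blue + (brown - blue) * strength
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def oracle_brownness(pixels: np.ndarray, mask: np.ndarray) -> float:
    """Mean red-minus-blue channel difference inside a compartment mask.

    The color rule an oracle uses to recover labels: DAB brown has R > B,
    hematoxylin blue has B > R, so positive compartments score high.
    """
    sub = pixels[mask].astype(np.float64)
    return float((sub[:, 0] - sub[:, 2]).mean())


def generate_images(spec: SyntheticImageSpec,
                    return_masks: bool = False):
    """Generate labeled synthetic images (deterministic for a fixed seed).

    Splits are assigned round-robin as train/train/train/train/validation/
    test to yield roughly a 4:1:1 ratio; callers can reassign freely.
    """
    rng = np.random.default_rng(spec.seed)
    Y = sample_label_matrix(spec, rng)
    intensities = rng.choice([1, 2, 3], size=Y.shape,
                             p=list(spec.intensity_probs))
    from .config import LOCATIONS
    images = []
    all_masks = []
    split_cycle = ("train", "train", "train", "train", "validation", "test")
    for i in range(spec.n_images):
        masks = _compartment_masks(spec.image_side, rng, spec.cell_types)
        annotations = {}
        for c, ct in enumerate(spec.cell_types):
            if Y[i, c]:
                k = int(rng.integers(1, 3))  # 1-2 subcellular locations
                locs = frozenset(rng.choice(LOCATIONS, size=k, replace=False))
                annotations[ct] = AnnotationEntry(int(intensities[i, c]), locs)
            else:
                annotations[ct] = AnnotationEntry(0)
        pixels = render_image(masks, annotations, spec, rng)
        images.append(LabeledImage(
            image_id=f"synth_{i:05d}", pixels=pixels,
            protein_id=f"P{i // 3:05d}", antibody_id=f"AB{i // 3:05d}",
            split=split_cycle[i % len(split_cycle)],
            annotations=annotations, cell_types=tuple(spec.cell_types)))
        if return_masks:
            all_masks.append(masks)
    return (images, all_masks) if return_masks else images


def oracle_recover_labels(images, masks_list, threshold: float = -35.0) -> np.ndarray:
    """Color-rule label recovery: positive iff mean brownness > threshold.

    The threshold sits between the counterstain's R-B (~ -80) and the weak
    stain's (~ -27); generated labels should be recoverable near-perfectly,
    guaranteeing the classification task is learnable.
    """
    out = np.zeros((len(images), len(images[0].cell_types)), dtype=np.int8)
    for i, (img, masks) in enumerate(zip(images, masks_list)):
        for c, ct in enumerate(img.cell_types):
            out[i, c] = oracle_brownness(img.pixels, masks[ct]) > threshold
    return out


# ---------------------------------------------------------------------------
# synthetic MC prediction sets

@dataclass
class SyntheticMCSpec:
    """Conditions for fabricated MC prediction samples."""

    true_labels: np.ndarray          # n x C binary
    T: int = 100
    difficulty: np.ndarray | float = 0.3   # per item in [0, 1]
    miscalibration: float = 0.0            # probability of a flipped target
    concentration_easy: float = 150.0      # Beta concentration at difficulty 0
    concentration_hard: float = 2.0        # ... at difficulty 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.true_labels = np.asarray(self.true_labels).astype(int)
        if self.true_labels.ndim != 2:
            raise ConfigError("true_labels must be n x C")
        n = self.true_labels.shape[0]
        d = np.asarray(self.difficulty, dtype=np.float64)
        if d.ndim == 0:
            d = np.full(n, float(d))
        if d.shape != (n,) or d.min() < 0 or d.max() > 1:
            raise ConfigError("difficulty must be per-item values in [0, 1]")
        self.difficulty = d
        if self.T < 2:
            raise ConfigError("T must be >= 2")


def generate_mc_samples(spec: SyntheticMCSpec):
    """Fabricate MC prediction sets with a known difficulty structure.

    Per item/label the Beta mean is pulled toward the true label by
    ``1 - difficulty`` (difficulty 0: mean at the label; difficulty 1: mean
    at 0.5) and the concentration interpolates log-linearly from easy to
    hard, so harder items produce both less separated and more dispersed
    samples.  Returns ``(mc_sets, correct)`` where ``correct`` flags whether
    thresholding the predictive mean at 0.5 recovers the truth.
    """
    rng = np.random.default_rng(spec.seed)
    Y = spec.true_labels
    n, C = Y.shape
    d = spec.difficulty
    target = Y.astype(np.float64)
    if spec.miscalibration > 0:
        flip = rng.random((n, C)) < spec.miscalibration
        target = np.where(flip, 1.0 - target, target)
    mean = 0.5 + (target - 0.5) * (1.0 - d)[:, None]
    mean = np.clip(mean, 0.02, 0.98)
    kappa = np.exp(np.log(spec.concentration_easy) * (1 - d)
                   + np.log(spec.concentration_hard) * d)[:, None]
    a = mean * kappa
    b = (1.0 - mean) * kappa
    samples = rng.beta(a[:, :, None], b[:, :, None], size=(n, C, spec.T))
    samples = np.transpose(samples, (0, 2, 1))        # n x T x C
    mc_sets = [MCPredictionSet(f"sim_{i:05d}", samples[i]) for i in range(n)]
    mu = samples.mean(axis=1)
    correct = (mu >= 0.5).astype(int) == Y
    return mc_sets, correct
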