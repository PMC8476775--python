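"""Handcrafted texture descriptors and the hybrid feature assembly.

Three classical descriptor families are extracted from the luminance image:

* HOG — histogram of oriented gradients with 8 unsigned orientation bins,
  8x8-pixel cells and 8x8-cell blocks (block stride one cell, per-block L2
  normalization).
* Haralick — the 13 classical gray-level co-occurrence statistics, averaged
  over the four directions (0, 45, 90, 135 degrees) of a symmetric,
  normalized GLCM.
* Hu — the seven moment invariants, reported on a signed log10-magnitude
  scale for numeric conditioning.

The concatenated descriptor is z-scored per feature (training statistics)
and reduced with PCA before being appended to the CNN feature vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray, rgb2hed
from skimage.feature import graycomatrix, hog as _sk_hog
from skimage.measure import moments_central, moments_hu, moments_normalized
from sklearn.decomposition import PCA as _SkPCA

from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)


def to_grayscale(pixels: np.ndarray) -> np.ndarray:
    """Luminance conversion (0.2125 R + 0.7154 G + 0.0721 B), floats in [0, 1]."""
    pixels = np.asarray(pixels)
    if pixels.ndim == 2:
        return pixels.astype(np.float64) / 255.0
    return rgb2gray(pixels)


def dab_channel(pixels: np.ndarray) -> np.ndarray:
    """DAB optical-density channel via color deconvolution, scaled to [0, 1].

    Separates the brown immunostain from the blue counterstain; on IHC-like
    input this channel is bright exactly where the protein is expressed, so
    texture descriptors computed on it localize the staining rather than
    general tissue structure.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim == 2:
        return pixels.astype(np.float64) / 255.0
    dab = rgb2hed(pixels)[:, :, 2]
    lo, hi = dab.min(), dab.max()
    if hi - lo < 1e-12:
        return np.zeros_like(dab)
    return (dab - lo) / (hi - lo)


_CHANNELS = {"luminance": to_grayscale, "dab": dab_channel}


# ---------------------------------------------------------------------------
# HOG

def hog_feature_length(side: int, orientations: int = 8, cell_px: int = 8,
                       cells_per_block: int = 8) -> int:
    """Closed-form HOG output length for a square side."""
    cells = side // cell_px
    nblocks = cells - cells_per_block + 1
    return nblocks * nblocks * cells_per_block ** 2 * orientations


def hog_features(gray: np.ndarray, orientations: int = 8, cell_px: int = 8,
                 cells_per_block: int = 8) -> np.ndarray:
    """HOG descriptor of a square grayscale image.

    Gradient orientation is unsigned (folded onto [0, 180)); blocks of
    ``cells_per_block`` x ``cells_per_block`` cells slide with a stride of one
    cell and are L2-normalized individually.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.ndim != 2:
        raise ValidationError(f"expected a 2-D grayscale image, got {gray.shape}")
    h, w = gray.shape
    if h % cell_px or w % cell_px:
        raise ValidationError(
            f"image sides {gray.shape} must be divisible by cell_px={cell_px}")
    if min(h, w) // cell_px < cells_per_block:
        raise ValidationError(
            f"image of {gray.shape} is smaller than one "
            f"{cells_per_block}x{cells_per_block}-cell block")
    vec = _sk_hog(
        gray,
        orientations=orientations,
        pixels_per_cell=(cell_px, cell_px),
        cells_per_block=(cells_per_block, cells_per_block),
        block_norm="L2",
        feature_vector=True,
    )
    return vec.astype(np.float64)


# ---------------------------------------------------------------------------
# Haralick

def _haralick_from_glcm(P: np.ndarray) -> np.ndarray:
    """The 13 classical statistics of one normalized symmetric GLCM."""
    L = P.shape[0]
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    eps = np.finfo(np.float64).tiny

    px = P.sum(axis=1)
    mu = (i * px).sum()
    var = ((i - mu) ** 2 * px).sum()

    # p_{x+y}(k), k = 0..2L-2 and p_{x-y}(k), k = 0..L-1
    ksum = (ii + jj).astype(np.intp)
    kdiff = np.abs(ii - jj).astype(np.intp)
    p_sum = np.bincount(ksum.ravel(), weights=P.ravel(), minlength=2 * L - 1)
    p_diff = np.bincount(kdiff.ravel(), weights=P.ravel(), minlength=L)
    k_sum = np.arange(2 * L - 1, dtype=np.float64)
    k_diff = np.arange(L, dtype=np.float64)

    f = np.empty(13)
    f[0] = (P ** 2).sum()                                   # angular 2nd moment
    f[1] = ((ii - jj) ** 2 * P).sum()                       # contrast
    if var > 0:                                             # correlation
        f[2] = ((ii - mu) * (jj - mu) * P).sum() / var
    else:
        f[2] = 0.0
    f[3] = var                                              # sum of squares: variance
    f[4] = (P / (1.0 + (ii - jj) ** 2)).sum()               # inverse difference moment
    f[5] = (k_sum * p_sum).sum()                            # sum average
    f[6] = ((k_sum - f[5]) ** 2 * p_sum).sum()              # sum variance
    f[7] = -(p_sum * np.log2(p_sum + eps))[p_sum > 0].sum() # sum entropy
    f[8] = -(P * np.log2(P + eps))[P > 0].sum()             # entropy
    f[9] = ((k_diff - (k_diff * p_diff).sum()) ** 2 * p_diff).sum()  # diff variance
    f[10] = -(p_diff * np.log2(p_diff + eps))[p_diff > 0].sum()      # diff entropy
    # information measures of correlation
    pxpy = np.outer(px, px)
    hxy = f[8]
    mask = (P > 0)
    hxy1 = -(P[mask] * np.log2(pxpy[mask] + eps)).sum()
    mask2 = pxpy > 0
    hxy2 = -(pxpy[mask2] * np.log2(pxpy[mask2])).sum()
    hx = -(px * np.log2(px + eps))[px > 0].sum()
    denom = max(hx, eps)  # symmetric GLCM: hx == hy
    f[11] = (hxy - hxy1) / denom if denom > eps else 0.0
    arg = 1.0 - np.exp(-2.0 * np.log(2.0) * (hxy2 - hxy))
    f[12] = np.sqrt(max(arg, 0.0))
    return f


def haralick_features(gray: np.ndarray, levels: int = 256, distance: int = 1,
                      average: bool = True) -> np.ndarray:
    """13 Haralick statistics of an 8-bit grayscale image.

    A symmetric, normalized GLCM is built per direction (0/45/90/135 degrees)
    at the given pixel ``distance``; with ``average=True`` (default) the 13
    statistics are averaged over the four directions, otherwise a 4x13 array
    is returned.  Degenerate single-valued images yield a defined, finite
    result (correlation is set to 0 when the gray-level variance vanishes).
    """
    gray = np.asarray(gray)
    if gray.ndim != 2 or gray.shape[0] < 2 or gray.shape[1] < 2:
        raise ValidationError(f"need a 2-D image of at least 2x2, got {gray.shape}")
    if gray.dtype != np.uint8:
        if np.issubdtype(gray.dtype, np.floating) and gray.max() <= 1.0:
            gray = np.clip(np.rint(gray * 255), 0, 255).astype(np.uint8)
        else:
            gray = np.clip(gray, 0, 255).astype(np.uint8)
    if levels < 256:
        gray = (gray.astype(np.uint16) * levels // 256).astype(np.uint8)
    glcm = graycomatrix(gray, distances=[distance],
                        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
                        levels=levels, symmetric=True, normed=True)
    per_dir = np.stack([_haralick_from_glcm(glcm[:, :, 0, a]) for a in range(4)])
    if not np.all(np.isfinite(per_dir)):
        raise AssertionError("Haralick features must be finite")
    return per_dir.mean(axis=0) if average else per_dir


# ---------------------------------------------------------------------------
# Hu moments

def hu_moments(gray: np.ndarray) -> np.ndarray:
    """Seven Hu invariant moments on a signed log10-magnitude scale.

    An all-zero image has no defined normalized moments; by convention it
    maps to the zero vector.
    """
    gray = np.asarray(gray, dtype=np.float64)
    if gray.size == 0 or gray.ndim != 2:
        raise ValidationError(f"need a non-empty 2-D image, got {gray.shape}")
    if gray.sum() == 0:
        return np.zeros(7)
    hu = moments_hu(moments_normalized(moments_central(gray)))
    out = np.zeros(7)
    nz = hu != 0
    out[nz] = np.sign(hu[nz]) * np.log10(np.abs(hu[nz]))
    return out


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCAModel:
    """Fitted principal-component model (orthonormal rows in ``components``)."""

    mean: np.ndarray
    components: np.ndarray          # k x d
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def save(self, path) -> None:
        np.savez(path, mean=self.mean, components=self.components,
                 explained_variance_ratio=self.explained_variance_ratio)

    @classmethod
    def load(cls, path) -> "PCAModel":
        with np.load(path) as data:
            return cls(data["mean"], data["components"],
                       data["explained_variance_ratio"])


def fit_pca(vectors: np.ndarray, target_dim: int) -> PCAModel:
    """Fit PCA on an n x d matrix; components ordered by decreasing variance."""
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError(f"need an n x d matrix with n >= 2, got {X.shape}")
    n, d = X.shape
    max_dim = min(n - 1, d)
    if not 1 <= target_dim <= max_dim:
        raise ConfigError(
            f"target_dim must be in 1..{max_dim} for a {n}x{d} matrix, "
            f"got {target_dim}")
    sk = _SkPCA(n_components=target_dim, svd_solver="full")
    sk.fit(X)
    return PCAModel(sk.mean_.copy(), sk.components_.copy(),
                    sk.explained_variance_ratio_.copy())


def apply_pca(model: PCAModel, vectors: np.ndarray) -> np.ndarray:
    """Centered projection onto the model's principal axes (1-D or 2-D input)."""
    X = np.asarray(vectors, dtype=np.float64)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    out = (X - model.mean) @ model.components.T
    return out[0] if single else out


# ---------------------------------------------------------------------------
# hybrid assembly and the end-to-end extractor

def assemble_hybrid(cnn_features: np.ndarray,
                    handcrafted_reduced: np.ndarray) -> np.ndarray:
    """Concatenate CNN features (first) with reduced handcrafted features."""
    cnn = np.asarray(cnn_features, dtype=np.float64).ravel()
    hc = np.asarray(handcrafted_reduced, dtype=np.float64).ravel()
    if not (np.all(np.isfinite(cnn)) and np.all(np.isfinite(hc))):
        raise ValidationError("hybrid components must be finite")
    return np.concatenate([cnn, hc])


class HandcraftedExtractor:
    """HOG + Haralick + Hu -> z-score -> PCA pipeline with persistence.

    ``fit`` learns the standardization statistics and the PCA basis on the
    training images only; ``transform`` is then deterministic.  When the
    requested PCA dimensionality exceeds what n-1 samples can support, it is
    clamped with a logged warning.
    """

    def __init__(self, orientations: int = 8, cell_px: int = 8,
                 cells_per_block: int = 8, levels: int = 256, distance: int = 1,
                 pca_dim: int = 3732, channel: str = "luminance"):
        if channel not in _CHANNELS:
            raise ConfigError(f"unknown channel {channel!r}; "
                              f"choose from {sorted(_CHANNELS)}")
        self.channel = channel
        self.orientations = orientations
        self.cell_px = cell_px
        self.cells_per_block = cells_per_block
        self.levels = levels
        self.distance = distance
        self.pca_dim = pca_dim
        self.feature_mean_: np.ndarray | None = None
        self.feature_std_: np.ndarray | None = None
        self.pca_: PCAModel | None = None

    def raw_features(self, pixels: np.ndarray) -> np.ndarray:
        gray = _CHANNELS[self.channel](pixels)
        hogv = hog_features(gray, self.orientations, self.cell_px,
                            self.cells_per_block)
        harv = haralick_features(gray, self.levels, self.distance)
        huv = hu_moments(gray)
        return np.concatenate([hogv, harv, huv])

    def raw_matrix(self, images) -> np.ndarray:
        return np.stack([self.raw_features(img) for img in images])

    def fit(self, images_or_matrix) -> "HandcraftedExtractor":
        X = (np.asarray(images_or_matrix, dtype=np.float64)
             if isinstance(images_or_matrix, np.ndarray)
             and np.asarray(images_or_matrix).ndim == 2
             else self.raw_matrix(images_or_matrix))
        n, d = X.shape
        self.feature_mean_ = X.mean(axis=0)
        std = X.std(axis=0, ddof=0)
        std[std == 0] = 1.0  # constant features carry no information
        self.feature_std_ = std
        Z = (X - self.feature_mean_) / self.feature_std_
        dim = min(self.pca_dim, n - 1, d)
        if dim < self.pca_dim:
            logger.warning("clamping PCA dimension from %d to %d (n=%d, d=%d)",
                           self.pca_dim, dim, n, d)
        self.pca_ = fit_pca(Z, dim)
        return self

    def transform(self, images_or_matrix) -> np.ndarray:
        if self.pca_ is None:
            raise ConfigError("HandcraftedExtractor used before fit()")
        X = (np.asarray(images_or_matrix, dtype=np.float64)
             if isinstance(images_or_matrix, np.ndarray)
             and np.asarray(images_or_matrix).ndim == 2
             else self.raw_matrix(images_or_matrix))
        Z = (X - self.feature_mean_) / self.feature_std_
        return apply_pca(self.pca_, Z)

    def fit_transform(self, images_or_matrix) -> np.ndarray:
        X = (np.asarray(images_or_matrix, dtype=np.float64)
             if isinstance(images_or_matrix, np.ndarray)
             and np.asarray(images_or_matrix).ndim == 2
             else self.raw_matrix(images_or_matrix))
        self.fit(X)
        return self.transform(X)

    # persistence -----------------------------------------------------------
    def save(self, path) -> None:
        if self.pca_ is None:
            raise ConfigError("cannot save an unfitted extractor")
        np.savez(path,
                 params=np.array([self.orientations, self.cell_px,
                                  self.cells_per_block, self.levels,
                                  self.distance, self.pca_dim]),
                 channel=np.array(self.channel),
                 feature_mean=self.feature_mean_, feature_std=self.feature_std_,
                 pca_mean=self.pca_.mean, pca_components=self.pca_.components,
                 pca_evr=self.pca_.explained_variance_ratio)

    @classmethod
    def load(cls, path) -> "HandcraftedExtractor":
        with np.load(path) as data:
            p = data["params"].astype(int)
            channel = str(data["channel"]) if "channel" in data.files \
                else "luminance"
            ex = cls(*p[:5], pca_dim=int(p[5]), channel=channel)
            ex.feature_mean_ = data["feature_mean"]
            ex.feature_std_ = data["feature_std"]
            ex.pca_ = PCAModel(data["pca_mean"], data["pca_components"],
                               data["pca_evr"])
        return ex
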