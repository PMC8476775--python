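"""The hybrid Bayesian classifier as a model/results pair.

:class:`HBNet` is constructed from data (labeled images plus configuration)
and ``fit()`` returns an :class:`HBNetResults` carrying the trained
parameters, the training log, the MCC-selected probability thresholds, and
methods for stochastic Monte-Carlo prediction, uncertainty scoring,
evaluation, triage and a text ``summary()``.

Pipeline inside ``fit``: resize images to the configured side, extract and
PCA-reduce the handcrafted block (statistics fitted on the training split
only), train the convolutional trunk + drop-weights head with AMSGrad on
mean per-label binary cross-entropy (no class weighting), checkpoint on
best validation mean per-label accuracy, then grid-search per-label
probability thresholds by MCC on the validation split.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _nn
from ._nn import HybridNet, mc_predict_probs, normalize_images, train_network
from .config import CELL_TYPES, ModelConfig, desk_config
from .errors import ConfigError, DataError
from .evaluation import (EvaluationReport, ThresholdSet, evaluate,
                         grid_search_thresholds)
from .features import HandcraftedExtractor
from .io import LabeledImage, resize_image
from .triage import TriageResult, apply_cutoffs, select_cutoff
from .uncertainty import MCPredictionSet, score_predictions


def _prepare_pixels(images: list[LabeledImage], side: int) -> np.ndarray:
    out = np.empty((len(images), side, side, 3), dtype=np.uint8)
    for i, img in enumerate(images):
        if img.pixels is None:
            raise DataError(f"{img.image_id}: pixels not loaded")
        out[i] = resize_image(img.pixels, (side, side))
    return out


class HBNet:
    """Hybrid Bayesian network model, built from labeled images.

    Parameters
    ----------
    images:
        Labeled images; their ``split`` field partitions them into train /
        validation (and optionally test, which ``fit`` ignores).
    config:
        :class:`ModelConfig`; defaults to the desk-scale profile.
    """

    def __init__(self, images: list[LabeledImage],
                 config: ModelConfig | None = None,
                 cell_types=CELL_TYPES):
        if not images:
            raise DataError("HBNet needs at least one labeled image")
        self.config = config or desk_config()
        self.cell_types = tuple(cell_types)
        self.config.n_labels = len(self.cell_types)
        self.images = list(images)
        ids = [im.image_id for im in self.images]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate image_id in input")
        self.splits = {s: [im for im in self.images if im.split == s]
                       for s in ("train", "validation", "test", "external")}
        if not self.splits["train"] or not self.splits["validation"]:
            raise DataError("need non-empty train and validation splits")

    @classmethod
    def from_images(cls, images, **kwargs) -> "HBNet":
        return cls(images, **kwargs)

    def label_matrix(self, split: str) -> np.ndarray:
        return np.stack([im.label_vector() for im in self.splits[split]])

    def fit(self, seed: int | None = None, progress: bool = False) -> "HBNetResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        t0 = time.time()

        train_imgs = self.splits["train"]
        val_imgs = self.splits["validation"]
        Xtr_u8 = _prepare_pixels(train_imgs, cfg.image_side)
        Xva_u8 = _prepare_pixels(val_imgs, cfg.image_side)
        Ytr = self.label_matrix("train")
        Yva = self.label_matrix("validation")

        extractor = HandcraftedExtractor(
            orientations=cfg.hog_orientations, cell_px=cfg.hog_cell_px,
            cells_per_block=cfg.hog_cells_per_block,
            levels=cfg.haralick_levels, distance=cfg.haralick_distance,
            pca_dim=cfg.pca_dim, channel=cfg.handcrafted_channel)
        HCtr = extractor.fit_transform(list(Xtr_u8))
        HCva = extractor.transform(list(Xva_u8))

        net = HybridNet(cfg, handcrafted_dim=HCtr.shape[1], rng=rng)
        best_state, log = train_network(
            net, normalize_images(Xtr_u8), HCtr, Ytr,
            normalize_images(Xva_u8), HCva, Yva,
            cfg, rng, progress=progress)

        # per-label probability thresholds from validation predictive means
        T_thr = max(2, min(cfg.mc_samples, 50))
        val_probs = mc_predict_probs(net, normalize_images(Xva_u8), HCva,
                                     T_thr, rng).mean(axis=1)
        if cfg.threshold_policy == "mcc":
            thresholds = grid_search_thresholds(Yva, val_probs,
                                                cell_types=self.cell_types)
        else:
            thresholds = ThresholdSet(self.cell_types,
                                      np.full(len(self.cell_types), 0.5))
        return HBNetResults(
            model=self, net=net, extractor=extractor,
            training_log=pd.DataFrame(log), thresholds=thresholds,
            fit_seconds=time.time() - t0)


@dataclass
class HBNetResults:
    """Fitted-model results: parameters, diagnostics and inference methods."""

    model: HBNet
    net: HybridNet = field(repr=False)
    extractor: HandcraftedExtractor = field(repr=False)
    training_log: pd.DataFrame = field(repr=False)
    thresholds: ThresholdSet = field(repr=False)
    fit_seconds: float = 0.0

    @property
    def best_val_accuracy(self) -> float:
        return float(self.training_log["val_accuracy"].max())

    # ---- inference --------------------------------------------------------
    def _features_for(self, images: list[LabeledImage]):
        side = self.model.config.image_side
        X_u8 = _prepare_pixels(images, side)
        HC = self.extractor.transform(list(X_u8))
        return normalize_images(X_u8), HC

    def predict_proba(self, images: list[LabeledImage]) -> np.ndarray:
        """Deterministic (expectation-pass) per-label probabilities."""
        X, HC = self._features_for(images)
        return self.net.forward_probs(X, HC, masks=None)

    def mc_predict(self, images: list[LabeledImage], T: int | None = None,
                   seed: int = 0) -> list[MCPredictionSet]:
        """T stochastic forward passes per image with fresh drop-weight masks."""
        T = self.model.config.mc_samples if T is None else T
        if T < 1:
            raise ConfigError(f"T must be >= 1, got {T}")
        rng = np.random.default_rng(seed)
        X, HC = self._features_for(images)
        probs = mc_predict_probs(self.net, X, HC, T, rng)
        return [MCPredictionSet(img.image_id, probs[i])
                for i, img in enumerate(images)]

    def score(self, mc_sets: list[MCPredictionSet],
              y_true: np.ndarray | None = None) -> pd.DataFrame:
        """Uncertainty records (mu, entropies, CPPD, DHC) per image x label."""
        return score_predictions(
            mc_sets, cell_types=self.model.cell_types,
            prob_thresholds=self.thresholds.prob_thresholds, y_true=y_true)

    def evaluate(self, images: list[LabeledImage], T: int | None = None,
                 seed: int = 0) -> EvaluationReport:
        """Metric suite on a labeled image set using MC predictive means."""
        mc_sets = self.mc_predict(images, T=T, seed=seed)
        mus = np.stack([ms.samples.mean(axis=0) for ms in mc_sets])
        Y = np.stack([im.label_vector() for im in images])
        Yp = (mus >= self.thresholds.prob_thresholds[None, :]).astype(int)
        return evaluate(Y, Yp, scores=mus, cell_types=self.model.cell_types)

    # ---- triage -----------------------------------------------------------
    def select_dhc_cutoffs(self, validation_records: pd.DataFrame,
                           target_accuracy: float = 0.95,
                           min_retained_fraction: float = 0.5) -> dict:
        """Per-label DHC cutoffs learned on scored validation records.

        Selection runs on the raw DHC scale: within one scored batch raw and
        min-max-normalized scores are affinely equivalent (identical retained
        sets), but only the raw scale is batch-independent, so raw cutoffs
        transfer from the validation batch to any later batch.
        """
        return {ct: select_cutoff(validation_records, ct,
                                  target_accuracy=target_accuracy,
                                  min_retained_fraction=min_retained_fraction,
                                  column="dhc_raw")
                for ct in self.model.cell_types}

    def triage(self, records: pd.DataFrame, cutoffs) -> TriageResult:
        """Retain/discard split; learned (dict) cutoffs act on raw DHC,
        named presets on the published normalized 0-1 scale."""
        column = "dhc_normalized" if isinstance(cutoffs, str) else "dhc_raw"
        return apply_cutoffs(records, cutoffs, cell_types=self.model.cell_types,
                             column=column)

    # ---- reporting --------------------------------------------------------
    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Hybrid Bayesian network — fit results",
            "=====================================",
            f"backbone             {cfg.backbone} ({cfg.image_side} px input)",
            f"hybrid feature dim   {cfg.cnn_feature_dim} CNN + "
            f"{self.extractor.pca_.n_components} handcrafted (post-PCA)",
            f"drop-weights rate    {cfg.drop_weight_rate}",
            f"train / validation   {len(self.model.splits['train'])} / "
            f"{len(self.model.splits['validation'])} images",
            f"epochs               {cfg.epochs} "
            f"(best val accuracy {self.best_val_accuracy:.4f})",
            f"fit time             {self.fit_seconds:.1f} s",
            "",
            "Per-label MCC-optimal probability thresholds",
            self.thresholds.as_frame().to_string(index=False),
        ]
        return "\n".join(lines)

    # ---- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint weights + config + PCA + vocabulary to one .npz file."""
        import json
        state = self.net.get_state()
        payload = {f"param_{k}": v for k, v in state.items()}
        payload["handcrafted_dim"] = np.array([self.net.handcrafted_dim])
        payload["config_json"] = np.frombuffer(
            json.dumps(self.model.config.to_dict()).encode(), dtype=np.uint8)
        payload["cell_types_json"] = np.frombuffer(
            json.dumps(list(self.model.cell_types)).encode(), dtype=np.uint8)
        payload["prob_thresholds"] = self.thresholds.prob_thresholds
        payload["feature_mean"] = self.extractor.feature_mean_
        payload["feature_std"] = self.extractor.feature_std_
        payload["pca_mean"] = self.extractor.pca_.mean
        payload["pca_components"] = self.extractor.pca_.components
        payload["pca_evr"] = self.extractor.pca_.explained_variance_ratio
        payload["training_log"] = self.training_log.to_numpy()
        np.savez(path, **payload)

    @classmethod
    def load(cls, path, images: list[LabeledImage] | None = None) -> "HBNetResults":
        """Restore a checkpoint; ``images`` rebuilds the model context
        (defaults to an empty shell usable for pure inference)."""
        import json

        from .features import PCAModel
        with np.load(path) as data:
            cfg = ModelConfig.from_dict(
                json.loads(bytes(data["config_json"]).decode()))
            cell_types = tuple(
                json.loads(bytes(data["cell_types_json"]).decode()))
            hc_dim = int(data["handcrafted_dim"][0])
            rng = np.random.default_rng(0)
            net = HybridNet(cfg, handcrafted_dim=hc_dim, rng=rng)
            net.set_state({k[len("param_"):]: data[k]
                           for k in data.files if k.startswith("param_")})
            extractor = HandcraftedExtractor(
                orientations=cfg.hog_orientations, cell_px=cfg.hog_cell_px,
                cells_per_block=cfg.hog_cells_per_block,
                levels=cfg.haralick_levels, distance=cfg.haralick_distance,
                pca_dim=cfg.pca_dim, channel=cfg.handcrafted_channel)
            extractor.feature_mean_ = data["feature_mean"]
            extractor.feature_std_ = data["feature_std"]
            extractor.pca_ = PCAModel(data["pca_mean"], data["pca_components"],
                                      data["pca_evr"])
            thresholds = ThresholdSet(cell_types, data["prob_thresholds"])
            log = pd.DataFrame(data["training_log"],
                               columns=["epoch", "loss", "val_accuracy"])
        if images is None:
            # inference-only shell: one placeholder per required split
            model = object.__new__(HBNet)
            model.config = cfg
            model.cell_types = cell_types
            model.images = []
            model.splits = {s: [] for s in ("train", "validation", "test",
                                            "external")}
        else:
            model = HBNet(images, config=cfg, cell_types=cell_types)
        return cls(model=model, net=net, extractor=extractor,
                   training_log=log, thresholds=thresholds)
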