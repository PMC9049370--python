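"""End-to-end orchestration: preprocess → separate → segment → features
→ train/predict → vote → evaluate.

The configuration defaults are the method's reference operating point:
λ = 0.2 stain sparsity, I0 = 255, CLBP P = 8 / R = 1, SVM c = 2 / g = 1,
20 random patches per image and a strict 10-of-20 non-carcinoma vote.
Every random choice derives from one global seed, so a configuration
fully determines the outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .classify import PatchVoteClassifier
from .exceptions import ConfigError, DegenerateInputError, StageError
from .features import CLBPExtractor, ColorCorrelogramExtractor, fuse
from .io import load_image, random_patches, rescale_half
from .metrics import confusion, metrics, roc_auc
from .segmentation import NucleiSegmenter, segment_foreground
from .stains import StainSeparator, separate

__all__ = ["PipelineConfig", "extract_patch_features", "run_pipeline",
           "run_synthetic_experiment"]


@dataclass
class PipelineConfig:
    """All knobs of the recognition pipeline in one place."""

    seed: int = 0
    rescale: bool = False
    patch_size: int = 512
    n_patches: int = 20
    stain_alpha: float = 0.2
    i0: float = 255.0
    s_min: float = 0.1
    se_radius: int = 5
    corner_window: int = 32
    max_blob: int = 200
    scale_se: bool = True
    clbp_p: int = 8
    clbp_r: float = 1.0
    svm_c: float = 2.0
    svm_gamma: float = 1.0
    vote_threshold: int = 10
    cache_dir: str | None = None

    def __post_init__(self):
        if self.patch_size < 16:
            raise ConfigError("patch_size must be at least 16 pixels")
        if not 0 <= self.vote_threshold < self.n_patches:
            raise ConfigError("vote_threshold must lie in [0, n_patches)")
        if self.stain_alpha < 0 or self.svm_c <= 0 or self.svm_gamma <= 0:
            raise ConfigError("stain_alpha >= 0 and svm c, g > 0 required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _patch_seed(global_seed: int, image_index: int) -> int:
    """Stable per-image seed below 2^31 derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{image_index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _cache_key(patch: np.ndarray, cfg: PipelineConfig) -> str:
    h = hashlib.sha256()
    h.update(patch.tobytes())
    h.update(json.dumps(asdict(cfg), sort_keys=True).encode())
    return h.hexdigest()


def extract_patch_features(patch: np.ndarray, cfg: PipelineConfig) -> np.ndarray:
    """Fused 246-dim descriptor of one RGB patch.

    Stain separation and segmentation run per patch; CLBP is computed on
    the nuclei-segmented image and the auto-correlogram on the
    stain-separated foreground. Results are cached on disk by content
    hash when ``cfg.cache_dir`` is set (stain separation dominates the
    runtime, so re-runs skip completed patches).
    """
    cache_file = None
    if cfg.cache_dir:
        cache_file = Path(cfg.cache_dir) / (_cache_key(patch, cfg) + ".npy")
        if cache_file.exists():
            return np.load(cache_file)

    separator = StainSeparator(
        alpha=cfg.stain_alpha, i0=cfg.i0, random_state=cfg.seed
    )
    fore, _ = separator.fit_separate(patch)
    try:
        labels, nuclei_img = segment_foreground(
            fore,
            s_min=cfg.s_min,
            se_radius=cfg.se_radius,
            corner_window=cfg.corner_window,
            max_blob=cfg.max_blob,
            scale_se=cfg.scale_se,
        )
    except DegenerateInputError:
        # a randomly cropped patch may contain no nuclei at all; its
        # segmented image is then empty (all white)
        nuclei_img = np.full_like(fore, 255)
    texture = CLBPExtractor(P=cfg.clbp_p, R=cfg.clbp_r).transform([nuclei_img])[0]
    color = ColorCorrelogramExtractor().transform([fore])[0]
    fused = fuse(texture, color)
    if cache_file is not None:
        cache_file.parent.mkdir(parents=True, exist_ok=True)
        np.save(cache_file, fused)
    return fused


def _featurize_images(images, labels, cfg: PipelineConfig, id_prefix: str):
    """Crop patches and extract fused features for a list of images."""
    X, y, ids = [], [], []
    for idx, (img, label) in enumerate(zip(images, labels)):
        image_id = f"{id_prefix}{idx:04d}"
        if cfg.rescale:
            img = rescale_half(img)
        patches = random_patches(
            img,
            n=cfg.n_patches,
            size=cfg.patch_size,
            seed=_patch_seed(cfg.seed, idx),
            parent_id=image_id,
            label=label,
        )
        for rec in patches:
            try:
                X.append(extract_patch_features(rec.patch, cfg))
            except StageError as exc:
                raise StageError(
                    f"{exc.stage} (image {image_id}, patch {rec.patch_index})",
                    exc.original,
                ) from exc
            y.append(label)
            ids.append(image_id)
    return np.asarray(X), np.asarray(y), np.asarray(ids)


def run_pipeline(
    train_images,
    train_labels,
    test_images,
    test_labels,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Train on one image set, evaluate on another; return the report.

    The report carries patch-wise and image-wise confusion counts, the
    five classification metrics (percent), and ROC AUC at both levels.
    """
    cfg = cfg or PipelineConfig()
    Xtr, ytr, _ = _featurize_images(train_images, train_labels, cfg, "train")
    Xte, yte, ids_te = _featurize_images(test_images, test_labels, cfg, "test")

    clf = PatchVoteClassifier(
        C=cfg.svm_c,
        gamma=cfg.svm_gamma,
        patches_per_image=cfg.n_patches,
        vote_threshold=cfg.vote_threshold,
    ).fit(Xtr, ytr)

    patch_pred = clf.predict(Xte)
    patch_scores = clf.decision_function(Xte)
    img_ids, img_pred, img_scores = clf.predict_images(Xte, ids_te)
    first_idx = {iid: np.flatnonzero(ids_te == iid)[0] for iid in img_ids}
    img_true = np.asarray([yte[first_idx[iid]] for iid in img_ids])

    patch_counts = confusion(yte, patch_pred)
    image_counts = confusion(img_true, img_pred)
    _, patch_auc = roc_auc(patch_scores, yte)
    _, image_auc = roc_auc(img_scores, img_true)

    return {
        "config": asdict(cfg),
        "patch_wise": {
            "counts": vars(patch_counts),
            "metrics": metrics(patch_counts).as_dict(),
            "auc": round(patch_auc, 4),
        },
        "image_wise": {
            "counts": vars(image_counts),
            "metrics": metrics(image_counts).as_dict(),
            "auc": round(image_auc, 4),
            "ids": list(map(str, img_ids)),
            "predictions": list(map(str, img_pred)),
        },
    }


def run_synthetic_experiment(
    n_per_class: int = 20,
    seed: int = 0,
    cfg: PipelineConfig | None = None,
    image_shape: tuple[int, int] = (256, 256),
) -> dict:
    """Full pipeline on a generated two-class dataset.

    Train and test sets are generated independently (seeds derived from
    the global seed), with ``n_per_class`` images per class in each.
    """
    if cfg is None:
        cfg = PipelineConfig(
            seed=seed, patch_size=image_shape[0] // 2, se_radius=5
        )
    tr_imgs, tr_manifest, _ = synthetic.make_dataset(
        n_per_class, seed=seed, image_shape=image_shape, split="train"
    )
    te_imgs, te_manifest, _ = synthetic.make_dataset(
        n_per_class, seed=seed + 1000, image_shape=image_shape, split="test"
    )
    return run_pipeline(
        tr_imgs,
        list(tr_manifest["label"]),
        te_imgs,
        list(te_manifest["label"]),
        cfg,
    )
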