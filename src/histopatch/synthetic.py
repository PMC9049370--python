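"""Synthetic H&E image generator with exact Beer–Lambert ground truth.

Scenes are built in stain-density space: nuclei are random ellipses
carrying hematoxylin density (with a 2-pixel Gaussian edge feather so
gradients and watershed behave as on real tissue), the surrounding
stroma carries eosin density, and optional Gaussian OD noise is added to
the density maps. Rendering inverts the optical-density relation
I = I0·exp(−W·H) with fixed reference stain vectors, so the true stain
matrix, density maps, binary/instance nucleus masks and class label are
all known exactly.

Class structure mirrors the qualitative histology cue that carcinoma
tissue shows denser, more pleomorphic, more crowded nuclei than normal
or benign tissue: the carcinoma-like class uses a high nucleus count,
wide size range and larger permitted overlap; the non-carcinoma-like
class sparse, regular, nearly non-overlapping nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse as draw_ellipse

from .classify import CARCINOMA, NON_CARCINOMA
from .exceptions import PackingError
from .stains import HEMATOXYLIN_REF, EOSIN_REF, StainModel

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "make_stain_matrix",
    "make_scene",
    "render_rgb",
    "make_dataset",
    "default_class_params",
]

#: reference nucleus-count ranges per class at the 512×512 reference
#: scale; other image sizes scale these by area.
CARCINOMA_COUNT_512 = (60, 90)
NON_CARCINOMA_COUNT_512 = (15, 30)


@dataclass
class SceneSpec:
    """Parameters of one synthetic H&E scene.

    Densities are in OD units: nuclei carry ``hematoxylin_density``
    (plus a small stromal baseline), the background carries
    ``eosin_background_density``. ``overlap_fraction`` bounds the allowed
    pairwise overlap of a new nucleus with existing ones, as a fraction
    of its own area.
    """

    height: int = 512
    width: int = 512
    n_nuclei: int = 30
    radius_range: tuple[float, float] = (6.0, 14.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.6)
    overlap_fraction: float = 0.1
    hematoxylin_density: float = 1.0
    eosin_background_density: float = 0.3
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.radius_range[0] <= 0:
            raise ValueError("nucleus radii must be positive")
        if self.radius_range[1] >= min(self.height, self.width) / 4:
            raise ValueError("nucleus radii must stay below image_size/4")


@dataclass
class GroundTruth:
    """Everything the generator knows about a rendered scene."""

    mask: np.ndarray
    instance_mask: np.ndarray
    W_true: StainModel
    H_true: np.ndarray
    class_label: str | None = None
    spec: SceneSpec | None = None


def make_stain_matrix() -> StainModel:
    """Unit-normalized reference H&E stain vectors (≈40° apart)."""
    W = np.stack(
        [np.asarray(HEMATOXYLIN_REF), np.asarray(EOSIN_REF)], axis=1
    ).astype(np.float64)
    return StainModel(W / np.linalg.norm(W, axis=0))


def make_scene(spec: SceneSpec) -> GroundTruth:
    """Place nuclei and build the true density maps for one scene."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=bool)
    instances = np.zeros((h, w), dtype=np.int32)
    placed = 0
    for i in range(spec.n_nuclei):
        ok = False
        for _ in range(200):
            a = rng.uniform(*spec.radius_range)
            ecc = rng.uniform(*spec.eccentricity_range)
            b = a * (1.0 - ecc)
            theta = rng.uniform(0, np.pi)
            margin = int(np.ceil(a)) + 1
            cy = rng.integers(margin, h - margin)
            cx = rng.integers(margin, w - margin)
            rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
            if rr.size == 0:
                continue
            overlap = mask[rr, cc].sum() / rr.size
            if overlap <= spec.overlap_fraction:
                mask[rr, cc] = True
                free = instances[rr, cc] == 0
                instances[rr[free], cc[free]] = placed + 1
                placed += 1
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place nucleus {i + 1}/{spec.n_nuclei} under "
                f"overlap <= {spec.overlap_fraction}"
            )

    feather = ndi.gaussian_filter(mask.astype(np.float64), sigma=2.0)
    baseline = 0.02
    h_density = spec.hematoxylin_density * feather + baseline
    e_density = spec.eosin_background_density * (1.0 - feather)
    H = np.stack([h_density.ravel(), e_density.ravel()])
    if spec.noise_sd > 0:
        H = H + rng.normal(0.0, spec.noise_sd, H.shape)
    H = np.maximum(H, 0.0)
    return GroundTruth(
        mask=mask.astype(np.uint8),
        instance_mask=instances,
        W_true=make_stain_matrix(),
        H_true=H,
        spec=spec,
    )


def render_rgb(gt: GroundTruth, i0: float = 255.0) -> np.ndarray:
    """Render a scene to 8-bit RGB by inverting the OD model."""
    h, w = gt.mask.shape
    V = gt.W_true.W @ gt.H_true
    img = np.rint(i0 * np.exp(-V)).clip(0, 255).astype(np.uint8)
    return img.T.reshape(h, w, 3)


def _scaled_counts(base: tuple[int, int], shape: tuple[int, int]) -> tuple[int, int]:
    factor = (shape[0] * shape[1]) / (512 * 512)
    lo = max(1, round(base[0] * factor))
    hi = max(lo + 1, round(base[1] * factor))
    return lo, hi


def default_class_params(image_shape: tuple[int, int] = (512, 512)) -> dict:
    """Per-class SceneSpec distributions at the given image size.

    Nucleus counts are the 512×512 reference ranges scaled by image
    area; carcinoma-like scenes are dense and pleomorphic (wide radius
    range, overlap up to 0.4), non-carcinoma-like scenes sparse and
    regular (narrow radii, overlap ≤ 0.1).
    """
    h, w = image_shape
    return {
        CARCINOMA: dict(
            height=h,
            width=w,
            n_nuclei_range=_scaled_counts(CARCINOMA_COUNT_512, image_shape),
            radius_range=(4.0, 16.0),
            eccentricity_range=(0.0, 0.7),
            overlap_fraction=0.4,
        ),
        NON_CARCINOMA: dict(
            height=h,
            width=w,
            n_nuclei_range=_scaled_counts(NON_CARCINOMA_COUNT_512, image_shape),
            radius_range=(7.0, 11.0),
            eccentricity_range=(0.0, 0.3),
            overlap_fraction=0.1,
        ),
    }


def make_dataset(
    n_per_class: int = 20,
    class_params: dict | None = None,
    seed: int = 0,
    image_shape: tuple[int, int] = (256, 256),
    split: str = "train",
):
    """Generate a balanced labeled synthetic dataset.

    Returns ``(images, manifest, ground_truths)`` where the manifest is a
    DataFrame with columns image_path (a synthetic id), label and split,
    aligned with the image and ground-truth lists. Fully reproducible for
    a given seed.
    """
    params = class_params or default_class_params(image_shape)
    rng = np.random.default_rng(seed)
    images, gts, rows = [], [], []
    for label in (CARCINOMA, NON_CARCINOMA):
        p = dict(params[label])
        lo, hi = p.pop("n_nuclei_range")
        for i in range(n_per_class):
            spec = SceneSpec(
                n_nuclei=int(rng.integers(lo, hi + 1)),
                seed=int(rng.integers(0, 2**31 - 1)),
                **p,
            )
            gt = make_scene(spec)
            gt.class_label = label
            images.append(render_rgb(gt))
            gts.append(gt)
            rows.append(
                {
                    "image_path": f"synthetic/{split}/{label}_{i:03d}.png",
                    "label": label,
                    "split": split,
                }
            )
    manifest = pd.DataFrame(rows)
    return images, manifest, gts
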