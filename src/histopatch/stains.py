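"""H&E stain separation by sparse non-negative matrix factorization.

Under the Beer–Lambert law a stained specimen attenuates light
multiplicatively, so the per-channel optical density

    V = ln(I0 / I)

is linear in stain concentration. For an H&E slide V (3×n over pixels)
factorizes as V ≈ W·H with W the 3×r stain color-appearance matrix
(unit-norm columns, r = 2 stains) and H the r×n density maps. W and H are
estimated jointly by minimizing

    ½‖V − WH‖²_F + λ Σ_j ‖H(j,:)‖₁   s.t.  W, H ≥ 0, ‖W(:,j)‖₂ = 1

with λ = 0.2 by default. H given W is a per-pixel non-negative LASSO,
solved here by cyclic coordinate descent with soft thresholding (the same
convex optimum LARS-LASSO reaches); W given H is updated multiplicatively
with column renormalization. Reconstructing each stain's contribution
separately and inverting the optical-density map yields the hematoxylin
"foreground" image (nuclei) and the eosin "background" image (stroma).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .exceptions import DegenerateInputError, DimensionError

__all__ = [
    "StainModel",
    "DensityMaps",
    "rgb_to_od",
    "od_to_rgb",
    "sparse_code",
    "estimate_stains",
    "order_stains",
    "separate",
    "snmf_objective",
    "StainSeparator",
]

#: Ruifrok-style reference optical-density colors (unit-normalized in
#: :func:`histopatch.synthetic.make_stain_matrix`); hematoxylin absorbs
#: red strongly, eosin barely.
HEMATOXYLIN_REF = (0.65, 0.70, 0.29)
EOSIN_REF = (0.07, 0.99, 0.11)


@dataclass
class StainModel:
    """Stain color appearance matrix W (3×r, unit-norm columns)."""

    W: np.ndarray
    stain_order: tuple[str, ...] = ("hematoxylin", "eosin")

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=np.float64)
        if self.W.ndim != 2 or self.W.shape[0] != 3:
            raise DimensionError(f"W must be 3×r, got {self.W.shape}")

    @property
    def n_stains(self) -> int:
        return self.W.shape[1]


@dataclass
class DensityMaps:
    """Per-pixel stain concentrations H (r×n)."""

    H: np.ndarray
    lam: float = 0.2

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=np.float64)
        if self.H.ndim != 2:
            raise DimensionError(f"H must be r×n, got {self.H.shape}")


def rgb_to_od(img: np.ndarray, i0: float = 255.0) -> np.ndarray:
    """Convert an H×W×3 RGB image to a 3×n optical-density matrix.

    Intensities are clamped to >= 1 before the logarithm so the OD of a
    fully dark pixel stays finite (ln(i0/1)).
    """
    if i0 <= 0:
        raise ValueError("reference intensity i0 must be positive")
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 3:
        flat = img.reshape(-1, img.shape[2]).T
    else:
        flat = img
    return np.log(i0 / np.maximum(flat, 1.0))


def od_to_rgb(V: np.ndarray, i0: float = 255.0, shape=None) -> np.ndarray:
    """Invert :func:`rgb_to_od`: I = round(i0 · exp(−V)), clipped to [0,255].

    If ``shape`` (H, W) is given the 3×n matrix is reshaped to H×W×3.
    """
    V = np.asarray(V, dtype=np.float64)
    out = np.rint(i0 * np.exp(-V)).clip(0, 255).astype(np.uint8)
    if shape is not None:
        out = out.T.reshape(shape[0], shape[1], -1)
    return out


def sparse_code(
    V: np.ndarray,
    W: np.ndarray,
    lam: float = 0.2,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> np.ndarray:
    """Non-negative LASSO coding of OD pixels against the stain basis.

    For every pixel column v solves

        min_h ½‖v − Wh‖² + λ‖h‖₁   s.t. h ≥ 0

    by cyclic coordinate descent with non-negative soft thresholding,
    vectorized across all pixels. Started from h = 0, so the objective
    never exceeds the all-zero solution.
    """
    W = np.asarray(getattr(W, "W", W), dtype=np.float64)
    V = np.atleast_2d(np.asarray(V, dtype=np.float64))
    if V.shape[0] != W.shape[0]:
        raise DimensionError(f"V has {V.shape[0]} channels, W has {W.shape[0]}")
    if not (np.isfinite(V).all() and np.isfinite(W).all()):
        raise ValueError("non-finite values in sparse coding inputs")
    r = W.shape[1]
    G = W.T @ W  # r×r Gram matrix
    WtV = W.T @ V  # r×n
    H = np.zeros((r, V.shape[1]))
    for _ in range(max_iter):
        delta = 0.0
        for j in range(r):
            resid = WtV[j] - G[j] @ H + G[j, j] * H[j]
            new = np.maximum(0.0, (resid - lam) / G[j, j])
            delta = max(delta, float(np.abs(new - H[j]).max(initial=0.0)))
            H[j] = new
        if delta < tol:
            break
    return H


def snmf_objective(V: np.ndarray, W: np.ndarray, H: np.ndarray, lam: float) -> float:
    """Evaluate the sparse-NMF objective ½‖V−WH‖²_F + λΣ‖H(j,:)‖₁."""
    resid = V - W @ H
    return 0.5 * float(np.sum(resid * resid)) + lam * float(np.abs(H).sum())


def _init_w(V_masked: np.ndarray, r: int) -> np.ndarray:
    """Deterministic stain-aware initialization.

    Columns are the masked OD pixels closest to the 99th and 1st
    percentile of the (OD-red − OD-blue) statistic: hematoxylin-dominated
    pixels carry a large red OD, eosin-dominated pixels a small one.
    """
    stat = V_masked[0] - V_masked[2]
    cols = []
    for q in np.linspace(99, 1, r):
        target = np.percentile(stat, q)
        cols.append(V_masked[:, np.argmin(np.abs(stat - target))])
    W = np.stack(cols, axis=1)
    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    return W / norms


def estimate_stains(
    V: np.ndarray,
    r: int = 2,
    lam: float = 0.2,
    max_iter: int = 50,
    tol: float = 1e-4,
    seed: int = 0,
    od_threshold: float = 0.15,
    max_fit_pixels: int = 20000,
) -> tuple[StainModel, DensityMaps]:
    """Alternating sparse-NMF estimation of (W, H) from an OD matrix.

    Pixels whose OD is below ``od_threshold`` in every channel (blank
    glass) are excluded from the fit; every pixel is still sparse-coded
    against the final W for reconstruction. When more than
    ``max_fit_pixels`` informative pixels are available a random subset
    (seeded) is used for the alternating loop.

    The objective is non-increasing across accepted iterations: if an
    update raises it, the previous best factors are kept and iteration
    stops.
    """
    V = np.asarray(V, dtype=np.float64)
    mask = (V >= od_threshold).any(axis=0)
    n_informative = int(mask.sum())
    if n_informative < r:
        raise DegenerateInputError(
            f"only {n_informative} informative pixels for {r} stains"
        )
    Vm = V[:, mask]
    if Vm.shape[1] > max_fit_pixels:
        rng = np.random.default_rng(seed)
        idx = rng.choice(Vm.shape[1], max_fit_pixels, replace=False)
        Vm = Vm[:, np.sort(idx)]

    W = _init_w(Vm, r)
    H = sparse_code(Vm, W, lam)
    best_obj = snmf_objective(Vm, W, H, lam)
    best_W = W.copy()
    eps = 1e-12
    for _ in range(max_iter):
        W_prev = W.copy()
        # multiplicative update for W, then project back to unit columns
        numer = Vm @ H.T
        denom = W @ (H @ H.T) + eps
        W = W * numer / denom
        norms = np.linalg.norm(W, axis=0)
        norms[norms == 0] = 1.0
        W = W / norms
        H = sparse_code(Vm, W, lam)
        obj = snmf_objective(Vm, W, H, lam)
        if obj > best_obj + 1e-10:
            W = best_W
            break
        best_obj, best_W = obj, W.copy()
        if np.linalg.norm(W - W_prev) / max(np.linalg.norm(W_prev), eps) < tol:
            break

    model = StainModel(best_W, tuple(f"stain_{j}" for j in range(r)))
    H_full = sparse_code(V, best_W, lam)
    maps = DensityMaps(H_full, lam)
    if r == 2:
        model, maps = order_stains(model, maps)
    return model, maps


def order_stains(
    model: StainModel, maps: DensityMaps | None = None
):
    """Fix column order to (hematoxylin, eosin) for a 2-stain model.

    Hematoxylin absorbs red light strongly while eosin barely does, so
    the column with the larger red-channel OD component is hematoxylin.
    Density rows are swapped consistently when maps are given.
    """
    if model.n_stains != 2:
        raise ValueError("stain ordering is defined only for r=2 models")
    order = (0, 1) if model.W[0, 0] >= model.W[0, 1] else (1, 0)
    out = StainModel(model.W[:, order], ("hematoxylin", "eosin"))
    if maps is None:
        return out
    return out, DensityMaps(maps.H[list(order), :], maps.lam)


def separate(
    img: np.ndarray,
    model: StainModel,
    maps: DensityMaps,
    i0: float = 255.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct the hematoxylin foreground and eosin background images.

    Each stain's OD contribution W(:,j)·H(j,:) is inverted back to RGB on
    its own, so the foreground shows only nuclei and the background only
    the eosin-stained stroma.
    """
    img = np.asarray(img)
    h, w = img.shape[:2]
    if maps.H.shape[1] != h * w:
        raise DimensionError(
            f"density maps cover {maps.H.shape[1]} pixels, image has {h * w}"
        )
    fore = od_to_rgb(np.outer(model.W[:, 0], maps.H[0]), i0, shape=(h, w))
    back = od_to_rgb(np.outer(model.W[:, 1], maps.H[1]), i0, shape=(h, w))
    return fore, back


class StainSeparator(BaseEstimator):
    """Estimator interface around sparse-NMF stain separation.

    Parameters
    ----------
    n_stains : number of stains r (2 for H&E).
    alpha : L1 sparsity weight λ on the density maps.
    i0 : illumination reference intensity.
    od_threshold : per-channel OD below which a pixel counts as blank
        glass and is excluded from the alternating fit.
    max_iter, tol : alternating-loop budget and relative-change stop.
    max_fit_pixels : subsample cap on informative pixels used in the fit.
    random_state : seed for the pixel subsample.

    Attributes
    ----------
    stain_matrix_ : fitted 3×r W with unit-norm columns,
        ordered (hematoxylin, eosin) when r=2.
    densities_ : DensityMaps for the image passed to :meth:`fit`.
    image_shape_ : (H, W) of the fitted image.
    """

    def __init__(
        self,
        n_stains: int = 2,
        alpha: float = 0.2,
        i0: float = 255.0,
        od_threshold: float = 0.15,
        max_iter: int = 50,
        tol: float = 1e-4,
        max_fit_pixels: int = 20000,
        random_state: int = 0,
    ):
        self.n_stains = n_stains
        self.alpha = alpha
        self.i0 = i0
        self.od_threshold = od_threshold
        self.max_iter = max_iter
        self.tol = tol
        self.max_fit_pixels = max_fit_pixels
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "StainSeparator":
        """Estimate the stain model from one RGB image (H×W×3 uint8)."""
        X = np.asarray(X)
        self.image_shape_ = X.shape[:2]
        V = rgb_to_od(X, self.i0)
        model, maps = estimate_stains(
            V,
            r=self.n_stains,
            lam=self.alpha,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
            od_threshold=self.od_threshold,
            max_fit_pixels=self.max_fit_pixels,
        )
        self.model_ = model
        self.stain_matrix_ = model.W
        self.densities_ = maps
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Sparse-code an RGB image against the fitted stain basis.

        Returns the density maps as an H×W×r array.
        """
        X = np.asarray(X)
        V = rgb_to_od(X, self.i0)
        H = sparse_code(V, self.stain_matrix_, self.alpha)
        return H.T.reshape(X.shape[0], X.shape[1], -1)

    def fit_separate(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fit on an image and return its (foreground, background) pair."""
        self.fit(X)
        return separate(X, self.model_, self.densities_, self.i0)
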