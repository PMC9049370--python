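"""RBF-SVM patch classification with image-level majority voting.

Patches inherit their parent image's label for training. At test time
each of the 20 patches of an image is classified independently and the
image is called non-carcinoma iff strictly more than 10 patches vote
non-carcinoma (ties at exactly 10 fall to carcinoma). The default SVM
uses K(x, z) = exp(−g‖x−z‖²) with penalty c = 2 and g = 1 (libsvm gamma
convention), after per-dimension min-max scaling of the fused features to
[0, 1] learned on the training set (test values clipped; constant
training dimensions map to 0).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .exceptions import DimensionError

__all__ = [
    "CARCINOMA",
    "NON_CARCINOMA",
    "majority_vote",
    "image_score",
    "PatchVoteClassifier",
]

CARCINOMA = "carcinoma"
NON_CARCINOMA = "non-carcinoma"


def majority_vote(
    patch_labels,
    patches_per_image: int = 20,
    threshold: int = 10,
    negative_class: str = NON_CARCINOMA,
    positive_class: str = CARCINOMA,
) -> str:
    """Image label from its patch labels: non-carcinoma iff the
    non-carcinoma count strictly exceeds ``threshold``."""
    labels = list(patch_labels)
    if len(labels) != patches_per_image:
        raise DimensionError(
            f"expected {patches_per_image} patch labels, got {len(labels)}"
        )
    n_negative = sum(1 for lab in labels if lab == negative_class)
    return negative_class if n_negative > threshold else positive_class


def image_score(patch_scores, patches_per_image: int = 20) -> float:
    """Image-level decision score: mean of the patch decision values."""
    scores = np.asarray(list(patch_scores), dtype=np.float64)
    if scores.shape != (patches_per_image,):
        raise DimensionError(
            f"expected {patches_per_image} patch scores, got {scores.shape}"
        )
    return float(scores.mean())


class PatchVoteClassifier(ClassifierMixin, BaseEstimator):
    """Min-max scaling + RBF SVM on patches, majority vote on images.

    Parameters
    ----------
    C, gamma : SVM penalty and kernel width (defaults 2 and 1).
    patches_per_image : patches cropped per image (20).
    vote_threshold : strict non-carcinoma vote threshold (10 of 20).

    Attributes
    ----------
    classes_ : sorted class labels seen in fit.
    scaler_, svm_ : fitted preprocessing and SVM stages.
    """

    def __init__(
        self,
        C: float = 2.0,
        gamma: float = 1.0,
        patches_per_image: int = 20,
        vote_threshold: int = 10,
    ):
        self.C = C
        self.gamma = gamma
        self.patches_per_image = patches_per_image
        self.vote_threshold = vote_threshold

    def fit(self, X, y) -> "PatchVoteClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        # clip=True reproduces the declared scaling rule: train min→0,
        # max→1, constant dimensions→0, test values clipped into [0,1]
        self.scaler_ = MinMaxScaler(clip=True).fit(X)
        self.svm_ = SVC(C=self.C, gamma=self.gamma, kernel="rbf")
        self.svm_.fit(self.scaler_.transform(X), y)
        self.classes_ = self.svm_.classes_
        return self

    def predict(self, X) -> np.ndarray:
        """Per-patch class labels."""
        X = np.asarray(X, dtype=np.float64)
        return self.svm_.predict(self.scaler_.transform(X))

    def decision_function(self, X) -> np.ndarray:
        """Signed per-patch scores, positive = carcinoma evidence."""
        X = np.asarray(X, dtype=np.float64)
        raw = self.svm_.decision_function(self.scaler_.transform(X))
        # sklearn's positive side is classes_[1]; flip so that carcinoma
        # is positive regardless of label sort order
        if self.classes_[1] != CARCINOMA and CARCINOMA in self.classes_:
            raw = -raw
        return raw

    def predict_images(self, X, image_ids):
        """Vote patch predictions up to image labels and scores.

        ``image_ids`` assigns each row of X to its parent image; each
        image must own exactly ``patches_per_image`` rows. Returns
        ``(unique_ids, image_labels, image_scores)`` with ids in order of
        first appearance.
        """
        image_ids = np.asarray(image_ids)
        patch_labels = self.predict(X)
        patch_scores = self.decision_function(X)
        ids, order = np.unique(image_ids, return_index=True)
        ids = ids[np.argsort(order)]
        labels, scores = [], []
        for iid in ids:
            sel = image_ids == iid
            labels.append(
                majority_vote(
                    patch_labels[sel],
                    patches_per_image=self.patches_per_image,
                    threshold=self.vote_threshold,
                )
            )
            scores.append(
                image_score(patch_scores[sel], self.patches_per_image)
            )
        return ids, np.asarray(labels), np.asarray(scores)
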