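"""Cell-state classification from nine morphology and intensity features.

A cell region is summarised by nine features — area, perimeter,
circularity, histogram mean and standard deviation, maximum gradient
magnitude, mean local standard deviation, and the (area-normalised) total
variation of the local-standard-deviation map and of the grey values —
and classified as apoptotic, flat (normal) or mitotic with a
1-nearest-neighbour rule under Euclidean distance.  Features are z-scored
on the training set by default; without scaling, the area feature would
dominate the distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .core import circularity, gradient_magnitude, local_std_map, mask_perimeter

__all__ = [
    "FEATURE_NAMES",
    "extract_features",
    "LabeledDataset",
    "ClassifierModel",
    "train_1nn",
    "predict",
    "loo_accuracy",
]

FEATURE_NAMES = (
    "area",
    "perimeter",
    "circularity",
    "hist_mean",
    "hist_std",
    "grad_max",
    "localstd_mean",
    "localstd_tv",
    "grey_tv",
)


def extract_features(image, mask) -> np.ndarray:
    """Nine-feature vector of a masked cell region (order: FEATURE_NAMES).

    The two total-variation features sum the gradient magnitude of the
    local-standard-deviation map and of the raw image over the mask and
    divide by the area, so they compare across cell sizes.
    """
    img = np.asarray(image, dtype=float)
    m = np.asarray(mask).astype(bool)
    if img.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    area = float(m.sum())
    if area == 0:
        raise ValueError("mask is empty")
    perim = mask_perimeter(m)
    circ = circularity(m)
    vals = img[m]
    grad = gradient_magnitude(img, eps=0.0)
    lstd = local_std_map(img)
    lstd_grad = gradient_magnitude(lstd, eps=0.0)
    vec = np.array([
        area,
        perim,
        circ,
        float(vals.mean()),
        float(vals.std()),
        float(grad[m].max()),
        float(lstd[m].mean()),
        float(lstd_grad[m].sum()) / area,
        float(grad[m].sum()) / area,
    ])
    if not np.all(np.isfinite(vec)):
        raise ValueError("non-finite feature value")
    return vec


@dataclass
class LabeledDataset:
    """Feature vectors with class labels (apoptotic / flat / mitotic)."""

    vectors: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        if len(self.vectors) != len(self.labels):
            raise ValueError("vectors and labels lengths differ")


@dataclass
class ClassifierModel:
    """A fitted 1-NN model: standardisation statistics plus exemplars.

    ``predict`` returns the label of the nearest standardised training
    exemplar; ties break to the lowest exemplar index.
    """

    exemplars: np.ndarray
    labels: list[str]
    mean: np.ndarray
    std: np.ndarray
    standardize: bool = True

    def to_json(self) -> str:
        return json.dumps({
            "exemplars": self.exemplars.tolist(),
            "labels": list(self.labels),
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
            "standardize": self.standardize,
        })

    @classmethod
    def from_json(cls, text: str) -> "ClassifierModel":
        d = json.loads(text)
        return cls(
            exemplars=np.asarray(d["exemplars"], dtype=float),
            labels=list(d["labels"]),
            mean=np.asarray(d["mean"], dtype=float),
            std=np.asarray(d["std"], dtype=float),
            standardize=bool(d["standardize"]),
        )


def train_1nn(dataset: LabeledDataset, standardize: bool = True) -> ClassifierModel:
    """Fit the 1-NN model: store z-scoring statistics and standardised exemplars."""
    if len(set(dataset.labels)) < 2:
        raise ValueError("training needs at least two classes")
    x = dataset.vectors
    if standardize:
        mean = x.mean(axis=0)
        std = x.std(axis=0)
        std = np.where(std > 0, std, 1.0)
    else:
        mean = np.zeros(x.shape[1])
        std = np.ones(x.shape[1])
    return ClassifierModel(
        exemplars=(x - mean) / std,
        labels=list(dataset.labels),
        mean=mean,
        std=std,
        standardize=standardize,
    )


def predict(model: ClassifierModel, vector) -> str:
    """Label of the nearest standardised exemplar (Euclidean distance)."""
    v = np.asarray(vector, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite feature value")
    z = (v - model.mean) / model.std
    d2 = ((model.exemplars - z) ** 2).sum(axis=1)
    return model.labels[int(np.argmin(d2))]  # argmin takes the lowest index on ties


def loo_accuracy(dataset: LabeledDataset, standardize: bool = True) -> float:
    """Leave-one-out 1-NN accuracy, refitting the standardisation per fold."""
    n = len(dataset.labels)
    if n < 2:
        raise ValueError("need at least two examples")
    correct = 0
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        train = LabeledDataset(dataset.vectors[keep],
                               [l for j, l in enumerate(dataset.labels) if j != i])
        if len(set(train.labels)) < 2:
            continue
        model = train_1nn(train, standardize=standardize)
        if predict(model, dataset.vectors[i]) == dataset.labels[i]:
            correct += 1
    return correct / n
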