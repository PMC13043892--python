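"""Classifier scoring (accuracy, ROC, power at fixed FPR) and Grad-CAM maps.

Power at a false-positive rate alpha uses a conservative empirical-quantile
convention: the detection threshold is the ceil((1-alpha)*m)-th order
statistic of the m neutral scores and detections are strictly above it, so
the realized FPR never exceeds alpha.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np
from scipy import ndimage
from sklearn import metrics as _skm

from .nn import Classifier

__all__ = [
    "accuracy",
    "power_at_fpr",
    "roc_curve",
    "roc_auc",
    "SaliencyMap",
    "gradcam",
    "mean_gradcam",
    "EvalReport",
]


def accuracy(scores, labels, threshold: float = 0.5) -> float:
    """Fraction of score>threshold calls matching the 0/1 labels.

    A score exactly at the threshold is classified neutral (0).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores/labels length mismatch")
    return float(((scores > threshold).astype(int) == labels).mean())


def power_at_fpr(neutral_scores, sweep_scores, alpha: float = 0.05) -> float:
    """Fraction of sweep scores detected at an empirical FPR of at most alpha.

    Threshold t is the ceil((1-alpha)*m)-th order statistic of the m neutral
    scores; a sweep is detected iff its score is strictly greater than t.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    neutral = np.sort(np.asarray(neutral_scores, dtype=np.float64))
    sweep = np.asarray(sweep_scores, dtype=np.float64)
    if neutral.size == 0 or sweep.size == 0:
        raise ValueError("both score sets must be non-empty")
    k = math.ceil((1.0 - alpha) * neutral.size)
    t = neutral[k - 1]
    return float((sweep > t).mean())


def roc_curve(scores, labels) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, thresholds) over all unique score cutoffs, including the
    (0,0) and (1,1) endpoints."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("roc_curve needs both classes present")
    fpr, tpr, thr = _skm.roc_curve(labels, np.asarray(scores, dtype=np.float64),
                                   drop_intermediate=False)
    return fpr, tpr, thr


def roc_auc(scores, labels) -> float:
    fpr, tpr, _ = roc_curve(scores, labels)
    return float(_skm.auc(fpr, tpr))


# ----------------------------------------------------------------------
# Grad-CAM


@dataclass
class SaliencyMap:
    """Non-negative, max-normalized class-evidence map at image resolution."""

    values: np.ndarray
    class_index: int
    n_images: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < 0).any():
            raise ValueError("saliency values must be non-negative")
        if self.values.size and self.values.max() > 1 + 1e-12:
            raise ValueError("saliency values must be max-normalized")


def _upsample_bilinear(cam: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    if cam.shape == tuple(shape):
        return cam
    zoom = (shape[0] / cam.shape[0], shape[1] / cam.shape[1])
    return ndimage.zoom(cam, zoom, order=1, grid_mode=True, mode="nearest")


def _normalize(cam: np.ndarray) -> np.ndarray:
    m = cam.max() if cam.size else 0.0
    return cam / m if m > 0 else cam


def _batch_cam(model: Classifier, x: np.ndarray, class_index: int) -> np.ndarray:
    """Raw (un-normalized) Grad-CAM maps for a batch, at image resolution."""
    A, dA = model.gradcam_components(x, class_index)
    w = dA.mean(axis=(2, 3))  # channel weights: spatial mean of gradients
    cam = np.maximum((w[:, :, None, None] * A).sum(axis=1), 0.0)
    out = np.empty((len(x), *model.spec.input_shape))
    for i in range(len(x)):
        out[i] = _upsample_bilinear(cam[i], model.spec.input_shape)
    return out


def gradcam(model: Classifier, image: np.ndarray, class_index: int) -> SaliencyMap:
    """Grad-CAM at the final convolution block.

    Channel weights are the spatial averages of d(class logit)/d(activation);
    the map is the rectified weighted activation sum, bilinearly upsampled to
    the image shape and max-normalized (an all-zero map stays all-zero).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("gradcam expects a single (n_sample, W) image")
    cam = _batch_cam(model, image[None], class_index)[0]
    return SaliencyMap(values=_normalize(cam), class_index=class_index, n_images=1)


def mean_gradcam(
    model: Classifier, images, class_index: int, batch_size: int = 128
) -> SaliencyMap:
    """Elementwise mean of per-image (normalized) maps, then max-normalized."""
    x = np.asarray(images.pixels if hasattr(images, "pixels") else images, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if len(x) == 0:
        raise ValueError("mean_gradcam needs at least one image")
    acc = np.zeros(tuple(model.spec.input_shape))
    for lo in range(0, len(x), batch_size):
        cams = _batch_cam(model, x[lo : lo + batch_size], class_index)
        for cam in cams:
            acc += _normalize(cam)
    return SaliencyMap(values=_normalize(acc / len(x)), class_index=class_index,
                       n_images=len(x))


# ----------------------------------------------------------------------
# Reports


@dataclass
class EvalReport:
    """Accuracy / ROC / power per (model, domain), plus replicate counts."""

    entries: Dict[str, dict] = field(default_factory=dict)

    @staticmethod
    def evaluate(scores_neutral, scores_sweep, alpha: float = 0.05,
                 threshold: float = 0.5) -> dict:
        scores_neutral = np.asarray(scores_neutral, dtype=np.float64)
        scores_sweep = np.asarray(scores_sweep, dtype=np.float64)
        scores = np.concatenate([scores_neutral, scores_sweep])
        labels = np.concatenate(
            [np.zeros(len(scores_neutral), dtype=int), np.ones(len(scores_sweep), dtype=int)]
        )
        fpr, tpr, _ = roc_curve(scores, labels)
        return {
            "accuracy": accuracy(scores, labels, threshold=threshold),
            "power_at_5fpr": power_at_fpr(scores_neutral, scores_sweep, alpha=alpha),
            "auc": float(_skm.auc(fpr, tpr)),
            "roc": [[float(a), float(b)] for a, b in zip(fpr, tpr)],
            "n_neutral": int(len(scores_neutral)),
            "n_sweep": int(len(scores_sweep)),
        }

    def add(self, model_name: str, domain: str, scores_neutral, scores_sweep,
            alpha: float = 0.05, threshold: float = 0.5) -> dict:
        entry = self.evaluate(scores_neutral, scores_sweep, alpha=alpha, threshold=threshold)
        self.entries[f"{model_name}/{domain}"] = entry
        return entry

    def to_json(self, path: Optional[Union[str, Path]] = None) -> str:
        text = json.dumps(self.entries, sort_keys=True, indent=1) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: Union[str, Path]) -> None:
        import pandas as pd

        rows = []
        for key, e in sorted(self.entries.items()):
            model_name, domain = key.split("/", 1)
            rows.append(
                {
                    "model": model_name,
                    "domain": domain,
                    "accuracy": e["accuracy"],
                    "power_at_5fpr": e["power_at_5fpr"],
                    "auc": e["auc"],
                    "n_neutral": e["n_neutral"],
                    "n_sweep": e["n_sweep"],
                }
            )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "EvalReport":
        return cls(entries=json.loads(Path(path).read_text()))
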