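"""Tumour vs stroma pixel classification with a random-forest classifier.

A small annotated set of representative tumour and stroma regions trains a
random-forest pixel classifier over multi-scale texture features of the
deconvolved OD channels; the trained model is then applied to every core of
the cohort, partitioning tissue into tumour and stroma compartments whose
areas (mm^2) turn cell counts into densities.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import joblib
import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .celldetect import TissueMask

__all__ = [
    "BACKGROUND",
    "TUMOUR",
    "STROMA",
    "CLASS_NAMES",
    "CompartmentMask",
    "Annotation",
    "PixelClassifierModel",
    "InsufficientAnnotationError",
    "IncompatibleModelError",
    "extract_features",
    "train_pixel_classifier",
    "classify_pixels",
    "post_process",
    "save_model",
    "load_model",
]

BACKGROUND, TUMOUR, STROMA = 0, 1, 2
CLASS_NAMES = {BACKGROUND: "background", TUMOUR: "tumour", STROMA: "stroma"}

DEFAULT_SCALES = (1, 2, 4, 8)


class InsufficientAnnotationError(ValueError):
    """Raised when a class has no annotated polygons."""


class IncompatibleModelError(ValueError):
    """Raised when feature schema does not match the trained model."""


@dataclass(frozen=True)
class CompartmentMask:
    """Per-pixel label map: 0 background, 1 tumour, 2 stroma."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.uint8)
        if not np.isin(np.unique(lab), [BACKGROUND, TUMOUR, STROMA]).all():
            raise ValueError("labels must be in {0, 1, 2}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "labels", lab)

    def _area(self, label: int) -> float:
        return float((self.labels == label).sum()) * self.pixel_size_um**2 / 1e6

    @property
    def tumour_area_mm2(self) -> float:
        return self._area(TUMOUR)

    @property
    def stroma_area_mm2(self) -> float:
        return self._area(STROMA)

    @property
    def tissue_area_mm2(self) -> float:
        return self.tumour_area_mm2 + self.stroma_area_mm2


@dataclass(frozen=True)
class Annotation:
    """A training polygon ((N, 2) array of (x, y) pixel vertices) with its class."""

    polygon: np.ndarray
    label: int

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError("polygon must be (N >= 3, 2) of (x, y) vertices")
        if self.label not in (TUMOUR, STROMA):
            raise ValueError("annotation class must be tumour or stroma")
        object.__setattr__(self, "polygon", poly)


def _feature_schema(n_channels: int, scales: tuple[int, ...]) -> str:
    key = f"gauss+grad+std|channels={n_channels}|scales={tuple(scales)}"
    return hashlib.sha1(key.encode()).hexdigest()[:12]


def extract_features(stain_od: np.ndarray, scales: tuple[int, ...] = DEFAULT_SCALES) -> np.ndarray:
    """Per-pixel feature stack over deconvolved OD channels.

    For each channel and scale: Gaussian-smoothed intensity, gradient
    magnitude of the smoothed channel, and local standard deviation.
    Borders are handled by reflection. Shape: (H, W, channels*scales*3).
    """
    stain_od = np.asarray(stain_od, dtype=float)
    feats = []
    for c in range(stain_od.shape[-1]):
        ch = stain_od[..., c]
        for s in scales:
            smooth = ndi.gaussian_filter(ch, sigma=s, mode="reflect")
            gy, gx = np.gradient(smooth)
            grad = np.hypot(gx, gy)
            sq = ndi.gaussian_filter(ch**2, sigma=s, mode="reflect")
            local_std = np.sqrt(np.maximum(sq - smooth**2, 0.0))
            feats.extend([smooth, grad, local_std])
    return np.stack(feats, axis=-1)


@dataclass(frozen=True)
class PixelClassifierModel:
    forest: RandomForestClassifier
    classes: tuple[int, ...]
    feature_schema: str
    scales: tuple[int, ...]
    training_seed: int
    holdout_accuracy: float


def _sample_annotation_pixels(
    annotations: list[Annotation],
    shape: tuple[int, int],
    cap_per_class: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize polygons and sample up to cap_per_class pixels per class."""
    by_class: dict[int, list[np.ndarray]] = {TUMOUR: [], STROMA: []}
    for ann in annotations:
        rr, cc = draw_polygon(ann.polygon[:, 1], ann.polygon[:, 0], shape=shape)
        by_class[ann.label].append(np.stack([rr, cc], axis=1))
    missing = [CLASS_NAMES[k] for k, v in by_class.items() if not v or not sum(len(a) for a in v)]
    if missing:
        raise InsufficientAnnotationError(f"no annotated pixels for class(es): {missing}")
    rows, cols, labels = [], [], []
    for label, chunks in by_class.items():
        pix = np.concatenate(chunks)
        if len(pix) > cap_per_class:
            pix = pix[rng.choice(len(pix), size=cap_per_class, replace=False)]
        rows.append(pix[:, 0])
        cols.append(pix[:, 1])
        labels.append(np.full(len(pix), label, dtype=np.uint8))
    return np.concatenate(rows), np.concatenate(cols), np.concatenate(labels)


def train_pixel_classifier(
    features: np.ndarray,
    annotations: list[Annotation],
    seed: int,
    n_trees: int = 100,
    max_depth: int = 16,
    cap_per_class: int = 10_000,
    holdout_fraction: float = 0.2,
    scales: tuple[int, ...] = DEFAULT_SCALES,
) -> PixelClassifierModel:
    """Train the tumour/stroma forest on pixels sampled from annotations.

    Deterministic for a fixed seed; reports held-out pixel accuracy so the
    training run is self-auditing.
    """
    rng = np.random.default_rng(seed)
    rows, cols, labels = _sample_annotation_pixels(
        annotations, features.shape[:2], cap_per_class, rng
    )
    x = features[rows, cols]
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, labels, test_size=holdout_fraction, random_state=seed % (2**32), stratify=labels
    )
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        max_features="sqrt",
        random_state=seed % (2**32),
        n_jobs=1,
    )
    forest.fit(x_tr, y_tr)
    acc = float(forest.score(x_te, y_te))
    return PixelClassifierModel(
        forest=forest,
        classes=tuple(int(c) for c in forest.classes_),
        feature_schema=_feature_schema(features.shape[-1] // (len(scales) * 3), tuple(scales)),
        scales=tuple(scales),
        training_seed=seed,
        holdout_accuracy=acc,
    )


def classify_pixels(
    model: PixelClassifierModel,
    features: np.ndarray,
    tissue: TissueMask,
) -> CompartmentMask:
    """Predict tumour/stroma for every tissue pixel; background elsewhere."""
    n_channels = features.shape[-1] // (len(model.scales) * 3)
    if _feature_schema(n_channels, model.scales) != model.feature_schema:
        raise IncompatibleModelError("feature stack does not match the trained model")
    labels = np.zeros(features.shape[:2], dtype=np.uint8)
    idx = np.flatnonzero(tissue.mask)
    if idx.size:
        flat = features.reshape(-1, features.shape[-1])
        pred = model.forest.predict(flat[idx]).astype(np.uint8)
        labels.reshape(-1)[idx] = pred
    return CompartmentMask(labels=labels, pixel_size_um=tissue.pixel_size_um)


def post_process(
    mask: CompartmentMask,
    min_region_area_um2: float = 1000.0,
    mode_filter_radius_px: int = 2,
) -> CompartmentMask:
    """Smooth the label map and absorb small islands into their surroundings.

    A majority (mode) filter removes salt-and-pepper labels, then connected
    tumour/stroma regions smaller than ``min_region_area_um2`` are reassigned
    to the other tissue class.
    """
    labels = mask.labels.copy()
    if mode_filter_radius_px > 0:
        tissue = labels > 0
        votes_tumour = ndi.uniform_filter((labels == TUMOUR).astype(float),
                                          size=2 * mode_filter_radius_px + 1)
        votes_stroma = ndi.uniform_filter((labels == STROMA).astype(float),
                                          size=2 * mode_filter_radius_px + 1)
        smoothed = np.where(votes_tumour >= votes_stroma, TUMOUR, STROMA).astype(np.uint8)
        labels = np.where(tissue, smoothed, BACKGROUND).astype(np.uint8)

    min_px = min_region_area_um2 / mask.pixel_size_um**2
    for cls, other in ((TUMOUR, STROMA), (STROMA, TUMOUR)):
        comp, n = ndi.label(labels == cls)
        if not n:
            continue
        sizes = ndi.sum_labels(np.ones_like(comp, dtype=np.uint8), comp, np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_px) + 1
        if small.size:
            labels[np.isin(comp, small)] = other
    return CompartmentMask(labels=labels, pixel_size_um=mask.pixel_size_um)


def save_model(model: PixelClassifierModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> PixelClassifierModel:
    model = joblib.load(path)
    if not isinstance(model, PixelClassifierModel):
        raise IncompatibleModelError("file does not contain a pixel classifier model")
    return model
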