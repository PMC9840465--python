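"""Segmentation and measurement of monolayer structures.

Nuclei are counted with a smooth/threshold/watershed chain; domes are
segmented purely from the topography height map (dome cells sit on a
higher plane than the surrounding sheet); mitochondria and
autophagosome puncta are segmented per field with either a
deterministic threshold or a trained random-forest pixel classifier,
then measured per object. All areas are calibrated to um^2 via the
pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max, structure_tensor, \
    structure_tensor_eigenvalues
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.segmentation import watershed
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

__all__ = [
    "LabelMap",
    "MonolayerMetrics",
    "ThresholdSpec",
    "PixelClassifierModel",
    "count_nuclei",
    "segment_domes",
    "extract_features",
    "feature_names",
    "train_pixel_classifier",
    "segment_mitochondria",
    "classify_enlarged",
    "count_large_puncta",
]

FEATURE_KINDS = (
    "gaussian", "gradient_magnitude", "laplacian",
    "structure_tensor_max_eig", "local_variance",
)


@dataclass
class LabelMap:
    """Connected-component labels (0 = background) with um/px calibration."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def object_table(self, cls: str = "object") -> pd.DataFrame:
        """One row per label: object_id, class, area_um2, centroid (um)."""
        px2 = self.pixel_size_um**2
        rows = [
            {
                "object_id": p.label,
                "class": cls,
                "area_um2": p.area * px2,
                "centroid_x_um": (p.centroid[1] + 0.5) * self.pixel_size_um,
                "centroid_y_um": (p.centroid[0] + 0.5) * self.pixel_size_um,
            }
            for p in regionprops(self.labels)
        ]
        return pd.DataFrame(
            rows,
            columns=["object_id", "class", "area_um2",
                     "centroid_x_um", "centroid_y_um"],
        )


@dataclass
class MonolayerMetrics:
    """Per-field summary of the imaging readouts."""

    nuclei_count: int = 0
    total_dome_area_um2: float = 0.0
    dome_count: int = 0
    mito_footprint: float = 0.0
    enlarged_mito_count: int = 0
    enlarged_mito_fraction: float = 0.0
    autophagosome_count: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mito_footprint <= 1.0):
            raise ValueError("mito_footprint must be in [0, 1]")

    def to_frame(self, well: str = "well", field_id: str = "field") -> pd.DataFrame:
        rows = [
            (well, field_id, k, v) for k, v in self.__dict__.items()
        ]
        return pd.DataFrame(rows, columns=["well", "field", "metric", "value"])


def count_nuclei(
    nuclear_composite: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 12.0,
    smooth_sigma_um: float = 1.0,
) -> tuple[int, np.ndarray]:
    """Count nuclei in a calibrated nuclear-channel composite.

    Chain: Gaussian smooth -> Otsu threshold -> hole fill ->
    distance-transform watershed (splits touching nuclei) -> minimum
    area filter. Blank images yield a count of zero.

    Returns ``(count, centroids_um)`` with centroids as (x, y) pairs.
    """
    img = np.asarray(nuclear_composite, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D composite")
    if img.max() == img.min():
        return 0, np.zeros((0, 2))
    sigma_px = max(smooth_sigma_um / pixel_size_um, 0.5)
    sm = ndimage.gaussian_filter(img, sigma_px, mode="reflect")
    mask = sm > threshold_otsu(sm)
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        return 0, np.zeros((0, 2))
    dist = ndimage.distance_transform_edt(mask)
    min_area_px = min_area_um2 / pixel_size_um**2
    # peaks separated by at least ~the radius of the smallest valid nucleus
    min_dist = max(3, int(round(np.sqrt(min_area_px / np.pi))))
    peaks = peak_local_max(
        dist, labels=mask, min_distance=min_dist, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-dist, markers, mask=mask)
    centroids = []
    for p in regionprops(labels):
        if p.area >= min_area_px:
            cy, cx = p.centroid
            centroids.append(((cx + 0.5) * pixel_size_um, (cy + 0.5) * pixel_size_um))
    return len(centroids), np.array(centroids).reshape(-1, 2)


def segment_domes(
    height_map_um: np.ndarray,
    min_height_um: float,
    min_area_um2: float = 500.0,
    pixel_size_um: float = 1.0,
) -> tuple[LabelMap, float]:
    """Segment domes as connected regions raised above the base plane.

    The base plane is the mode of the height values (robust while domes
    cover less than half the field); dome pixels satisfy
    ``height - base >= min_height_um``; components smaller than
    ``min_area_um2`` are discarded. Returns the label map and the total
    dome area in um^2.
    """
    h = np.asarray(height_map_um, dtype=float)
    vals, counts = np.unique(np.round(h, 6), return_counts=True)
    if vals.size > 0.5 * h.size:
        raise ValueError(
            "height map has no modal plateau (>50% unique values); "
            "smooth the height map before dome segmentation"
        )
    base = float(vals[np.argmax(counts)])
    mask = (h - base) >= min_height_um
    labels = cc_label(mask, connectivity=2)
    min_area_px = min_area_um2 / pixel_size_um**2
    keep = np.zeros(labels.max() + 1, dtype=bool)
    for p in regionprops(labels):
        keep[p.label] = p.area >= min_area_px
    cleaned = np.where(keep[labels], labels, 0)
    # relabel consecutively
    cleaned = cc_label(cleaned > 0, connectivity=2)
    total_area = float((cleaned > 0).sum()) * pixel_size_um**2
    return LabelMap(labels=cleaned, pixel_size_um=pixel_size_um), total_area


def feature_names(scales) -> list[str]:
    return [f"{kind}_s{s:g}" for s in scales for kind in FEATURE_KINDS]


def extract_features(image: np.ndarray, scales=(1.0, 2.0, 4.0)) -> np.ndarray:
    """Per-pixel texture features at each scale; shape (H, W, 5*len(scales)).

    Per scale: Gaussian-smoothed intensity, gradient magnitude,
    Laplacian of Gaussian, largest structure-tensor eigenvalue, and
    local variance. Deterministic and translation-equivariant in the
    interior.
    """
    scales = tuple(scales)
    if not scales:
        raise ValueError("scales must be non-empty")
    img = np.asarray(image, dtype=np.float64)
    feats = []
    for s in scales:
        sm = ndimage.gaussian_filter(img, s, mode="reflect")
        grad = ndimage.gaussian_gradient_magnitude(img, s, mode="reflect")
        lap = ndimage.gaussian_laplace(img, s, mode="reflect")
        A = structure_tensor(img, sigma=s, mode="reflect")
        eig = structure_tensor_eigenvalues(A)[0]  # largest eigenvalue
        win = int(2 * round(s) + 1) | 1
        mean = ndimage.uniform_filter(img, win, mode="reflect")
        sq = ndimage.uniform_filter(img * img, win, mode="reflect")
        var = np.clip(sq - mean * mean, 0.0, None)
        feats.extend([sm, grad, lap, eig, var])
    return np.stack(feats, axis=-1)


@dataclass
class PixelClassifierModel:
    """Random-forest pixel classifier over multiscale texture features."""

    scales: tuple
    classes: tuple
    seed: int
    estimator: RandomForestClassifier
    holdout_accuracy: float
    feature_names: list[str] = field(default_factory=list)

    def predict(self, image: np.ndarray) -> np.ndarray:
        """Per-pixel class labels (values from ``classes``)."""
        feats = extract_features(image, self.scales)
        flat = feats.reshape(-1, feats.shape[-1])
        pred = self.estimator.predict(flat)
        return pred.reshape(image.shape)

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        feats = extract_features(image, self.scales)
        flat = feats.reshape(-1, feats.shape[-1])
        proba = self.estimator.predict_proba(flat)
        return proba.reshape(image.shape + (len(self.classes),))


def train_pixel_classifier(
    images: list[np.ndarray],
    label_masks: list[np.ndarray],
    seed: int = 0,
    scales=(1.0, 2.0, 4.0),
    n_estimators: int = 100,
    min_labels_per_class: int = 50,
) -> PixelClassifierModel:
    """Train a random forest on sparsely labeled pixels.

    ``label_masks`` hold 0 for unlabeled pixels and positive integers
    for class labels. Requires at least two classes with at least
    ``min_labels_per_class`` labeled pixels each; reports held-out pixel
    accuracy on a 20% stratified split. Fixed seed gives an identical
    model.
    """
    X_parts, y_parts = [], []
    for img, lab in zip(images, label_masks):
        lab = np.asarray(lab)
        feats = extract_features(img, scales)
        m = lab > 0
        X_parts.append(feats[m])
        y_parts.append(lab[m])
    X = np.concatenate(X_parts, axis=0)
    y = np.concatenate(y_parts, axis=0)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError(
            f"need >= 2 labeled classes, got {classes.tolist()}"
        )
    for c, n in zip(classes, counts):
        if n < min_labels_per_class:
            raise ValueError(
                f"class {c} has only {n} labeled pixels "
                f"(need >= {min_labels_per_class})"
            )
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.2, stratify=y, random_state=seed
    )
    rf = RandomForestClassifier(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    rf.fit(X_tr, y_tr)
    acc = float(rf.score(X_te, y_te))
    return PixelClassifierModel(
        scales=tuple(scales),
        classes=tuple(classes.tolist()),
        seed=seed,
        estimator=rf,
        holdout_accuracy=acc,
        feature_names=feature_names(scales),
    )


@dataclass(frozen=True)
class ThresholdSpec:
    """Deterministic foreground threshold: Otsu or a fixed intensity."""

    method: str = "otsu"
    value: float | None = None

    def mask(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image, dtype=float)
        if self.method == "fixed":
            if self.value is None:
                raise ValueError("fixed threshold requires a value")
            return img > self.value
        if self.method == "otsu":
            if img.max() == img.min():
                return np.zeros(img.shape, dtype=bool)
            return img > threshold_otsu(img)
        raise ValueError(f"unknown threshold method {self.method!r}")


def segment_mitochondria(
    mito_channel: np.ndarray,
    pixel_size_um: float,
    model: PixelClassifierModel | None = None,
    threshold: ThresholdSpec | None = None,
    foreground_class: int = 2,
) -> tuple[LabelMap, pd.DataFrame, float]:
    """Segment mitochondria and measure the footprint.

    Either a trained pixel classifier (foreground = pixels predicted as
    ``foreground_class``) or a deterministic threshold produces the
    foreground mask; connected components give per-object areas. The
    mitochondrial footprint is the fraction of field pixels occupied by
    foreground, so the object areas sum exactly to footprint x field
    area.
    """
    if (model is None) == (threshold is None):
        raise ValueError("provide exactly one of model or threshold")
    if model is not None:
        mask = model.predict(mito_channel) == foreground_class
    else:
        mask = threshold.mask(mito_channel)
    labels = cc_label(mask, connectivity=2)
    lm = LabelMap(labels=labels, pixel_size_um=pixel_size_um)
    table = lm.object_table(cls="mito")
    footprint = float(mask.sum()) / mask.size
    return lm, table, footprint


def classify_enlarged(
    objects: pd.DataFrame, area_threshold_um2: float
) -> tuple[int, float, pd.DataFrame]:
    """Mark objects strictly larger than the area threshold as enlarged.

    Returns ``(enlarged_count, enlarged_fraction, annotated_table)``;
    the fraction is zero for an empty table.
    """
    if area_threshold_um2 < 0:
        raise ValueError("area threshold must be non-negative")
    out = objects.copy()
    out["class"] = np.where(
        out["area_um2"] > area_threshold_um2, "enlarged", "regular"
    )
    n_enl = int((out["class"] == "enlarged").sum())
    frac = n_enl / len(out) if len(out) else 0.0
    return n_enl, frac, out


def enlarged_threshold_from_controls(
    control_areas_um2: np.ndarray, percentile: float = 97.5
) -> float:
    """Default enlargement cutoff: a high percentile of control-field areas."""
    areas = np.asarray(control_areas_um2, dtype=float)
    if areas.size == 0:
        raise ValueError("no control areas provided")
    return float(np.percentile(areas, percentile))


def count_large_puncta(
    channel: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float,
    intensity_quantile: float = 0.99,
) -> int:
    """Count bright puncta with area >= ``min_area_um2``.

    The foreground threshold is the given intensity quantile of the
    image; blank images yield zero. Doubling ``min_area_um2`` can never
    increase the count.
    """
    if not (0.0 < intensity_quantile < 1.0):
        raise ValueError("intensity_quantile must be in (0, 1)")
    img = np.asarray(channel, dtype=float)
    thresh = float(np.quantile(img, intensity_quantile))
    mask = img > thresh
    labels = cc_label(mask, connectivity=2)
    min_area_px = min_area_um2 / pixel_size_um**2
    return sum(1 for p in regionprops(labels) if p.area >= min_area_px)
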