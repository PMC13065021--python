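"""Worm segmentation from the fluorescence channel plus frame QC.

The segmentation chain mirrors classic intensity-based worm pipelines:
Sobel gradient magnitude, automatic thresholding of the gradient, closing
of contour gaps by connecting nearest endpoints, filling, and small-object
removal.  All thresholds are relative to the image's own intensity scale,
so uniformly dimming a frame leaves the mask unchanged.

Frames where segmentation or straightening failed are flagged by an
ensemble of 20 bagged decision trees operating on shape features of the
straightened animal, and excluded (left as gaps) downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line
from skimage.filters import sobel, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import thin
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from wormgrowth import morphometry

__all__ = [
    "EdgeMap",
    "WormMask",
    "ShapeFeatures",
    "QcClassifier",
    "detect_edges",
    "close_contours",
    "mask_from_contours",
    "segment_frame",
    "extract_shape_features",
    "features_from_mask",
    "train_qc_classifier",
    "classify_frame",
    "FEATURE_NAMES",
    "SENTINEL_FEATURES",
]


@dataclass
class EdgeMap:
    edges: np.ndarray  # bool
    gradient: np.ndarray  # Sobel magnitude
    threshold: float


@dataclass
class WormMask:
    mask: np.ndarray  # bool, at most one component
    frame_index: int = -1
    qc_label: str = "unscored"  # pass / fail / unscored
    qc_score: float = float("nan")
    failed: bool = False  # segmentation produced no usable object

    @property
    def area(self) -> int:
        return int(self.mask.sum())


FEATURE_NAMES = (
    "length_px",
    "width_mean",
    "width_cv",
    "width_max_min_ratio",
    "solidity",
    "curvature_total",
    "boundary_roughness",
    "area_ratio_straightened",
    "border_contact_fraction",
)

#: routed straight to a "fail" call; never a plausible real measurement
SENTINEL_FEATURES = np.full(len(FEATURE_NAMES), -1.0)


@dataclass
class ShapeFeatures:
    values: np.ndarray  # fixed order, see FEATURE_NAMES
    is_sentinel: bool = False


@dataclass
class QcClassifier:
    """Bagged decision-tree ensemble flagging faulty frames."""

    model: BaggingClassifier
    seed: int
    feature_names: tuple[str, ...] = FEATURE_NAMES
    oob_accuracy: float = float("nan")
    n_trees: int = 20


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def detect_edges(image: np.ndarray, threshold_multiplier: float = 1.0) -> EdgeMap:
    """Sobel edge detection with an automatic (Otsu) gradient threshold.

    The threshold is Otsu's value over the nonzero gradient magnitudes
    multiplied by ``threshold_multiplier``; being a quantile-type statistic
    of the gradient distribution it scales with image intensity, which
    makes segmentation invariant to uniform dimming.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    grad = sobel(image)
    nz = grad[grad > 0]
    if nz.size == 0:
        return EdgeMap(np.zeros(image.shape, bool), grad, float("inf"))
    if np.ptp(nz) == 0:
        # a single gradient level (e.g. an ideal step): keep it all
        thr = 0.5 * float(nz[0]) * threshold_multiplier
    else:
        thr = float(threshold_otsu(nz)) * threshold_multiplier
    return EdgeMap(grad > thr, grad, thr)


def _endpoints(skel: np.ndarray) -> np.ndarray:
    """Pixels of a thinned edge set with exactly one 8-neighbour."""
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    neigh = ndimage.convolve(skel.astype(int), kernel, mode="constant")
    return np.argwhere(skel & (neigh == 1))


def close_contours(edge_map: EdgeMap, max_gap_px: int = 10) -> np.ndarray:
    """Close contour gaps by bridging nearest endpoint pairs.

    The edge set is thinned to its ridge (the gradient maximum, which sits
    on the object boundary for a blurred step edge), endpoints
    (single-neighbour pixels) located, and nearest pairs connected by
    straight pixel lines, closest first, skipping pairs farther apart than
    ``max_gap_px``; repeated until no endpoints remain or none are in
    range.
    """
    out = thin(edge_map.edges)
    for _ in range(50):
        ep = _endpoints(thin(out))
        if len(ep) < 2:
            break
        d = np.linalg.norm(ep[:, None, :] - ep[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        order = np.argsort(d, axis=None)
        used: set[int] = set()
        bridged = False
        for flat in order:
            i, j = np.unravel_index(flat, d.shape)
            if d[i, j] > max_gap_px:
                break
            if i in used or j in used or i >= j:
                continue
            rr, cc = draw_line(*ep[i], *ep[j])
            out[rr, cc] = True
            used.update((int(i), int(j)))
            bridged = True
        if not bridged:
            break
    return out


def mask_from_contours(
    contours: np.ndarray,
    min_area_px: int = 200,
    frame_index: int = -1,
    image: np.ndarray | None = None,
) -> WormMask:
    """Fill closed contours and keep the largest plausible object.

    Enclosed regions are filled, objects below ``min_area_px`` removed,
    the largest connected component kept, and its internal holes filled.
    An empty result marks the frame as segmentation-failed.

    When ``image`` is given, pixels on the 1-px contour ring itself are
    kept only where the intensity exceeds the local half-max level
    (midway between the object's interior median and the background
    median).  The ring straddles the true boundary, so including it
    wholesale dilates the mask by ~0.5 px; the half-max rule makes the
    per-pixel decision unbiased while staying intensity-scale invariant.
    """
    filled = ndimage.binary_fill_holes(contours)
    labels, n = ndimage.label(filled, structure=np.ones((3, 3)))
    if n == 0:
        return WormMask(np.zeros(contours.shape, bool), frame_index, failed=True)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area_px:
        return WormMask(np.zeros(contours.shape, bool), frame_index, failed=True)
    mask = ndimage.binary_fill_holes(labels == best)
    if image is not None:
        image = np.asarray(image, dtype=float)
        ring = mask & contours
        interior = mask & ~ring
        if interior.sum() >= min_area_px // 2:
            far = ~ndimage.binary_dilation(
                mask, ndimage.generate_binary_structure(2, 2), iterations=3
            )
            if far.any():
                half = 0.5 * (np.median(image[interior]) + np.median(image[far]))
                mask = interior | (ring & (image > half))
                labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
                if n > 1:
                    sizes = ndimage.sum_labels(
                        np.ones_like(labels), labels, np.arange(1, n + 1)
                    )
                    mask = labels == (int(np.argmax(sizes)) + 1)
                mask = ndimage.binary_fill_holes(mask)
    return WormMask(mask, frame_index)


def segment_frame(
    image: np.ndarray,
    threshold_multiplier: float = 1.0,
    max_gap_px: int = 10,
    min_area_px: int = 200,
    frame_index: int = -1,
) -> WormMask:
    """Full per-frame chain: edges → gap closing → filled mask."""
    edges = detect_edges(image, threshold_multiplier)
    closed = close_contours(edges, max_gap_px)
    return mask_from_contours(closed, min_area_px, frame_index, image=image)


# ---------------------------------------------------------------------------
# shape features and QC
# ---------------------------------------------------------------------------

def extract_shape_features(
    straightened: morphometry.StraightenedWorm | None,
    mask: np.ndarray,
    midline: morphometry.Midline | None = None,
    taper_frac: float = 0.1,
) -> ShapeFeatures:
    """Fixed-order shape feature vector of a straightened worm.

    A ``None`` straightening result (failed midline) yields the sentinel
    vector, which the classifier routes directly to "fail".
    """
    mask = np.asarray(mask, dtype=bool)
    if straightened is None or straightened.width.size < 4:
        return ShapeFeatures(SENTINEL_FEATURES.copy(), is_sentinel=True)

    w = straightened.width
    n = w.size
    core = w[int(taper_frac * n): max(int((1 - taper_frac) * n), int(taper_frac * n) + 1)]
    core = core[core > 0]
    if core.size == 0:
        return ShapeFeatures(SENTINEL_FEATURES.copy(), is_sentinel=True)

    props = regionprops(mask.astype(np.uint8))[0]
    perimeter = max(props.perimeter, 1.0)
    area = props.area

    if midline is not None and len(midline.points) > 2:
        tang = np.diff(midline.points, axis=0)
        ang = np.unwrap(np.arctan2(tang[:, 0], tang[:, 1]))
        curvature_total = float(np.sum(np.abs(np.diff(ang))))
    else:
        curvature_total = 0.0

    boundary = mask & ~ndimage.binary_erosion(mask)
    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    n_boundary = max(int(boundary.sum()), 1)
    border_contact = float((boundary & border).sum()) / n_boundary

    straightened_area = float(np.sum(w))
    values = np.array(
        [
            float(straightened.length),
            float(core.mean()),
            float(core.std() / core.mean()) if core.mean() > 0 else 0.0,
            float(core.max() / max(core.min(), 1e-9)),
            float(props.solidity),
            curvature_total,
            float(perimeter**2 / (4 * np.pi * area)),
            float(area / max(straightened_area, 1e-9)),
            border_contact,
        ]
    )
    values[~np.isfinite(values)] = 0.0
    return ShapeFeatures(values)


def features_from_mask(mask: np.ndarray, image: np.ndarray | None = None) -> ShapeFeatures:
    """Straighten a mask (largest component) and extract its features.

    Convenience wrapper used both in the pipeline and for building QC
    training tables from generated masks; failures map to the sentinel.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n == 0:
        return ShapeFeatures(SENTINEL_FEATURES.copy(), is_sentinel=True)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        main = labels == (int(np.argmax(sizes)) + 1)
    else:
        main = mask
    img = np.asarray(image, dtype=float) if image is not None else main.astype(float)
    try:
        midline = morphometry.extract_midline(main)
        straightened = morphometry.straighten(img, main, midline)
    except morphometry.StraighteningError:
        return ShapeFeatures(SENTINEL_FEATURES.copy(), is_sentinel=True)
    return extract_shape_features(straightened, mask, midline)


def train_qc_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    n_trees: int = 20,
    seed: int = 0,
) -> QcClassifier:
    """Train the bagged decision-tree frame-QC ensemble.

    Each of the ``n_trees`` trees is fit on a bootstrap resample of the
    training rows; the out-of-bag accuracy is recorded.  Labels: 0 = good,
    1 = faulty.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2 or features.shape[0] != labels.size:
        raise ValueError("features must be (n_samples, n_features) matching labels")
    if np.unique(labels).size < 2:
        raise ValueError("training data must contain both classes")
    model = BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=seed),
        n_estimators=n_trees,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
    )
    model.fit(features, labels)
    return QcClassifier(
        model=model,
        seed=seed,
        oob_accuracy=float(model.oob_score_),
        n_trees=n_trees,
    )


def classify_frame(
    classifier: QcClassifier, features: ShapeFeatures
) -> tuple[str, float]:
    """QC label and score for one frame.

    The score is the fraction of trees voting "faulty"; the frame fails
    when the score exceeds 0.5 (majority rule).  Sentinel feature vectors
    fail unconditionally with score 1.
    """
    if features.is_sentinel:
        return "fail", 1.0
    x = features.values[None, :]
    votes = np.array(
        [
            est.predict(x[:, feats])[0]
            for est, feats in zip(
                classifier.model.estimators_, classifier.model.estimators_features_
            )
        ]
    )
    score = float(np.mean(votes == 1))
    return ("fail" if score > 0.5 else "pass"), score
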