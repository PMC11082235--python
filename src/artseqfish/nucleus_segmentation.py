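"""Iterative 2D nucleus segmentation with learned rejection of failures.

No single global filter separates every nucleus in every image, so each
nuclear-stain slice is segmented repeatedly under a bank of (threshold
method, smoothing, optional watershed split) combinations.  All resulting
labels are pooled, scored by a support-vector model trained to recognise
plausible nucleus shapes, and deduplicated by mask overlap so each nucleus
keeps its best-scoring representative per slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.measure import regionprops
from skimage.segmentation import watershed
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """One (global threshold, smoothing, split) combination of the sweep."""

    method: str = "otsu"       # "otsu" | "triangle"
    sigma: float = 2.0         # Gaussian smoothing before thresholding, px
    watershed_split: bool = False
    min_area_px: int = 60

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "triangle"):
            raise SegmentationError(f"unknown threshold method {self.method!r}")


def default_filter_bank() -> tuple[FilterSpec, ...]:
    return tuple(
        FilterSpec(method=m, sigma=s, watershed_split=w)
        for m in ("otsu", "triangle")
        for s in (1.0, 2.0, 4.0)
        for w in (False, True)
    )


@dataclass
class SegmentationCandidate:
    """A single labelled region from one (filter, parameters) combination."""

    slice_index: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    mask: np.ndarray                 # boolean, cropped to bbox
    centroid: tuple[float, float]    # (y, x) in full-frame px
    area: float
    features: np.ndarray
    provenance: FilterSpec
    provenance_index: int
    score: float | None = None
    accepted: bool | None = None


FEATURE_NAMES = ("log_area", "solidity", "eccentricity", "circularity",
                 "extent", "axis_ratio", "ellipse_iou")


def mask_shape_features(mask: np.ndarray) -> np.ndarray:
    """Shape descriptors of a single connected 2D mask.

    ``ellipse_iou`` — overlap between the mask and the ellipse implied by its
    second moments — is the workhorse: merged, clipped and speckle labels all
    deviate from their moment ellipse even when they stay convex.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise SegmentationError("empty mask has no shape features")
    props = regionprops(mask.astype(np.uint8))[0]
    area = props.area
    perim = max(props.perimeter, 1.0)
    circularity = 4.0 * np.pi * area / perim**2
    major = max(props.axis_major_length, 1e-6)
    minor = max(props.axis_minor_length, 1e-6)
    # moment-fit ellipse: region (p-c)^T C^-1 (p-c) <= 4 shares the mask's
    # centroid and second moments (no angle-convention pitfalls)
    cy, cx = props.centroid
    mu = props.moments_central
    m00 = mu[0, 0]
    cov = np.array([[mu[2, 0], mu[1, 1]], [mu[1, 1], mu[0, 2]]]) / m00
    cov += np.eye(2) * 1e-3  # guard 1-px-thin masks
    inv = np.linalg.inv(cov)
    yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    dy, dx = yy - cy, xx - cx
    q = inv[0, 0] * dy**2 + 2 * inv[0, 1] * dy * dx + inv[1, 1] * dx**2
    ell = q <= 4.0
    inter = float(np.count_nonzero(ell & mask))
    union = float(np.count_nonzero(ell | mask))
    ellipse_iou = inter / union if union else 0.0
    return np.array([
        np.log10(area), props.solidity, props.eccentricity,
        min(circularity, 1.2), props.extent, minor / major, ellipse_iou,
    ])


def _segment_once(image: np.ndarray, spec: FilterSpec) -> np.ndarray:
    smoothed = ndimage.gaussian_filter(image.astype(np.float32), spec.sigma)
    lo, hi = float(smoothed.min()), float(smoothed.max())
    if hi - lo < 1e-9:
        return np.zeros(image.shape, dtype=np.int32)
    thr = threshold_otsu(smoothed) if spec.method == "otsu" else threshold_triangle(smoothed)
    binary = ndimage.binary_fill_holes(smoothed > thr)
    if not binary.any():
        return np.zeros(image.shape, dtype=np.int32)
    if spec.watershed_split:
        dist = ndimage.distance_transform_edt(binary)
        smooth_dist = ndimage.gaussian_filter(dist, 2.0)
        seeds, _ = ndimage.label(smooth_dist > 0.6 * smooth_dist.max())
        if seeds.max() >= 1:
            labels = watershed(-dist, markers=seeds, mask=binary)
        else:
            labels, _ = ndimage.label(binary)
    else:
        labels, _ = ndimage.label(binary)
    return labels.astype(np.int32)


def sweep_segment(dapi_slice: np.ndarray, filter_bank=None,
                  slice_index: int = 0) -> list[SegmentationCandidate]:
    """Union of candidate labels over all filter-bank combinations."""
    if filter_bank is None:
        filter_bank = default_filter_bank()
    filter_bank = tuple(filter_bank)
    if not filter_bank:
        raise SegmentationError("empty filter bank")
    out: list[SegmentationCandidate] = []
    for prov_idx, spec in enumerate(filter_bank):
        labels = _segment_once(dapi_slice, spec)
        if labels.max() == 0:
            continue
        for props in regionprops(labels):
            if props.area < spec.min_area_px:
                continue
            minr, minc, maxr, maxc = props.bbox
            mask = labels[minr:maxr, minc:maxc] == props.label
            try:
                feats = mask_shape_features(mask)
            except SegmentationError:
                continue
            out.append(SegmentationCandidate(
                slice_index=slice_index, bbox=(minr, minc, maxr, maxc),
                mask=mask, centroid=props.centroid, area=float(props.area),
                features=feats, provenance=spec, provenance_index=prov_idx))
    return out


@dataclass
class LabelQualityClassifier:
    model: Pipeline
    threshold: float
    holdout_accuracy: float
    n_good: int
    n_bad: int
    seed: int

    def score(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(features)
        if features.shape[1] != len(FEATURE_NAMES):
            raise SegmentationError(
                f"expected {len(FEATURE_NAMES)} shape features, got {features.shape[1]}")
        return self.model.predict_proba(features)[:, 1]


def train_label_quality_classifier(good_masks, bad_masks, seed: int = 0,
                                   threshold: float = 0.5,
                                   holdout_fraction: float = 0.25) -> LabelQualityClassifier:
    """Train the failed-segmentation filter on good vs corrupted masks."""
    X = np.array([mask_shape_features(m) for m in list(good_masks) + list(bad_masks)])
    y = np.concatenate([np.ones(len(good_masks), dtype=int),
                        np.zeros(len(bad_masks), dtype=int)])
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=holdout_fraction,
                                              stratify=y, random_state=seed)
    model = Pipeline([
        ("scale", StandardScaler()),
        ("svc", CalibratedClassifierCV(
            SVC(kernel="rbf", C=10.0, gamma="scale", random_state=seed),
            method="sigmoid", cv=3, ensemble=False)),
    ])
    model.fit(X_tr, y_tr)
    acc = float((model.predict(X_te) == y_te).mean())
    return LabelQualityClassifier(model=model, threshold=threshold, holdout_accuracy=acc,
                                  n_good=len(good_masks), n_bad=len(bad_masks), seed=seed)


def score_labels(candidates: list[SegmentationCandidate],
                 clf: LabelQualityClassifier) -> list[SegmentationCandidate]:
    """Attach quality scores and accepted flags in place; returns the list."""
    if not candidates:
        return candidates
    scores = clf.score(np.array([c.features for c in candidates]))
    for cand, s in zip(candidates, scores):
        cand.score = float(s)
        cand.accepted = bool(s >= clf.threshold)
    return candidates


def _mask_iou(a: SegmentationCandidate, b: SegmentationCandidate) -> float:
    (ar0, ac0, ar1, ac1), (br0, bc0, br1, bc1) = a.bbox, b.bbox
    r0, c0 = max(ar0, br0), max(ac0, bc0)
    r1, c1 = min(ar1, br1), min(ac1, bc1)
    if r0 >= r1 or c0 >= c1:
        return 0.0
    sub_a = a.mask[r0 - ar0 : r1 - ar0, c0 - ac0 : c1 - ac0]
    sub_b = b.mask[r0 - br0 : r1 - br0, c0 - bc0 : c1 - bc0]
    inter = float(np.count_nonzero(sub_a & sub_b))
    if inter == 0.0:
        return 0.0
    union = a.mask.sum() + b.mask.sum() - inter
    return inter / union


def _contains(a: SegmentationCandidate, b: SegmentationCandidate) -> float:
    """Intersection over the smaller mask's area (1.0 for nested masks)."""
    (ar0, ac0, ar1, ac1), (br0, bc0, br1, bc1) = a.bbox, b.bbox
    r0, c0 = max(ar0, br0), max(ac0, bc0)
    r1, c1 = min(ar1, br1), min(ac1, bc1)
    if r0 >= r1 or c0 >= c1:
        return 0.0
    sub_a = a.mask[r0 - ar0 : r1 - ar0, c0 - ac0 : c1 - ac0]
    sub_b = b.mask[r0 - br0 : r1 - br0, c0 - bc0 : c1 - bc0]
    inter = float(np.count_nonzero(sub_a & sub_b))
    return inter / min(a.mask.sum(), b.mask.sum())


def deduplicate_labels(candidates: list[SegmentationCandidate],
                       iou_threshold: float = 0.5,
                       containment_threshold: float = 0.8) -> list[SegmentationCandidate]:
    """Keep one representative per nucleus: greedy clustering by mask overlap.

    Two candidates are duplicates when their IoU reaches ``iou_threshold`` or
    when one mask is essentially nested in the other (intersection covering
    ``containment_threshold`` of the smaller mask) — heavy smoothing in the
    sweep produces halo masks whose IoU against the tight mask of the same
    nucleus stays low, but which are still the same nucleus.  Candidates are
    visited best-first (higher score, then larger area, then lower provenance
    index); fully deterministic.
    """
    ordered = sorted(
        candidates,
        key=lambda c: (-(c.score if c.score is not None else 0.0), -c.area,
                       c.provenance_index, c.centroid),
    )
    kept: list[SegmentationCandidate] = []
    for cand in ordered:
        if all(_mask_iou(cand, k) < iou_threshold
               and _contains(cand, k) < containment_threshold for k in kept):
            kept.append(cand)
    return kept


def segment_slice(dapi_slice: np.ndarray, clf: LabelQualityClassifier,
                  filter_bank=None, iou_threshold: float = 0.5,
                  slice_index: int = 0) -> list[SegmentationCandidate]:
    """sweep -> score -> accept -> deduplicate, for one slice."""
    cands = sweep_segment(dapi_slice, filter_bank, slice_index=slice_index)
    score_labels(cands, clf)
    accepted = [c for c in cands if c.accepted]
    return deduplicate_labels(accepted, iou_threshold)


def segment_stack(dapi_volume: np.ndarray, clf: LabelQualityClassifier,
                  filter_bank=None, iou_threshold: float = 0.5) -> dict[int, list[SegmentationCandidate]]:
    """Per-slice accepted, deduplicated labels for a (z, y, x) nuclear stain."""
    return {
        z: segment_slice(dapi_volume[z], clf, filter_bank, iou_threshold, slice_index=z)
        for z in range(dapi_volume.shape[0])
    }
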