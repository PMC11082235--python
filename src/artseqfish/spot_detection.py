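"""Per-round, per-channel spot detection with learned PSF classification.

Each (round, channel) volume is denoised and sharpened in six configurable
steps, candidate spots are taken as 3D local maxima, and a support-vector
classifier trained on true point-spread-function patches decides which
maxima are genuine hybridisation signals.  No fixed global intensity
threshold is applied: the final preprocessing step rescales each volume to
[0, 1] and all patch features are peak-normalized, so the accepted set is
invariant to a global intensity scaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from artseqfish.stack import ImageStack


class SpotDetectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# six-step preprocessing


def _step_median_hot_pixel(vol: np.ndarray, size: int = 3, ratio: float = 2.5) -> np.ndarray:
    """Replace isolated hot pixels by the local median.

    Only pixels exceeding ``ratio`` times their per-slice 3x3 median are
    replaced, so genuine PSF peaks (whose neighbours carry ~half the peak)
    pass through untouched and two-point resolution is preserved.  The test
    is a ratio, keeping the step invariant to global intensity scaling.
    """
    med = ndimage.median_filter(vol, size=(1, size, size))
    return np.where(vol > ratio * med, med, vol)


def _step_tophat_background(vol: np.ndarray, size: int = 11) -> np.ndarray:
    """Subtract slowly varying background by a per-slice grey top-hat."""
    return vol - ndimage.grey_opening(vol, size=(1, size, size))


def _step_gaussian_denoise(vol: np.ndarray, sigma: float = 0.5) -> np.ndarray:
    return ndimage.gaussian_filter(vol, sigma=(0.0, sigma, sigma))


def _step_log_sharpen(vol: np.ndarray, alpha: float = 0.6) -> np.ndarray:
    """Laplacian-of-Gaussian style unsharpening; keeps intensities non-negative."""
    lap = ndimage.laplace(vol)
    return np.clip(vol - alpha * lap, 0.0, None)


def _step_slice_normalize(vol: np.ndarray) -> np.ndarray:
    """Subtract each z-slice's median so the background sits near zero."""
    med = np.median(vol, axis=(1, 2), keepdims=True)
    return np.clip(vol - med, 0.0, None)


def _step_rescale(vol: np.ndarray) -> np.ndarray:
    """Rescale to [0, 1] by the volume maximum (making detection scale-free)."""
    peak = float(vol.max())
    return vol / peak if peak > 0 else vol


STEP_REGISTRY = {
    "median_hot_pixel": _step_median_hot_pixel,
    "tophat_background": _step_tophat_background,
    "gaussian_denoise": _step_gaussian_denoise,
    "log_sharpen": _step_log_sharpen,
    "slice_normalize": _step_slice_normalize,
    "rescale": _step_rescale,
}

DEFAULT_SIX_STEPS: tuple[tuple[str, dict], ...] = (
    ("median_hot_pixel", {}),
    ("tophat_background", {}),
    ("gaussian_denoise", {}),
    ("log_sharpen", {}),
    ("slice_normalize", {}),
    ("rescale", {}),
)


@dataclass(frozen=True)
class PreprocessConfig:
    """Exactly six named preprocessing steps, applied in order."""

    steps: tuple[tuple[str, dict], ...] = DEFAULT_SIX_STEPS

    def __post_init__(self) -> None:
        if len(self.steps) != 6:
            raise SpotDetectionError(f"expected six preprocessing steps, got {len(self.steps)}")
        for name, _params in self.steps:
            if name not in STEP_REGISTRY:
                raise SpotDetectionError(
                    f"unknown step {name!r}; registry: {sorted(STEP_REGISTRY)}")


def preprocess_volume(vol: np.ndarray, cfg: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    out = np.asarray(vol, dtype=np.float32)
    for name, params in cfg.steps:
        out = STEP_REGISTRY[name](out, **params)
    return out


def preprocess(stack: ImageStack, cfg: PreprocessConfig = PreprocessConfig()) -> ImageStack:
    """Apply the six-step chain to every (round, channel) volume."""
    out = np.empty_like(stack.data)
    for r in range(stack.n_rounds):
        for ci in range(stack.n_channels):
            out[r, ci] = preprocess_volume(stack.data[r, ci], cfg)
    return stack.with_data(out, preprocess_steps=[name for name, _ in cfg.steps])


# ---------------------------------------------------------------------------
# candidates


@dataclass
class SpotCandidate:
    round_index: int
    channel: str
    z: float
    y: float
    x: float
    peak_intensity: float
    score: float | None = None
    accepted: bool | None = None


def _parabolic_offset(vm: float, v0: float, vp: float) -> float:
    """Subpixel offset of a 3-point parabola vertex, clipped to +-0.5."""
    denom = vm - 2.0 * v0 + vp
    if denom >= -1e-12:
        return 0.0
    return float(np.clip(0.5 * (vm - vp) / denom, -0.5, 0.5))


def detect_local_maxima(volume: np.ndarray, min_distance: int = 2,
                        min_prominence: float = 0.1) -> list[SpotCandidate]:
    """3D local maxima above ``min_prominence``, with subpixel lateral refinement.

    ``volume`` should be preprocessed (background near zero, max near one);
    ``min_prominence`` then acts on background-subtracted relative intensity.
    """
    vol = np.asarray(volume, dtype=np.float32)
    if vol.ndim != 3:
        raise SpotDetectionError(f"expected a 3D (z, y, x) volume, got shape {vol.shape}")
    if not np.any(vol > min_prominence):
        return []
    peaks = peak_local_max(vol, min_distance=min_distance,
                           threshold_abs=min_prominence, exclude_border=False)
    out = []
    nz, ny, nx = vol.shape
    for z, y, x in peaks:
        dy = dx = 0.0
        if 0 < y < ny - 1:
            dy = _parabolic_offset(vol[z, y - 1, x], vol[z, y, x], vol[z, y + 1, x])
        if 0 < x < nx - 1:
            dx = _parabolic_offset(vol[z, y, x - 1], vol[z, y, x], vol[z, y, x + 1])
        out.append(SpotCandidate(round_index=-1, channel="", z=float(z),
                                 y=float(y) + dy, x=float(x) + dx,
                                 peak_intensity=float(vol[z, y, x])))
    # deterministic ordering: brightest first, then position
    out.sort(key=lambda c: (-c.peak_intensity, c.z, c.y, c.x))
    return out


def extract_features(volume: np.ndarray, center: tuple[float, float, float],
                     patch_half_width: int = 3) -> np.ndarray:
    """Feature vector of the patch around a candidate maximum.

    Concatenates the peak-normalized (2w+1)^3 patch, the lateral radial mean
    profile at the peak slice, a second-moment width estimate and the local
    signal-to-background ratio.  Edge patches are padded by reflection.
    """
    w = int(patch_half_width)
    if w < 1 or 2 * w + 1 < 3:
        raise SpotDetectionError("patch_half_width must be >= 1")
    vol = np.asarray(volume, dtype=np.float32)
    z, y, x = (int(round(c)) for c in center)
    # crop the in-bounds part, then reflect-pad just the patch (cheap per call)
    lo = [max(z - w, 0), max(y - w, 0), max(x - w, 0)]
    hi = [min(z + w + 1, vol.shape[0]), min(y + w + 1, vol.shape[1]),
          min(x + w + 1, vol.shape[2])]
    core = vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(np.float64)
    pads = [(lo[0] - (z - w), (z + w + 1) - hi[0]),
            (lo[1] - (y - w), (y + w + 1) - hi[1]),
            (lo[2] - (x - w), (x + w + 1) - hi[2])]
    patch = np.pad(core, pads, mode="reflect") if any(p != (0, 0) for p in pads) else core
    # local background: median of the patch border shell
    shell = patch.copy()
    shell[1:-1, 1:-1, 1:-1] = np.nan
    bg = np.nanmedian(shell)
    peak = patch[w, w, w]
    sbr = (peak + 1e-9) / (bg + 1e-9)
    norm = patch / (peak + 1e-12)
    # lateral radial profile at the peak slice
    yy, xx = np.mgrid[-w : w + 1, -w : w + 1]
    rad = np.hypot(yy, xx)
    mid = norm[w]
    profile = np.array([mid[(rad >= k) & (rad < k + 1)].mean() for k in range(w + 1)])
    # width: intensity-weighted lateral second moment above background
    above = np.clip(mid - norm[w].min(), 0, None)
    total = above.sum() + 1e-12
    width = float(np.sqrt((above * rad**2).sum() / total))
    return np.concatenate([norm.ravel(), profile, [width, np.log10(max(sbr, 1e-6))]])


def feature_length(patch_half_width: int = 3) -> int:
    w = patch_half_width
    return (2 * w + 1) ** 3 + (w + 1) + 2


# ---------------------------------------------------------------------------
# the PSF classifier


@dataclass
class PsfClassifier:
    model: Pipeline
    patch_half_width: int
    threshold: float
    holdout_accuracy: float
    n_positives: int
    n_negatives: int
    seed: int

    def score(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(features)
        expected = feature_length(self.patch_half_width)
        if features.shape[1] != expected:
            raise SpotDetectionError(
                f"feature length {features.shape[1]} does not match the trained "
                f"patch size (expected {expected})")
        return self.model.predict_proba(features)[:, 1]


def _patches_to_features(patches, w: int) -> np.ndarray:
    return np.array([extract_features(vol, center, w) for vol, center in patches])


def train_psf_classifier(positives, negatives, seed: int = 0,
                         patch_half_width: int = 3, threshold: float = 0.5,
                         holdout_fraction: float = 0.25) -> PsfClassifier:
    """Train the true-PSF support-vector classifier on labelled patches.

    ``positives`` / ``negatives`` are lists of (volume, centre) pairs such as
    produced by :func:`artseqfish.simulate.make_psf_training_patches`.  A
    stratified hold-out split measures accuracy; the model is fit on the
    training portion only, so the reported accuracy is honest.
    """
    n_pos, n_neg = len(positives), len(negatives)
    if min(n_pos, n_neg) < 100:
        raise SpotDetectionError("need at least 100 examples per class")
    if max(n_pos, n_neg) > 10 * min(n_pos, n_neg):
        raise SpotDetectionError(
            f"class imbalance {n_pos}:{n_neg} exceeds 10:1; rebalance the training set")
    X = np.vstack([_patches_to_features(positives, patch_half_width),
                   _patches_to_features(negatives, patch_half_width)])
    y = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])
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
    return PsfClassifier(model=model, patch_half_width=patch_half_width,
                         threshold=threshold, holdout_accuracy=acc,
                         n_positives=n_pos, n_negatives=n_neg, seed=seed)


# ---------------------------------------------------------------------------
# detection


def detect_spots(stack: ImageStack, classifier: PsfClassifier,
                 preprocess_cfg: PreprocessConfig = PreprocessConfig(),
                 min_distance: int = 2, min_prominence: float = 0.1,
                 threshold: float | None = None,
                 channels: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Detect and classify spots in every (round, channel) volume.

    Returns one row per candidate with its classifier score and accepted
    flag (score >= threshold).  ``channels`` restricts detection to a subset
    of channel labels.
    """
    thr = classifier.threshold if threshold is None else threshold
    w = classifier.patch_half_width
    rows = []
    use = stack.channels if channels is None else channels
    for r in range(stack.n_rounds):
        for ch in use:
            ci = stack.channels.index(ch)
            vol = preprocess_volume(stack.data[r, ci], preprocess_cfg)
            cands = detect_local_maxima(vol, min_distance, min_prominence)
            if not cands:
                continue
            feats = np.array([extract_features(vol, (c.z, c.y, c.x), w) for c in cands])
            scores = classifier.score(feats)
            for cand, s in zip(cands, scores):
                rows.append({
                    "round": r, "channel": ch, "z_px": cand.z, "y_px": cand.y,
                    "x_px": cand.x, "z_um": cand.z * stack.z_step_um,
                    "y_um": cand.y * stack.pixel_size_um,
                    "x_um": cand.x * stack.pixel_size_um,
                    "intensity": cand.peak_intensity,
                    "score": float(s), "accepted": bool(s >= thr),
                })
    cols = ["round", "channel", "z_px", "y_px", "x_px", "z_um", "y_um", "x_um",
            "intensity", "score", "accepted"]
    return pd.DataFrame(rows, columns=cols)
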