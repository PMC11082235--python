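"""Inter-round drift correction.

A global integer shift per hybridisation round is estimated by
cross-correlating the segmented-nucleus masks (nuclei are the only features
shared by every round), then refined by sliding the round's detected spots
across a narrow window of integer shifts and maximizing the number of spots
that land within the colocalization radius of a reference-round spot.
Round 0 is the reference and carries zero total shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree


class RegistrationError(ValueError):
    pass


@dataclass
class DriftEstimate:
    round_index: int
    global_shift: tuple[float, float]      # (dy, dx) px to apply to this round
    refinement: tuple[float, float]
    overlap_before: int
    overlap_after: int

    @property
    def total(self) -> tuple[float, float]:
        return (self.global_shift[0] + self.refinement[0],
                self.global_shift[1] + self.refinement[1])


def nucleus_mask_from_dapi(dapi_volume: np.ndarray) -> np.ndarray:
    """Binary nucleus fiducial mask: Otsu threshold of the max projection."""
    from skimage.filters import threshold_otsu
    proj = np.asarray(dapi_volume).max(axis=0)
    if proj.max() - proj.min() < 1e-9:
        raise RegistrationError("no nuclei to register: flat nuclear stain")
    return proj > threshold_otsu(proj)


def estimate_global_shift(ref_mask: np.ndarray, round_mask: np.ndarray) -> tuple[int, int]:
    """Integer (dy, dx) to apply to ``round_mask`` so it aligns with ``ref_mask``.

    Uses full (zero-padded) cross-correlation of the nucleus masks, so large
    drifts cannot alias through periodic wraparound the way plain FFT phase
    correlation does.
    """
    ref = np.asarray(ref_mask, dtype=np.float32)
    mov = np.asarray(round_mask, dtype=np.float32)
    if not ref.any() or not mov.any():
        raise RegistrationError("no nuclei to register: empty mask")
    corr = fftconvolve(ref, mov[::-1, ::-1], mode="full")
    iy, ix = np.unravel_index(int(np.argmax(corr)), corr.shape)
    return iy - (mov.shape[0] - 1), ix - (mov.shape[1] - 1)


def _overlap_count(ref_yx: np.ndarray, moving_yx: np.ndarray, radius: float) -> int:
    """Number of moving spots whose nearest reference spot is within ``radius``."""
    tree = cKDTree(ref_yx)
    d, _ = tree.query(moving_yx, k=1, distance_upper_bound=radius + 1e-9)
    return int(np.sum(np.isfinite(d)))


def refine_shift(ref_spots: np.ndarray, round_spots: np.ndarray,
                 search_radius: int = 3, coloc_radius: float = 1.0
                 ) -> tuple[tuple[int, int], int, int]:
    """Brute-force integer refinement within +-search_radius.

    ``ref_spots`` / ``round_spots`` are (n, 2) arrays of lateral (y, x)
    positions in px after the global shift.  Returns the refinement shift,
    the matched-pair count before, and the count after.  Ties are broken by
    smaller Euclidean norm, then lexicographically (dy, dx).
    """
    ref_yx = np.atleast_2d(np.asarray(ref_spots, dtype=float))
    mov_yx = np.atleast_2d(np.asarray(round_spots, dtype=float))
    if ref_yx.size == 0 or mov_yx.size == 0:
        import warnings
        warnings.warn("no spots to refine against; refinement is zero", stacklevel=2)
        return (0, 0), 0, 0
    before = _overlap_count(ref_yx, mov_yx, coloc_radius)
    best = None
    s = int(search_radius)
    for dy in range(-s, s + 1):
        for dx in range(-s, s + 1):
            count = _overlap_count(ref_yx, mov_yx + np.array([dy, dx]), coloc_radius)
            key = (-count, dy * dy + dx * dx, dy, dx)
            if best is None or key < best[0]:
                best = (key, (dy, dx), count)
    return best[1], before, best[2]


def apply_shift_to_spots(spots: pd.DataFrame, shift: tuple[float, float],
                         bounds_yx: tuple[int, int] | None = None) -> pd.DataFrame:
    """Translate spot positions by (dy, dx) px; flag spots leaving the field."""
    out = spots.copy()
    out["y_px"] = out["y_px"] + shift[0]
    out["x_px"] = out["x_px"] + shift[1]
    if bounds_yx is not None:
        ny, nx = bounds_yx
        out["in_field"] = ((out["y_px"] >= 0) & (out["y_px"] <= ny - 1)
                           & (out["x_px"] >= 0) & (out["x_px"] <= nx - 1))
    return out


def register_rounds(nucleus_masks: list[np.ndarray], spots: pd.DataFrame,
                    search_radius: int = 3, coloc_radius: float = 1.0,
                    pixel_size_um: float | None = None) -> tuple[pd.DataFrame, list[DriftEstimate]]:
    """Align every round's spots to round 0.

    ``nucleus_masks`` holds one binary 2D nucleus mask per round (max
    projection of the segmented nuclear stain); ``spots`` is a detection
    table with round / y_px / x_px columns.  Returns the drift-corrected spot
    table and the per-round estimates.
    """
    n_rounds = len(nucleus_masks)
    estimates: list[DriftEstimate] = []
    ref_spots = spots[spots["round"] == 0][["y_px", "x_px"]].to_numpy()
    corrected = []
    for r in range(n_rounds):
        sub = spots[spots["round"] == r]
        if r == 0:
            est = DriftEstimate(0, (0.0, 0.0), (0.0, 0.0),
                                len(sub), len(sub))
            corrected.append(sub.copy())
        else:
            gdy, gdx = estimate_global_shift(nucleus_masks[0], nucleus_masks[r])
            moved = sub[["y_px", "x_px"]].to_numpy() + np.array([gdy, gdx])
            if len(ref_spots) and len(moved):
                (rdy, rdx), before, after = refine_shift(
                    ref_spots, moved, search_radius, coloc_radius)
            else:
                (rdy, rdx), before, after = (0, 0), 0, 0
            est = DriftEstimate(r, (float(gdy), float(gdx)), (float(rdy), float(rdx)),
                                before, after)
            corrected.append(apply_shift_to_spots(sub, est.total))
        estimates.append(est)
    out = pd.concat(corrected, ignore_index=True) if corrected else spots.copy()
    if pixel_size_um is not None and len(out):
        out["y_um"] = out["y_px"] * pixel_size_um
        out["x_um"] = out["x_px"] * pixel_size_um
    return out, estimates


def drift_table(estimates: list[DriftEstimate]) -> pd.DataFrame:
    return pd.DataFrame([
        {"round": e.round_index, "global_dy": e.global_shift[0],
         "global_dx": e.global_shift[1], "refine_dy": e.refinement[0],
         "refine_dx": e.refinement[1], "total_dy": e.total[0],
         "total_dx": e.total[1], "overlap_before": e.overlap_before,
         "overlap_after": e.overlap_after}
        for e in estimates
    ])
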