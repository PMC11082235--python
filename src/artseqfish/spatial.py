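"""Micropattern-referenced spatial statistics.

Colonies grow on adhesive 750-um discs; expression gradients are described
relative to the pattern edge.  A cell farther than 125 um from the edge is
"centre", everything else "edge"; radial profiles bin the distance-to-edge
axis into seven positions by default.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from artseqfish.decoding import CellByTargetMatrix

DEFAULT_RADIUS_UM = 375.0
DEFAULT_CENTRE_THRESHOLD_UM = 125.0
DEFAULT_N_BINS = 7

INF_SENTINEL = "inf"


class SpatialError(ValueError):
    pass


@dataclass(frozen=True)
class MicropatternGeometry:
    centre_yx_um: tuple[float, float]
    radius_um: float = DEFAULT_RADIUS_UM
    centre_threshold_um: float = DEFAULT_CENTRE_THRESHOLD_UM
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not self.radius_um > self.centre_threshold_um > 0:
            raise SpatialError("need radius > centre_threshold > 0")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


def fit_geometry(centroids_yx_um: np.ndarray, known_radius_um: float | None = None,
                 centre_threshold_um: float = DEFAULT_CENTRE_THRESHOLD_UM
                 ) -> MicropatternGeometry:
    """Fit the pattern centre as the minimum enclosing circle of cell centroids.

    The pattern is fabricated at a known size, so passing
    ``known_radius_um=375`` is recommended; the fitted radius is used only
    when no known radius is given.  A near-zero fitted radius (all cells in
    one clump) is flagged degenerate.
    """
    pts = np.atleast_2d(np.asarray(centroids_yx_um, dtype=float))
    if len(pts) < 3:
        raise SpatialError(f"need at least 3 cells to fit the pattern, got {len(pts)}")
    circle = shapely.minimum_bounding_circle(
        shapely.MultiPoint([(x, y) for y, x in pts]))
    cx, cy = shapely.centroid(circle).x, shapely.centroid(circle).y
    fitted_r = float(np.sqrt(circle.area / np.pi))
    radius = float(known_radius_um) if known_radius_um is not None else fitted_r
    degenerate = fitted_r < centre_threshold_um
    if degenerate and known_radius_um is None:
        warnings.warn("fitted pattern radius is degenerate (cells in one clump)",
                      stacklevel=2)
        return MicropatternGeometry((cy, cx), radius_um=radius,
                                    centre_threshold_um=centre_threshold_um,
                                    degenerate=True)
    return MicropatternGeometry((cy, cx), radius_um=radius,
                                centre_threshold_um=centre_threshold_um)


def distance_to_edge(yx_um: np.ndarray, geom: MicropatternGeometry) -> np.ndarray:
    """Distance from each (y, x) position to the pattern edge, clamped at 0.

    Positions beyond the nominal radius (fit jitter) clamp to 0.
    """
    pts = np.atleast_2d(np.asarray(yx_um, dtype=float))
    r = np.hypot(pts[:, 0] - geom.centre_yx_um[0], pts[:, 1] - geom.centre_yx_um[1])
    return np.clip(geom.radius_um - r, 0.0, geom.radius_um)


def classify_region(d_um: float | np.ndarray, geom: MicropatternGeometry):
    """"centre" iff strictly farther than the threshold from the edge, else "edge"."""
    d = np.asarray(d_um, dtype=float)
    out = np.where(d > geom.centre_threshold_um, "centre", "edge")
    return out.item() if out.ndim == 0 else out


def annotate_positions(cell_meta: pd.DataFrame, geom: MicropatternGeometry,
                       n_bins: int = DEFAULT_N_BINS) -> pd.DataFrame:
    """Add distance-to-edge, region and radial bin columns to a cell table.

    Expects ``y_um`` / ``x_um`` columns.  Bins are equal-width in
    distance-to-edge over [0, radius]; bin 0 touches the edge.
    """
    out = cell_meta.copy()
    d = distance_to_edge(out[["y_um", "x_um"]].to_numpy(), geom)
    out["dist_edge_um"] = d
    out["region"] = classify_region(d, geom)
    edges = np.linspace(0.0, geom.radius_um, n_bins + 1)
    out["position_bin"] = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    out["beyond_radius"] = np.hypot(out["y_um"] - geom.centre_yx_um[0],
                                    out["x_um"] - geom.centre_yx_um[1]) > geom.radius_um
    return out


@dataclass
class RadialProfile:
    bin_edges_um: np.ndarray      # distance-to-edge, length n_bins + 1
    means: np.ndarray             # NaN where the bin holds no cells / pixels
    sems: np.ndarray
    n_per_bin: np.ndarray

    @property
    def n_bins(self) -> int:
        return len(self.means)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start_um": self.bin_edges_um[:-1], "bin_end_um": self.bin_edges_um[1:],
            "mean": self.means, "sem": self.sems, "n": self.n_per_bin,
        })


def _profile_from_values(d: np.ndarray, values: np.ndarray, radius: float,
                         n_bins: int) -> RadialProfile:
    edges = np.linspace(0.0, radius, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    means = np.full(n_bins, np.nan)
    sems = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = values[idx == b]
        counts[b] = len(sel)
        if len(sel):
            means[b] = sel.mean()
            sems[b] = sel.std(ddof=1) / np.sqrt(len(sel)) if len(sel) > 1 else 0.0
    return RadialProfile(edges, means, sems, counts)


def spots_per_cell_profile(matrix: CellByTargetMatrix, target: str,
                           geom: MicropatternGeometry,
                           n_bins: int = DEFAULT_N_BINS) -> RadialProfile:
    """Mean spots per cell of one target (or species/functional class) per radial bin.

    ``target`` may be a target_id or a species_class / functional_class
    label, in which case member targets are summed per cell.  Empty bins are
    reported as NaN, never as zero.
    """
    counts = matrix.counts
    if target in counts.columns:
        values = counts[target].to_numpy(dtype=float)
    else:
        tm = matrix.target_meta
        members = tm.index[(tm["species_class"] == target)
                           | (tm["functional_class"] == target)].tolist()
        if not members:
            raise SpatialError(f"unknown target or class {target!r}")
        values = counts[members].sum(axis=1).to_numpy(dtype=float)
    meta = matrix.cell_meta.loc[counts.index]
    d = distance_to_edge(meta[["y_um", "x_um"]].to_numpy(), geom)
    return _profile_from_values(d, values, geom.radius_um, n_bins)


def edge_centre_fold_change(matrix: CellByTargetMatrix,
                            geom: MicropatternGeometry) -> pd.DataFrame:
    """Per-target mean fold change between edge and centre cells.

    fold = mean(edge) / mean(centre); a zero centre mean yields the "inf"
    sentinel together with the raw means so nothing is hidden.
    """
    meta = matrix.cell_meta.loc[matrix.counts.index]
    d = distance_to_edge(meta[["y_um", "x_um"]].to_numpy(), geom)
    region = classify_region(d, geom)
    for name in ("edge", "centre"):
        if not np.any(region == name):
            raise SpatialError(f"no cells in the {name} region")
    rows = []
    for t in matrix.counts.columns:
        v = matrix.counts[t].to_numpy(dtype=float)
        me, mc = v[region == "edge"].mean(), v[region == "centre"].mean()
        fold = me / mc if mc > 0 else (float("inf") if me > 0 else float("nan"))
        rows.append({
            "target_id": t, "mean_edge": me, "mean_centre": mc,
            "fold_change": fold if np.isfinite(fold) else INF_SENTINEL,
            "log2_fold": np.log2(fold) if np.isfinite(fold) and fold > 0 else np.nan,
        })
    return pd.DataFrame(rows).set_index("target_id")


def radial_intensity_profile(image: np.ndarray, geom: MicropatternGeometry,
                             pixel_size_um: float, n_bins: int = DEFAULT_N_BINS,
                             normalize: bool = True) -> RadialProfile:
    """Mean pixel intensity per distance-to-edge bin over the pattern disc.

    ``image`` is a 2D z-projection; ``normalize=True`` divides the profile
    by its maximum ("relative fluorescent intensity").
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise SpatialError("expected a 2D (z-projected) image")
    cy, cx = np.asarray(geom.centre_yx_um) / pixel_size_um
    r_px = geom.radius_um / pixel_size_um
    ny, nx = img.shape
    if not (0 <= cy < ny and 0 <= cx < nx):
        raise SpatialError("pattern geometry lies outside the image")
    yy, xx = np.mgrid[0:ny, 0:nx]
    r = np.hypot(yy - cy, xx - cx)
    inside = r <= r_px
    d = (r_px - r[inside]) * pixel_size_um
    prof = _profile_from_values(d, img[inside], geom.radius_um, n_bins)
    if normalize:
        peak = np.nanmax(prof.means)
        if peak > 0:
            prof.means = prof.means / peak
            prof.sems = prof.sems / peak
    return prof
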