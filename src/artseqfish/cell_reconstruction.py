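"""Assembly of per-slice nucleus labels into 3D nuclei.

Accepted 2D labels become nodes of an undirected graph; labels on nearby
z-slices whose lateral centroids are close are connected, and each connected
component becomes one nucleus.  Missing slices inside a component are filled
by linear interpolation of signed distance maps (shape-aware, so a gap
between two circles of different radii interpolates to an intermediate
circle), and a support-vector model flags bounding boxes that contain more
than one nucleus so they can be excluded from counting.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.measure import regionprops
from sklearn.model_selection import train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from artseqfish.nucleus_segmentation import SegmentationCandidate


class ReconstructionError(ValueError):
    pass


def build_graph(labels_per_slice: dict[int, list[SegmentationCandidate]],
                pixel_size_um: float, d_max_um: float | None = None,
                g_max: int = 2) -> nx.Graph:
    """Connect per-slice labels whose centroids stack up across z.

    An edge joins two labels iff their slice gap is <= ``g_max`` and their
    lateral centroid distance is <= ``d_max_um``; when ``d_max_um`` is None
    the cutoff adapts to nucleus size as half the equivalent radius of the
    larger label, so the rule is magnification-independent.
    """
    g = nx.Graph()
    nodes = []
    for z, cands in sorted(labels_per_slice.items()):
        for i, cand in enumerate(cands):
            node = (z, i)
            g.add_node(node, candidate=cand)
            nodes.append((z, i, cand))
    for zi, ii, a in nodes:
        for zj, jj, b in nodes:
            if zj <= zi or zj - zi > g_max:
                continue
            dist_um = float(np.hypot(a.centroid[0] - b.centroid[0],
                                     a.centroid[1] - b.centroid[1])) * pixel_size_um
            if d_max_um is None:
                r_eq = np.sqrt(max(a.area, b.area) / np.pi) * pixel_size_um
                cutoff = 0.5 * r_eq
            else:
                cutoff = d_max_um
            if dist_um <= cutoff:
                g.add_edge((zi, ii), (zj, jj))
    return g


@dataclass
class Nucleus3D:
    cell_id: int
    slices: dict[int, tuple[tuple[int, int, int, int], np.ndarray]]  # z -> (bbox, mask)
    interpolated: set[int]
    pixel_size_um: float
    z_step_um: float
    single_nucleus: bool | None = None
    single_score: float | None = None

    @property
    def z_range(self) -> tuple[int, int]:
        zs = sorted(self.slices)
        return zs[0], zs[-1]

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def area_px(self, z: int) -> float:
        return float(self.slices[z][1].sum())

    @property
    def volume_um3(self) -> float:
        voxel = self.pixel_size_um**2 * self.z_step_um
        return sum(m.sum() for _b, m in self.slices.values()) * voxel

    def centroid_um(self) -> tuple[float, float, float]:
        tot, zs, ys, xs = 0.0, 0.0, 0.0, 0.0
        for z, (bbox, mask) in self.slices.items():
            a = mask.sum()
            cy, cx = ndimage.center_of_mass(mask)
            tot += a
            zs += a * z
            ys += a * (cy + bbox[0])
            xs += a * (cx + bbox[1])
        return (zs / tot * self.z_step_um, ys / tot * self.pixel_size_um,
                xs / tot * self.pixel_size_um)

    def bounding_box(self) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
        zs = sorted(self.slices)
        r0 = min(b[0] for b, _ in self.slices.values())
        c0 = min(b[1] for b, _ in self.slices.values())
        r1 = max(b[2] for b, _ in self.slices.values())
        c1 = max(b[3] for b, _ in self.slices.values())
        return (zs[0], zs[-1] + 1), (r0, r1), (c0, c1)

    def mask_volume(self) -> np.ndarray:
        """Boolean (z, y, x) volume of the nucleus, cropped to its bounding box."""
        (z0, z1), (r0, r1), (c0, c1) = self.bounding_box()
        vol = np.zeros((z1 - z0, r1 - r0, c1 - c0), dtype=bool)
        for z, (bbox, mask) in self.slices.items():
            vol[z - z0, bbox[0] - r0 : bbox[2] - r0, bbox[1] - c0 : bbox[3] - c0] |= mask
        return vol


def cluster_components(graph: nx.Graph, pixel_size_um: float, z_step_um: float,
                       min_slices: int = 3) -> list[Nucleus3D]:
    """Connected components -> nuclei; components spanning < min_slices are debris."""
    nuclei = []
    comps = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    cell_id = 0
    for comp in comps:
        by_z: dict[int, tuple[tuple[int, int, int, int], np.ndarray]] = {}
        for node in comp:
            cand: SegmentationCandidate = graph.nodes[node]["candidate"]
            z = cand.slice_index
            if z in by_z:  # two labels of one component on one slice: keep larger
                if cand.area <= by_z[z][1].sum():
                    continue
            by_z[z] = (cand.bbox, cand.mask)
        if len(by_z) < min_slices:
            continue
        nuclei.append(Nucleus3D(cell_id=cell_id, slices=by_z, interpolated=set(),
                                pixel_size_um=pixel_size_um, z_step_um=z_step_um))
        cell_id += 1
    return nuclei


def _signed_distance(mask: np.ndarray) -> np.ndarray:
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def interpolate_gaps(nucleus: Nucleus3D) -> Nucleus3D:
    """Fill missing z-slices by linear interpolation of signed distance maps."""
    zs = sorted(nucleus.slices)
    z0, z1 = zs[0], zs[-1]
    missing = [z for z in range(z0, z1 + 1) if z not in nucleus.slices]
    if not missing:
        return nucleus
    (zz0, zz1), (r0, r1), (c0, c1) = nucleus.bounding_box()
    pad = 3
    h, w = r1 - r0 + 2 * pad, c1 - c0 + 2 * pad

    def full(z: int) -> np.ndarray:
        bbox, mask = nucleus.slices[z]
        out = np.zeros((h, w), dtype=bool)
        out[bbox[0] - r0 + pad : bbox[2] - r0 + pad,
            bbox[1] - c0 + pad : bbox[3] - c0 + pad] = mask
        return out

    for z in missing:
        below = max(s for s in zs if s < z)
        above = min(s for s in zs if s > z)
        t = (z - below) / (above - below)
        sdf = (1 - t) * _signed_distance(full(below)) + t * _signed_distance(full(above))
        mask = sdf > 0
        if not mask.any():
            continue
        rows = np.any(mask, axis=1).nonzero()[0]
        cols = np.any(mask, axis=0).nonzero()[0]
        bbox = (rows[0] + r0 - pad, cols[0] + c0 - pad,
                rows[-1] + 1 + r0 - pad, cols[-1] + 1 + c0 - pad)
        nucleus.slices[z] = (bbox, mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1])
        nucleus.interpolated.add(z)
    return nucleus


# ---------------------------------------------------------------------------
# single-nucleus QC


NUCLEUS_FEATURE_NAMES = ("n_slices", "fill_fraction", "mean_slice_circularity",
                         "min_slice_solidity", "profile_valley_depth",
                         "max_centroid_jump_px", "axial_aspect")


def _valley_depth(areas: np.ndarray) -> float:
    """Depth of the deepest valley in the per-slice area profile, in [0, 1].

    Zero for a unimodal (dome-shaped) profile; large when two nuclei stacked
    along z produce a two-humped profile with a pinch between them.
    """
    if len(areas) < 3:
        return 0.0
    peak = areas.max()
    depth = 0.0
    for i in range(1, len(areas) - 1):
        left, right = areas[: i + 1].max(), areas[i:].max()
        depth = max(depth, (min(left, right) - areas[i]) / peak)
    return float(depth)


def nucleus_shape_features(volume: np.ndarray, pixel_size_um: float = 1.0,
                           z_step_um: float = 1.0) -> np.ndarray:
    """Derived features of a 3D boolean nucleus volume for single-nucleus QC.

    Per-slice shape statistics (circularity, solidity, centroid jumps) are
    computed on "substantial" slices only (area >= 25% of the largest slice),
    so the faint, erratically segmented tail slices at the nucleus poles do
    not drown the signal from the nucleus body.
    """
    vol = np.asarray(volume, dtype=bool)
    if not vol.any():
        raise ReconstructionError("empty nucleus volume")
    # crop to the tight bounding box so features ignore canvas padding
    nz_idx, ny_idx, nx_idx = (np.any(vol, axis=ax).nonzero()[0]
                              for ax in ((1, 2), (0, 2), (0, 1)))
    vol = vol[nz_idx[0] : nz_idx[-1] + 1, ny_idx[0] : ny_idx[-1] + 1,
              nx_idx[0] : nx_idx[-1] + 1]
    z_any = [z for z in range(vol.shape[0]) if vol[z].any()]
    areas = np.array([float(vol[z].sum()) for z in z_any])
    substantial = [z for z, a in zip(z_any, areas) if a >= 0.25 * areas.max()]
    circ, solid, cents = [], [], []
    for z in substantial:
        props = regionprops(vol[z].astype(np.uint8))
        area = sum(p.area for p in props)
        perim = sum(max(p.perimeter, 1.0) for p in props)
        circ.append(min(4 * np.pi * area / perim**2, 1.2))
        solid.append(min(p.solidity for p in props))
        cents.append(ndimage.center_of_mass(vol[z]))
    fill = vol.sum() / np.prod(vol.shape)
    jumps = [np.hypot(a[0] - b[0], a[1] - b[1]) for a, b in zip(cents, cents[1:])]
    max_jump = float(max(jumps)) if jumps else 0.0
    z_extent = (z_any[-1] - z_any[0] + 1) * z_step_um
    lat_diam = 2 * np.sqrt(areas.mean() / np.pi) * pixel_size_um
    return np.array([len(z_any), fill, float(np.mean(circ)), float(np.min(solid)),
                     _valley_depth(areas), max_jump, z_extent / max(lat_diam, 1e-9)])


@dataclass
class SingleNucleusClassifier:
    model: Pipeline
    threshold: float
    holdout_accuracy: float
    seed: int

    def score(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(features)
        if features.shape[1] != len(NUCLEUS_FEATURE_NAMES):
            raise ReconstructionError(
                f"expected {len(NUCLEUS_FEATURE_NAMES)} features, got {features.shape[1]}")
        return self.model.predict_proba(features)[:, 1]


def train_single_nucleus_classifier(singles, multis, seed: int = 0,
                                    threshold: float = 0.5,
                                    holdout_fraction: float = 0.25) -> SingleNucleusClassifier:
    """Train the bounding-box QC model on single vs merged/fragmented volumes."""
    X = np.array([nucleus_shape_features(v) for v in list(singles) + list(multis)])
    y = np.concatenate([np.ones(len(singles), dtype=int), np.zeros(len(multis), dtype=int)])
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
    return SingleNucleusClassifier(model=model, threshold=threshold,
                                   holdout_accuracy=acc, seed=seed)


def is_single_nucleus(nucleus: Nucleus3D, clf: SingleNucleusClassifier) -> tuple[bool, float]:
    feats = nucleus_shape_features(nucleus.mask_volume())
    score = float(clf.score(feats)[0])
    nucleus.single_score = score
    nucleus.single_nucleus = bool(score >= clf.threshold)
    return nucleus.single_nucleus, score


def reconstruct_cells(labels_per_slice: dict[int, list[SegmentationCandidate]],
                      pixel_size_um: float, z_step_um: float,
                      clf: SingleNucleusClassifier | None = None,
                      d_max_um: float | None = None, g_max: int = 2,
                      min_slices: int = 3) -> list[Nucleus3D]:
    """Full reconstruction: graph -> components -> gap interpolation -> QC."""
    graph = build_graph(labels_per_slice, pixel_size_um, d_max_um, g_max)
    nuclei = cluster_components(graph, pixel_size_um, z_step_um, min_slices)
    for nuc in nuclei:
        interpolate_gaps(nuc)
        if clf is not None:
            is_single_nucleus(nuc, clf)
    return nuclei


def label_volume(nuclei: list[Nucleus3D], shape_zyx: tuple[int, int, int]) -> np.ndarray:
    """Rasterize reconstructed nuclei into a (z, y, x) label volume (0 = background).

    Labels are ``cell_id + 1``; later nuclei never overwrite earlier voxels.
    """
    out = np.zeros(shape_zyx, dtype=np.int32)
    for nuc in nuclei:
        for z, (bbox, mask) in nuc.slices.items():
            if not 0 <= z < shape_zyx[0]:
                continue
            sub = out[z, bbox[0] : bbox[2], bbox[1] : bbox[3]]
            sub[mask & (sub == 0)] = nuc.cell_id + 1
    return out
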