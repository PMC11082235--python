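"""Barcode decoding and single-cell assignment.

Drift-corrected detections from all rounds are collocated into clusters
(one molecule fluoresces at the same physical position in every round its
barcode lights up), each cluster's (round, channel) signature is matched
against the codebook, and decoded molecules are assigned to the cell whose
nucleus they fall in — or, for cytoplasmic molecules, to the cell with the
shortest distance from the spot to the nucleus surface.  The output is the
cells x targets integer count matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from artseqfish.codebook import Codebook

UNDECODED = "undecoded"
UNASSIGNED = -1


class DecodingError(ValueError):
    pass


@dataclass
class SpotCluster:
    members: pd.DataFrame         # one row per member detection
    signature: frozenset          # set of (round, channel)
    z: float                      # consensus position, px (intensity weighted)
    y: float
    x: float
    target_id: str = UNDECODED
    match_type: str = "none"      # exact | one-dropout | none
    cell_id: int = UNASSIGNED
    compartment: str = "none"     # nuclear | cytoplasmic | none


def collocate_across_rounds(spots: pd.DataFrame, coloc_radius: float = 1.5,
                            z_weight: float | None = None) -> list[SpotCluster]:
    """Greedy brightest-first agglomeration of detections into molecules.

    Seeds are taken in decreasing intensity order (ties broken by position);
    each seed collects, per (round, channel), the nearest unclaimed detection
    within ``coloc_radius`` (an anisotropy-corrected Euclidean distance: z is
    scaled by ``z_weight``, default z_step/pixel ratio of 1.0).  Every
    detection ends up in exactly one cluster.
    """
    if len(spots) == 0:
        return []
    df = spots.reset_index(drop=True)
    zw = 1.0 if z_weight is None else float(z_weight)
    coords = np.column_stack([df["z_px"].to_numpy() * zw,
                              df["y_px"].to_numpy(), df["x_px"].to_numpy()])
    tree = cKDTree(coords)
    order = df.sort_values(["intensity", "z_px", "y_px", "x_px"],
                           ascending=[False, True, True, True]).index.to_numpy()
    claimed = np.zeros(len(df), dtype=bool)
    clusters: list[SpotCluster] = []
    for seed in order:
        if claimed[seed]:
            continue
        neigh = tree.query_ball_point(coords[seed], r=coloc_radius)
        # nearest unclaimed member per (round, channel)
        chosen: dict[tuple[int, str], int] = {}
        for idx in sorted(neigh, key=lambda i: np.linalg.norm(coords[i] - coords[seed])):
            if claimed[idx]:
                continue
            key = (int(df.at[idx, "round"]), df.at[idx, "channel"])
            if key not in chosen:
                chosen[key] = idx
        members_idx = sorted(chosen.values())
        claimed[members_idx] = True
        members = df.loc[members_idx]
        wsum = members["intensity"].sum()
        w = members["intensity"] / wsum if wsum > 0 else 1.0 / len(members)
        clusters.append(SpotCluster(
            members=members,
            signature=frozenset((int(r), c) for r, c in
                                zip(members["round"], members["channel"])),
            z=float((members["z_px"] * w).sum()),
            y=float((members["y_px"] * w).sum()),
            x=float((members["x_px"] * w).sum()),
        ))
    return clusters


def decode_cluster(signature: frozenset, codebook: Codebook,
                   allow_dropout: bool = True) -> tuple[str, str]:
    """Match an observed (round, channel) signature against the codebook.

    Exact match wins; otherwise, if ``allow_dropout`` and exactly one
    codeword is the signature plus one extra slot, that target is called with
    match type "one-dropout".  Anything else is undecoded.  With a codebook
    of pairwise set difference >= 2 a dropped signature can never equal
    another codeword, so the rescue is safe and enabled by default; it
    declines whenever more than one superset codeword exists.
    """
    sig = frozenset(signature)
    for entry in codebook.entries:
        if entry.barcode.slots == sig:
            return entry.target_id, "exact"
    if allow_dropout:
        supersets = [e.target_id for e in codebook.entries
                     if sig < e.barcode.slots and len(e.barcode.slots) == len(sig) + 1]
        if len(supersets) == 1:
            return supersets[0], "one-dropout"
    return UNDECODED, "none"


def decode_clusters(clusters: list[SpotCluster], codebook: Codebook,
                    allow_dropout: bool = True) -> list[SpotCluster]:
    for cl in clusters:
        cl.target_id, cl.match_type = decode_cluster(cl.signature, codebook, allow_dropout)
    return clusters


def assign_spots_to_cells(clusters: list[SpotCluster], labels: np.ndarray,
                          pixel_size_um: float, z_step_um: float,
                          max_distance_um: float = 15.0) -> list[SpotCluster]:
    """Assign each cluster to a cell via its nucleus label volume.

    A cluster whose consensus voxel lies inside a nucleus is nuclear and
    belongs to that cell; otherwise it is cytoplasmic and belongs to the cell
    with the nearest nucleus surface (anisotropy-aware Euclidean distance),
    provided that distance is at most ``max_distance_um``.
    """
    if labels.max() == 0:
        warnings.warn("no reconstructed cells: all spots unassigned", stacklevel=2)
        for cl in clusters:
            cl.cell_id, cl.compartment = UNASSIGNED, "none"
        return clusters
    sampling = (z_step_um, pixel_size_um, pixel_size_um)
    dist, (iz, iy, ix) = ndimage.distance_transform_edt(
        labels == 0, sampling=sampling, return_indices=True)
    nz, ny, nx = labels.shape
    for cl in clusters:
        z = int(np.clip(round(cl.z), 0, nz - 1))
        y = int(np.clip(round(cl.y), 0, ny - 1))
        x = int(np.clip(round(cl.x), 0, nx - 1))
        lab = labels[z, y, x]
        if lab > 0:
            cl.cell_id, cl.compartment = int(lab) - 1, "nuclear"
        elif dist[z, y, x] <= max_distance_um:
            cl.cell_id = int(labels[iz[z, y, x], iy[z, y, x], ix[z, y, x]]) - 1
            cl.compartment = "cytoplasmic"
        else:
            cl.cell_id, cl.compartment = UNASSIGNED, "none"
    return clusters


@dataclass
class CellByTargetMatrix:
    counts: pd.DataFrame          # index cell_id, columns target_id, integer
    cell_meta: pd.DataFrame       # per-cell centroid etc.
    target_meta: pd.DataFrame     # species / functional class per target
    n_undecoded: int = 0
    n_unassigned: int = 0

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())


def build_count_matrix(clusters: list[SpotCluster], cell_ids: list[int],
                       codebook: Codebook,
                       cell_meta: pd.DataFrame | None = None) -> CellByTargetMatrix:
    """Tally decoded, assigned clusters into the cells x targets matrix.

    Undecoded or unassigned clusters are counted separately, never silently
    dropped; the matrix total equals the number of decoded AND assigned
    molecules.
    """
    targets = codebook.target_ids
    counts = pd.DataFrame(0, index=pd.Index(sorted(cell_ids), name="cell_id"),
                          columns=targets, dtype=int)
    n_undecoded = n_unassigned = 0
    for cl in clusters:
        if cl.target_id == UNDECODED:
            n_undecoded += 1
            continue
        if cl.cell_id == UNASSIGNED or cl.cell_id not in counts.index:
            n_unassigned += 1
            continue
        counts.at[cl.cell_id, cl.target_id] += 1
    target_meta = pd.DataFrame([
        {"target_id": e.target_id, "species_class": e.species_class,
         "functional_class": e.functional_class}
        for e in codebook.entries
    ]).set_index("target_id")
    if cell_meta is None:
        cell_meta = pd.DataFrame(index=counts.index)
    return CellByTargetMatrix(counts=counts, cell_meta=cell_meta,
                              target_meta=target_meta,
                              n_undecoded=n_undecoded, n_unassigned=n_unassigned)


def decoded_spot_table(clusters: list[SpotCluster], pixel_size_um: float,
                       z_step_um: float) -> pd.DataFrame:
    return pd.DataFrame([
        {"target_id": cl.target_id, "match_type": cl.match_type,
         "cell_id": cl.cell_id, "compartment": cl.compartment,
         "z_px": cl.z, "y_px": cl.y, "x_px": cl.x,
         "z_um": cl.z * z_step_um, "y_um": cl.y * pixel_size_um,
         "x_um": cl.x * pixel_size_um,
         "signature_size": len(cl.signature)}
        for cl in clusters
    ])


def false_positive_rate(accepted_spots: pd.DataFrame, control_truth: pd.DataFrame,
                        coloc_radius: float = 1.5) -> dict[str, float]:
    """Per-channel fraction of accepted detections attributable to the control.

    For a merged stack (negative control + true signal), an accepted
    detection is attributed to the control component when it lies within
    ``coloc_radius`` px (lateral; same round and channel) of a control
    ground-truth spurious position.  Channels without accepted detections
    report NaN.
    """
    if control_truth is None:
        raise DecodingError("control ground truth is required")
    rates: dict[str, float] = {}
    acc = accepted_spots[accepted_spots["accepted"]] if "accepted" in accepted_spots \
        else accepted_spots
    for ch in sorted(acc["channel"].unique()):
        acc_ch = acc[acc["channel"] == ch]
        total = len(acc_ch)
        if total == 0:
            rates[ch] = float("nan")
            continue
        ctrl_ch = control_truth[control_truth["channel"] == ch]
        n_fp = 0
        for r in acc_ch["round"].unique():
            a = acc_ch[acc_ch["round"] == r]
            c = ctrl_ch[ctrl_ch["round"] == r]
            if len(c) == 0:
                continue
            tree = cKDTree(c[["y_px", "x_px"]].to_numpy())
            d, _ = tree.query(a[["y_px", "x_px"]].to_numpy(), k=1,
                              distance_upper_bound=coloc_radius + 1e-9)
            n_fp += int(np.sum(np.isfinite(d)))
        rates[ch] = n_fp / total
    return rates
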