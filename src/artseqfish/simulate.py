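"""Seeded generator of synthetic sequential-FISH experiments with ground truth.

Emulates the acquisition geometry of the real assay: micropatterned colonies
(750-um disc), ellipsoidal nuclei imaged as a DAPI z-stack (0.5-um z-step),
diffraction-limited spots rendered as 3D Gaussians into the (round, channel)
planes dictated by each target's colour barcode, Poisson shot noise plus
Gaussian read noise, per-round rigid drift, and negative-control stacks whose
only "signal" is spurious PSF-like spots at a configurable per-cell rate
(anchored to the 0.03-0.5 spots/cell observed in real negative controls).

Everything is deterministic for a fixed config + seed.  Image-scale configs
render a field of view that is a small crop of a colony; colony-scale cell
positions and radially varying expression (edge/centre gradients) are
generated separately by :func:`simulate_cell_positions` /
:func:`simulate_counts`, which do not require rendering images.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from artseqfish.codebook import Codebook, generate_codebook
from artseqfish.stack import ImageStack, write_stack

MICROPATTERN_RADIUS_UM = 375.0  # 750-um-diameter adhesive disc
CENTRE_THRESHOLD_UM = 125.0     # cells farther than this from the edge are "centre"


class PlacementError(RuntimeError):
    """Nuclei could not be placed without overlap within the retry budget."""


@lru_cache(maxsize=4)
def default_codebook(n_targets: int = 12, n_rounds: int = 4) -> Codebook:
    """The stock synthetic codebook: 2-3 colour slots per target, set difference >= 2."""
    return generate_codebook(n_targets, n_rounds, min_slots=2, max_slots=3,
                             min_set_difference=2, seed=7)


@dataclass
class SimulationConfig:
    """Study conditions for one rendered field of view.

    Defaults describe a small crop of a colony: 10 z-slices of 256x256 px at
    0.325 um/px (83 x 83 x 5 um), ten nuclei, 12 targets at a mean of
    4.5 molecules per target per cell, rendered as resolvable amplicons.
    """

    shape: tuple[int, int, int] = (10, 256, 256)  # (z, y, x) voxels
    pixel_size_um: float = 0.325
    z_step_um: float = 0.5
    micropattern_radius_um: float = MICROPATTERN_RADIUS_UM
    n_cells: int = 10
    nucleus_radius_lat_um: tuple[float, float] = (3.0, 4.5)
    nucleus_radius_ax_um: tuple[float, float] = (1.5, 2.1)
    codebook: Codebook | None = None  # None -> default_codebook()
    mean_counts: float | dict = 4.5   # molecules per target per cell
    psf_sigma_px: tuple[float, float] = (0.95, 0.9)  # (axial, lateral)
    amplitude_range: tuple[float, float] = (400.0, 800.0)
    background: float = 100.0
    dapi_amplitude: float = 600.0
    dapi_background: float = 50.0
    poisson_noise: bool = True
    read_noise_sigma: float = 2.0
    drift_px: tuple[tuple[float, float], ...] | None = None  # per-round (dy, dx)
    false_spot_rate: dict = field(default_factory=dict)  # channel -> spurious/cell
    spot_max_offset_factor: float = 1.8  # spots within this multiple of the nucleus radii
    min_separation_um: float = 8.0       # gap between nucleus surfaces
    min_spot_separation_px: float = 2.5  # resolvable-amplicon spacing (0 disables)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.codebook is None:
            self.codebook = default_codebook()
        for val in (self.pixel_size_um, self.z_step_um, self.background + 1,
                    self.micropattern_radius_um):
            if val <= 0:
                raise ValueError("physical quantities must be positive")
        if self.drift_px is not None and len(self.drift_px) != self.codebook.n_rounds:
            raise ValueError("drift_px must give one (dy, dx) per hybridisation round")

    def drift(self) -> np.ndarray:
        if self.drift_px is None:
            return np.zeros((self.codebook.n_rounds, 2))
        return np.asarray(self.drift_px, dtype=float)

    def mean_count_of(self, target_id: str) -> float:
        if isinstance(self.mean_counts, dict):
            return float(self.mean_counts.get(target_id, 0.0))
        return float(self.mean_counts)


def merged_control_benchmark(seed: int = 1, n_cells: int = 100,
                             noisiest_rate: float = 0.3,
                             other_rate: float = 0.05,
                             noisiest_channel: str = "ATTO488"
                             ) -> tuple["SimulationConfig", "SimulationConfig"]:
    """Configs for the in-silico merged negative-control experiment.

    Returns (control_cfg, signal_cfg) over the same ~100-cell field: the
    control carries no readout signal, only spurious PSF-like spots at
    ``noisiest_rate`` per cell in the noisiest channel (the green channel in
    the real assay) and ``other_rate`` elsewhere; the signal config renders
    the default-density experiment.  Merging the two stacks voxelwise and
    re-detecting measures how far true signal dilutes the false positives.
    """
    common = dict(shape=(10, 640, 640), n_cells=n_cells,
                  nucleus_radius_lat_um=(2.2, 3.2),
                  nucleus_radius_ax_um=(1.5, 2.0))
    rates = {noisiest_channel: noisiest_rate}
    for ch in ("ATTO488", "TAMRA", "CY5"):
        rates.setdefault(ch, other_rate)
    control = SimulationConfig(seed=seed * 7919 % (2**31 - 1),
                               false_spot_rate=rates, **common)
    signal = SimulationConfig(seed=seed, **common)
    return control, signal


@dataclass
class GroundTruth:
    """Per-cell nucleus parameters and the true molecule table."""

    cells: pd.DataFrame  # cell_id, z/y/x_um, z/y/x_px, rz/ry/rx_um
    spots: pd.DataFrame  # spot_id, target_id, cell_id, z/y/x px+um, amplitude[, round, channel]


# ---------------------------------------------------------------------------
# geometry helpers


def _place_nuclei(cfg: SimulationConfig, rng: np.random.Generator,
                  max_tries: int | None = None) -> pd.DataFrame:
    """Rejection-sample non-overlapping nucleus centres and radii."""
    if max_tries is None:
        max_tries = max(5000, 500 * cfg.n_cells)
    nz, ny, nx = cfg.shape
    px = cfg.pixel_size_um
    centres, r_lat, r_ax = [], [], []
    tries = 0
    while len(centres) < cfg.n_cells:
        if tries > max_tries:
            raise PlacementError(
                f"placed only {len(centres)}/{cfg.n_cells} nuclei after {max_tries} tries; "
                "reduce n_cells or nucleus radii")
        tries += 1
        rl = rng.uniform(*cfg.nucleus_radius_lat_um)
        ra = rng.uniform(*cfg.nucleus_radius_ax_um)
        # spots reach spot_max_offset_factor * rl; keep them inside the frame
        margin = cfg.spot_max_offset_factor * rl / px + 3
        y = rng.uniform(margin, ny - margin)
        x = rng.uniform(margin, nx - margin)
        z = nz / 2.0 + rng.uniform(-0.5, 0.5)
        ok = True
        for (cy, cx), orl in zip(centres, r_lat):
            if np.hypot(y - cy, x - cx) * px < rl + orl + cfg.min_separation_um:
                ok = False
                break
        if ok:
            centres.append((y, x))
            r_lat.append(rl)
            r_ax.append(ra)
    rows = []
    for i, ((y, x), rl, ra) in enumerate(zip(centres, r_lat, r_ax)):
        z = cfg.shape[0] / 2.0 - 0.5
        rows.append({
            "cell_id": i, "z_px": z, "y_px": y, "x_px": x,
            "z_um": z * cfg.z_step_um, "y_um": y * px, "x_um": x * px,
            "rz_um": ra, "ry_um": rl, "rx_um": rl,
        })
    return pd.DataFrame(rows)


def _render_nuclei(cfg: SimulationConfig, cells: pd.DataFrame,
                   drift_yx: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Rasterize ellipsoidal nuclei (noise-free DAPI signal, no background)."""
    nz, ny, nx = cfg.shape
    vol = np.zeros(cfg.shape, dtype=np.float32)
    dy, dx = drift_yx
    for row in cells.itertuples():
        rz = max(row.rz_um / cfg.z_step_um, 1.0)
        rl = row.ry_um / cfg.pixel_size_um
        cz, cy, cx = row.z_px, row.y_px + dy, row.x_px + dx
        z0, z1 = max(int(cz - rz) - 1, 0), min(int(cz + rz) + 2, nz)
        y0, y1 = max(int(cy - rl) - 1, 0), min(int(cy + rl) + 2, ny)
        x0, x1 = max(int(cx - rl) - 1, 0), min(int(cx + rl) + 2, nx)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        zz, yy, xx = np.meshgrid(np.arange(z0, z1), np.arange(y0, y1),
                                 np.arange(x0, x1), indexing="ij")
        rho2 = (((zz - cz) / rz) ** 2 + ((yy - cy) / rl) ** 2 + ((xx - cx) / rl) ** 2)
        body = np.clip(1.0 - rho2, 0.0, None) ** 0.5  # projected-sphere profile
        vol[z0:z1, y0:y1, x0:x1] += cfg.dapi_amplitude * body.astype(np.float32)
    return ndimage.gaussian_filter(vol, sigma=(0.5, 1.0, 1.0))


def _stamp_gaussian(vol: np.ndarray, z: float, y: float, x: float, amp: float,
                    sigma_z: float, sigma_yx: float) -> None:
    nz, ny, nx = vol.shape
    hz, hxy = int(np.ceil(3.5 * sigma_z)), int(np.ceil(3.5 * sigma_yx))
    z0, z1 = max(int(z) - hz, 0), min(int(z) + hz + 1, nz)
    y0, y1 = max(int(y) - hxy, 0), min(int(y) + hxy + 1, ny)
    x0, x1 = max(int(x) - hxy, 0), min(int(x) + hxy + 1, nx)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    gz = np.exp(-0.5 * ((np.arange(z0, z1) - z) / sigma_z) ** 2)
    gy = np.exp(-0.5 * ((np.arange(y0, y1) - y) / sigma_yx) ** 2)
    gx = np.exp(-0.5 * ((np.arange(x0, x1) - x) / sigma_yx) ** 2)
    vol[z0:z1, y0:y1, x0:x1] += amp * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def _apply_noise(signal: np.ndarray, cfg: SimulationConfig,
                 rng: np.random.Generator, background: float) -> np.ndarray:
    lam = np.clip(signal + background, 0.0, None)
    if cfg.poisson_noise:
        out = rng.poisson(lam).astype(np.float32)
    else:
        out = lam.astype(np.float32)
    if cfg.read_noise_sigma > 0:
        out = out + rng.normal(0.0, cfg.read_noise_sigma, size=out.shape).astype(np.float32)
    return np.clip(out, 0.0, None)


class _SeparationGrid:
    """Hash-grid rejection helper enforcing a minimum 3D spot spacing."""

    def __init__(self, radius: float):
        self.r = radius
        self.cell = max(radius, 1e-6)
        self.buckets: dict[tuple[int, int, int], list[tuple[float, float, float]]] = {}

    def _key(self, z: float, y: float, x: float) -> tuple[int, int, int]:
        c = self.cell
        return (int(z // c), int(y // c), int(x // c))

    def ok(self, z: float, y: float, x: float) -> bool:
        kz, ky, kx = self._key(z, y, x)
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    for pz, py, px_ in self.buckets.get((kz + dz, ky + dy, kx + dx), ()):
                        if (pz - z) ** 2 + (py - y) ** 2 + (px_ - x) ** 2 < self.r**2:
                            return False
        return True

    def add(self, z: float, y: float, x: float) -> None:
        self.buckets.setdefault(self._key(z, y, x), []).append((z, y, x))


def _draw_spots(cfg: SimulationConfig, cells: pd.DataFrame,
                rng: np.random.Generator) -> pd.DataFrame:
    """Poisson molecule counts per (cell, target); positions around each nucleus.

    When ``min_spot_separation_px`` > 0 positions are rejection-sampled so no
    two molecules sit closer than that (resolvable amplicons); a spot that
    cannot be placed after the retry budget is placed anyway, so the Poisson
    counts are never silently truncated.
    """
    nz, ny, nx = cfg.shape
    grid = _SeparationGrid(cfg.min_spot_separation_px) \
        if cfg.min_spot_separation_px > 0 else None
    rows = []
    sid = 0
    for row in cells.itertuples():
        for target_id in cfg.codebook.target_ids:
            n = rng.poisson(cfg.mean_count_of(target_id))
            for _ in range(n):
                # lateral: uniform within spot_max_offset_factor nucleus radii;
                # axial: uniform through the monolayer depth (cytoplasm fills it)
                for _try in range(200):
                    theta = rng.uniform(0, 2 * np.pi)
                    s = cfg.spot_max_offset_factor * np.sqrt(rng.uniform())
                    dy = s * np.sin(theta) * row.ry_um / cfg.pixel_size_um
                    dx = s * np.cos(theta) * row.rx_um / cfg.pixel_size_um
                    z = float(rng.uniform(0.8, nz - 1.8))
                    y = float(np.clip(row.y_px + dy, 2.0, ny - 3.0))
                    x = float(np.clip(row.x_px + dx, 2.0, nx - 3.0))
                    if grid is None or grid.ok(z, y, x):
                        break
                if grid is not None:
                    grid.add(z, y, x)
                rows.append({
                    "spot_id": sid, "target_id": target_id, "cell_id": row.cell_id,
                    "z_px": z, "y_px": y, "x_px": x,
                    "z_um": z * cfg.z_step_um, "y_um": y * cfg.pixel_size_um,
                    "x_um": x * cfg.pixel_size_um,
                    "amplitude": rng.uniform(*cfg.amplitude_range),
                })
                sid += 1
    cols = ["spot_id", "target_id", "cell_id", "z_px", "y_px", "x_px",
            "z_um", "y_um", "x_um", "amplitude"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# experiment rendering


def render_experiment(cfg: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a full multi-round experiment and return it with its ground truth.

    For every (round, channel), each molecule whose barcode contains that
    slot is stamped as a 3D Gaussian at its true position shifted by the
    round's drift, then background plus noise is added.  The nuclear stain
    is rendered per round (drifting with the readout channels).
    """
    rng = np.random.default_rng(cfg.seed)
    cells = _place_nuclei(cfg, rng) if cfg.n_cells > 0 else pd.DataFrame(
        columns=["cell_id", "z_px", "y_px", "x_px", "z_um", "y_um", "x_um",
                 "rz_um", "ry_um", "rx_um"])
    spots = _draw_spots(cfg, cells, rng)
    cb = cfg.codebook
    drift = cfg.drift()
    sz, sxy = cfg.psf_sigma_px
    n_r, channels = cb.n_rounds, tuple(cb.channels.labels)
    data = np.zeros((n_r, len(channels)) + cfg.shape, dtype=np.float32)
    slots_of = {e.target_id: e.barcode.slots for e in cb.entries}
    for r in range(n_r):
        dy, dx = drift[r]
        for ci, ch in enumerate(channels):
            vol = data[r, ci]
            for spot in spots.itertuples():
                if (r, ch) in slots_of[spot.target_id]:
                    _stamp_gaussian(vol, spot.z_px, spot.y_px + dy, spot.x_px + dx,
                                    spot.amplitude, sz, sxy)
            data[r, ci] = _apply_noise(vol, cfg, rng, cfg.background)
    dapi = np.stack([
        _apply_noise(_render_nuclei(cfg, cells, tuple(drift[r])), cfg, rng,
                     cfg.dapi_background)
        for r in range(n_r)
    ])
    stack = ImageStack(data=data, pixel_size_um=cfg.pixel_size_um,
                       z_step_um=cfg.z_step_um, channels=channels, dapi=dapi,
                       metadata={"seed": cfg.seed, "kind": "experiment"})
    return stack, GroundTruth(cells=cells, spots=spots)


def render_negative_control(cfg: SimulationConfig) -> tuple[ImageStack, GroundTruth]:
    """Render a stack with nuclei and noise but no codebook-consistent signal.

    Spurious PSF-like spots (unspecific probe binding) are added per channel
    at ``cfg.false_spot_rate[channel]`` expected spots per cell, each in a
    single random round.  The returned truth table lists them with
    ``target_id == "spurious"`` and their (round, channel).
    """
    rng = np.random.default_rng(cfg.seed)
    cells = _place_nuclei(cfg, rng) if cfg.n_cells > 0 else pd.DataFrame(
        columns=["cell_id", "z_px", "y_px", "x_px", "z_um", "y_um", "x_um",
                 "rz_um", "ry_um", "rx_um"])
    cb = cfg.codebook
    n_r, channels = cb.n_rounds, tuple(cb.channels.labels)
    nz, ny, nx = cfg.shape
    sz, sxy = cfg.psf_sigma_px
    rows, sid = [], 0
    for ch in channels:
        rate = float(cfg.false_spot_rate.get(ch, 0.0))
        n_spurious = rng.poisson(rate * max(cfg.n_cells, 1)) if rate > 0 else 0
        for _ in range(n_spurious):
            z = rng.uniform(1.0, nz - 2.0)
            y = rng.uniform(3.0, ny - 4.0)
            x = rng.uniform(3.0, nx - 4.0)
            rows.append({
                "spot_id": sid, "target_id": "spurious", "cell_id": -1,
                "z_px": z, "y_px": y, "x_px": x,
                "z_um": z * cfg.z_step_um, "y_um": y * cfg.pixel_size_um,
                "x_um": x * cfg.pixel_size_um,
                "amplitude": rng.uniform(*cfg.amplitude_range),
                "round": int(rng.integers(n_r)), "channel": ch,
            })
            sid += 1
    cols = ["spot_id", "target_id", "cell_id", "z_px", "y_px", "x_px",
            "z_um", "y_um", "x_um", "amplitude", "round", "channel"]
    spurious = pd.DataFrame(rows, columns=cols)
    drift = cfg.drift()
    data = np.zeros((n_r, len(channels)) + cfg.shape, dtype=np.float32)
    for r in range(n_r):
        dy, dx = drift[r]
        for ci, ch in enumerate(channels):
            vol = data[r, ci]
            sel = spurious[(spurious["round"] == r) & (spurious["channel"] == ch)]
            for spot in sel.itertuples():
                _stamp_gaussian(vol, spot.z_px, spot.y_px + dy, spot.x_px + dx,
                                spot.amplitude, sz, sxy)
            data[r, ci] = _apply_noise(vol, cfg, rng, cfg.background)
    dapi = np.stack([
        _apply_noise(_render_nuclei(cfg, cells, tuple(drift[r])), cfg, rng,
                     cfg.dapi_background)
        for r in range(n_r)
    ])
    stack = ImageStack(data=data, pixel_size_um=cfg.pixel_size_um,
                       z_step_um=cfg.z_step_um, channels=channels, dapi=dapi,
                       metadata={"seed": cfg.seed, "kind": "negative_control"})
    return stack, GroundTruth(cells=cells, spots=spurious)


def merge_stacks(a: ImageStack, b: ImageStack) -> ImageStack:
    """In-silico merge of two stacks by voxelwise maximum."""
    if a.data.shape != b.data.shape:
        raise ValueError(f"shape mismatch: {a.data.shape} vs {b.data.shape}")
    if (a.pixel_size_um, a.z_step_um, a.channels) != (b.pixel_size_um, b.z_step_um, b.channels):
        raise ValueError("calibration/channel mismatch between stacks")
    dapi = None
    if a.dapi is not None and b.dapi is not None:
        dapi = np.maximum(a.dapi, b.dapi)
    elif a.dapi is not None or b.dapi is not None:
        dapi = a.dapi if a.dapi is not None else b.dapi
    return ImageStack(data=np.maximum(a.data, b.data), pixel_size_um=a.pixel_size_um,
                      z_step_um=a.z_step_um, channels=a.channels, dapi=dapi,
                      metadata={"kind": "merged"})


def apply_drift(stack: ImageStack, shifts, fill: float | None = None) -> ImageStack:
    """Translate every round's planes by its (dy, dx) shift.

    Out-of-frame voxels are filled with ``fill`` (default: the per-volume
    median, a background estimate).  Subpixel shifts use linear interpolation.
    """
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (stack.n_rounds, 2):
        raise ValueError(f"expected {stack.n_rounds} (dy, dx) shifts, got {shifts.shape}")
    _, _, _, ny, nx = stack.data.shape
    if np.any(np.abs(shifts[:, 0]) >= ny) or np.any(np.abs(shifts[:, 1]) >= nx):
        raise ValueError("shift larger than the image")
    out = np.empty_like(stack.data)
    for r in range(stack.n_rounds):
        dy, dx = shifts[r]
        for ci in range(stack.n_channels):
            vol = stack.data[r, ci]
            cval = float(np.median(vol)) if fill is None else fill
            order = 0 if float(dy).is_integer() and float(dx).is_integer() else 1
            out[r, ci] = ndimage.shift(vol, (0.0, dy, dx), order=order,
                                       mode="constant", cval=cval)
    shifted = stack.with_data(out, applied_drift=shifts.tolist())
    shifted.dapi = stack.dapi
    return shifted


# ---------------------------------------------------------------------------
# colony-scale simulation (positions and counts; no image rendering)


def simulate_cell_positions(n_cells: int, radius_um: float = MICROPATTERN_RADIUS_UM,
                            min_separation_um: float = 12.0, seed: int = 0,
                            radial_density: str = "uniform") -> pd.DataFrame:
    """Sample cell centroids on the micropattern disc (2D, in micrometres).

    ``radial_density`` may be "uniform" or "edge" (a donut-like bias toward
    the rim, mimicking dense colony edges).
    """
    rng = np.random.default_rng(seed)
    pts: list[tuple[float, float]] = []
    tries = 0
    while len(pts) < n_cells:
        if tries > 200 * n_cells + 1000:
            raise PlacementError(f"could not place {n_cells} cells on the disc")
        tries += 1
        u = rng.uniform()
        r = radius_um * (u ** 0.5 if radial_density == "uniform" else u ** 0.35)
        theta = rng.uniform(0, 2 * np.pi)
        y, x = r * np.sin(theta), r * np.cos(theta)
        if all(np.hypot(y - py, x - px_) >= min_separation_um for py, px_ in pts):
            pts.append((y, x))
    return pd.DataFrame({"cell_id": np.arange(n_cells),
                         "y_um": [p[0] for p in pts], "x_um": [p[1] for p in pts]})


def simulate_counts(positions: pd.DataFrame, target_ids, mean_count: float = 10.0,
                    edge_enrichment: dict | None = None,
                    radius_um: float = MICROPATTERN_RADIUS_UM,
                    centre_threshold_um: float = CENTRE_THRESHOLD_UM,
                    profile: str = "step", seed: int = 0) -> pd.DataFrame:
    """Draw Poisson counts per cell per target with an optional radial gradient.

    ``edge_enrichment[target]`` = f sets the edge/centre mean ratio: with the
    default "step" profile the per-cell mean is ``mean_count * f`` in the edge
    band (distance-to-edge <= 125 um) and ``mean_count`` in the centre; the
    "exponential" profile interpolates smoothly, f**(1 - d/R).
    """
    rng = np.random.default_rng(seed)
    edge_enrichment = edge_enrichment or {}
    r = np.hypot(positions["y_um"].to_numpy(), positions["x_um"].to_numpy())
    d = np.clip(radius_um - r, 0.0, None)  # distance to the pattern edge
    counts = {}
    for t in target_ids:
        f = float(edge_enrichment.get(t, 1.0))
        if profile == "step":
            mean = np.where(d <= centre_threshold_um, mean_count * f, mean_count)
        elif profile == "exponential":
            mean = mean_count * f ** (1.0 - d / radius_um)
        else:
            raise ValueError(f"unknown profile {profile!r}")
        counts[t] = rng.poisson(mean)
    out = positions.copy()
    for t, c in counts.items():
        out[t] = c
    return out


# ---------------------------------------------------------------------------
# classifier training material


def make_psf_training_patches(n_pos: int = 1000, n_neg: int = 1000,
                              patch_half_width: int = 3,
                              psf_sigma_px: tuple[float, float] = (0.95, 0.9),
                              amplitude_range: tuple[float, float] = (400.0, 800.0),
                              background: float = 100.0,
                              read_noise_sigma: float = 2.0,
                              seed: int = 0):
    """Synthetic training volumes for the PSF classifier.

    Positives: one Gaussian PSF with subvoxel jitter at the centre of a small
    noisy volume.  Negatives: background-noise volumes re-centred on their
    own brightest voxel, i.e. exactly the local maxima a detector would be
    fooled by.  Returns ``(pos, neg)`` as lists of (volume, (z, y, x) centre).
    """
    rng = np.random.default_rng(seed)
    w = patch_half_width
    shape = (2 * w + 3, 4 * w + 3, 4 * w + 3)
    cz, cy, cx = (s // 2 for s in shape)
    sz, sxy = psf_sigma_px

    def noisy(signal: np.ndarray) -> np.ndarray:
        out = rng.poisson(np.clip(signal + background, 0, None)).astype(np.float32)
        return np.clip(out + rng.normal(0, read_noise_sigma, shape).astype(np.float32), 0, None)

    pos = []
    for _ in range(n_pos):
        vol = np.zeros(shape, dtype=np.float32)
        jz, jy, jx = rng.uniform(-0.5, 0.5, 3)
        amp = rng.uniform(*amplitude_range)
        _stamp_gaussian(vol, cz + jz, cy + jy, cx + jx, amp, sz, sxy)
        pos.append((noisy(vol), (cz, cy, cx)))
    neg = []
    for _ in range(n_neg):
        vol = noisy(np.zeros(shape, dtype=np.float32))
        # centre on the brightest voxel away from the borders
        inner = vol[1:-1, w : -w, w : -w]
        iz, iy, ix = np.unravel_index(np.argmax(inner), inner.shape)
        neg.append((vol, (iz + 1, iy + w, ix + w)))
    return pos, neg


def make_mask_training_set(n_good: int = 300, n_bad: int = 300, size: int = 64,
                           seed: int = 0):
    """Good vs failed 2D nucleus masks for the label-quality classifier.

    Good masks are rotated ellipses with mild boundary roughness.  Bad masks
    cycle through the typical failure modes of a threshold sweep: two nuclei
    merged into one label, a clipped partial nucleus, a dilated speckle blob,
    and a thin sliver.
    """
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:size, 0:size]
    c = size / 2.0

    def ellipse(cy, cx, ry, rx, theta) -> np.ndarray:
        ct, st = np.cos(theta), np.sin(theta)
        u = (yy - cy) * ct + (xx - cx) * st
        v = -(yy - cy) * st + (xx - cx) * ct
        return (u / ry) ** 2 + (v / rx) ** 2 <= 1.0

    def roughen(mask: np.ndarray) -> np.ndarray:
        noise = rng.random(mask.shape) < 0.03
        out = mask ^ (noise & ndimage.binary_dilation(mask) & ~ndimage.binary_erosion(mask, iterations=2))
        lab, n = ndimage.label(out)
        if n > 1:  # keep the largest component only
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
            out = lab == (1 + int(np.argmax(sizes)))
        return ndimage.binary_fill_holes(out)

    good = []
    for _ in range(n_good):
        ry, rx = rng.uniform(8, 18), rng.uniform(8, 18)
        m = ellipse(c + rng.uniform(-4, 4), c + rng.uniform(-4, 4), ry, rx,
                    rng.uniform(0, np.pi))
        good.append(roughen(m))
    bad = []
    kinds = ["merged", "clipped", "speckle", "sliver"]
    for i in range(n_bad):
        kind = kinds[i % 4]
        if kind == "merged":
            ry, rx = rng.uniform(8, 14), rng.uniform(8, 14)
            off = rng.uniform(1.1, 1.5) * (ry + rx) / 2
            th = rng.uniform(0, 2 * np.pi)
            m = ellipse(c, c, ry, rx, 0) | ellipse(c + off * np.sin(th), c + off * np.cos(th),
                                                   ry * rng.uniform(0.8, 1.2),
                                                   rx * rng.uniform(0.8, 1.2), 0)
        elif kind == "clipped":
            m = ellipse(c, c, rng.uniform(10, 18), rng.uniform(10, 18), rng.uniform(0, np.pi))
            th = rng.uniform(0, 2 * np.pi)
            cut = (yy - c) * np.sin(th) + (xx - c) * np.cos(th) > rng.uniform(-4, 2)
            m = m & ~cut
        elif kind == "speckle":
            m = rng.random((size, size)) < 0.08
            m = ndimage.binary_dilation(m, iterations=2)
            m &= ellipse(c, c, 20, 20, 0)
        else:  # sliver
            m = ellipse(c, c, rng.uniform(1.5, 3.0), rng.uniform(12, 22), rng.uniform(0, np.pi))
        if not m.any():
            m = ellipse(c, c, 2, 15, 0)
        bad.append(ndimage.binary_fill_holes(m))
    return good, bad


def make_nucleus3d_training_set(n_single: int = 150, n_multi: int = 150,
                                shape: tuple[int, int, int] = (12, 64, 64),
                                seed: int = 0):
    """Single vs non-single 3D nucleus voxel sets for the bounding-box QC model.

    Singles are ellipsoids with per-slice centroid jitter below 1 px.  The
    non-single class alternates laterally fused pairs, axially stacked pairs,
    and fragmented nuclei whose slices jump around.  Returns two lists of
    boolean (z, y, x) volumes.
    """
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape

    def ellipsoid(cz, cy, cx, rz, ry, rx, jitter=0.6, area_noise=0.12) -> np.ndarray:
        # area_noise emulates the slice-to-slice size wobble that a threshold
        # sweep produces on real stains (each z picks a different filter)
        vol = np.zeros(shape, dtype=bool)
        yy, xx = np.mgrid[0:ny, 0:nx]
        for z in range(nz):
            t = (z - cz) / rz
            if abs(t) >= 1:
                continue
            r_here = (1 - t * t) ** 0.5 * (1.0 + rng.uniform(-area_noise, area_noise))
            jy, jx = rng.uniform(-jitter, jitter, 2)
            vol[z] = ((yy - cy - jy) / (ry * r_here)) ** 2 + \
                     ((xx - cx - jx) / (rx * r_here)) ** 2 <= 1.0
        return vol

    singles, multis = [], []
    for _ in range(n_single):
        # wide parameter coverage: slice extents from stubby to canvas-filling,
        # per-slice jitter from razor-straight to sloppy segmentations
        singles.append(ellipsoid(nz / 2 + rng.uniform(-1, 1), ny / 2 + rng.uniform(-5, 5),
                                 nx / 2 + rng.uniform(-5, 5), rng.uniform(3, 6.5),
                                 rng.uniform(9, 15), rng.uniform(9, 15),
                                 jitter=rng.uniform(0.0, 1.1),
                                 area_noise=rng.uniform(0.0, 0.22)))
    kinds = ["lateral", "axial", "fragmented"]
    for i in range(n_multi):
        kind = kinds[i % 3]
        if kind == "lateral":
            ry = rng.uniform(9, 13)
            off = rng.uniform(1.2, 1.7) * ry
            th = rng.uniform(0, 2 * np.pi)
            a = ellipsoid(nz / 2, ny / 2, nx / 2 - off / 2, rng.uniform(3, 4.5), ry, ry)
            b = ellipsoid(nz / 2 + rng.uniform(-1, 1), ny / 2 + off * np.sin(th) * 0.3,
                          nx / 2 + off / 2, rng.uniform(3, 4.5), ry, ry)
            multis.append(a | b)
        elif kind == "axial":
            a = ellipsoid(nz * 0.33, ny / 2, nx / 2, rng.uniform(2.2, 3.0),
                          rng.uniform(9, 14), rng.uniform(9, 14))
            b = ellipsoid(nz * 0.7, ny / 2 + rng.uniform(-6, 6), nx / 2 + rng.uniform(-6, 6),
                          rng.uniform(2.2, 3.0), rng.uniform(9, 14), rng.uniform(9, 14))
            multis.append(a | b)
        else:
            v = ellipsoid(nz / 2, ny / 2, nx / 2, rng.uniform(3.5, 4.5),
                          rng.uniform(9, 14), rng.uniform(9, 14), jitter=0.0)
            for z in range(nz):
                if v[z].any() and rng.uniform() < 0.5:
                    v[z] = ndimage.shift(v[z].astype(float), rng.uniform(-8, 8, 2),
                                         order=0) > 0.5
            multis.append(v)
    return singles, multis


# ---------------------------------------------------------------------------
# on-disk fixtures


def write_ground_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    truth.cells.to_csv(out_dir / "truth_cells.csv", index=False)
    truth.spots.to_csv(out_dir / "truth_spots.csv", index=False)


def read_ground_truth(out_dir: str | Path) -> GroundTruth:
    out_dir = Path(out_dir)
    return GroundTruth(cells=pd.read_csv(out_dir / "truth_cells.csv"),
                       spots=pd.read_csv(out_dir / "truth_spots.csv"))


def write_experiment(cfg: SimulationConfig, out_dir: str | Path) -> Path:
    """Render an experiment and write TIFFs, manifest and ground-truth CSVs."""
    out_dir = Path(out_dir)
    stack, truth = render_experiment(cfg)
    manifest = write_stack(stack, out_dir)
    write_ground_truth(truth, out_dir)
    from artseqfish.codebook import write_codebook
    write_codebook(cfg.codebook, out_dir / "codebook.csv")
    cfg_dict = dataclasses.asdict(cfg)
    cfg_dict.pop("codebook")
    (out_dir / "simulation_config.json").write_text(json.dumps(cfg_dict, indent=1, default=str))
    return manifest
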