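"""End-to-end orchestration: raw stacks + codebook -> count matrix on disk.

The run configuration is a YAML file pointing at a stack manifest (an
explicit JSON mapping (round, channel) -> TIFF, avoiding fragile filename
parsing) and a codebook, plus per-stage parameter blocks and a single seed
that feeds every source of randomness, including the synthetic training
material for the three support-vector models.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

import artseqfish
from artseqfish import simulate
from artseqfish.cell_reconstruction import (
    label_volume, reconstruct_cells, train_single_nucleus_classifier)
from artseqfish.codebook import read_codebook
from artseqfish.decoding import (
    UNDECODED, build_count_matrix, collocate_across_rounds, decode_clusters,
    decoded_spot_table, assign_spots_to_cells)
from artseqfish.nucleus_segmentation import (
    default_filter_bank, segment_stack, train_label_quality_classifier)
from artseqfish.registration import drift_table, nucleus_mask_from_dapi, register_rounds
from artseqfish.spot_detection import (
    PreprocessConfig, detect_spots, train_psf_classifier)
from artseqfish.stack import read_stack


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    stack_manifest: str
    codebook: str
    out_dir: str
    seed: int = 0
    min_distance_px: int = 2
    min_prominence: float = 0.1
    score_threshold: float = 0.5
    coloc_radius_px: float = 1.5
    allow_dropout: bool = True
    max_assign_distance_um: float = 15.0
    search_radius_px: int = 3
    n_training_patches: int = 600
    spatial: bool = False
    known_pattern_radius_um: float | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def preflight(self) -> None:
        for name in ("stack_manifest", "codebook"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise PipelineError(f"{name} does not exist: {p}")


def _train_models(seed: int, n: int):
    """The three SVMs, trained on seeded synthetic material."""
    pos, neg = simulate.make_psf_training_patches(n_pos=n, n_neg=n, seed=seed)
    psf_clf = train_psf_classifier(pos, neg, seed=seed)
    good, bad = simulate.make_mask_training_set(n_good=max(n // 2, 150),
                                                n_bad=max(n // 2, 150), seed=seed + 1)
    label_clf = train_label_quality_classifier(good, bad, seed=seed + 1)
    singles, multis = simulate.make_nucleus3d_training_set(seed=seed + 2)
    single_clf = train_single_nucleus_classifier(singles, multis, seed=seed + 2)
    return psf_clf, label_clf, single_clf


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns the run manifest (also written to out_dir).

    The manifest is written even on partial failure, with the failing stage
    recorded, so a broken run is never silent.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": f"artseqfish {artseqfish.__version__}",
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "counts": {},
        "warnings": [],
        "stage_failed": None,
    }
    stage = "preflight"
    try:
        cfg.preflight()
        stage = "load"
        stack = read_stack(cfg.stack_manifest)
        codebook = read_codebook(cfg.codebook)
        if stack.dapi is None:
            raise PipelineError("stack has no nuclear-stain (DAPI) volumes")

        stage = "train_models"
        psf_clf, label_clf, single_clf = _train_models(cfg.seed, cfg.n_training_patches)

        stage = "segment"
        labels = segment_stack(stack.dapi[0], label_clf, default_filter_bank())
        manifest["counts"]["segmentation_labels"] = sum(len(v) for v in labels.values())

        stage = "reconstruct"
        nuclei = reconstruct_cells(labels, stack.pixel_size_um, stack.z_step_um,
                                   clf=single_clf)
        kept = [n for n in nuclei if n.single_nucleus]
        manifest["counts"]["nuclei_3d"] = len(nuclei)
        manifest["counts"]["single_nuclei"] = len(kept)
        # all nuclei stay in the assignment volume so a QC-rejected cell still
        # claims its own spots (they are then excluded, not re-assigned)
        labels_vol = label_volume(nuclei, stack.shape_zyx)

        stage = "detect"
        spots = detect_spots(stack, psf_clf, PreprocessConfig(),
                             min_distance=cfg.min_distance_px,
                             min_prominence=cfg.min_prominence,
                             threshold=cfg.score_threshold)
        accepted = spots[spots["accepted"]].reset_index(drop=True)
        manifest["counts"]["spot_candidates"] = len(spots)
        manifest["counts"]["accepted_spots"] = len(accepted)
        spots.to_csv(out_dir / "spots.csv", index=False)

        stage = "register"
        masks = [nucleus_mask_from_dapi(stack.dapi[r])
                 for r in range(stack.n_rounds)]
        registered, drifts = register_rounds(masks, accepted,
                                             search_radius=cfg.search_radius_px,
                                             pixel_size_um=stack.pixel_size_um)
        drift_table(drifts).to_csv(out_dir / "drift.csv", index=False)

        stage = "decode"
        clusters = collocate_across_rounds(registered, cfg.coloc_radius_px)
        decode_clusters(clusters, codebook, allow_dropout=cfg.allow_dropout)
        manifest["counts"]["clusters"] = len(clusters)
        manifest["counts"]["decoded"] = sum(c.target_id != UNDECODED for c in clusters)

        stage = "assign"
        assign_spots_to_cells(clusters, labels_vol, stack.pixel_size_um,
                              stack.z_step_um, cfg.max_assign_distance_um)
        cell_meta = pd.DataFrame([
            dict(zip(("z_um", "y_um", "x_um"), n.centroid_um()),
                 cell_id=n.cell_id, volume_um3=n.volume_um3)
            for n in kept
        ]).set_index("cell_id") if kept else pd.DataFrame(index=pd.Index([], name="cell_id"))
        matrix = build_count_matrix(clusters, [n.cell_id for n in kept], codebook,
                                    cell_meta=cell_meta)
        manifest["counts"]["assigned"] = matrix.total
        matrix.counts.to_csv(out_dir / "count_matrix.csv")
        matrix.cell_meta.to_csv(out_dir / "cells.csv")
        decoded_spot_table(clusters, stack.pixel_size_um,
                           stack.z_step_um).to_csv(out_dir / "decoded_spots.csv",
                                                   index=False)

        if cfg.spatial and len(kept) >= 3:
            stage = "spatial"
            from artseqfish import spatial as sp
            geom = sp.fit_geometry(cell_meta[["y_um", "x_um"]].to_numpy(),
                                   known_radius_um=cfg.known_pattern_radius_um)
            annotated = sp.annotate_positions(cell_meta, geom)
            annotated.to_csv(out_dir / "cell_positions.csv")
            geom.to_json(out_dir / "geometry.json")
        manifest["stage_failed"] = None
    except Exception as exc:
        manifest["stage_failed"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def simulate_fixture(sim_cfg: simulate.SimulationConfig, out_dir: str | Path,
                     pipeline_seed: int | None = None) -> Path:
    """Render a synthetic experiment and write a ready-to-run pipeline config."""
    out_dir = Path(out_dir)
    manifest_path = simulate.write_experiment(sim_cfg, out_dir)
    cfg = PipelineConfig(
        stack_manifest=str(manifest_path),
        codebook=str(out_dir / "codebook.csv"),
        out_dir=str(out_dir / "results"),
        seed=sim_cfg.seed if pipeline_seed is None else pipeline_seed,
    )
    cfg_path = out_dir / "pipeline.yaml"
    cfg.to_yaml(cfg_path)
    return cfg_path
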