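"""Micropattern geometry, edge/centre classification and radial statistics."""

import numpy as np
import pandas as pd
import pytest

from artseqfish import simulate as sim
from artseqfish import spatial as sp
from artseqfish.decoding import CellByTargetMatrix


def matrix_from_counts(counts_df, positions):
    targets = [c for c in counts_df.columns if c not in ("cell_id", "y_um", "x_um")]
    return CellByTargetMatrix(
        counts=counts_df[targets].set_index(positions["cell_id"].to_numpy()),
        cell_meta=positions.set_index("cell_id"),
        target_meta=pd.DataFrame({"species_class": "mRNA", "functional_class": "x"},
                                 index=pd.Index(targets, name="target_id")),
    )


class TestGeometry:
    def test_centre_recovered_from_circle_of_cells(self):
        theta = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.column_stack([300 * np.sin(theta), 300 * np.cos(theta)])
        geom = sp.fit_geometry(pts, known_radius_um=375.0)
        assert np.hypot(*geom.centre_yx_um) < 1.0
        assert geom.radius_um == 375.0

    def test_single_clump_flagged_degenerate(self):
        pts = np.array([[0, 0], [1, 1], [0.5, 0.2], [0.1, 0.9]])
        with pytest.warns(UserWarning, match="degenerate"):
            geom = sp.fit_geometry(pts)
        assert geom.degenerate

    def test_fit_invariant_to_ordering(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-300, 300, (50, 2))
        a = sp.fit_geometry(pts, known_radius_um=375.0)
        b = sp.fit_geometry(pts[::-1], known_radius_um=375.0)
        assert a.centre_yx_um == pytest.approx(b.centre_yx_um)

    def test_too_few_cells(self):
        with pytest.raises(sp.SpatialError, match="at least 3"):
            sp.fit_geometry(np.array([[0, 0], [1, 1]]))


class TestRegionClassification:
    GEOM = sp.MicropatternGeometry((0.0, 0.0))

    @pytest.mark.parametrize("r,expected", [(300.0, "edge"),   # d = 75
                                            (200.0, "centre"),  # d = 175
                                            (250.0, "edge")])   # d = 125 exactly
    def test_distance_rule(self, r, expected):
        d = sp.distance_to_edge(np.array([[r, 0.0]]), self.GEOM)[0]
        assert sp.classify_region(d, self.GEOM) == expected

    def test_partition_covers_all_cells(self):
        pos = sim.simulate_cell_positions(200, seed=7)
        ann = sp.annotate_positions(pos, self.GEOM)
        assert set(ann["region"]) <= {"edge", "centre"}
        assert (ann["region"] == "edge").sum() + (ann["region"] == "centre").sum() == 200

    def test_beyond_radius_clamped_and_flagged(self):
        ann = sp.annotate_positions(pd.DataFrame({"y_um": [400.0], "x_um": [0.0]}),
                                    self.GEOM)
        assert ann["dist_edge_um"].iloc[0] == 0.0
        assert bool(ann["beyond_radius"].iloc[0])


class TestSpotsPerCellProfile:
    GEOM = sp.MicropatternGeometry((0.0, 0.0))

    def test_uniform_expression_gives_flat_profile(self):
        # enough cells that even the small innermost bin is well populated
        pos = sim.simulate_cell_positions(800, seed=11, min_separation_um=8.0)
        counts = sim.simulate_counts(pos, ["t"], mean_count=50, seed=12)
        prof = sp.spots_per_cell_profile(matrix_from_counts(counts, pos), "t", self.GEOM)
        occupied = prof.means[np.isfinite(prof.means)]
        assert occupied.max() / occupied.min() <= 1.2

    def test_exponential_edge_enrichment_decreases_monotonically(self):
        pos = sim.simulate_cell_positions(600, seed=13, min_separation_um=9.0)
        counts = sim.simulate_counts(pos, ["t"], mean_count=30,
                                     edge_enrichment={"t": 4.0},
                                     profile="exponential", seed=14)
        prof = sp.spots_per_cell_profile(matrix_from_counts(counts, pos), "t", self.GEOM)
        means = prof.means[np.isfinite(prof.means)]
        assert np.all(np.diff(means) < 0)

    def test_single_bin_equals_global_mean(self):
        pos = sim.simulate_cell_positions(100, seed=15)
        counts = sim.simulate_counts(pos, ["t"], mean_count=8, seed=16)
        m = matrix_from_counts(counts, pos)
        prof = sp.spots_per_cell_profile(m, "t", self.GEOM, n_bins=1)
        assert prof.means[0] == pytest.approx(m.counts["t"].mean())

    def test_species_class_aggregation_and_unknown_target(self):
        pos = sim.simulate_cell_positions(50, seed=17)
        counts = sim.simulate_counts(pos, ["a", "b"], mean_count=5, seed=18)
        m = matrix_from_counts(counts, pos)
        prof = sp.spots_per_cell_profile(m, "mRNA", self.GEOM, n_bins=1)
        assert prof.means[0] == pytest.approx((m.counts["a"] + m.counts["b"]).mean())
        with pytest.raises(sp.SpatialError, match="unknown"):
            sp.spots_per_cell_profile(m, "nope", self.GEOM)

    def test_profiles_rotation_invariant(self):
        pos = sim.simulate_cell_positions(200, seed=19)
        counts = sim.simulate_counts(pos, ["t"], mean_count=10, seed=20)
        rot = pos.copy()
        ang = 1.1
        y, x = pos["y_um"].to_numpy(), pos["x_um"].to_numpy()
        rot["y_um"] = y * np.cos(ang) - x * np.sin(ang)
        rot["x_um"] = y * np.sin(ang) + x * np.cos(ang)
        a = sp.spots_per_cell_profile(matrix_from_counts(counts, pos), "t", self.GEOM)
        counts_rot = counts.copy()
        counts_rot[["y_um", "x_um"]] = rot[["y_um", "x_um"]]
        b = sp.spots_per_cell_profile(matrix_from_counts(counts_rot, rot), "t", self.GEOM)
        assert np.allclose(a.means, b.means, equal_nan=True)


class TestFoldChange:
    GEOM = sp.MicropatternGeometry((0.0, 0.0))

    @pytest.mark.parametrize("f", [0.5, 1.0, 2.0, 4.0])
    def test_configured_ratio_recovered(self, f):
        pos = sim.simulate_cell_positions(300, seed=23)
        counts = sim.simulate_counts(pos, ["t"], mean_count=15,
                                     edge_enrichment={"t": f}, seed=int(f * 10))
        fc = sp.edge_centre_fold_change(matrix_from_counts(counts, pos), self.GEOM)
        assert float(fc.loc["t", "fold_change"]) == pytest.approx(f, rel=0.15)

    def test_swapping_regions_inverts_fold(self):
        pos = sim.simulate_cell_positions(300, seed=24)
        counts = sim.simulate_counts(pos, ["t"], mean_count=12,
                                     edge_enrichment={"t": 2.0}, seed=25)
        m = matrix_from_counts(counts, pos)
        fc = sp.edge_centre_fold_change(m, self.GEOM)
        # invert by relabelling: swap d against the threshold via mirrored radius
        mirrored = pos.copy()
        r = np.hypot(pos["y_um"], pos["x_um"])
        new_r = np.where(375 - r <= 125, 100.0, 320.0)  # edge cells -> centre band
        scale = np.where(r > 0, new_r / r, 0.0)
        mirrored["y_um"] = pos["y_um"] * scale
        mirrored["x_um"] = pos["x_um"] * scale
        m2 = matrix_from_counts(counts.assign(y_um=mirrored["y_um"],
                                              x_um=mirrored["x_um"]), mirrored)
        fc2 = sp.edge_centre_fold_change(m2, self.GEOM)
        assert float(fc2.loc["t", "fold_change"]) == pytest.approx(
            1.0 / float(fc.loc["t", "fold_change"]), rel=0.05)

    def test_empty_region_is_an_error(self):
        pos = pd.DataFrame({"cell_id": range(5), "y_um": [360.0] * 5, "x_um": [0.0] * 5})
        counts = sim.simulate_counts(pos, ["t"], mean_count=5, seed=1)
        with pytest.raises(sp.SpatialError, match="centre"):
            sp.edge_centre_fold_change(matrix_from_counts(counts, pos), self.GEOM)

    def test_zero_centre_mean_reports_sentinel(self):
        pos = pd.DataFrame({"cell_id": [0, 1], "y_um": [360.0, 0.0], "x_um": [0.0, 0.0]})
        counts = pos.copy()
        counts["t"] = [3, 0]
        fc = sp.edge_centre_fold_change(matrix_from_counts(counts, pos), self.GEOM)
        assert fc.loc["t", "fold_change"] == sp.INF_SENTINEL


class TestRadialIntensity:
    def test_uniform_image_flat_at_one(self):
        geom = sp.MicropatternGeometry((50.0 * 3, 50.0 * 3), radius_um=140.0)
        img = np.full((100, 100), 7.0)
        prof = sp.radial_intensity_profile(img, geom, pixel_size_um=3.0, n_bins=5)
        assert np.allclose(prof.means[np.isfinite(prof.means)], 1.0)

    def test_bright_ring_peaks_in_matching_bin(self):
        # ring of brightness at distance-to-edge ~100 um (radius 275 um)
        px = 3.0
        geom = sp.MicropatternGeometry((150 * px, 150 * px))
        yy, xx = np.mgrid[0:300, 0:300]
        r_um = np.hypot(yy - 150, xx - 150) * px
        img = np.where(np.abs(r_um - 275.0) < 15.0, 100.0, 10.0)
        prof = sp.radial_intensity_profile(img, geom, pixel_size_um=px, n_bins=7)
        peak_bin = int(np.nanargmax(prof.means))
        lo, hi = prof.bin_edges_um[peak_bin], prof.bin_edges_um[peak_bin + 1]
        assert lo <= 100.0 <= hi

    def test_normalization_preserves_argmax(self):
        px = 3.0
        geom = sp.MicropatternGeometry((150 * px, 150 * px))
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 50, (300, 300))
        raw = sp.radial_intensity_profile(img, geom, px, normalize=False)
        norm = sp.radial_intensity_profile(img, geom, px, normalize=True)
        assert np.nanargmax(raw.means) == np.nanargmax(norm.means)

    def test_geometry_outside_image_rejected(self):
        geom = sp.MicropatternGeometry((5000.0, 5000.0))
        with pytest.raises(sp.SpatialError, match="outside"):
            sp.radial_intensity_profile(np.zeros((50, 50)), geom, 1.0)
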