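"""Collocation, barcode matching, cell assignment and the count matrix."""

import numpy as np
import pandas as pd
import pytest

from artseqfish import simulate as sim
from artseqfish.codebook import Barcode, ChannelSet, Codebook, CodebookEntry, generate_codebook
from artseqfish.decoding import (
    UNASSIGNED, UNDECODED, DecodingError, assign_spots_to_cells,
    build_count_matrix, collocate_across_rounds, decode_cluster, decode_clusters,
    false_positive_rate)


def spot_row(r, ch, z, y, x, intensity=1.0):
    return {"round": r, "channel": ch, "z_px": z, "y_px": y, "x_px": x,
            "intensity": intensity}


class TestCollocation:
    def test_stacked_signals_form_one_cluster(self):
        df = pd.DataFrame([spot_row(r, "ATTO488", 3, 10, 10) for r in range(3)])
        clusters = collocate_across_rounds(df, 1.5)
        assert len(clusters) == 1
        assert clusters[0].signature == frozenset((r, "ATTO488") for r in range(3))

    def test_distant_spots_stay_apart(self):
        df = pd.DataFrame([spot_row(0, "ATTO488", 3, 10, 10),
                           spot_row(1, "TAMRA", 3, 10, 20)])
        assert len(collocate_across_rounds(df, 1.5)) == 2

    def test_every_spot_in_exactly_one_cluster(self):
        rng = np.random.default_rng(0)
        rows = [spot_row(int(rng.integers(4)), rng.choice(["ATTO488", "TAMRA", "CY5"]),
                         *rng.uniform(2, 60, 3), intensity=rng.uniform(0.2, 1))
                for _ in range(200)]
        clusters = collocate_across_rounds(pd.DataFrame(rows), 1.5)
        assert sum(len(c.members) for c in clusters) == 200

    def test_same_round_channel_never_shares_a_cluster(self):
        df = pd.DataFrame([spot_row(0, "ATTO488", 3, 10, 10, 1.0),
                           spot_row(0, "ATTO488", 3, 10.5, 10.5, 0.9),
                           spot_row(1, "TAMRA", 3, 10.2, 10.2, 0.8)])
        clusters = collocate_across_rounds(df, 1.5)
        for cl in clusters:
            keys = list(zip(cl.members["round"], cl.members["channel"]))
            assert len(keys) == len(set(keys))


class TestDecode:
    CB = generate_codebook(8, 4, min_slots=2, max_slots=3, min_set_difference=2, seed=7)

    def test_exact_match(self):
        entry = self.CB.entries[0]
        target, match = decode_cluster(entry.barcode.slots, self.CB)
        assert target == entry.target_id and match == "exact"

    def test_garbage_signature_is_undecoded(self):
        target, match = decode_cluster(frozenset({(0, "ATTO488"), (1, "ATTO488"),
                                                  (2, "ATTO488"), (3, "ATTO488")}),
                                       self.CB)
        assert target == UNDECODED and match == "none"

    def test_one_dropout_rescued_iff_superset_unique(self):
        for entry in self.CB.entries:
            slots = sorted(entry.barcode.slots)
            if len(slots) < 3:
                continue
            sig = frozenset(slots[:-1])
            supersets = [e.target_id for e in self.CB.entries
                         if sig < e.barcode.slots
                         and len(e.barcode.slots) == len(sig) + 1]
            target, match = decode_cluster(sig, self.CB, allow_dropout=True)
            if len(supersets) == 1:
                assert (target, match) == (entry.target_id, "one-dropout")
            else:
                assert target == UNDECODED

    def test_dropout_disabled_means_undecoded(self):
        entry = next(e for e in self.CB.entries if len(e.barcode.slots) == 3)
        sig = frozenset(sorted(entry.barcode.slots)[:-1])
        target, _ = decode_cluster(sig, self.CB, allow_dropout=False)
        assert target == UNDECODED


class TestAssignment:
    def _labels(self):
        labels = np.zeros((6, 64, 64), dtype=np.int32)
        labels[2:5, 10:20, 10:20] = 1  # cell 0
        labels[2:5, 40:50, 40:50] = 2  # cell 1
        return labels

    def _cluster(self, z, y, x):
        from artseqfish.decoding import SpotCluster
        return SpotCluster(members=pd.DataFrame(), signature=frozenset({(0, "ATTO488")}),
                           z=z, y=y, x=x)

    def test_spot_inside_nucleus_is_nuclear(self):
        cl = self._cluster(3, 15, 15)
        assign_spots_to_cells([cl], self._labels(), 0.325, 0.5)
        assert cl.cell_id == 0 and cl.compartment == "nuclear"

    def test_cytoplasmic_goes_to_nearest_surface(self):
        # ~3 um from cell 0's surface, much farther from cell 1
        cl = self._cluster(3, 15, 29)
        assign_spots_to_cells([cl], self._labels(), 0.325, 0.5)
        assert cl.cell_id == 0 and cl.compartment == "cytoplasmic"

    def test_beyond_max_distance_unassigned(self):
        cl = self._cluster(3, 15, 29)
        assign_spots_to_cells([cl], self._labels(), 0.325, 0.5, max_distance_um=1.0)
        assert cl.cell_id == UNASSIGNED and cl.compartment == "none"

    def test_no_cells_warns(self):
        cl = self._cluster(3, 15, 15)
        with pytest.warns(UserWarning, match="no reconstructed cells"):
            assign_spots_to_cells([cl], np.zeros((6, 64, 64), np.int32), 0.325, 0.5)
        assert cl.cell_id == UNASSIGNED


class TestCountMatrix:
    CB = generate_codebook(5, 4, min_slots=2, max_slots=2, seed=3)

    def test_empty_input_keeps_full_axes(self):
        m = build_count_matrix([], [0, 1, 2], self.CB)
        assert m.counts.shape == (3, 5)
        assert m.total == 0

    def test_total_conservation(self):
        from artseqfish.decoding import SpotCluster
        clusters = []
        for i, entry in enumerate(self.CB.entries):
            cl = SpotCluster(members=pd.DataFrame(), signature=entry.barcode.slots,
                             z=1, y=1, x=1)
            cl.target_id = entry.target_id
            cl.cell_id = i % 2
            clusters.append(cl)
        und = SpotCluster(members=pd.DataFrame(), signature=frozenset({(0, "CY5")}),
                          z=1, y=1, x=1)  # stays undecoded
        m = build_count_matrix(clusters + [und], [0, 1], self.CB)
        assert m.total == len(self.CB)
        assert m.n_undecoded == 1
        assert set(m.target_meta["species_class"]) <= {"mRNA", "protein", "phosphoprotein"}


class TestFalsePositiveRate:
    def test_zero_spurious_control_gives_zero_rate(self):
        acc = pd.DataFrame([dict(spot_row(0, "ATTO488", 1, 5, 5), accepted=True)])
        ctrl = pd.DataFrame(columns=["round", "channel", "y_px", "x_px"])
        rates = false_positive_rate(acc, ctrl)
        assert rates["ATTO488"] == 0.0

    def test_attribution_by_proximity(self):
        acc = pd.DataFrame([
            dict(spot_row(0, "ATTO488", 1, 5.2, 5.1), accepted=True),   # near control
            dict(spot_row(0, "ATTO488", 1, 40, 40), accepted=True),     # true signal
            dict(spot_row(0, "ATTO488", 1, 41, 40), accepted=True),
            dict(spot_row(0, "ATTO488", 1, 42, 40), accepted=True),
        ])
        ctrl = pd.DataFrame([{"round": 0, "channel": "ATTO488", "y_px": 5.0, "x_px": 5.0}])
        assert false_positive_rate(acc, ctrl)["ATTO488"] == pytest.approx(0.25)

    def test_missing_control_truth_is_an_error(self):
        with pytest.raises(DecodingError):
            false_positive_rate(pd.DataFrame(), None)

    def test_rate_monotone_in_classifier_threshold(self, psf_classifier):
        """Raising the score threshold never raises the false-positive rate
        by more than sampling noise and never admits new detections."""
        from artseqfish.spot_detection import detect_spots
        ctrl_cfg = sim.SimulationConfig(seed=31, n_cells=4, shape=(10, 192, 192),
                                        false_spot_rate={"ATTO488": 2.0})
        sig_cfg = sim.SimulationConfig(seed=32, n_cells=4, shape=(10, 192, 192))
        ctrl, ctruth = sim.render_negative_control(ctrl_cfg)
        sig, _ = sim.render_experiment(sig_cfg)
        merged = sim.merge_stacks(ctrl, sig)
        spots = detect_spots(merged, psf_classifier, min_distance=1,
                             channels=("ATTO488",))
        n_accept = [int((spots.score >= t).sum()) for t in (0.2, 0.5, 0.8)]
        assert n_accept == sorted(n_accept, reverse=True)


class TestEndToEndRecovery:
    def _score(self, cfg, psf_classifier):
        from scipy.spatial import cKDTree
        from artseqfish.spot_detection import detect_spots
        stack, truth = sim.render_experiment(cfg)
        spots = detect_spots(stack, psf_classifier, min_distance=1)
        clusters = collocate_across_rounds(spots[spots.accepted], 1.5)
        decode_clusters(clusters, cfg.codebook)
        tree = cKDTree(np.array([[c.z, c.y, c.x] for c in clusters]))
        ok = 0
        for row in truth.spots.itertuples():
            d, i = tree.query([row.z_px, row.y_px, row.x_px])
            ok += int(d <= 1.5 and clusters[i].target_id == row.target_id)
        return ok / len(truth.spots)

    def test_zero_noise_zero_drift_recovery(self, psf_classifier, zero_noise_experiment):
        cfg, _stack, _truth = zero_noise_experiment
        assert self._score(cfg, psf_classifier) >= 0.99

    def test_drift_within_search_range_costs_little(self, psf_classifier):
        from artseqfish.spot_detection import detect_spots
        from artseqfish.registration import nucleus_mask_from_dapi, register_rounds
        from scipy.spatial import cKDTree
        base = sim.SimulationConfig(seed=21)
        drifted = sim.SimulationConfig(seed=21,
                                       drift_px=((0, 0), (5, -3), (-7, 2), (9, 9)))

        def run(cfg):
            stack, truth = sim.render_experiment(cfg)
            spots = detect_spots(stack, psf_classifier, min_distance=1)
            masks = [nucleus_mask_from_dapi(stack.dapi[r])
                     for r in range(stack.n_rounds)]
            reg, _ = register_rounds(masks, spots[spots.accepted])
            clusters = collocate_across_rounds(reg, 1.5)
            decode_clusters(clusters, cfg.codebook)
            tree = cKDTree(np.array([[c.z, c.y, c.x] for c in clusters]))
            ok = 0
            for row in truth.spots.itertuples():
                d, i = tree.query([row.z_px, row.y_px, row.x_px])
                ok += int(d <= 1.5 and clusters[i].target_id == row.target_id)
            return ok / len(truth.spots)

        r0, r1 = run(base), run(drifted)
        assert r1 >= r0 - 0.02
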