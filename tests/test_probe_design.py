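"""Probe architecture: assembly, GC filtering, off-target checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from artseqfish import probe_design as pdx

ARCH = pdx.ProbeArchitecture()


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_revcomp(seq):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("ATGC", 50.0), ("GGCC", 100.0),
                                              ("AAAA", 0.0), ("ACGTACGT", 50.0)])
    def test_known_values(self, seq, expected):
        assert pdx.gc_content(seq) == pytest.approx(expected)

    def test_rejects_bad_input(self):
        with pytest.raises(pdx.ProbeDesignError):
            pdx.gc_content("")
        with pytest.raises(pdx.ProbeDesignError):
            pdx.gc_content("ACGU")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=80))
    @settings(max_examples=60, deadline=None)
    def test_strand_symmetric_and_scale_free(self, seq):
        assert pdx.gc_content(seq) == pytest.approx(
            pdx.gc_content(pdx.reverse_complement(seq)))
        assert pdx.gc_content(seq) == pytest.approx(pdx.gc_content(seq * 2))

    def test_gc_filter_bounds_inclusive(self):
        # 45% and 65% are accepted; just outside is not
        assert pdx.passes_gc_filter("G" * 9 + "A" * 11)          # 45%
        assert pdx.passes_gc_filter("G" * 13 + "A" * 7)          # 65%
        assert not pdx.passes_gc_filter("G" * 7 + "A" * 3)       # 70%
        assert not pdx.passes_gc_filter("G" * 4 + "A" * 6)       # 40%


class TestTargetRegion:
    def test_single_window_transcript(self):
        seq = ("AGCT" * 9)  # 36 nt; both 18-nt halves sit at 50% GC
        window, offset = pdx.select_target_region(pdx.SequenceRecord("t", seq))
        assert window == seq and offset == 0

    def test_all_a_transcript_has_no_region(self):
        with pytest.raises(pdx.NoValidRegionError, match="polyA"):
            pdx.select_target_region(pdx.SequenceRecord("polyA", "A" * 100))

    def test_leftmost_window_matches_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            seq = random_seq(rng, 200)
            rec = pdx.SequenceRecord("t", seq)

            def gc_ok(s):  # independently coded GC filter
                gc = 100.0 * sum(b in "GC" for b in s) / len(s)
                return 45.0 <= gc <= 65.0

            expected = None
            for off in range(len(seq) - 36 + 1):
                w = seq[off : off + 36]
                if gc_ok(w[:18]) and gc_ok(w[18:]):
                    expected = off
                    break
            if expected is None:
                with pytest.raises(pdx.NoValidRegionError):
                    pdx.select_target_region(rec)
            else:
                _w, offset = pdx.select_target_region(rec)
                assert offset == expected


class TestAssembly:
    def test_plp_dimensions_and_polyA_arms(self):
        plp = pdx.assemble_plp("A" * 36, "G" * 28, "C" * 20)
        assert len(plp.full_seq) == 84
        assert plp.arm5 == "T" * 18 and plp.arm3 == "T" * 18

    def test_plp_arm_roundtrip_against_revcomp_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            target = random_seq(rng, 36)
            plp = pdx.assemble_plp(target, random_seq(rng, 28), random_seq(rng, 20))
            assert len(plp.full_seq) == 84
            # the two arms jointly reverse-complement the target window
            assert brute_force_revcomp(plp.arm5 + plp.arm3) == target

    def test_plp_wrong_component_length(self):
        with pytest.raises(pdx.ProbeDesignError, match="expected length 28"):
            pdx.assemble_plp("A" * 36, "G" * 27, "C" * 20)

    def test_brp_dimensions_and_spacer_positions(self):
        brp = pdx.assemble_brp(["A" * 18] * 4, "C" * 28)
        assert len(brp.full_seq) == 108
        # spacer offsets follow from the layout by index arithmetic
        for pos in (18, 38, 68, 88):
            assert brp.full_seq[pos : pos + 2] == "AA"
        assert brp.full_seq[40:68] == "C" * 28

    def test_brp_requires_four_readouts(self):
        with pytest.raises(pdx.ProbeDesignError, match="4 readout"):
            pdx.assemble_brp(["A" * 18] * 3, "C" * 28)

    def test_ab_oligo_layout(self):
        ab = pdx.assemble_ab_oligo("T" * 36)
        assert len(ab.full_seq) == 46
        assert ab.full_seq == "A" * 10 + "T" * 36

    @given(st.data())
    @settings(max_examples=40, deadline=None)
    def test_assembled_lengths_invariant(self, data):
        base = st.sampled_from("ACGT")
        t36 = "".join(data.draw(st.lists(base, min_size=36, max_size=36)))
        u28 = "".join(data.draw(st.lists(base, min_size=28, max_size=28)))
        p20 = "".join(data.draw(st.lists(base, min_size=20, max_size=20)))
        r18 = ["".join(data.draw(st.lists(base, min_size=18, max_size=18)))
               for _ in range(4)]
        u36 = "".join(data.draw(st.lists(base, min_size=36, max_size=36)))
        assert len(pdx.assemble_plp(t36, u28, p20).full_seq) == 84
        assert len(pdx.assemble_brp(r18, u28).full_seq) == 108
        assert len(pdx.assemble_ab_oligo(u36).full_seq) == 46


def brute_force_longest_match(probe, transcripts):
    """Exhaustive O(n*m*L): longest probe substring whose revcomp is off-target."""
    best = 0
    for tx in transcripts:
        for i in range(len(probe)):
            for j in range(i + best + 1, len(probe) + 1):
                if brute_force_revcomp(probe[i:j]) in tx.seq:
                    best = max(best, j - i)
                else:
                    break
    return best


class TestCrossHybridization:
    def test_13nt_match_fails_12nt_passes(self):
        rng = np.random.default_rng(3)
        probe = random_seq(rng, 40)
        hit13 = brute_force_revcomp(probe[10:23])  # 13-nt complement
        tx = pdx.SequenceRecord("off", random_seq(rng, 50) + hit13 + random_seq(rng, 50))
        res = pdx.cross_hybridization_check(probe, [tx])
        assert not res.passed and res.longest_match >= 13
        hit12 = brute_force_revcomp(probe[10:22])
        tx12 = pdx.SequenceRecord("off", "A" * 30 + hit12 + "A" * 30)
        res12 = pdx.cross_hybridization_check(probe, [tx12])
        # only the planted 12-mer (or chance extensions) can match
        if res12.longest_match == 12:
            assert res12.passed

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(8):
            probe = random_seq(rng, 60)
            txs = [pdx.SequenceRecord(f"t{i}", random_seq(rng, 200)) for i in range(5)]
            res = pdx.cross_hybridization_check(probe, txs)
            assert res.longest_match == brute_force_longest_match(probe, txs)

    def test_empty_transcriptome_warns_and_passes(self):
        with pytest.warns(UserWarning, match="empty transcriptome"):
            res = pdx.cross_hybridization_check("ACGT" * 10, [])
        assert res.passed and res.longest_match == 0


class TestFastaAndManifest:
    def test_fasta_roundtrip(self, tmp_path):
        recs = [pdx.SequenceRecord("a", "ACGTACGT"), pdx.SequenceRecord("b", "GGCC")]
        path = tmp_path / "x.fasta"
        pdx.write_fasta(recs, path)
        assert pdx.read_fasta(path) == recs

    def test_design_probe_set_manifest(self):
        rng = np.random.default_rng(9)
        mrnas = [pdx.SequenceRecord(f"g{i}", random_seq(rng, 150)) for i in range(3)]
        uniques, readouts = [], []
        for _ in range(3):
            uniques.append(random_seq(rng, 28))
            readouts.append([random_seq(rng, 18) for _ in range(4)])
        table = pdx.design_probe_set(mrnas, uniques, random_seq(rng, 20), readouts,
                                     transcriptome=mrnas)
        assert list(table["target_id"]) == ["g0", "g1", "g2"]
        assert (table["plp_full_seq"].str.len() == 84).all()
        assert (table["brp_full_seq"].str.len() == 108).all()
        assert "offtarget_pass" in table.columns
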