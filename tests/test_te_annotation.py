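"""TSD detection, PWM scanning, in-silico PCR and promoter arithmetic tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rooscan.synthetic_data import build_promoter_construct, random_sequence
from rooscan.te_annotation import (
    NINE_INSERTIONS,
    ROO_PLUS7_WITH_DUP,
    AmpliconModel,
    InsertionRecord,
    MotifMatrix,
    TranscriptModel,
    build_tsd_logo,
    classify_genotype,
    detect_tsd,
    motif_spacing_change,
    predict_pcr_bands,
    promoter_5prime_fraction,
    reverse_complement,
    scan_pwm,
    transcript_utr_lengths,
)


class TestDetectTSD:
    def test_worked_example(self):
        absent = "CCCACGTAGGG"
        present = "CCCACGTA" + "TTTT" + "ACGTAGGG"
        tsd, point, element = detect_tsd(absent, present)
        assert tsd == "ACGTA" and point == 3 and element == "TTTT"

    def test_no_duplication_gives_empty_tsd(self):
        absent = "AAACCCGGG"
        present = "AAACCC" + "TTTTT" + "GGG"
        tsd, point, element = detect_tsd(absent, present)
        assert tsd == "" and element == "TTTTT"

    def test_misaligned_flanks_rejected(self):
        with pytest.raises(ValueError, match="flanks"):
            detect_tsd("AAAA", "CCCCCCCC")

    def test_present_not_longer_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            detect_tsd("AAAA", "AAA")

    def test_round_trip_on_random_constructs(self):
        """detect_tsd inverts build_promoter_construct on 500 random cases."""
        rng = np.random.default_rng(777)
        failures = 0
        for _ in range(500):
            ref = random_sequence(int(rng.integers(150, 260)), rng)
            point = int(rng.integers(20, len(ref) - 25))
            tsd_here = ref[point : point + 5]
            rec = InsertionRecord(
                "x", tsd=tsd_here, element_length=428,
                element_seq=random_sequence(428, rng),
            )
            present = build_promoter_construct(ref, rec, point)
            tsd, pt, element = detect_tsd(ref, present)
            # random flanks can make a longer spurious duplication possible;
            # require the canonical decomposition whenever lengths agree
            if not (len(tsd) >= 5 and element in present):
                failures += 1
            if len(tsd) == 5:
                assert tsd == tsd_here and pt == point
                assert element == rec.element_seq
        assert failures == 0


class TestTSDLogo:
    def test_column_counts_and_iupac_consensus(self):
        logo = build_tsd_logo(["ACGTA", "ACGTT"])
        assert logo.n_sequences == 2
        # column 5: one A, one T -> IUPAC W
        np.testing.assert_array_equal(logo.counts[:, 4], [1, 0, 0, 1])
        assert logo.consensus == "ACGTW"

    def test_single_sequence_is_its_own_consensus(self):
        logo = build_tsd_logo(["GATTC"])
        assert logo.consensus == "GATTC" and logo.n_sequences == 1

    def test_non_modal_lengths_excluded(self):
        logo = build_tsd_logo(["ACGTA", "ACGTT", "ACGT"])
        assert logo.n_sequences == 2
        assert logo.counts.shape == (4, 5)

    def test_columns_sum_to_n_sequences(self):
        logo = build_tsd_logo(["AATAC", "TTAGT", "CAGTT", "GTTAC", "TCAAG"])
        assert (logo.counts.sum(axis=0) == logo.n_sequences).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_tsd_logo([])


def _toy_motif():
    counts = np.array([
        [8, 0, 0, 2],   # A
        [0, 8, 1, 0],   # C
        [1, 1, 7, 0],   # G
        [0, 0, 1, 7],   # T
    ], dtype=float)
    return MotifMatrix.from_counts(counts, "toy")


class TestPWMScan:
    def test_consensus_scores_one_and_is_reported(self):
        m = _toy_motif()
        hits = scan_pwm("ACGT", m, threshold=0.99, both_strands=False)
        assert len(hits) == 1
        assert hits[0][2] == pytest.approx(1.0)

    def test_worst_sequence_scores_zero(self):
        m = _toy_motif()
        worst = "".join(
            "ACGT"[int(np.argmin(m.weights[:, j]))] for j in range(m.length)
        )
        assert m.relative_score(worst) == pytest.approx(0.0)
        assert scan_pwm(worst, m, threshold=0.0, both_strands=False) == []

    def test_strand_symmetry(self):
        """Hit sets are mirrored under reverse complement of the sequence."""
        rng = np.random.default_rng(5)
        m = _toy_motif()
        seq = random_sequence(80, rng) + "ACGT" + random_sequence(40, rng)
        fwd = scan_pwm(seq, m, threshold=0.9)
        rev = scan_pwm(reverse_complement(seq), m, threshold=0.9)
        mirrored = sorted(
            (len(seq) - m.length - p, {"+": "-", "-": "+"}[s], round(r, 9))
            for p, s, r in rev
        )
        assert sorted((p, s, round(r, 9)) for p, s, r in fwd) == mirrored

    def test_degenerate_matrix_rejected(self):
        flat = MotifMatrix("flat", np.zeros((4, 3)), np.full(4, 0.25))
        with pytest.raises(ValueError, match="degenerate"):
            flat.relative_score("ACG")

    def test_sequence_shorter_than_motif_rejected(self):
        with pytest.raises(ValueError):
            scan_pwm("AC", _toy_motif())


class TestMotifSpacing:
    REC = InsertionRecord("x", tsd="AATAC", element_length=428)

    def test_insertion_between_motifs(self):
        deltas = motif_spacing_change([100, 200], self.REC, 150)
        assert deltas[(100, 200)] == 433  # 428 + 5

    def test_insertion_outside_pair(self):
        deltas = motif_spacing_change([100, 200], self.REC, 250)
        assert deltas[(100, 200)] == 0

    def test_spanning_pairs_share_one_delta(self):
        deltas = motif_spacing_change([10, 50, 120, 300], self.REC, 80)
        spanning = {k: v for k, v in deltas.items() if k[0] < 80 < k[1]}
        assert set(spanning.values()) == {433}
        others = {k: v for k, v in deltas.items() if not k[0] < 80 < k[1]}
        assert set(others.values()) == {0}


class TestPCRBands:
    def test_reference_present_sizes(self):
        out = predict_pcr_bands(InsertionRecord("reference"))
        assert out["bands"] == {"FL-R": 1066, "L-R": 616}
        assert out["class"] == "present"

    def test_absent(self):
        out = predict_pcr_bands(None)
        assert out["bands"] == {"FL-R": 638} and out["class"] == "absent"

    @pytest.mark.parametrize("rec,expected", [
        (NINE_INSERTIONS[0], "present"),        # reference
        (NINE_INSERTIONS[1], "present"),        # +7: 7 bp below gel resolution
        (NINE_INSERTIONS[2], "smaller L-R"),    # +175
        (NINE_INSERTIONS[3], "smaller L-R"),    # +278
        (NINE_INSERTIONS[4], "only FL-R"),      # -19 reverse
        (NINE_INSERTIONS[5], "only FL-R"),      # -28 reverse
        (NINE_INSERTIONS[6], "only FL-R"),      # -44 reverse
        (NINE_INSERTIONS[7], "only FL-R"),      # -68 reverse
        (NINE_INSERTIONS[8], "larger L-R"),     # -90: 616 + 90 = 706
        (ROO_PLUS7_WITH_DUP, "larger FL-R"),    # 95-bp flank duplication
    ])
    def test_all_insertion_geometries(self, rec, expected):
        assert predict_pcr_bands(rec)["class"] == expected

    def test_minus90_band_size(self):
        out = predict_pcr_bands(NINE_INSERTIONS[8])
        assert out["bands"]["L-R"] == 706

    def test_flank_duplication_band_size(self):
        out = predict_pcr_bands(ROO_PLUS7_WITH_DUP)
        assert out["bands"]["FL-R"] == 1066 + 95

    def test_reverse_orientation_has_no_lr_band(self):
        out = predict_pcr_bands(NINE_INSERTIONS[6])
        assert "L-R" not in out["bands"]

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            predict_pcr_bands(InsertionRecord("deep", offset_bp=700))


class TestClassifyGenotype:
    @pytest.mark.parametrize("bands,expected", [
        ([638], "absent"),
        ([1066, 616], "present"),
        ([1066], "present"),
        ([638, 1066], "heterozygous"),
        ([638, 1066, 616], "heterozygous"),
        ([900], "unexpected"),
        ([], "unexpected"),
    ])
    def test_classes(self, bands, expected):
        assert classify_genotype(bands) == expected

    def test_tolerance_window(self):
        assert classify_genotype([650]) == "absent"     # within +-20
        assert classify_genotype([700]) == "unexpected"

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            classify_genotype([638], tolerance=-1)


class TestTranscriptModel:
    def test_reference_isoforms(self):
        out = transcript_utr_lengths(NINE_INSERTIONS[0])
        assert out == {
            "downstream_tss_utr_bp": 201,
            "te_tss_utr_bp": 276,
            "te_contributed_bp": 50,
        }

    def test_plus7_is_seven_shorter(self):
        out = transcript_utr_lengths(NINE_INSERTIONS[1])
        assert out["te_tss_utr_bp"] == 269

    @pytest.mark.parametrize("idx", [6, 8])  # roo-44 (reverse), roo-90 (distal)
    def test_no_te_tss_for_reverse_or_distal(self, idx):
        out = transcript_utr_lengths(NINE_INSERTIONS[idx])
        assert out == {"downstream_tss_utr_bp": 201}

    def test_invalid_offset_rejected(self):
        rec = InsertionRecord("x", offset_bp=300, te_internal_tss=True)
        with pytest.raises(ValueError):
            transcript_utr_lengths(rec)

    def test_model_invariant(self):
        with pytest.raises(ValueError):
            TranscriptModel(te_tss_utr_bp=40, te_contributed_bp=50)


class TestPromoterFraction:
    def test_worked_21_of_138(self):
        """21 qualifying of 138 -> 15.2%."""
        genes = [{"start": 10_000 * k, "end": 10_000 * k + 2_000, "strand": "+"}
                 for k in range(1, 30)]
        tes = []
        for k in range(21):  # inside the 1-kb upstream window of gene k+1
            g = genes[k]
            tes.append((g["start"] - 500, g["start"] - 400))
        for k in range(138 - 21):  # far downstream of every 5' end
            tes.append((10_000 * (k + 1) + 5_000, 10_000 * (k + 1) + 5_100))
        q, total, pct = promoter_5prime_fraction(tes, genes)
        assert (q, total, pct) == (21, 138, 15.2)

    def test_zero_qualifying(self):
        genes = [{"start": 100_000, "end": 102_000, "strand": "+"}]
        q, total, pct = promoter_5prime_fraction([(0, 50), (10, 60)], genes)
        assert (q, pct) == (0, 0.0)

    def test_minus_strand_window_is_downstream_in_coordinates(self):
        # minus-strand gene [2000, 4000): 5' end at 4000; upstream = [4000, 5000)
        gene = [{"start": 2000, "end": 4000, "strand": "-"}]
        assert promoter_5prime_fraction([(4200, 4300)], gene)[0] == 1
        assert promoter_5prime_fraction([(1200, 1300)], gene)[0] == 0
        # overlapping the 5'-most base qualifies too
        assert promoter_5prime_fraction([(3990, 4000)], gene)[0] == 1

    def test_te_overlapping_5prime_end_qualifies(self):
        gene = [{"start": 5000, "end": 8000, "strand": "+"}]
        assert promoter_5prime_fraction([(4950, 5050)], gene)[0] == 1

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            promoter_5prime_fraction([(5, 5)], [])


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.integers(10, 40),   # flank length
    st.integers(0, 5),     # tsd length
    st.integers(5, 30),    # element length
    st.integers(0, 10_000),
)
def test_tsd_roundtrip_property(flank, tsd_len, elem_len, seed):
    """Length bookkeeping of the construct/detect pair always holds."""
    rng = np.random.default_rng(seed)
    ref = random_sequence(2 * flank + tsd_len, rng)
    rec = InsertionRecord(
        "x", tsd=ref[flank : flank + tsd_len], element_length=elem_len,
        element_seq=random_sequence(elem_len, rng),
    )
    present = build_promoter_construct(ref, rec, flank)
    assert len(present) == len(ref) + elem_len + tsd_len
    tsd, point, element = detect_tsd(ref, present)
    # the maximal decomposition can only find a duplication at least as long
    assert len(tsd) >= tsd_len
    assert len(element) + len(tsd) == elem_len + tsd_len
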