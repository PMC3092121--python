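"""Prediction-to-truth distance, reciprocal classification, microhomology."""

from __future__ import annotations

import numpy as np
import pytest

from anchorpet.junctions import (
    JunctionPair,
    ReciprocalClass,
    classify_reciprocal,
    junction_microhomology,
    microhomology,
    prediction_distance,
)
from anchorpet.sequtils import random_dna
from anchorpet.simulate import (
    SimulationConfig,
    make_reference,
    plant_translocation,
)

# Predicted interval vs. validated flanking pair for every junction with an
# unambiguous nearest-boundary-gap distance (two cell lines, two patients,
# both fusion orientations where detected).
DISTANCE_CASES = [
    ((27_762, 27_909), (27_878, 27_879), 0),
    ((110_241, 110_242), (110_299, 110_300), 57),
    ((63_843, 63_853), (63_929, 63_930), 76),
    ((110_241, 110_242), (110_096, 110_097), 144),
    ((63_843, 63_853), (63_804, 63_805), 38),
    ((109_790, 109_830), (109_781, 109_782), 8),
    ((125_280, 125_623), (125_326, 125_327), 0),
    ((109_790, 109_830), (109_670, 109_671), 119),
    ((125_280, 125_623), (149_445, 149_446), 23_822),
    ((109_702, 109_867), (109_834, 109_835), 0),
    ((102_484, 102_653), (102_524, 102_525), 0),
    ((109_702, 109_867), (109_869, 109_870), 2),
    ((102_484, 102_653), (102_526, 102_527), 0),
]


class TestPredictionDistance:
    @pytest.mark.parametrize("prediction, actual, expected", DISTANCE_CASES)
    def test_validated_junction_distances(self, prediction, actual, expected):
        assert prediction_distance(prediction, actual) == expected

    def test_symmetric_under_coordinate_reflection(self):
        rng = np.random.default_rng(2)
        c = 1_000_000
        for _ in range(200):
            a = int(rng.integers(1, 900_000))
            b = a + int(rng.integers(0, 1_000))
            x = int(rng.integers(1, 999_000))
            forward = prediction_distance((a, b), (x, x + 1))
            reflected = prediction_distance((c - b, c - a), (c - x - 1, c - x))
            assert forward == reflected

    def test_malformed_inputs_rejected(self):
        with pytest.raises(ValueError):
            prediction_distance((10, 5), (7, 8))
        with pytest.raises(ValueError):
            prediction_distance((5, 10), (7, 9))


class TestClassifyReciprocal:
    def jp(self, fusion, c5, c3):
        return JunctionPair(fusion, (c5, c5 + 1), (c3 - 1, c3))

    def test_consecutive_coordinates_balanced(self):
        calls = classify_reciprocal(
            self.jp("A->B", 3_000, 90_001), self.jp("B->A", 90_000, 3_001)
        )
        assert all(c.classification is ReciprocalClass.BALANCED for c in calls)
        assert all(c.size == 0 for c in calls)

    def test_bcr_like_duplication_203bp(self):
        # BCR side retained to 110,299 in the forward fusion but already
        # restarting at 110,097 in the reciprocal: 203 bp in both derivatives
        calls = classify_reciprocal(
            self.jp("A->B", 110_299, 63_930), self.jp("B->A", 63_804, 110_097)
        )
        a_call, b_call = calls
        assert a_call.classification is ReciprocalClass.DUPLICATION
        assert a_call.size == 203
        assert b_call.classification is ReciprocalClass.DELETION
        assert b_call.size == 63_930 - 63_804 - 1  # 125 bp lost

    def test_bcr_like_deletion_35bp(self):
        calls = classify_reciprocal(
            self.jp("A->B", 109_834, 102_525), self.jp("B->A", 102_526, 109_870)
        )
        a_call, _ = calls
        assert a_call.classification is ReciprocalClass.DELETION
        assert a_call.size == 35

    def test_non_reciprocal_fusions_rejected(self):
        with pytest.raises(ValueError, match="reciprocal"):
            classify_reciprocal(
                self.jp("A->B", 10, 20), self.jp("A->B", 10, 20)
            )

    def test_out_of_locus_coordinates_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            classify_reciprocal(
                self.jp("A->B", 3_000, 90_001),
                self.jp("B->A", 90_000, 3_001),
                locus_lengths=(2_000, 100_000),
            )

    @pytest.mark.parametrize(
        "kwargs, expected_a, expected_b",
        [
            ({}, (ReciprocalClass.BALANCED, 0), (ReciprocalClass.BALANCED, 0)),
            ({"dup_a": 203}, (ReciprocalClass.DUPLICATION, 203),
             (ReciprocalClass.BALANCED, 0)),
            ({"del_b": 24_119}, (ReciprocalClass.BALANCED, 0),
             (ReciprocalClass.DELETION, 24_119)),
            ({"del_a": 35}, (ReciprocalClass.DELETION, 35),
             (ReciprocalClass.BALANCED, 0)),
            ({"dup_b": 76}, (ReciprocalClass.BALANCED, 0),
             (ReciprocalClass.DUPLICATION, 76)),
        ],
    )
    def test_recovers_planted_truth_exactly(self, kwargs, expected_a, expected_b):
        config = SimulationConfig(seed=6, **kwargs)
        loci = make_reference(config)
        _, _, truth = plant_translocation(loci, config)
        j_ab = JunctionPair(
            "locusA->locusB",
            (truth.junction_ab.five_last_retained,
             truth.junction_ab.five_last_retained + 1),
            (truth.junction_ab.three_first_retained - 1,
             truth.junction_ab.three_first_retained),
        )
        j_ba = JunctionPair(
            "locusB->locusA",
            (truth.junction_ba.five_last_retained,
             truth.junction_ba.five_last_retained + 1),
            (truth.junction_ba.three_first_retained - 1,
             truth.junction_ba.three_first_retained),
        )
        a_call, b_call = classify_reciprocal(j_ab, j_ba, config.locus_lengths)
        assert (a_call.classification, a_call.size) == expected_a
        assert (b_call.classification, b_call.size) == expected_b


def naive_microhomology(seq_5: str, seq_3: str, b5: int, b3: int) -> int:
    """Oracle: count every alternative junction placement that reproduces the
    fused sequence, sliding the break across both donors simultaneously."""
    fused = seq_5[:b5] + seq_3[b3 - 1 :]
    consistent = 0
    for t in range(-min(b5, b3 - 1), min(len(seq_5) - b5, len(seq_3) - b3 + 1) + 1):
        if seq_5[: b5 + t] + seq_3[b3 + t - 1 :] == fused:
            consistent += 1
    return consistent - 1  # the nominal placement itself always matches


class TestMicrohomology:
    def test_no_shared_flank_is_unambiguous(self):
        result = microhomology("GGGGAAAC", "TTTGCCCC", break_5=8, break_3=5)
        # 5' donor ends ...AAAC; 3' donor context ends ...TTTG before its
        # retained segment: no base can slide across the junction
        assert result.length == 0

    def test_planted_shared_pentamer(self):
        # GAGTG present at the end of the 5' retained segment and immediately
        # upstream of the 3' retained segment: junction slides over 5 bases
        seq_5 = "TTTTTGAGTGA"  # break after position 10 (…GAGTG|A)
        seq_3 = "CCGAGTGTTTT"  # retained from position 8 (CCGAGTG|TTTT)
        result = microhomology(seq_5, seq_3, break_5=10, break_3=8)
        assert result.length == 5
        assert result.sequence == "GAGTG"

    def test_identical_donors_flagged_degenerate(self):
        result = microhomology("AAAAAA", "AAAAAA", break_5=3, break_3=4)
        assert result.length == 6
        assert result.degenerate

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            microhomology("ACGU", "ACGT")

    def test_matches_bruteforce_slide_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            seq_5 = random_dna(100, rng)
            seq_3 = random_dna(100, rng)
            b5 = int(rng.integers(1, 100))
            b3 = int(rng.integers(2, 100))
            result = microhomology(seq_5, seq_3, break_5=b5, break_3=b3)
            assert result.length == naive_microhomology(seq_5, seq_3, b5, b3)

    def test_simulator_planted_homology_recovered_at_both_junctions(self):
        config = SimulationConfig(microhomology_len=5, seed=19)
        loci = make_reference(config)
        loci, _, truth = plant_translocation(loci, config)
        locus_a, locus_b = loci
        j1 = junction_microhomology(
            locus_a, locus_b,
            truth.junction_ab.five_last_retained,
            truth.junction_ab.three_first_retained,
        )
        j2 = junction_microhomology(
            locus_b, locus_a,
            truth.junction_ba.five_last_retained,
            truth.junction_ba.three_first_retained,
        )
        assert j1.length == 5 and j2.length == 5
        assert j1.sequence == truth.microhomology_seq == j2.sequence
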