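"""Vote zones, accumulation, and breakpoint calling."""

from __future__ import annotations

import numpy as np
import pytest

from anchorpet.align import MappedTag, TargetLocus
from anchorpet.breakpoints import (
    BreakpointPrediction,
    CallStatus,
    CallThresholds,
    VoteProfile,
    accumulate_votes,
    call_breakpoint,
    fusion_orientation,
    predict_all,
    vote_zones,
)
from anchorpet.junctions import prediction_distance
from anchorpet.petcall import ChromPET, FragmentLengthModel, PetClass
from anchorpet.pipeline import run_simulated_replicate
from anchorpet.simulate import SimulationConfig

MODEL = FragmentLengthModel(mean=500, sd=50, n=100)


def make_tag(start, strand="+", locus="locusA", read_id="r0", mate=1):
    return MappedTag(read_id, mate, locus, start, start + 37, strand)


def junctional_pet(read_id, start_a, strand_a, start_b, strand_b):
    return ChromPET(
        read_id,
        make_tag(start_a, strand_a, "locusA", read_id, 1),
        make_tag(start_b, strand_b, "locusB", read_id, 2),
        "s",
        PetClass.JUNCTIONAL,
    )


def naive_profile(tags, model, locus_length):
    """Oracle: recompute zones from the stated convention, position by
    position, without the difference-array machinery."""
    votes = np.zeros(locus_length, dtype=int)
    for tag in tags:
        s = tag.start if tag.strand == "+" else tag.end
        direction = 1 if tag.strand == "+" else -1
        spans = [
            (0, model.mean - 1, 3),
            (model.mean, model.mean + model.sd - 1, 2),
            (model.mean + model.sd, model.mean + 2 * model.sd - 1, 1),
        ]
        for lo, hi, weight in spans:
            for offset in range(lo, hi + 1):
                pos = s + direction * offset
                if 1 <= pos <= locus_length:
                    votes[pos - 1] += weight
    return votes


class TestVoteZones:
    def test_forward_zone_geometry_and_mass(self):
        zones = vote_zones(make_tag(100), MODEL, 10_000)
        assert [(z.start, z.end, z.weight) for z in zones] == [
            (100, 599, 3), (600, 649, 2), (650, 699, 1),
        ]
        mass = sum((z.end - z.start + 1) * z.weight for z in zones)
        assert mass == 3 * 500 + 2 * 50 + 1 * 50  # 1650

    def test_reverse_zones_mirror(self):
        tag = make_tag(963, strand="-")  # 5'-most base at 1000
        assert tag.five_prime() == 1000
        zones = vote_zones(tag, MODEL, 10_000)
        assert [(z.start, z.end, z.weight) for z in zones] == [
            (501, 1000, 3), (451, 500, 2), (401, 450, 1),
        ]

    def test_zones_clipped_at_locus_end(self):
        zones = vote_zones(make_tag(6_900), MODEL, 7_000)
        assert [(z.start, z.end, z.weight) for z in zones] == [(6_900, 7_000, 3)]

    def test_zero_sd_leaves_only_weight3_zone(self):
        model = FragmentLengthModel(mean=500, sd=0, n=10)
        zones = vote_zones(make_tag(100), model, 10_000)
        assert [(z.weight) for z in zones] == [3]


class TestAccumulateVotes:
    def locus(self, length=2_000):
        return TargetLocus("locusA", "A" * length)

    def pets(self, starts_strands):
        return [
            junctional_pet(f"r{i}", start, strand, 100, "-")
            for i, (start, strand) in enumerate(starts_strands)
        ]

    def test_single_tag_profile_equals_zones(self):
        locus = self.locus()
        profile = accumulate_votes(self.pets([(100, "+")]), locus, MODEL)
        expected = naive_profile([make_tag(100)], MODEL, 2_000)
        assert np.array_equal(profile.votes, expected)

    def test_two_identical_tags_double_the_profile(self):
        locus = self.locus()
        single = accumulate_votes(self.pets([(100, "+")]), locus, MODEL)
        double = accumulate_votes(self.pets([(100, "+"), (100, "+")]), locus, MODEL)
        assert np.array_equal(double.votes, 2 * single.votes)

    def test_matches_naive_recount_on_random_tags(self):
        rng = np.random.default_rng(21)
        locus = self.locus(3_000)
        starts_strands = [
            (int(rng.integers(1, 2_963)), rng.choice(["+", "-"]))
            for _ in range(20)
        ]
        profile = accumulate_votes(self.pets(starts_strands), locus, MODEL)
        tags = [make_tag(s, st) for s, st in starts_strands]
        assert np.array_equal(profile.votes, naive_profile(tags, MODEL, 3_000))

    def test_vote_conservation_after_clipping(self):
        rng = np.random.default_rng(22)
        locus = self.locus(1_200)  # small enough that zones clip
        starts_strands = [
            (int(rng.integers(1, 1_163)), rng.choice(["+", "-"]))
            for _ in range(15)
        ]
        profile = accumulate_votes(self.pets(starts_strands), locus, MODEL)
        expected_mass = 0
        for s, st in starts_strands:
            for z in vote_zones(make_tag(s, st), MODEL, 1_200):
                expected_mass += (z.end - z.start + 1) * z.weight
        assert profile.total_votes == expected_mass

    def test_pet_without_tag_on_locus_is_an_error(self):
        pet = junctional_pet("r0", 100, "+", 100, "-")
        with pytest.raises(ValueError, match="locusC"):
            accumulate_votes([pet], TargetLocus("locusC", "A" * 100), MODEL)


class TestCallBreakpoint:
    def test_overlapping_weight3_zones_called_at_their_intersection(self):
        starts = [1_000 + 50 * i for i in range(9)] + [1_440]
        locus = TargetLocus("locusA", "A" * 3_000)
        pets = [
            junctional_pet(f"r{i}", s, "+", 100, "-") for i, s in enumerate(starts)
        ]
        profile = accumulate_votes(pets, locus, MODEL)
        pred = call_breakpoint(profile, len(pets), MODEL)
        assert pred.status is CallStatus.CALLED
        assert pred.interval == (1_440, 1_499)  # [max start, min start + mean - 1]
        assert pred.max_vote == 30
        # oracle: argmax of the naive recount
        naive = naive_profile([make_tag(s) for s in starts], MODEL, 3_000)
        run = np.nonzero(naive == naive.max())[0]
        assert (run[0] + 1, run[-1] + 1) == pred.interval

    def test_sparse_disjoint_votes_no_call(self):
        locus = TargetLocus("locusA", "A" * 5_000)
        pets = [
            junctional_pet("r0", 100, "+", 100, "-"),
            junctional_pet("r1", 4_000, "+", 100, "-"),
        ]
        profile = accumulate_votes(pets, locus, MODEL)
        pred = call_breakpoint(profile, 2, MODEL)
        assert pred.status is CallStatus.NO_CALL
        assert pred.max_vote < 9

    def test_two_tied_peaks_ambiguous(self):
        locus = TargetLocus("locusA", "A" * 8_000)
        pets = [
            junctional_pet(f"a{i}", 1_000, "+", 100, "-") for i in range(5)
        ] + [junctional_pet(f"b{i}", 5_000, "+", 100, "-") for i in range(5)]
        profile = accumulate_votes(pets, locus, MODEL)
        pred = call_breakpoint(profile, 10, MODEL)
        assert pred.status is CallStatus.AMBIGUOUS

    def test_strong_secondary_peak_ambiguous(self):
        locus = TargetLocus("locusA", "A" * 8_000)
        pets = [
            junctional_pet(f"a{i}", 1_000, "+", 100, "-") for i in range(10)
        ] + [junctional_pet(f"b{i}", 5_000, "+", 100, "-") for i in range(8)]
        profile = accumulate_votes(pets, locus, MODEL)
        pred = call_breakpoint(profile, 18, MODEL)
        # secondary run carries 24 votes = 0.8 of the 30-vote maximum
        assert pred.status is CallStatus.AMBIGUOUS

    def test_wide_flat_maximum_no_call(self):
        votes = np.zeros(3_000, dtype=np.int64)
        votes[1_000:1_700] = 9  # 700-bp plateau > mean + 2 sd = 600
        pred = call_breakpoint(VoteProfile("locusA", votes), 3, MODEL)
        assert pred.status is CallStatus.NO_CALL

    def test_empty_profile_no_call_zero_support(self):
        pred = call_breakpoint(
            VoteProfile("locusA", np.zeros(100, dtype=np.int64)), 0, MODEL
        )
        assert pred.status is CallStatus.NO_CALL and pred.support == 0

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            CallThresholds(min_vote=0)


class TestFusionOrientation:
    def test_plus_tag_marks_five_prime_donor(self):
        pet = junctional_pet("r0", 100, "+", 200, "-")
        assert fusion_orientation(pet, ["locusA", "locusB"]) == "locusA->locusB"
        pet = junctional_pet("r1", 100, "-", 200, "+")
        assert fusion_orientation(pet, ["locusA", "locusB"]) == "locusB->locusA"

    def test_same_strand_pair_has_no_orientation(self):
        pet = junctional_pet("r0", 100, "+", 200, "+")
        assert fusion_orientation(pet, ["locusA", "locusB"]) is None


class TestPredictAll:
    def test_reciprocal_simulation_called_on_both_orientations(self):
        config = SimulationConfig(
            locus_lengths=(7_000, 30_000), breakpoint_b=15_000,
            n_pairs=3_000, seed=17,
        )
        result = run_simulated_replicate(config, seed=17, min_junctional=20)
        truth = result.sample.truth
        preds = result.run.predictions["sample1"]
        ab, ba = preds["locusA->locusB"], preds["locusB->locusA"]
        for pred, junction in (
            (ab["locusA"], truth.junction_ab.five_last_retained),
            (ab["locusB"], truth.junction_ab.three_first_retained - 1),
            (ba["locusB"], truth.junction_ba.five_last_retained),
            (ba["locusA"], truth.junction_ba.three_first_retained - 1),
        ):
            assert pred.status is CallStatus.CALLED
            # within the worst error observed on validated junctions
            assert prediction_distance(pred.interval, (junction, junction + 1)) <= 144

    def test_single_orientation_leaves_other_no_call(self):
        loci = [TargetLocus("locusA", "A" * 3_000), TargetLocus("locusB", "A" * 3_000)]
        pets = [junctional_pet(f"r{i}", 1_000, "+", 500, "-") for i in range(4)]
        preds = predict_all(pets, loci, MODEL)
        assert preds["locusA->locusB"]["locusA"].status is CallStatus.CALLED
        assert preds["locusB->locusA"]["locusA"].status is CallStatus.NO_CALL
        assert preds["locusB->locusA"]["locusA"].support == 0

    def test_consistent_extra_evidence_does_not_worsen_calls(self):
        """Adding a junction-consistent chromPET moves the called interval
        closer to (or at most one SD away from) the truth, never far off."""
        rng = np.random.default_rng(33)
        locus = TargetLocus("locusA", "A" * 8_000)
        junction = 4_000
        worsenings = []
        for _ in range(30):
            n = int(rng.integers(3, 8))
            starts = [
                int(rng.integers(junction - 450, junction - 37)) for _ in range(n)
            ]
            pets = [
                junctional_pet(f"r{i}", s, "+", 100, "-")
                for i, s in enumerate(starts)
            ]
            extra = junctional_pet(
                "extra", int(rng.integers(junction - 450, junction - 37)), "+",
                100, "-",
            )
            before = call_breakpoint(
                accumulate_votes(pets, locus, MODEL), n, MODEL
            )
            after = call_breakpoint(
                accumulate_votes(pets + [extra], locus, MODEL), n + 1, MODEL
            )
            if (
                before.status is CallStatus.CALLED
                and after.status is CallStatus.CALLED
            ):
                d_before = prediction_distance(before.interval, (junction, junction + 1))
                d_after = prediction_distance(after.interval, (junction, junction + 1))
                worsenings.append(d_after - d_before)
        assert worsenings, "no comparable trials"
        assert max(worsenings) <= MODEL.sd
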