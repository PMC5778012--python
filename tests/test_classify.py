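"""Read-pair categorisation into F1/F2/F3/F4 and the F2a derivation."""

import numpy as np
import pytest

from telopair import (
    ErrorProfile,
    ReadPairCounts,
    classify_pair,
    count_pairs,
    extract_telbam,
    is_fully_telomeric,
    profile_telbam,
)
from telopair.classify import ORIENT_C, ORIENT_G, compute_read_stats
from telopair.telbam import iter_read_pairs, reverse_complement

from conftest import make_read, write_pairs_bam

RANDOM = "ACGATCGTAGCATGCATCGATCGATGCTAGCTACGATCGTAGCTAGCATCGATGCATGCATCGATCGTACGATCGATGCATGCATACGATCGATTACGAT"
PURE_C = ("CCCTAA" * 17)[:100]
PURE_G = ("TTAGGG" * 17)[:100]


def _mask(p: int, L: int, cells=()) -> ErrorProfile:
    E = np.zeros((p + 1, L + 1), dtype=bool)
    for i, j in cells:
        E[i, j] = True
    return ErrorProfile(E=E, k=0, p_min=0, p_max=p)


class TestIsFullyTelomeric:
    def test_pure_repeat_is_complete(self):
        complete, orientation = is_fully_telomeric(make_read(PURE_G), None)
        assert complete and orientation == ORIENT_G
        complete, orientation = is_fully_telomeric(make_read(PURE_C), None)
        assert complete and orientation == ORIENT_C

    def test_degraded_read_rescued_only_inside_mask(self):
        # 15 scattered substitutions -> 85% telomere, fails the 90% rule
        seq = list(PURE_C)
        rng = np.random.default_rng(5)
        loci = rng.choice(100, size=15, replace=False)
        for i in loci:
            seq[i] = {"C": "G", "T": "A", "A": "T"}[seq[i]]
        read = make_read("".join(seq), 20)
        stats = compute_read_stats(read, p_min=2)
        assert stats.frac_telomere < 0.90 and stats.z >= 15

        inside = _mask(40, 100, cells=[(stats.lam, stats.z)])
        outside = _mask(40, 100)
        assert is_fully_telomeric(read, inside, p_min=2)[0]
        assert not is_fully_telomeric(read, outside, p_min=2)[0]

    def test_ninety_percent_threshold_is_boundary(self):
        # C can never match TTAGGG, so the tail is exactly 10 mismatches:
        # 90% telomere is still complete, one more mismatch is not
        read = make_read(PURE_G[:90] + "C" * 10)
        stats = compute_read_stats(read, p_min=0)
        assert stats.z == 10
        assert is_fully_telomeric(read, None)[0]
        read11 = make_read(PURE_G[:89] + "C" * 11)
        assert not is_fully_telomeric(read11, None)[0]


class TestClassifyPair:
    @pytest.mark.parametrize(
        "r1, r2, expected",
        [
            (PURE_G, PURE_C, "F1"),
            (PURE_C, RANDOM, "F2"),
            (PURE_G, RANDOM, "F4"),
            (RANDOM, RANDOM[::-1], "F3"),
        ],
        ids=["both-complete", "cstrand-complete", "gstrand-complete", "neither"],
    )
    def test_categories(self, r1, r2, expected):
        assert classify_pair(make_read(r1), make_read(r2)) == expected

    def test_tied_orientation_falls_back_to_f3(self):
        balanced = "TTAGGG" * 8 + "CCCTAA" * 8 + "TTAG"
        stats = compute_read_stats(make_read(balanced), 0)
        assert classify_pair(make_read(balanced), make_read(RANDOM)) == "F3"

    def test_orientation_symmetry_f2_f4_swap(self):
        """Reverse-complementing both mates and swapping them maps F2<->F4."""
        pairs = [
            (make_read(PURE_C), make_read(RANDOM)),
            (make_read(PURE_G), make_read(RANDOM)),
            (make_read(PURE_G), make_read(PURE_C)),
            (make_read(RANDOM), make_read(RANDOM[::-1])),
        ]
        swap = {"F2": "F4", "F4": "F2", "F1": "F1", "F3": "F3"}
        for r1, r2 in pairs:
            forward = classify_pair(r1, r2)
            flipped = classify_pair(
                make_read(reverse_complement(r2.sequence)),
                make_read(reverse_complement(r1.sequence)),
            )
            assert flipped == swap[forward]


class TestCountPairs:
    def test_f2a_subtraction(self):
        counts = ReadPairCounts(f1=0, f2=100, f3=0, f4=7)
        assert counts.f2a == 93

    def test_negative_f2a_clamped_with_warning(self, caplog):
        counts = ReadPairCounts(f1=0, f2=3, f3=0, f4=9, sample_id="noisy")
        with caplog.at_level("WARNING"):
            assert counts.f2a == 0
        assert "clamping" in caplog.text

    def test_category_total_equals_pair_count(self, telomere_sample):
        _, bam, truth = telomere_sample
        handle = extract_telbam(bam)
        profile = profile_telbam(handle.path, seed=0)
        assert profile.counts.total == handle.pair_count

    def test_classification_matches_generator_truth_without_error(self, telomere_sample):
        """With error injection off, classification must agree with the
        generator's per-read ground truth (boundary shifted by the 10%
        completeness allowance)."""
        spec, bam, truth = telomere_sample
        handle = extract_telbam(bam)
        L = spec.read_length
        slack = L // 10  # reads ≥90% inside count as complete
        n_ambiguous = n_checked = 0
        for r1, r2 in iter_read_pairs(handle.path):
            _, _, _, start, insert = r1.query_name.split(":")
            start, insert = int(start), int(insert)
            # bases of each read lying beyond the telomere tract
            outside = [
                max(start + L - truth.tl_bp, 0),
                max(start + insert - truth.tl_bp, 0),
            ]
            # near the 90% threshold, chance matches of subtelomere bases
            # to the repeat legitimately flip completeness; skip that window
            if any(slack < o < 4 * slack for o in outside):
                n_ambiguous += 1
                continue
            complete = [o <= slack for o in outside]
            expected = {2: "F1", 1: "F2", 0: "F3"}[sum(complete)]
            assert classify_pair(r1, r2, None) == expected
            n_checked += 1
        assert n_checked > 100
        assert n_ambiguous < 0.05 * (n_checked + n_ambiguous)

    def test_itr_f4_matches_f2_on_itr_only_sample(self, itr_only_sample):
        """An ITR has two boundaries: its CCCTAA-complete and TTAGGG-complete
        pair counts are exchangeable draws of the same window."""
        _, bam, truth = itr_only_sample
        handle = extract_telbam(bam)
        profile = profile_telbam(handle.path, seed=0)
        assert truth.itr_f2b > 0 and truth.itr_f4 > 0
        assert profile.counts.f2 > 0 and profile.counts.f4 > 0
        # symmetric windows: the two counts agree within sampling error
        diff = abs(profile.counts.f2 - profile.counts.f4)
        assert diff <= 4 * np.sqrt(profile.counts.f2 + profile.counts.f4)
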