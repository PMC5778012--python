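"""Fragmentary alignment, joint Phred/mismatch matrices and the error mask."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telopair import (
    build_error_mask,
    build_joint_matrices,
    find_mismatching_loci,
    summarize_read,
)
from telopair.error_profile import MismatchVector

from conftest import make_read


def brute_force_best_offset(seq: str, unit: str = "TTAGGG") -> int:
    """Minimum Hamming distance over all phase alignments of the full read."""
    L = len(seq)
    return min(
        sum(seq[i] != unit[(i + o) % len(unit)] for i in range(L))
        for o in range(len(unit))
    )


class TestFindMismatchingLoci:
    def test_perfect_repeat_has_no_divergence(self):
        for unit in ("TTAGGG", "CCCTAA"):
            read = make_read((unit * 17)[:100])
            assert find_mismatching_loci(read).z == 0

    def test_single_substitution_marks_exactly_that_locus(self):
        read = make_read("TTAGGGTTAGGGTTCGGGTTAGGG")
        mv = find_mismatching_loci(read)
        assert list(np.nonzero(mv.m)[0]) == [14]
        # cross-check: full-read best-phase alignment also finds one divergence
        assert brute_force_best_offset(read.sequence) == 1

    def test_deletion_marks_lowest_phred_junction_locus(self):
        # one base deleted from the first repeat; junction loci 4 and 5
        phred = np.full(23, 30)
        phred[5] = 12
        mv = find_mismatching_loci(make_read("TTAGGTTAGGGTTAGGGTTAGGG", phred))
        assert list(np.nonzero(mv.m)[0]) == [5]
        # with the Phreds swapped the other junction locus is chosen
        phred2 = np.full(23, 30)
        phred2[4] = 12
        mv2 = find_mismatching_loci(make_read("TTAGGTTAGGGTTAGGGTTAGGG", phred2))
        assert list(np.nonzero(mv2.m)[0]) == [4]

    def test_read_shorter_than_hexamer_all_mismatching(self):
        assert find_mismatching_loci(make_read("TTAGG")).z == 5

    def test_n_bases_never_match(self):
        read = make_read("TTAGGGTTAGGGNTTAGGGTTAGGGTT")
        mv = find_mismatching_loci(read)
        assert mv.m[12] == 1
        assert mv.z == 1

    def test_random_read_divergence_tops_out_near_three_quarters(self):
        """Non-telomere reads match the repeat ~25% by chance, so the
        mismatch count's upper tail sits near 0.75·L."""
        rng = np.random.default_rng(42)
        zs = [
            find_mismatching_loci(
                make_read("".join(rng.choice(list("ACGT"), 100)))
            ).z
            for _ in range(300)
        ]
        p95 = float(np.percentile(zs, 95))
        assert 70 <= p95 <= 80
        assert np.mean(zs) < p95

    @given(st.integers(0, 5), st.integers(6, 40))
    @settings(max_examples=30, deadline=None)
    def test_rotated_perfect_repeat_is_clean(self, phase, length):
        tandem = "TTAGGG" * 9
        seq = tandem[phase : phase + length]
        assert find_mismatching_loci(make_read(seq)).z == 0

    @given(st.text(alphabet="ACGTN", min_size=6, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_mismatch_vector_is_binary_and_bounded(self, seq):
        mv = find_mismatching_loci(make_read(seq))
        assert set(np.unique(mv.m)) <= {0, 1}
        assert 0 <= mv.z <= len(seq)


class TestSummarizeRead:
    def test_hand_evaluated_example(self):
        s = summarize_read(
            MismatchVector(np.array([0, 0, 1, 0, 1])), [30, 30, 20, 30, 40], p_min=2
        )
        assert (s.z, s.lam) == (2, 28)

    def test_all_mismatching_constant_phred(self):
        L, P, p_min = 10, 31, 4
        s = summarize_read(MismatchVector(np.ones(L)), [P] * L, p_min)
        assert (s.z, s.lam) == (L, P - p_min)

    def test_lower_bound_of_lam(self):
        m = np.zeros(5)
        m[0] = 1
        s = summarize_read(MismatchVector(m), [2, 30, 30, 30, 30], p_min=2)
        assert (s.z, s.lam) == (1, 0)

    def test_zero_mismatch_read_is_excluded(self):
        with pytest.raises(ValueError, match="no mismatching loci"):
            summarize_read(MismatchVector(np.zeros(5)), [30] * 5, 2)


class TestJointMatrices:
    def test_identical_reads_fill_single_cell(self):
        # ten reads, each z = 1, lam = 5
        summaries = [(1, 5, np.full(20, 30))] * 10
        X, Y = build_joint_matrices(
            [], seed=0, p_min=0, p_max=40, read_length=20, summaries=summaries
        )
        assert X[5, 1] == 10
        assert X.sum() == 10
        assert Y.sum() == 10

    def test_conservation_sum_x_equals_sum_y(self):
        rng = np.random.default_rng(3)
        reads = [
            make_read(
                "".join(rng.choice(list("ACGT"), 60)),
                rng.integers(2, 40, 60),
            )
            for _ in range(50)
        ]
        X, Y = build_joint_matrices(reads, seed=1)
        assert X.sum() == Y.sum() == 50  # every random read diverges somewhere

    def test_hand_tallied_cells_with_seeded_random_loci(self):
        phred = np.array([10, 10, 10, 30, 30, 30, 30, 30, 30, 30])
        summaries = [(2, 10 - 5, phred), (3, 10 - 5, phred)]
        X, Y = build_joint_matrices(
            [], seed=7, p_min=5, p_max=35, read_length=10, summaries=summaries
        )
        assert X[5, 2] == 1 and X[5, 3] == 1
        # reproduce Y's sampled loci with the same seed
        rng = np.random.default_rng(7)
        for z in (2, 3):
            loci = rng.choice(10, size=z, replace=False)
            mu = int(np.floor(phred[loci].sum() / z)) - 5
            assert Y[mu, z] >= 1
        assert Y.sum() == 2


class TestErrorMask:
    def test_x_equals_y_gives_empty_mask(self):
        X = np.random.default_rng(0).integers(0, 5, size=(21, 41))
        profile = build_error_mask(X, X.copy())
        assert profile.k >= 0
        assert not profile.E.any()

    def test_threshold_is_quadrant_maximum(self):
        # quadrant (i in (p/2, p], j in (L/2, L]) holds values ≤ 2;
        # a low-Phred cell exceeding k must enter the raw mask
        p, L = 20, 40
        X = np.zeros((p + 1, L + 1), dtype=int)
        Y = np.zeros_like(X)
        X[p, L] = 2  # quadrant cell -> k = 2
        X[0, 1] = 10
        X[0, 2] = 9
        X[1, 1] = 8
        X[1, 2] = 7  # block of excess cells at low Phred, low z
        profile = build_error_mask(X, Y)
        assert profile.k == 2
        assert profile.E[0, 1] and profile.E[1, 2]
        assert not profile.E[p, L]

    def test_isolated_high_phred_cells_removed(self):
        p, L = 20, 40
        X = np.zeros((p + 1, L + 1), dtype=int)
        Y = np.zeros_like(X)
        X[0, 1] = 10
        X[1, 1] = 10  # anchored 2-cell component at low Phred
        X[15, 10] = 10  # isolated mid-matrix cell outside the k quadrant
        profile = build_error_mask(X, Y)
        assert profile.E[0, 1] and profile.E[1, 1]
        assert not profile.E[15, 10]

    def test_low_phred_fill_is_monotone(self):
        """Every positive-excess low-Phred cell left of a masked column is set."""
        rng = np.random.default_rng(11)
        X = rng.integers(0, 6, size=(25, 50))
        Y = rng.integers(0, 6, size=(25, 50))
        X[:4, :12] += 8  # strong low-Phred excess block
        profile = build_error_mask(X, Y)
        D = X - Y
        r = (X.shape[0] - 1) // 4
        low_cols = np.nonzero(profile.E[: r + 1].any(axis=0))[0]
        assert low_cols.size
        jmax = low_cols.max()
        fill_region = (D[: r + 1, : jmax + 1] > 0)
        assert np.all(profile.E[: r + 1, : jmax + 1][fill_region])

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            build_error_mask(np.zeros((3, 3)), np.zeros((4, 3)))

    def test_null_random_mismatches_leave_mask_nearly_empty(self):
        """If 'mismatches' are themselves random loci, X and Y are exchangeable
        and the thresholded excess survives refinement almost nowhere."""
        rng = np.random.default_rng(99)
        p_min, p_max, L = 2, 40, 60
        fractions = []
        for _ in range(5):
            summaries = []
            for _ in range(400):
                phred = rng.integers(p_min, p_max + 1, L)
                z = int(rng.integers(1, L))
                loci = rng.choice(L, size=z, replace=False)
                lam = int(np.floor(phred[loci].sum() / z)) - p_min
                summaries.append((z, lam, phred))
            X, Y = build_joint_matrices(
                [], seed=int(rng.integers(2**31)), p_min=p_min, p_max=p_max,
                read_length=L, summaries=summaries,
            )
            profile = build_error_mask(X, Y)
            fractions.append(profile.E.mean())
        assert np.mean(fractions) < 0.02
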