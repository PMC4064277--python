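import numpy as np
import pytest

from runalign import AlignOp, InputError
from runalign.consistency import (
    ConservedElement,
    MatchMatrix,
    agreement_histogram,
    agreement_profile,
    build_match_matrix,
    elements_to_bed,
    find_conserved_elements,
    kmer_frequencies,
    restrict_to_common_regions,
    summarize_methods,
)
from runalign.engine import AlignmentResult
from runalign.seqio import SequenceRecord


def make_result(ops, t_start=0):
    """Minimal AlignmentResult for mask-building tests."""
    t_len = sum(l for op, l in ops
                if op in (AlignOp.MATCH, AlignOp.MISMATCH, AlignOp.INSERT_QUERY_GAP))
    q_len = sum(l for op, l in ops
                if op in (AlignOp.MATCH, AlignOp.MISMATCH, AlignOp.INSERT_TARGET_GAP))
    return AlignmentResult(
        score=0, target_interval=(t_start, t_start + t_len),
        query_interval=(0, q_len), operations=tuple(ops),
        aligned_target="", aligned_query="", max_contiguity=0, identity=0.0,
    )


def matrix_from_profiles(matched_rows, covered_rows, ref_id="ref"):
    matched = np.array(matched_rows, dtype=bool)
    covered = np.array(covered_rows, dtype=bool)
    ids = [f"g{i}" for i in range(matched.shape[0])]
    return MatchMatrix(ref_id, matched.shape[1], ids, matched, covered)


REF6 = SequenceRecord("ref", "", "ACGTAC")


class TestBuildMatchMatrix:
    def test_pure_match_block(self):
        mm = build_match_matrix(REF6, [("g0", make_result([(AlignOp.MATCH, 4)]), None)])
        assert mm.matched[0].tolist() == [1, 1, 1, 1, 0, 0]
        assert mm.covered[0].tolist() == [1, 1, 1, 1, 0, 0]

    def test_mismatch_covers_without_matching(self):
        ops = [(AlignOp.MATCH, 2), (AlignOp.MISMATCH, 1), (AlignOp.MATCH, 1)]
        mm = build_match_matrix(REF6, [("g0", make_result(ops), None)])
        assert mm.matched[0, :4].tolist() == [1, 1, 0, 1]
        assert mm.covered[0, :4].tolist() == [1, 1, 1, 1]

    def test_deletion_in_genome_covers_gapped_positions(self):
        ops = [(AlignOp.MATCH, 2), (AlignOp.INSERT_QUERY_GAP, 2), (AlignOp.MATCH, 2)]
        mm = build_match_matrix(REF6, [("g0", make_result(ops), None)])
        assert mm.covered[0].tolist() == [1, 1, 1, 1, 1, 1]
        assert mm.matched[0].tolist() == [1, 1, 0, 0, 1, 1]

    def test_insertion_in_genome_consumes_no_reference(self):
        ops = [(AlignOp.MATCH, 2), (AlignOp.INSERT_TARGET_GAP, 3), (AlignOp.MATCH, 2)]
        mm = build_match_matrix(REF6, [("g0", make_result(ops), None)])
        assert mm.covered[0].tolist() == [1, 1, 1, 1, 0, 0]

    def test_duplicate_genome_rejected(self):
        r = make_result([(AlignOp.MATCH, 2)])
        with pytest.raises(InputError, match="duplicate"):
            build_match_matrix(REF6, [("g0", r, None), ("g0", r, None)])

    def test_interval_overflow_rejected(self):
        r = make_result([(AlignOp.MATCH, 5)], t_start=3)
        with pytest.raises(InputError, match="exceeds"):
            build_match_matrix(REF6, [("g0", r, None)])


class TestAgreementProfile:
    def test_full_agreement(self):
        mm = matrix_from_profiles([[1, 1], [1, 1]], [[1, 1], [1, 1]])
        assert agreement_profile(mm).tolist() == [1.0, 1.0]

    def test_covered_denominator_ignores_uncovering_genomes(self):
        mm = matrix_from_profiles([[1, 0], [0, 0]], [[1, 0], [1, 0]])
        prof = agreement_profile(mm, "covered_genomes")
        assert prof[0] == 0.5
        assert np.isnan(prof[1])

    def test_all_genomes_denominator(self):
        mm = matrix_from_profiles([[1, 0], [0, 0]], [[1, 0], [1, 0]])
        assert agreement_profile(mm, "all_genomes").tolist() == [0.5, 0.0]


class TestAgreementHistogram:
    def test_identical_baseline_gives_zero_differences(self):
        mm = matrix_from_profiles([[1, 0, 1]], [[1, 1, 1]])
        _, diff = agreement_histogram(mm, bins=5, baseline=mm)
        assert np.allclose(diff, 0)

    def test_uniform_full_agreement_masses_top_bin(self):
        mm = matrix_from_profiles([[1, 1, 1]], [[1, 1, 1]])
        _, vals = agreement_histogram(mm, bins=10)
        assert vals[-1] == 1.0 and vals[:-1].sum() == 0

    def test_normalisation_sums_to_one(self):
        mm = matrix_from_profiles(
            [[1, 0, 1, 1], [1, 1, 0, 0]], [[1, 1, 1, 1], [1, 1, 1, 0]]
        )
        _, vals = agreement_histogram(mm, bins=4)
        assert vals.sum() == pytest.approx(1.0)

    def test_mismatched_positions_rejected(self):
        a = matrix_from_profiles([[1, 1]], [[1, 1]])
        b = matrix_from_profiles([[1]], [[1]])
        with pytest.raises(ValueError):
            agreement_histogram(a, bins=4, baseline=b)


class TestConservedElements:
    def run_scan(self, fractions, min_len=6, min_frac=0.9):
        """Build a 10-genome matrix realizing the given agreement fractions."""
        g = 10
        matched = np.zeros((g, len(fractions)), dtype=bool)
        covered = np.ones((g, len(fractions)), dtype=bool)
        for p, f in enumerate(fractions):
            matched[: round(f * g), p] = True
        mm = matrix_from_profiles(matched, covered)
        return find_conserved_elements(mm, min_len=min_len, min_frac=min_frac)

    def test_plain_run_scan(self):
        els = self.run_scan([1, 1, 1, 1, 1, 1, 0.5, 0.5])
        assert [el.interval for el in els] == [(0, 6)]
        assert els[0].length == 6

    def test_below_threshold_everywhere(self):
        assert self.run_scan([0.8] * 10) == []

    def test_boundary_equal_position_merges_runs(self):
        els = self.run_scan([1] * 5 + [0.9] + [1] * 5)
        assert [el.interval for el in els] == [(0, 11)]
        assert els[0].min_agreement == pytest.approx(0.9)

    def test_uncovered_positions_break_runs(self):
        g = 10
        matched = np.ones((g, 13), dtype=bool)
        covered = np.ones((g, 13), dtype=bool)
        matched[:, 6] = False
        covered[:, 6] = False
        mm = matrix_from_profiles(matched, covered)
        els = find_conserved_elements(mm, min_len=6, min_frac=0.9)
        assert [el.interval for el in els] == [(0, 6), (7, 13)]

    def test_counts_non_increasing_in_thresholds(self):
        fracs = [1, 1, 0.9, 1, 1, 1, 1, 0.8, 1, 1, 1, 1, 1, 0.95]
        for tighter, looser in [((6, 0.95), (6, 0.9)), ((8, 0.9), (6, 0.9))]:
            e_tight = self.run_scan(fracs, min_len=tighter[0], min_frac=tighter[1])
            e_loose = self.run_scan(fracs, min_len=looser[0], min_frac=looser[1])
            assert len(e_tight) <= len(e_loose)
            assert sum(e.length for e in e_tight) <= sum(e.length for e in e_loose)

    def test_bed_rendering(self):
        els = [ConservedElement((2, 8), 6, 0.95)]
        bed = elements_to_bed(els, "chrX")
        assert bed == "chrX\t2\t8\telement_0\t0.950\n"


class TestKmerFrequencies:
    def test_exact_motif_window(self):
        els = [ConservedElement((0, 6), 6, 1.0)]
        assert kmer_frequencies("AATAAA", els, 6) == {"AATAAA": 1}

    def test_sliding_windows_overlap(self):
        els = [ConservedElement((0, 8), 8, 1.0)]
        counts = kmer_frequencies("AATAATAA", els, 5)
        assert counts == {"AATAA": 2, "ATAAT": 1, "TAATA": 1}

    def test_window_count_equals_length_minus_k_plus_one(self):
        els = [ConservedElement((0, 7), 7, 1.0)]
        counts = kmer_frequencies("AATAAAA", els, 6)
        assert sum(counts.values()) == 2
        assert counts == {"AATAAA": 1, "ATAAAA": 1}

    def test_short_elements_contribute_nothing(self):
        els = [ConservedElement((0, 5), 5, 1.0)]
        assert kmer_frequencies("AATAA", els, 6) == {}


class TestCommonRegionRestriction:
    def two_methods(self):
        a = matrix_from_profiles([[1, 1, 1, 0]], [[1, 1, 1, 1]])
        b = matrix_from_profiles([[0, 1, 1, 1]], [[0, 1, 1, 1]])
        return {"A": a, "B": b}

    def test_coverage_intersected(self):
        out = restrict_to_common_regions(self.two_methods())
        assert out["A"].covered[0].tolist() == [0, 1, 1, 1]
        assert out["A"].matched[0].tolist() == [0, 1, 1, 0]

    def test_idempotent(self):
        once = restrict_to_common_regions(self.two_methods())
        twice = restrict_to_common_regions(once)
        for k in once:
            assert np.array_equal(once[k].covered, twice[k].covered)
            assert np.array_equal(once[k].matched, twice[k].matched)

    def test_symmetric_in_method_order(self):
        fwd = restrict_to_common_regions(self.two_methods())
        rev = restrict_to_common_regions(dict(reversed(self.two_methods().items())))
        assert np.array_equal(fwd["A"].covered, rev["A"].covered)

    def test_different_genome_sets_rejected(self):
        a = matrix_from_profiles([[1, 1]], [[1, 1]])
        b = MatchMatrix("ref", 2, ["other"], np.ones((1, 2), bool), np.ones((1, 2), bool))
        with pytest.raises(InputError):
            restrict_to_common_regions({"A": a, "B": b})


class TestSummarizeMethods:
    def test_identical_methods_identical_rows(self):
        mm = matrix_from_profiles([[1] * 8], [[1] * 8])
        ref = SequenceRecord("ref", "", "AATAAAGG")
        table = summarize_methods({"A": [mm], "B": [mm]}, [ref])
        rows = table.set_index("method")
        assert (rows.loc["A"] == rows.loc["B"]).all()
        assert rows.loc["A", "focal_kmer_count"] == 1

    def test_extra_match_inside_common_coverage_counts(self):
        base = matrix_from_profiles([[1, 1, 0, 1]], [[1, 1, 1, 1]])
        better = matrix_from_profiles([[1, 1, 1, 1]], [[1, 1, 1, 1]])
        ref = SequenceRecord("ref", "", "ACGT")
        table = summarize_methods(
            {"A": [base], "B": [better]}, [ref], min_len=4, min_frac=0.5
        )
        rows = table.set_index("method")
        assert rows.loc["B", "matched_nucleotides"] == rows.loc["A", "matched_nucleotides"] + 1

    def test_reference_mismatch_rejected(self):
        mm = matrix_from_profiles([[1, 1]], [[1, 1]])
        ref = SequenceRecord("other", "", "AC")
        with pytest.raises(InputError, match="reference"):
            summarize_methods({"A": [mm]}, [ref])
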