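"""LST scar scoring: boundary rules, smoothing semantics, and oracles."""

import numpy as np
import pytest

from oxphos.lst import (
    HRD,
    HRP,
    MB,
    NEAR_DIPLOID,
    NEAR_TETRAPLOID,
    CopyNumberProfile,
    SegmentRecord,
    classify_hrd,
    count_lst,
    dna_index,
    lst_pipeline,
    ploidy_class,
    smooth_and_filter,
)


def make_profile(layout):
    """layout: {chrom: [(length_mb, total, major), ...]} laid end to end."""
    segments = {}
    for chrom, segs in layout.items():
        pos, out = 0, []
        for length_mb, total, major in segs:
            end = pos + int(length_mb * MB)
            out.append(SegmentRecord(chrom, pos, end, total, major))
            pos = end
        segments[chrom] = out
    return CopyNumberProfile(segments)


class TestSegmentValidation:
    def test_rejects_inverted_interval(self):
        with pytest.raises(ValueError, match="end must exceed start"):
            SegmentRecord("chr1", 10, 10, 2, 1)

    def test_rejects_major_above_total(self):
        with pytest.raises(ValueError, match="major_cn"):
            SegmentRecord("chr1", 0, 100, 2, 3)

    def test_rejects_minor_allele_as_major(self):
        with pytest.raises(ValueError, match="larger allele"):
            SegmentRecord("chr1", 0, 100, 4, 1)

    def test_rejects_overlap_within_chromosome(self):
        a = SegmentRecord("chr1", 0, 100, 2, 1)
        b = SegmentRecord("chr1", 50, 200, 3, 2)
        with pytest.raises(ValueError, match="overlap"):
            CopyNumberProfile({"chr1": [a, b]})


class TestDnaIndex:
    def test_uniform_diploid_is_one(self):
        assert dna_index(make_profile({"chr1": [(100, 2, 1)]})) == 1.0

    def test_uniform_tetraploid_is_two(self):
        assert dna_index(make_profile({"chr1": [(100, 4, 2)]})) == 2.0

    def test_length_weighted_mean(self):
        # half genome at 2, half at 3 (equal lengths) -> (2+3)/2/2 = 1.25
        p = make_profile({"chr1": [(50, 2, 1), (50, 3, 2)]})
        assert dna_index(p) == pytest.approx(1.25)

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError):
            dna_index(CopyNumberProfile({}))


class TestPloidyClass:
    @pytest.mark.parametrize(
        "index,expected",
        [(1.29, NEAR_DIPLOID), (1.3, NEAR_TETRAPLOID), (2.0, NEAR_TETRAPLOID), (0.9, NEAR_DIPLOID)],
    )
    def test_boundary(self, index, expected):
        assert ploidy_class(index) == expected


class TestSmoothAndFilter:
    def test_variant_between_equal_states_merges_across(self):
        p = make_profile({"chr1": [(12, 2, 1), (2, 4, 2), (12, 2, 1)]})
        out = smooth_and_filter(p)
        segs = out.segments["chr1"]
        assert len(segs) == 1
        assert segs[0].length == 26 * MB
        assert segs[0].state == (2, 1)

    def test_variant_between_unequal_states_leaves_one_breakpoint(self):
        p = make_profile({"chr1": [(12, 2, 1), (2, 4, 2), (12, 3, 2)]})
        segs = smooth_and_filter(p).segments["chr1"]
        assert [s.state for s in segs] == [(2, 1), (3, 2)]
        assert segs[0].end == segs[1].start  # contiguous after midpoint split
        assert sum(s.length for s in segs) == 26 * MB

    def test_profile_without_short_segments_is_fixpoint(self):
        p = make_profile({"chr1": [(12, 2, 1), (15, 3, 2)]})
        out = smooth_and_filter(p)
        assert [s.state for s in out.segments["chr1"]] == [(2, 1), (3, 2)]
        assert [(s.start, s.end) for s in out.segments["chr1"]] == [
            (s.start, s.end) for s in p.segments["chr1"]
        ]

    def test_exactly_3mb_segment_is_kept(self):
        p = make_profile({"chr1": [(12, 2, 1), (3, 4, 2), (12, 2, 1)]})
        assert len(smooth_and_filter(p).segments["chr1"]) == 3

    def test_terminal_short_segment_dropped(self):
        p = make_profile({"chr1": [(2, 4, 2), (20, 2, 1)]})
        segs = smooth_and_filter(p).segments["chr1"]
        assert len(segs) == 1 and segs[0].state == (2, 1)

    def test_equal_state_neighbours_merge(self):
        p = make_profile({"chr1": [(12, 2, 1), (12, 2, 1)]})
        assert len(smooth_and_filter(p).segments["chr1"]) == 1


class TestCountLst:
    def test_single_segment_per_chromosome_is_zero(self):
        p = make_profile({"chr1": [(100, 2, 1)], "chr2": [(80, 3, 2)]})
        assert count_lst(p) == 0

    def test_copy_neutral_allelic_change_counts(self):
        p = make_profile({"chr1": [(15, 2, 1), (15, 2, 2)]})
        assert count_lst(p) == 1

    def test_short_flank_disqualifies(self):
        p = make_profile({"chr1": [(9, 2, 1), (15, 3, 2)]})
        assert count_lst(p) == 0

    def test_exact_10mb_flanks_qualify(self):
        p = make_profile({"chr1": [(10, 2, 1), (10, 3, 2)]})
        assert count_lst(p) == 1

    def test_unsmoothed_input_rejected(self):
        p = make_profile({"chr1": [(15, 2, 1), (15, 2, 1)]})
        with pytest.raises(ValueError, match="smooth"):
            count_lst(p)


class TestClassifyHrd:
    @pytest.mark.parametrize(
        "count,ploidy,expected,cutoff",
        [
            (15, NEAR_DIPLOID, HRD, 15),
            (14, NEAR_DIPLOID, HRP, 15),
            (20, NEAR_TETRAPLOID, HRD, 20),
            (19, NEAR_TETRAPLOID, HRP, 20),
            (0, NEAR_DIPLOID, HRP, 15),
        ],
    )
    def test_ploidy_specific_cutoffs(self, count, ploidy, expected, cutoff):
        status, used = classify_hrd(count, ploidy)
        assert status == expected
        assert used == cutoff


def brute_force_lst(profile, min_region_mb=10.0):
    """Independent count: enumerate breakpoints, check both flank lengths."""
    min_len = min_region_mb * MB
    total = 0
    for segs in profile.segments.values():
        for i in range(len(segs) - 1):
            left, right = segs[i], segs[i + 1]
            if left.state != right.state and left.length >= min_len and right.length >= min_len:
                total += 1
    return total


class TestLstPipeline:
    def test_uniform_diploid_genome(self):
        p = make_profile({f"chr{i}": [(100, 2, 1)] for i in range(1, 23)})
        r = lst_pipeline(p)
        assert (r.dna_index, r.ploidy_class, r.lst_count, r.hr_status) == (
            1.0,
            NEAR_DIPLOID,
            0,
            HRP,
        )

    def test_constructed_neardiploid_16_breakpoints_is_hrd(self):
        # 16 alternating >= 10 Mb segments spread over 4 chromosomes
        layout = {
            f"chr{c}": [(12, 2, 1) if i % 2 == 0 else (12, 3, 2) for i in range(5)]
            for c in range(1, 5)
        }
        r = lst_pipeline(make_profile(layout))
        assert r.lst_count == 16
        assert r.ploidy_class == NEAR_DIPLOID
        assert r.hr_status == HRD

    def test_count_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n_segs = int(rng.integers(1, 12))
            lengths = rng.integers(1, 40, size=n_segs)  # Mb, some below 10
            states = [(int(t), int(t) - int(rng.integers(0, t // 2 + 1))) for t in rng.integers(1, 6, size=n_segs)]
            pos, segs = 0, []
            for L, (t, m) in zip(lengths, states):
                end = pos + int(L) * MB
                segs.append(SegmentRecord("chr1", pos, end, t, m))
                pos = end
            p = smooth_and_filter(CopyNumberProfile({"chr1": segs}))
            assert count_lst(p) == brute_force_lst(p)


class TestSmoothingInvariances:
    def base_profile(self):
        return make_profile({"chr1": [(20, 2, 1), (25, 3, 2), (30, 2, 2)]})

    def test_splitting_a_segment_preserves_count(self):
        p = self.base_profile()
        base = count_lst(smooth_and_filter(p))
        segs = p.segments["chr1"]
        mid = (segs[1].start + segs[1].end) // 2
        split = [
            segs[0],
            SegmentRecord("chr1", segs[1].start, mid, 3, 2),
            SegmentRecord("chr1", mid, segs[1].end, 3, 2),
            segs[2],
        ]
        q = CopyNumberProfile({"chr1": split})
        assert count_lst(smooth_and_filter(q)) == base

    def test_small_variant_insertion_preserves_count(self):
        p = self.base_profile()
        base = count_lst(smooth_and_filter(p))
        segs = p.segments["chr1"]
        host = segs[1]
        v0 = host.start + 8 * MB
        variant = [
            segs[0],
            SegmentRecord("chr1", host.start, v0, 3, 2),
            SegmentRecord("chr1", v0, v0 + 2 * MB, 5, 3),
            SegmentRecord("chr1", v0 + 2 * MB, host.end, 3, 2),
            segs[2],
        ]
        q = CopyNumberProfile({"chr1": variant})
        assert count_lst(smooth_and_filter(q)) == base

    def test_count_nonincreasing_in_min_region(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            lengths = rng.integers(5, 40, size=6)
            pos, segs = 0, []
            for i, L in enumerate(lengths):
                end = pos + int(L) * MB
                t = 2 + i % 2
                segs.append(SegmentRecord("chr1", pos, end, t, t - 1))
                pos = end
            p = smooth_and_filter(CopyNumberProfile({"chr1": segs}))
            counts = [count_lst(p, min_region_mb=mb) for mb in (5, 10, 15, 20)]
            assert counts == sorted(counts, reverse=True)
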