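"""Large-scale state transition (LST) scoring of allele-specific copy-number profiles.

The LST signature calls homologous-recombination status from segmented,
absolute copy-number profiles.  A large-scale state transition is a
chromosomal breakpoint — a change in total copy number or in major allele
count — whose flanking segments are each at least 10 Mb long, counted after
variant regions shorter than 3 Mb have been smoothed away.  Tumors at or
above a ploidy-specific cutoff (15 LST for near-diploid genomes, 20 for
near-tetraploid, split at DNA index 1.3) are called HR-deficient (HRD),
below it HR-proficient (HRP).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

MB = 1_000_000

NEAR_DIPLOID = "near-diploid"
NEAR_TETRAPLOID = "near-tetraploid"
HRD = "HRD"
HRP = "HRP"

#: ploidy-specific LST cutoffs (LST per genome)
LST_CUTOFFS = {NEAR_DIPLOID: 15, NEAR_TETRAPLOID: 20}
#: DNA-index boundary between the two ploidy classes
PLOIDY_INDEX_THRESHOLD = 1.3


@dataclass(frozen=True)
class SegmentRecord:
    """One copy-number segment, 0-based half-open internal coordinates."""

    chromosome: str
    start: int
    end: int
    total_cn: int
    major_cn: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"segment {self.chromosome}:{self.start}-{self.end}: end must exceed start"
            )
        if self.total_cn < 0 or self.major_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.major_cn > self.total_cn:
            raise ValueError(
                f"segment {self.chromosome}:{self.start}-{self.end}: "
                f"major_cn {self.major_cn} exceeds total_cn {self.total_cn}"
            )
        if self.major_cn < self.total_cn - self.major_cn:
            raise ValueError(
                f"segment {self.chromosome}:{self.start}-{self.end}: "
                "major_cn must be the larger allele count"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def state(self) -> tuple[int, int]:
        return (self.total_cn, self.major_cn)


@dataclass
class CopyNumberProfile:
    """Ordered, non-overlapping segments grouped by chromosome."""

    segments: dict[str, list[SegmentRecord]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, segs in self.segments.items():
            segs.sort(key=lambda s: s.start)
            for left, right in zip(segs, segs[1:]):
                if right.start < left.end:
                    raise ValueError(
                        f"overlapping segments on {chrom}: "
                        f"{left.start}-{left.end} and {right.start}-{right.end}"
                    )

    @property
    def chromosomes(self) -> list[str]:
        return list(self.segments)

    def all_segments(self) -> list[SegmentRecord]:
        return [s for segs in self.segments.values() for s in segs]

    @property
    def covered_length(self) -> int:
        return sum(s.length for s in self.all_segments())

    @property
    def n_segments(self) -> int:
        return sum(len(v) for v in self.segments.values())


@dataclass(frozen=True)
class LSTResult:
    dna_index: float
    ploidy_class: str
    lst_count: int
    hr_status: str
    cutoff_used: int


def dna_index(profile: CopyNumberProfile) -> float:
    """Length-weighted mean copy number on the diploid = 1.0 scale.

    The average total copy number over the covered genome is divided by 2 so
    that a uniformly diploid genome scores 1.0, matching the cytometry-style
    index scale on which the 1.3 ploidy boundary is defined.
    """
    total = profile.covered_length
    if total == 0:
        raise ValueError("cannot compute DNA index of an empty profile")
    weighted = sum(s.length * s.total_cn for s in profile.all_segments())
    return weighted / total / 2.0


def ploidy_class(index: float) -> str:
    """Near-diploid below DNA index 1.3, near-tetraploid at or above."""
    if index <= 0:
        raise ValueError("DNA index must be positive")
    return NEAR_DIPLOID if index < PLOIDY_INDEX_THRESHOLD else NEAR_TETRAPLOID


def _merge_equal_adjacent(segs: list[SegmentRecord]) -> list[SegmentRecord]:
    merged: list[SegmentRecord] = []
    for seg in segs:
        if merged and merged[-1].state == seg.state:
            merged[-1] = replace(merged[-1], end=seg.end)
        else:
            merged.append(seg)
    return merged


def smooth_and_filter(
    profile: CopyNumberProfile, min_variant_mb: float = 3.0
) -> CopyNumberProfile:
    """Remove sub-threshold variant regions and merge equal-state neighbours.

    Iterates to a fixpoint, per chromosome:

    * adjacent segments with identical (total_cn, major_cn) state are merged;
    * an interstitial segment shorter than ``min_variant_mb`` (strict) whose
      state differs from both neighbours is removed — if the neighbours share
      a state they merge across the gap (lengths add), otherwise each is
      extended to the midpoint of the removed span;
    * a terminal segment shorter than the threshold is dropped without
      extending its neighbour;
    * a chromosome consisting of a single short segment is left alone (it is
      not a variant region relative to anything).

    Segments at or above the threshold are never removed.
    """
    min_len = int(round(min_variant_mb * MB))
    out: dict[str, list[SegmentRecord]] = {}
    for chrom, segs in profile.segments.items():
        cur = list(segs)
        while True:
            cur = _merge_equal_adjacent(cur)
            idx = next(
                (
                    i
                    for i, s in enumerate(cur)
                    if s.length < min_len and len(cur) > 1
                ),
                None,
            )
            if idx is None:
                break
            if idx == 0 or idx == len(cur) - 1:
                del cur[idx]  # terminal short segment: drop, no extension
                continue
            left, removed, right = cur[idx - 1], cur[idx], cur[idx + 1]
            if left.state == right.state:
                cur[idx - 1 : idx + 2] = [replace(left, end=right.end)]
            else:
                mid = (removed.start + removed.end) // 2
                cur[idx - 1 : idx + 2] = [
                    replace(left, end=mid),
                    replace(right, start=mid),
                ]
        out[chrom] = cur
    return CopyNumberProfile(out)


def count_lst(profile: CopyNumberProfile, min_region_mb: float = 10.0) -> int:
    """Count breakpoints flanked on both sides by segments >= ``min_region_mb``.

    The profile must already be smoothed (no equal-state neighbours); a
    change in major allele count alone qualifies as a state change.
    """
    min_len = int(round(min_region_mb * MB))
    count = 0
    for chrom, segs in profile.segments.items():
        for left, right in zip(segs, segs[1:]):
            if left.state == right.state:
                raise ValueError(
                    f"adjacent equal-state segments on {chrom}; "
                    "run smooth_and_filter before counting LST"
                )
            if left.length >= min_len and right.length >= min_len:
                count += 1
    return count


def classify_hrd(lst_count: int, ploidy: str) -> tuple[str, int]:
    """HRD/HRP call: HRD iff the LST count reaches the ploidy-specific cutoff."""
    if lst_count < 0:
        raise ValueError("lst_count must be non-negative")
    cutoff = LST_CUTOFFS[ploidy]
    return (HRD if lst_count >= cutoff else HRP), cutoff


def lst_pipeline(
    profile: CopyNumberProfile,
    min_variant_mb: float = 3.0,
    min_region_mb: float = 10.0,
) -> LSTResult:
    """DNA index -> ploidy class -> smoothing -> LST count -> HR status."""
    index = dna_index(profile)
    ploidy = ploidy_class(index)
    smoothed = smooth_and_filter(profile, min_variant_mb=min_variant_mb)
    count = count_lst(smoothed, min_region_mb=min_region_mb)
    status, cutoff = classify_hrd(count, ploidy)
    return LSTResult(
        dna_index=index,
        ploidy_class=ploidy,
        lst_count=count,
        hr_status=status,
        cutoff_used=cutoff,
    )
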