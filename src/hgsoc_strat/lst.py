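"""Large-scale state transition (LST) signature of homologous recombination
deficiency, computed from absolute copy-number segment profiles.

An LST is a chromosomal breakpoint — a change in total copy number or major
allele count — between two adjacent genomic regions each of at least 10 Mb,
counted genome-wide after smoothing the profile and filtering out copy-number
variant regions shorter than 3 Mb.  Tumors are called near-diploid or
near-tetraploid from the DNA index (length-weighted mean copy number / 2,
threshold 1.3) and classified LST-high (HRD) or LST-low against the
ploidy-specific cut-off: 15 LST per genome for near-diploid tumors, 20 for
near-tetraploid.

Counting is per-chromosome by default; when centromere intervals are
supplied, segments are split at the centromere and transitions are counted
within arms only (the original formulation of the score).
"""

from __future__ import annotations

import logging

from .types import MB, LstCall, PloidyCall, Segment, SegmentProfile

logger = logging.getLogger(__name__)

DIPLOID_CUTOFF = 15
TETRAPLOID_CUTOFF = 20
DNA_INDEX_THRESHOLD = 1.3


def compute_dna_index(profile: SegmentProfile, raw: bool = False) -> float:
    """Length-weighted mean copy number, rescaled so diploid ~= 1.0.

    With ``raw=True`` the unscaled mean copy number is returned (the literal
    "averaged copy number" reading; the 1.3 ploidy threshold assumes the
    rescaled convention).
    """
    if not profile.segments:
        raise ValueError(f"sample {profile.sample_id}: empty profile")
    total_len = profile.total_length_bp
    if total_len <= 0:
        raise ValueError(f"sample {profile.sample_id}: zero total length")
    weighted = sum(seg.length_bp * seg.total_cn for seg in profile.segments)
    mean_cn = weighted / total_len
    return mean_cn if raw else mean_cn / 2.0


def classify_ploidy(dna_index: float) -> PloidyCall:
    """Near-diploid below 1.3, near-tetraploid at or above."""
    if not dna_index > 0:
        raise ValueError(f"DNA index must be positive, got {dna_index}")
    cls = "near_diploid" if dna_index < DNA_INDEX_THRESHOLD else "near_tetraploid"
    return PloidyCall(dna_index, cls)


def _merge_adjacent(segments: list[Segment]) -> list[Segment]:
    """Merge runs of consecutive same-chromosome segments with equal state."""
    merged: list[Segment] = []
    for seg in segments:
        if merged and merged[-1].chrom == seg.chrom and merged[-1].state == seg.state:
            prev = merged[-1]
            merged[-1] = Segment(
                prev.chrom, prev.start_bp, seg.end_bp, prev.total_cn, prev.major_cn
            )
        else:
            merged.append(seg)
    return merged


def smooth_and_filter(
    profile: SegmentProfile, min_variant_mb: float = 3.0
) -> SegmentProfile:
    """Smooth a profile and remove copy-number variant regions < 3 Mb.

    Iteratively: (1) merge adjacent same-state segments; (2) delete the
    shortest remaining segment under ``min_variant_mb`` (ties broken by
    genomic position) and re-merge its now-adjacent neighbours when their
    states are equal; repeat to the fixed point.  The procedure is
    deterministic and idempotent.
    """
    min_len = int(min_variant_mb * MB)
    segments = _merge_adjacent(list(profile.segments))
    while True:
        short = [s for s in segments if s.length_bp < min_len]
        if not short:
            break
        victim = min(short, key=lambda s: (s.length_bp, s.chrom, s.start_bp))
        segments.remove(victim)
        segments = _merge_adjacent(segments)
    return SegmentProfile(profile.sample_id, segments)


def _split_at_centromeres(
    segments: list[Segment], arm_boundaries: dict[str, tuple[int, int]]
) -> list[list[Segment]]:
    """Partition a chromosome-ordered segment list into arm-level runs.

    ``arm_boundaries`` maps chromosome -> centromere interval (1-based,
    closed).  Segments overlapping the centromere are truncated to the part
    on each arm; transitions across the boundary are never counted.
    """
    runs: list[list[Segment]] = []
    by_chrom: dict[str, list[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        if chrom not in arm_boundaries:
            runs.append(segs)
            continue
        cen_start, cen_end = arm_boundaries[chrom]
        p_arm: list[Segment] = []
        q_arm: list[Segment] = []
        for seg in segs:
            if seg.end_bp < cen_start:
                p_arm.append(seg)
            elif seg.start_bp > cen_end:
                q_arm.append(seg)
            else:  # spans or touches the centromere: truncate to each arm
                if seg.start_bp < cen_start:
                    p_arm.append(
                        Segment(chrom, seg.start_bp, cen_start - 1, seg.total_cn,
                                seg.major_cn)
                    )
                if seg.end_bp > cen_end:
                    q_arm.append(
                        Segment(chrom, cen_end + 1, seg.end_bp, seg.total_cn,
                                seg.major_cn)
                    )
        runs.extend(run for run in (p_arm, q_arm) if run)
    return runs


def _states_differ(a: Segment, b: Segment, use_major: bool) -> bool:
    if use_major and a.major_cn is not None and b.major_cn is not None:
        return a.state != b.state
    return a.total_cn != b.total_cn


def count_lst(
    profile: SegmentProfile,
    min_region_mb: float = 10.0,
    arm_boundaries: dict[str, tuple[int, int]] | None = None,
    smooth: bool = True,
    min_variant_mb: float = 3.0,
) -> int:
    """Count large-scale state transitions in a profile.

    A transition between consecutive retained segments on the same
    chromosome (or arm) counts when total or major-allele copy number
    differs and both flanking segments span at least ``min_region_mb``.
    Chromosome and arm boundaries never count as breakpoints.  By default
    the profile is smoothed/filtered first (idempotent, so passing an
    already-filtered profile is safe); ``smooth=False`` skips it.
    """
    if arm_boundaries is not None:
        known = set(profile.chromosomes())
        unknown = set(arm_boundaries) - known
        if unknown:
            raise ValueError(
                f"arm boundaries reference unknown chromosomes: {sorted(unknown)}"
            )
    if smooth:
        profile = smooth_and_filter(profile, min_variant_mb=min_variant_mb)
    min_len = int(min_region_mb * MB)

    missing_major = any(s.major_cn is None for s in profile.segments)
    use_major = not missing_major
    if missing_major and any(s.major_cn is not None for s in profile.segments):
        logger.warning(
            "sample %s: some segments lack major_cn; breakpoints use total_cn only",
            profile.sample_id,
        )

    if arm_boundaries is not None:
        runs = _split_at_centromeres(profile.segments, arm_boundaries)
    else:
        runs = list(profile.by_chromosome().values())

    count = 0
    for run in runs:
        for left, right in zip(run, run[1:]):
            if (
                _states_differ(left, right, use_major)
                and left.length_bp >= min_len
                and right.length_bp >= min_len
            ):
                count += 1
    return count


def call_hrd(
    profile: SegmentProfile,
    min_region_mb: float = 10.0,
    min_variant_mb: float = 3.0,
    arm_boundaries: dict[str, tuple[int, int]] | None = None,
) -> tuple[PloidyCall, LstCall]:
    """Full HRD call: DNA index -> ploidy class -> filtered LST count ->
    LST-high/low against the ploidy-specific cut-off."""
    ploidy = classify_ploidy(compute_dna_index(profile))
    cutoff = DIPLOID_CUTOFF if ploidy.ploidy_class == "near_diploid" else TETRAPLOID_CUTOFF
    n_lst = count_lst(
        profile,
        min_region_mb=min_region_mb,
        arm_boundaries=arm_boundaries,
        smooth=True,
        min_variant_mb=min_variant_mb,
    )
    cls = "LST_high" if n_lst >= cutoff else "LST_low"
    return ploidy, LstCall(n_lst, cutoff, cls)
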