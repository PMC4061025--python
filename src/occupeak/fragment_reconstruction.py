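"""Fragment-length estimation from strand-separated pileups, and 3' extension.

Sequenced reads are much shorter than the sheared DNA fragments they come
from, so around a true binding site forward-strand tags pile up shifted 5'
of reverse-strand tags.  The original fragment length is estimated from that
shift: regions are built per strand, scored with the background model, and
the median distance between the midpoints of the most significant uniquely
overlapping forward/reverse region pairs is taken as the fragment length.
All tags are then extended in their 3' direction to that length before the
strands are merged for peak calling.

Note the midpoint distance for symmetric end-read pileups is closer to
(fragment - read) length than to the fragment length itself; the median
distance is nevertheless used directly as the estimate, which keeps the
procedure assumption-free about the pileup geometry at the cost of a small
downward bias of about one read length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment_io import FORWARD, ChromTable, Tag
from .background_model import assign_significance, fit_background
from .coverage_regions import Region, build_regions, count_cumulative

#: Regions more significant than this are excluded as likely alignment
#: artefacts (log10 scale, matching the peak-calling threshold scale).
MAX_LOG_ER = 50.0

#: Number of most significant pairs whose midpoint distances enter the median.
MAX_PAIRS = 200


class FragmentEstimationError(ValueError):
    """Fragment length could not be estimated; supply one explicitly."""


@dataclass
class FragmentEstimate:
    """Estimated fragment length and the pair distances behind it."""

    length: int
    pairs_used: int
    distances: np.ndarray


def _strand_regions(
    tags: Sequence[Tag], chroms: ChromTable, strand_name: str
) -> list[Region]:
    """Regions for one strand over all chromosomes, with log_er assigned."""
    by_chrom: dict[str, list[Tag]] = {}
    for tag in tags:
        by_chrom.setdefault(tag.chrom, []).append(tag)
    regions: list[Region] = []
    for chrom in chroms:
        if chrom in by_chrom:
            regions.extend(build_regions(by_chrom[chrom], chrom))
    if not regions:
        raise FragmentEstimationError(
            f"no {strand_name}-strand regions; cannot estimate fragment length"
        )
    counts = count_cumulative(regions)
    try:
        fit = fit_background(counts, label=f"{strand_name} strand")
    except ValueError as exc:
        raise FragmentEstimationError(
            f"fragment length estimation failed ({exc}); "
            "supply a fragment length explicitly (--fraglen)"
        ) from exc
    assign_significance(regions, counts, fit)
    return regions


def _unique_pairs(
    fwd: Sequence[Region], rev: Sequence[Region]
) -> list[tuple[Region, Region]]:
    """1:1 overlapping pairs: f overlaps exactly one r and vice versa."""
    pairs: list[tuple[int, int]] = []
    fwd_hits = np.zeros(len(fwd), dtype=np.int64)
    rev_hits = np.zeros(len(rev), dtype=np.int64)
    j0 = 0
    for i, f in enumerate(fwd):
        j = j0
        while j < len(rev) and rev[j].end <= f.start:
            j += 1
        j0 = j
        while j < len(rev) and rev[j].start < f.end:
            pairs.append((i, j))
            fwd_hits[i] += 1
            rev_hits[j] += 1
            j += 1
    return [
        (fwd[i], rev[j])
        for i, j in pairs
        if fwd_hits[i] == 1 and rev_hits[j] == 1
    ]


def estimate_fragment_length(
    fwd_tags: Sequence[Tag],
    rev_tags: Sequence[Tag],
    chroms: ChromTable,
    min_pairs: int = 20,
    max_pairs: int = MAX_PAIRS,
    max_log_er: float = MAX_LOG_ER,
) -> FragmentEstimate:
    """Estimate the DNA fragment length from forward/reverse region pairs.

    Pipeline: per-strand regions and background fits; drop regions with
    log10(ER) above ``max_log_er`` (artefact guard); keep forward/reverse
    pairs that uniquely overlap (1:1); rank pairs genome-wide by
    min(log_er_fwd, log_er_rev) — a pair is only as credible as its weaker
    strand — take the top ``max_pairs``; the estimate is the median of the
    reverse-minus-forward midpoint distances, rounded to the nearest bp.

    Raises
    ------
    FragmentEstimationError
        If fewer than ``min_pairs`` pairs remain after filtering, or the
        median distance is not positive (strand orientation anomaly); in
        either case supply the fragment length explicitly.
    """
    fwd_regions = _strand_regions(fwd_tags, chroms, "forward")
    rev_regions = _strand_regions(rev_tags, chroms, "reverse")
    fwd_regions = [r for r in fwd_regions if r.log_er <= max_log_er]
    rev_regions = [r for r in rev_regions if r.log_er <= max_log_er]

    paired: list[tuple[float, Region, Region]] = []
    for chrom in chroms:
        fwd_c = [r for r in fwd_regions if r.chrom == chrom]
        rev_c = [r for r in rev_regions if r.chrom == chrom]
        for f, r in _unique_pairs(fwd_c, rev_c):
            paired.append((min(f.log_er, r.log_er), f, r))

    if len(paired) < min_pairs:
        raise FragmentEstimationError(
            f"only {len(paired)} uniquely overlapping strand region pairs "
            f"(need >= {min_pairs}); supply a fragment length explicitly "
            "(--fraglen)"
        )
    # most significant first; positional tie-break keeps ranking deterministic
    paired.sort(key=lambda t: (-t[0], t[1].chrom, t[1].start))
    top = paired[:max_pairs]
    distances = np.array([r.midpoint - f.midpoint for _, f, r in top])
    median = float(np.median(distances))
    if median <= 0:
        raise FragmentEstimationError(
            f"median strand shift is {median:.1f} bp (expected > 0); "
            "check strand orientation or supply a fragment length explicitly"
        )
    return FragmentEstimate(
        length=int(np.rint(median)), pairs_used=len(top), distances=distances
    )


def extend_tags(
    tags: Sequence[Tag], length: int, chroms: ChromTable
) -> list[Tag]:
    """Extend every tag 3'-wards to ``length`` bp, clamped to the chromosome.

    Forward tags keep their start, reverse tags keep their end; strand is
    retained for bookkeeping although peak calling merges both strands.
    """
    if length <= 0:
        raise ValueError(f"fragment length must be positive, got {length}")
    out: list[Tag] = []
    for tag in tags:
        limit = chroms[tag.chrom]
        if tag.strand == FORWARD:
            out.append(Tag(tag.chrom, tag.start, min(tag.start + length, limit), tag.strand))
        else:
            out.append(Tag(tag.chrom, max(tag.end - length, 0), tag.end, tag.strand))
    return out
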