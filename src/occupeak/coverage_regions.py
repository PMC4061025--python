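"""Maximal coverage regions and the cumulative region-count table N(n).

A *region* is a maximal run of mutually overlapping tags: the union interval
of one connected component of the tag-overlap graph, where two tags overlap
iff they share at least one covered base (strict ``max(starts) < min(ends)``
under half-open coordinates — tags that merely abut do not merge).

``N(n)`` counts regions whose maximum per-base overlap depth is at least
``n``; this cumulative table is what the background model is fitted to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .alignment_io import Tag


@dataclass
class Region:
    """A maximal interval of contiguous tag coverage.

    max_depth
        Largest number of tags overlapping any single base of the region
        (the model's ``n``).
    tag_count
        Number of tags in the region's component.
    area
        Sum of the lengths of the contributing tags (bp); this is the "surface
        area" written to BED column 4.
    log_er
        log10 excess ratio; ``None`` until assigned by the background model.
    """

    chrom: str
    start: int
    end: int
    max_depth: int
    tag_count: int
    area: int
    log_er: Optional[float] = None

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class CountTable:
    """Cumulative counts N(n) of regions with depth >= n, n = 1..n_max.

    ``counts[i]`` holds N(i+1).  Monotone non-increasing by construction.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or len(self.counts) == 0:
            raise ValueError("CountTable requires a non-empty 1-d count vector")
        if np.any(np.diff(self.counts) > 0):
            raise ValueError("N(n) must be non-increasing in n")

    @property
    def n_max(self) -> int:
        return len(self.counts)

    def n(self, depth: int) -> float:
        """N(depth); 0 beyond the largest observed depth."""
        if depth < 1:
            raise ValueError("depth must be >= 1")
        if depth > self.n_max:
            return 0.0
        return float(self.counts[depth - 1])


def build_regions(tags: Sequence[Tag], chrom: str) -> list[Region]:
    """Assemble maximal coverage regions from tags on a single chromosome.

    Sweep-line construction: tags sorted by start are chained into components
    wherever the next start falls strictly before the running maximum end;
    per-component maximum depth comes from a +1/-1 event sweep in which end
    events sort before start events at equal coordinates (half-open
    semantics).  Equivalent to thresholding a per-base depth array at >=1 and
    taking connected components, except that abutting tags stay separate.
    """
    if any(t.chrom != chrom for t in tags):
        raise ValueError(f"build_regions: tags not all on chromosome {chrom!r}")
    if not tags:
        return []

    starts = np.fromiter((t.start for t in tags), dtype=np.int64, count=len(tags))
    ends = np.fromiter((t.end for t in tags), dtype=np.int64, count=len(tags))
    order = np.argsort(starts, kind="stable")
    starts = starts[order]
    ends = ends[order]

    running_end = np.maximum.accumulate(ends)
    # component boundary where a tag starts at/after everything seen so far ends
    is_new = np.empty(len(starts), dtype=bool)
    is_new[0] = True
    is_new[1:] = starts[1:] >= running_end[:-1]
    first_tag = np.flatnonzero(is_new)  # index of first tag of each region

    region_starts = starts[first_tag]
    last_tag = np.append(first_tag[1:], len(starts)) - 1
    region_ends = running_end[last_tag]
    tag_counts = np.diff(np.append(first_tag, len(starts)))
    areas = np.add.reduceat(ends - starts, first_tag)

    # depth sweep: key orders by position, end events (-1) before starts (+1)
    n = len(starts)
    ev_key = np.concatenate([2 * starts + 1, 2 * ends])
    ev_delta = np.concatenate([np.ones(n, np.int64), -np.ones(n, np.int64)])
    ev_order = np.argsort(ev_key, kind="stable")
    depth = np.cumsum(ev_delta[ev_order])
    # events are position-contiguous per region; max running depth per block
    block_first = np.searchsorted(ev_key[ev_order], 2 * region_starts + 1, "left")
    max_depths = np.maximum.reduceat(depth, block_first)

    return [
        Region(
            chrom=chrom,
            start=int(region_starts[i]),
            end=int(region_ends[i]),
            max_depth=int(max_depths[i]),
            tag_count=int(tag_counts[i]),
            area=int(areas[i]),
        )
        for i in range(len(first_tag))
    ]


def count_cumulative(
    regions: Sequence[Region],
    n_cap: Optional[int] = None,
    statistic: str = "depth",
) -> CountTable:
    """Tabulate N(n) = number of regions with depth (or tag count) >= n.

    ``statistic="depth"`` (default) uses the maximum single-base overlap
    depth, the quantity whose background expectation is geometric under the
    model; ``statistic="count"`` uses the region's total tag count instead
    and is retained for sensitivity analysis.
    """
    if not regions:
        raise ValueError("count_cumulative: empty region list")
    if statistic == "depth":
        values = np.fromiter((r.max_depth for r in regions), dtype=np.int64)
    elif statistic == "count":
        values = np.fromiter((r.tag_count for r in regions), dtype=np.int64)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    n_max = int(values.max())
    hist = np.bincount(values, minlength=n_max + 1)
    cumulative = np.cumsum(hist[::-1])[::-1][1:]  # index i -> N(i+1)
    if n_cap is not None:
        cumulative = cumulative[: int(n_cap)]
    return CountTable(cumulative)
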