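"""Interval overlap utilities for comparing peak sets.

Overlap between two intervals means at least one shared genome coordinate:
strict ``max(starts) < min(ends)`` under half-open coordinates, so a single
shared base suffices and mere abutment does not count.  Peak sets from
several callers are compared through *merged peaks* — connected components
of the union of all intervals — each annotated with which source hit it and
with the most significant value among that source's overlapping peaks.
Differences in overlap proportions are tested with a pooled two-sample
Z-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm

Interval = tuple  # (chrom, start, end[, significance])


def _by_chrom(intervals: Sequence[Interval]) -> dict[str, np.ndarray]:
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        out.setdefault(iv[0], []).append((int(iv[1]), int(iv[2])))
    return {
        chrom: np.array(sorted(pairs), dtype=np.int64).reshape(-1, 2)
        for chrom, pairs in out.items()
    }


def overlaps(
    set_a: Sequence[Interval], set_b: Sequence[Interval]
) -> tuple[np.ndarray, int]:
    """For each interval in A, does any interval in B share a coordinate?

    Returns the per-A boolean array (in input order) and the count of
    overlapping A intervals.  O((n+m) log m) via sorted starts and a prefix
    maximum of ends per chromosome.
    """
    b_idx = _by_chrom(set_b)
    prefix_max = {
        chrom: np.maximum.accumulate(arr[:, 1]) for chrom, arr in b_idx.items()
    }
    hit = np.zeros(len(set_a), dtype=bool)
    for i, iv in enumerate(set_a):
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        arr = b_idx.get(chrom)
        if arr is None:
            continue
        j = int(np.searchsorted(arr[:, 0], end, side="left")) - 1
        if j >= 0 and prefix_max[chrom][j] > start:
            hit[i] = True
    return hit, int(hit.sum())


@dataclass
class MergedPeak:
    """Union interval of overlapping peaks across sources."""

    chrom: str
    start: int
    end: int
    #: source name -> most significant value among its overlapping peaks
    best_significance: dict[str, float] = field(default_factory=dict)

    def present(self, source: str) -> bool:
        return source in self.best_significance


def merge_peak_sets(
    sources: Mapping[str, Sequence[Interval]],
) -> list[MergedPeak]:
    """Merge named peak sets into disjoint union intervals.

    Each input interval may carry a significance as its fourth element
    (defaults to NaN).  When several peaks of one source fall into the same
    merged peak the most significant (largest) value is kept.  Idempotent:
    merging the merged set returns it unchanged.
    """
    records: list[tuple[str, int, int, str, float]] = []
    for name, intervals in sources.items():
        for iv in intervals:
            sig = float(iv[3]) if len(iv) > 3 else float("nan")
            records.append((iv[0], int(iv[1]), int(iv[2]), name, sig))
    records.sort(key=lambda r: (r[0], r[1], r[2]))

    merged: list[MergedPeak] = []
    for chrom, start, end, name, sig in records:
        last = merged[-1] if merged else None
        if last is not None and last.chrom == chrom and start < last.end:
            last.end = max(last.end, end)
        else:
            last = MergedPeak(chrom, start, end)
            merged.append(last)
        prev = last.best_significance.get(name)
        if prev is None or (np.isnan(prev) and not np.isnan(sig)) or sig > prev:
            last.best_significance[name] = sig
    return merged


def proportion_z_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled two-sample Z-test for a difference in proportions.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion;
    the two-sided p-value comes from the standard normal.  Degenerate inputs
    with zero pooled variance (both proportions 0 or both 1) return z=0, p=1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    variance = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if variance == 0:
        return 0.0, 1.0
    z = (p1 - p2) / np.sqrt(variance)
    p = 2 * norm.sf(abs(z))
    return float(z), float(p)
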