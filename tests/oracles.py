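"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's sweep-line path: region
structure comes from connected components of the explicit pairwise-overlap
graph (scipy.sparse.csgraph) and depths from a per-base difference array.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components


def oracle_regions(tags, chrom_length: int):
    """Regions as (start, end, max_depth, tag_count, area) tuples, sorted.

    Two tags belong to the same region iff they are linked by a chain of
    strict interval overlaps (shared covered base); abutting tags stay
    separate.
    """
    if not tags:
        return []
    starts = np.array([t.start for t in tags])
    ends = np.array([t.end for t in tags])
    # pairwise strict-overlap adjacency
    adj = (starts[:, None] < ends[None, :]) & (starts[None, :] < ends[:, None])
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)

    depth = np.zeros(chrom_length + 1, dtype=np.int64)
    np.add.at(depth, starts, 1)
    np.add.at(depth, ends, -1)
    depth = np.cumsum(depth)[:chrom_length]

    regions = []
    for comp in range(n_comp):
        members = labels == comp
        start = int(starts[members].min())
        end = int(ends[members].max())
        regions.append(
            (
                start,
                end,
                int(depth[start:end].max()),
                int(members.sum()),
                int((ends[members] - starts[members]).sum()),
            )
        )
    return sorted(regions)


def oracle_cumulative_counts(depths) -> np.ndarray:
    """N(n) for n = 1..max(depths) by direct counting."""
    depths = np.asarray(depths)
    return np.array(
        [(depths >= n).sum() for n in range(1, depths.max() + 1)], dtype=float
    )


def oracle_overlap_matrix(set_a, set_b) -> np.ndarray:
    """O(n*m) overlap test: per-A boolean, shared-coordinate predicate."""
    out = np.zeros(len(set_a), dtype=bool)
    for i, a in enumerate(set_a):
        for b in set_b:
            if a[0] == b[0] and max(a[1], b[1]) < min(a[2], b[2]):
                out[i] = True
                break
    return out


def oracle_fragment_length(fwd_regions, rev_regions, max_pairs: int = 200):
    """Exhaustive-pairing fragment estimate on pre-scored strand regions.

    All-pairs overlap scan, 1:1 uniqueness filter, rank by the weaker
    strand's significance, median midpoint distance of the top pairs.
    ``*_regions`` are (start, end, log_er) tuples on one chromosome.
    """
    pairs = []
    for fi, (fs, fe, _) in enumerate(fwd_regions):
        for ri, (rs, re, _) in enumerate(rev_regions):
            if max(fs, rs) < min(fe, re):
                pairs.append((fi, ri))
    from collections import Counter

    fwd_hits = Counter(fi for fi, _ in pairs)
    rev_hits = Counter(ri for _, ri in pairs)
    unique = [
        (fi, ri) for fi, ri in pairs if fwd_hits[fi] == 1 and rev_hits[ri] == 1
    ]
    scored = sorted(
        unique,
        key=lambda p: (
            -min(fwd_regions[p[0]][2], rev_regions[p[1]][2]),
            fwd_regions[p[0]][0],
        ),
    )[:max_pairs]
    distances = [
        (rev_regions[ri][0] + rev_regions[ri][1]) / 2
        - (fwd_regions[fi][0] + fwd_regions[fi][1]) / 2
        for fi, ri in scored
    ]
    return float(np.median(distances)), len(scored)
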