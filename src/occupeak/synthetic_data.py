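"""Simulated ChIP-seq datasets with known ground truth, written as valid SAM.

The background emulates a sequencing run in which every position on a
chromosome has the same chance to receive a tag: 5' starts are i.i.d.
uniform per chromosome, chromosomes weighted by length, strands a fair
coin.  Enrichment is modelled as loci where a chosen number of sheared
fragments of fixed length pile up, each fragment sequenced from one end
(single-end ChIP-seq): a forward read at its 5' end or a reverse read at
its 3' end.

The simulation deliberately omits mappability structure, GC bias and
sequencing errors — reads are coordinates, not sequences — so it exercises
the statistics of the caller, not alignment artefacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pysam

from .alignment_io import FORWARD, REVERSE, ChromTable, Tag

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated dataset.

    peaks
        Enriched loci as ``(chrom, center, n_fragments)`` triples; at each
        locus the fragments' 5' ends fall uniformly within half a fragment
        length of the center.
    read_mode
        ``"coin"`` — each fragment yields one read from a random end
        (default, matching single-end sequencing); ``"both"`` — one forward
        and one reverse read per fragment.
    """

    chroms: ChromTable
    n_background: int
    read_length: int = 36
    fragment_length: int = 200
    peaks: tuple[tuple[str, int, int], ...] = ()
    seed: int = 0
    read_mode: str = "coin"

    def __post_init__(self) -> None:
        if self.n_background <= 0:
            raise ValueError("n_background must be positive")
        if self.read_length <= 0 or self.fragment_length < self.read_length:
            raise ValueError("need 0 < read_length <= fragment_length")
        if self.read_mode not in ("coin", "both"):
            raise ValueError(f"unknown read_mode {self.read_mode!r}")
        for chrom, center, n_fragments in self.peaks:
            if chrom not in self.chroms:
                raise ValueError(f"peak locus on unknown chromosome {chrom!r}")
            half = self.fragment_length / 2
            if not (half <= center <= self.chroms[chrom] - 1.5 * self.fragment_length):
                raise ValueError(
                    f"locus {chrom}:{center} too close to a chromosome edge"
                )
            if n_fragments <= 0:
                raise ValueError("n_fragments must be positive")


def default_spec(seed: int = 7) -> SimulationSpec:
    """The standard test dataset: 10 Mb, 1e5 background tags, 100 loci x 50
    fragments, fragment length 200, read length 36."""
    chrom = "chrS"
    length = 10_000_000
    centers = np.linspace(50_000, length - 50_000, 100).astype(int)
    return SimulationSpec(
        chroms=ChromTable({chrom: length}),
        n_background=100_000,
        read_length=36,
        fragment_length=200,
        peaks=tuple((chrom, int(c), 50) for c in centers),
        seed=seed,
    )


def _background_tags(spec: SimulationSpec, rng: np.random.Generator) -> list[Tag]:
    names = list(spec.chroms)
    lengths = np.array([spec.chroms[c] for c in names], dtype=float)
    chosen = rng.choice(len(names), size=spec.n_background, p=lengths / lengths.sum())
    strands = rng.random(spec.n_background) < 0.5
    tags: list[Tag] = []
    for idx, is_fwd in zip(chosen, strands):
        chrom = names[idx]
        start = int(rng.integers(0, spec.chroms[chrom] - spec.read_length + 1))
        tags.append(
            Tag(chrom, start, start + spec.read_length, FORWARD if is_fwd else REVERSE)
        )
    return tags


def simulate_background(spec: SimulationSpec) -> list[Tag]:
    """Uniform background only: ``n_background`` tags, deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    return _background_tags(spec, rng)


def simulate_chipseq(
    spec: SimulationSpec,
) -> tuple[list[Tag], list[tuple[str, int, int]]]:
    """Background plus enriched loci; returns (tags, truth intervals).

    Truth intervals are the union span of the fragments actually placed at
    each locus (merged with a warning if loci overlap).
    """
    rng = np.random.default_rng(spec.seed)
    tags = _background_tags(spec, rng)
    truth: list[tuple[str, int, int]] = []
    L, r = spec.fragment_length, spec.read_length
    for chrom, center, n_fragments in spec.peaks:
        lo = int(center - L // 2)
        starts = rng.integers(lo, lo + L + 1, size=n_fragments)
        for s in starts:
            s = int(s)
            emit_fwd = emit_rev = True
            if spec.read_mode == "coin":
                if rng.random() < 0.5:
                    emit_rev = False
                else:
                    emit_fwd = False
            if emit_fwd:
                tags.append(Tag(chrom, s, s + r, FORWARD))
            if emit_rev:
                tags.append(Tag(chrom, s + L - r, s + L, REVERSE))
        truth.append((chrom, int(starts.min()), int(starts.max()) + L))

    truth.sort()
    merged: list[tuple[str, int, int]] = []
    for iv in truth:
        if merged and merged[-1][0] == iv[0] and iv[1] < merged[-1][2]:
            logger.warning("overlapping truth loci merged: %s", iv)
            merged[-1] = (iv[0], merged[-1][1], max(merged[-1][2], iv[2]))
        else:
            merged.append(iv)
    return tags, merged


def write_sam(
    tags: Sequence[Tag], chroms: ChromTable, path: Union[str, Path]
) -> None:
    """Write tags as a SAM file with a proper header built from ``chroms``.

    Round-trips exactly through :func:`occupeak.alignment_io.read_tags` and
    is byte-deterministic for a fixed tag list.
    """
    header = chroms.to_header()
    ref_id = {name: i for i, name in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "w", header=header, add_sam_header=True) as out:
        for i, tag in enumerate(tags):
            rec = pysam.AlignedSegment(header)
            rec.query_name = f"sim{i}"
            rec.flag = 16 if tag.strand == REVERSE else 0
            rec.reference_id = ref_id[tag.chrom]
            rec.reference_start = tag.start
            rec.mapping_quality = 255
            rec.cigartuples = [(0, tag.length)]
            rec.query_sequence = "N" * tag.length
            out.write(rec)


def write_truth_bed(
    truth: Sequence[tuple[str, int, int]], path: Union[str, Path]
) -> None:
    """Write ground-truth enriched intervals as BED3."""
    with open(path, "w") as fh:
        for chrom, start, end in truth:
            fh.write(f"{chrom}\t{start}\t{end}\n")
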