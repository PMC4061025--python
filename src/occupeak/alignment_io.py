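"""Reading aligned ChIP-seq tags from SAM files.

A *tag* is a read aligned to the genome, reduced to a strand-aware genomic
interval.  Tags are the unit of coverage everywhere downstream: regions are
built from overlapping tags, the background model is fitted to region counts,
and peaks are thresholded regions.

Coordinates are 0-based half-open throughout the package; SAM's 1-based
inclusive convention is converted on read, BED is written natively.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence, TextIO, Union

import pysam

logger = logging.getLogger(__name__)

FORWARD = "+"
REVERSE = "-"

#: SAM flag bits that exclude a record from tag conversion.
_FLAG_UNMAPPED = 0x4
_FLAG_SECONDARY = 0x100
_FLAG_SUPPLEMENTARY = 0x800


class Tag(NamedTuple):
    """One aligned read as a genomic interval with strand.

    ``start``/``end`` are 0-based half-open.  ``end - start`` is the aligned
    read length before fragment extension, or the reconstructed fragment
    length after extension.
    """

    chrom: str
    start: int
    end: int
    strand: str

    @property
    def five_prime(self) -> int:
        """5' position: ``start`` for forward tags, ``end`` for reverse tags."""
        return self.start if self.strand == FORWARD else self.end

    @property
    def length(self) -> int:
        return self.end - self.start


class ChromTable(dict):
    """Ordered map chromosome name -> length (bp).

    The table defines the reference space: tags on chromosomes absent from
    the table are skipped on read, and simulated/extended coordinates are
    clamped to these lengths.
    """

    def __init__(self, items: Union[dict, Iterable[tuple[str, int]]] = ()):
        super().__init__()
        pairs = items.items() if isinstance(items, dict) else items
        for name, length in pairs:
            self[name] = length

    def __setitem__(self, name: str, length: int) -> None:
        length = int(length)
        if length <= 0:
            raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        if name in self:
            raise ValueError(f"duplicate chromosome name {name!r}")
        super().__setitem__(name, length)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ChromTable":
        """Load a chromosome-lengths text file: one ``name<TAB>length`` per line.

        Blank lines and ``#`` comments are ignored; whitespace other than tab
        is accepted as separator.
        """
        table = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 'name length', got {line!r}"
                    )
                try:
                    table[fields[0]] = int(fields[1])
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
        if not table:
            raise ValueError(f"{path}: no chromosomes found")
        return table

    def to_header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_references(
            list(self.keys()), list(self.values())
        )


class SamParseError(ValueError):
    """A SAM line could not be parsed; the message names the line number."""


class NoTagsError(ValueError):
    """A SAM source yielded zero usable tags."""


def _iter_lines(sam_source: Union[str, Path, TextIO]) -> Iterator[str]:
    if hasattr(sam_source, "read"):
        yield from sam_source
    else:
        with open(sam_source) as fh:
            yield from fh


def read_tags(
    sam_source: Union[str, Path, TextIO],
    chroms: ChromTable,
) -> list[Tag]:
    """Read mapped, primary SAM records into :class:`Tag` objects.

    The SAM header is optional: records are interpreted against ``chroms``,
    so a headerless Bowtie-style SAM works as long as the chromosome-lengths
    file matches the reference.  Records that are unmapped, secondary or
    supplementary are skipped silently; records on chromosomes absent from
    ``chroms`` are skipped with a logged count.

    Raises
    ------
    SamParseError
        If a non-header line cannot be parsed (message names the line number).
    NoTagsError
        If no usable record is found.
    """
    header = chroms.to_header()
    tags: list[Tag] = []
    skipped_unknown = 0
    for lineno, line in enumerate(_iter_lines(sam_source), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("@"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise SamParseError(
                f"SAM line {lineno}: expected >=11 tab-separated fields, "
                f"got {len(fields)}"
            )
        rname = fields[2]
        if rname != "*" and rname not in chroms:
            skipped_unknown += 1
            continue
        try:
            rec = pysam.AlignedSegment.fromstring(line, header)
        except ValueError as exc:
            raise SamParseError(f"SAM line {lineno}: {exc}") from exc
        if rec.flag & (_FLAG_UNMAPPED | _FLAG_SECONDARY | _FLAG_SUPPLEMENTARY):
            continue
        start = rec.reference_start
        end = rec.reference_end  # reference footprint from the CIGAR
        if end is None:  # htslib demotes CIGAR-less records to unmapped
            continue
        end = min(end, chroms[rec.reference_name])
        tags.append(
            Tag(rec.reference_name, start, end, REVERSE if rec.is_reverse else FORWARD)
        )
    if skipped_unknown:
        logger.warning(
            "skipped %d record(s) on chromosomes absent from the length table",
            skipped_unknown,
        )
    if not tags:
        raise NoTagsError("no tags: SAM source contains no usable mapped records")
    return tags


def remove_duplicates(tags: Sequence[Tag]) -> list[Tag]:
    """Drop PCR duplicates: keep one tag per (chrom, 5' position, strand).

    The 5' end rather than the full interval is used as the key so that reads
    of slightly different trimmed lengths from the same amplicon still
    collapse.  Order-stable and idempotent.  Apply before fragment extension.
    """
    seen: set[tuple[str, int, str]] = set()
    kept: list[Tag] = []
    for tag in tags:
        key = (tag.chrom, tag.five_prime, tag.strand)
        if key not in seen:
            seen.add(key)
            kept.append(tag)
    return kept
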