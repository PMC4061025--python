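"""Pipeline orchestration: windows, per-window fits, thresholding, BED output.

The full run is: estimate the fragment length (or take an override), extend
tags 3'-wards, merge strands, then per sampling window build regions, fit
the background model to N(1)..N(4) and convert each region's depth class
into a log10 excess ratio.  Regions at or above the threshold (default 2,
i.e. ER >= 100) are emitted as peaks in BED9, together with a per-window
summary of the model parameters, peak counts and genome coverage.

The default window is the whole chromosome: chromosome-wide background
modelling gives a higher positive predictive value than small local windows,
whose only systematic effect is losing weak peaks to reduced fitting power.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, TextIO, Union

import numpy as np
import pandas as pd

from .alignment_io import ChromTable, Tag
from .background_model import (
    BackgroundFit,
    InsufficientBackgroundError,
    assign_significance,
    fit_background,
)
from .coverage_regions import Region, build_regions, count_cumulative
from .fragment_reconstruction import (
    FragmentEstimate,
    estimate_fragment_length,
    extend_tags,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 2.0
MIN_WINDOW_SIZE = 100_000

#: Default ER colour bands: log10(ER) in [2,5) red, [5,10) green, [10,inf) blue.
DEFAULT_CATEGORIES: tuple[tuple[float, tuple[int, int, int]], ...] = (
    (2.0, (255, 0, 0)),
    (5.0, (0, 128, 0)),
    (10.0, (0, 0, 255)),
)


@dataclass
class Peak:
    """A region passing the excess-ratio threshold, with BED output fields."""

    chrom: str
    start: int
    end: int
    area: int
    log_er: float


@dataclass
class Window:
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class WindowSummary:
    """Per-window fit diagnostics for the run summary file."""

    window: Window
    status: str  # "ok" or a failure reason
    p: float = math.nan
    A: float = math.nan
    B: float = math.nan
    counts: tuple[float, float, float, float] = (math.nan,) * 4
    n_regions: int = 0
    n_peaks: int = 0
    peak_bp: int = 0

    @property
    def coverage_total(self) -> float:
        """Peak bp divided by the window's total length."""
        return self.peak_bp / self.window.length

    @property
    def coverage_mappable(self) -> float:
        """Peak bp divided by the fitted effective mappable length A."""
        return self.peak_bp / self.A if self.A > 0 else math.nan


@dataclass
class RunSummary:
    fragment_length: int
    threshold: float
    fragment_estimate: Optional[FragmentEstimate]
    windows: list[WindowSummary] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ws in self.windows:
            rows.append(
                {
                    "chrom": ws.window.chrom,
                    "start": ws.window.start,
                    "end": ws.window.end,
                    "status": ws.status,
                    "p": ws.p,
                    "A": ws.A,
                    "B": ws.B,
                    "N1": ws.counts[0],
                    "N2": ws.counts[1],
                    "N3": ws.counts[2],
                    "N4": ws.counts[3],
                    "n_regions": ws.n_regions,
                    "n_peaks": ws.n_peaks,
                    "peak_bp": ws.peak_bp,
                    "coverage_total": ws.coverage_total,
                    "coverage_mappable": ws.coverage_mappable,
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, sink: Union[str, Path, TextIO]) -> None:
        self.to_frame().to_csv(sink, sep="\t", index=False, float_format="%.6g")


def partition_windows(
    chroms: ChromTable, window_size: Optional[int] = None
) -> list[Window]:
    """Cover every chromosome with uniformly placed, minimally overlapping windows.

    ``window_size=None`` (the default) gives one chromosome-wide window.
    Otherwise k = ceil(len/ws) windows of width ws are placed with starts
    round(i*(len-ws)/(k-1)): the first is flush left, the last flush right,
    and the unavoidable overlap is spread evenly.  Sizes below
    :data:`MIN_WINDOW_SIZE` leave too few regions for a stable fit and are
    rejected at the CLI, not here.
    """
    windows: list[Window] = []
    for chrom, length in chroms.items():
        if window_size is None:
            windows.append(Window(chrom, 0, length))
            continue
        ws = int(window_size)
        if ws <= 0:
            raise ValueError(f"window size must be positive, got {ws}")
        if ws >= length:
            logger.info(
                "window size %d >= length of %s (%d); using one window",
                ws, chrom, length,
            )
            windows.append(Window(chrom, 0, length))
            continue
        k = math.ceil(length / ws)
        for i in range(k):
            start = int(round(i * (length - ws) / (k - 1)))
            windows.append(Window(chrom, start, start + ws))
    return windows


def subsample_tags(tags: Sequence[Tag], fraction: float, seed: int) -> list[Tag]:
    """Keep each tag independently with probability ``fraction`` (seeded)."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1:
        return list(tags)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(tags)) < fraction
    return [t for t, k in zip(tags, keep) if k]


def _assign_to_windows(
    regions: Sequence[Region], windows: Sequence[Window]
) -> list[list[Region]]:
    """Assign each region to the window containing its midpoint.

    In overlap zones a midpoint lies in two windows; the window whose center
    is nearest wins (lower index on ties), so every region is evaluated
    exactly once.
    """
    buckets: list[list[Region]] = [[] for _ in windows]
    starts = np.array([w.start for w in windows])
    for region in regions:
        mid = region.midpoint
        idx = int(np.searchsorted(starts, mid, side="right")) - 1
        idx = max(idx, 0)
        best = idx
        if idx > 0 and windows[idx - 1].end > mid:
            if abs(windows[idx - 1].center - mid) <= abs(windows[idx].center - mid):
                best = idx - 1
        buckets[best].append(region)
    return buckets


def call_peaks(
    tags: Sequence[Tag],
    chroms: ChromTable,
    threshold: float = DEFAULT_THRESHOLD,
    window_size: Optional[int] = None,
    fraglen_override: Optional[int] = None,
    min_pairs: int = 20,
    statistic: str = "depth",
) -> tuple[list[Peak], RunSummary]:
    """Run the full peak-calling pipeline.

    Returns the called peaks (sorted by chromosome order and start) and a
    :class:`RunSummary` holding the fragment length, per-window model
    parameters, N(1..4), peak counts and coverage.  Windows whose background
    cannot be fitted are skipped with a warning and recorded in the summary;
    if every window fails the run errors out.
    """
    if not tags:
        raise ValueError("call_peaks: no tags")

    if fraglen_override is not None:
        if fraglen_override <= 0:
            raise ValueError("fragment length override must be positive")
        estimate = None
        fragment_length = int(fraglen_override)
    else:
        fwd = [t for t in tags if t.strand == "+"]
        rev = [t for t in tags if t.strand == "-"]
        estimate = estimate_fragment_length(fwd, rev, chroms, min_pairs=min_pairs)
        fragment_length = estimate.length
        logger.info(
            "estimated fragment length %d bp from %d strand region pairs",
            fragment_length, estimate.pairs_used,
        )

    extended = extend_tags(tags, fragment_length, chroms)  # strands merged below

    by_chrom: dict[str, list[Tag]] = {}
    for tag in extended:
        by_chrom.setdefault(tag.chrom, []).append(tag)

    summary = RunSummary(fragment_length, threshold, estimate)
    peaks: list[Peak] = []
    any_ok = False
    for chrom in chroms:
        chrom_tags = by_chrom.get(chrom)
        if not chrom_tags:
            continue
        regions = build_regions(chrom_tags, chrom)
        wsize = None if window_size is None else int(window_size)
        windows = partition_windows(ChromTable({chrom: chroms[chrom]}), wsize)
        for window, assigned in zip(windows, _assign_to_windows(regions, windows)):
            ws = WindowSummary(window=window, status="ok")
            summary.windows.append(ws)
            if not assigned:
                ws.status = "no regions"
                continue
            ws.n_regions = len(assigned)
            counts = count_cumulative(assigned, statistic=statistic)
            try:
                fit = fit_background(
                    counts, label=f"{chrom}:{window.start}-{window.end}"
                )
            except (InsufficientBackgroundError, RuntimeError) as exc:
                logger.warning("window skipped: %s", exc)
                ws.status = str(exc)
                continue
            any_ok = True
            ws.p, ws.A, ws.B = fit.p, fit.A, fit.B
            ws.counts = tuple(counts.n(i) for i in range(1, 5))
            assign_significance(assigned, counts, fit, statistic=statistic)
            called = [r for r in assigned if r.log_er >= threshold]
            ws.n_peaks = len(called)
            ws.peak_bp = sum(r.end - r.start for r in called)
            peaks.extend(
                Peak(r.chrom, r.start, r.end, r.area, r.log_er) for r in called
            )
        logger.info("%s: %d regions", chrom, len(regions))
    if not any_ok:
        raise RuntimeError(
            "background fitting failed in every window; "
            "see the run summary for per-window reasons"
        )
    chrom_rank = {name: i for i, name in enumerate(chroms)}
    peaks.sort(key=lambda p: (chrom_rank[p.chrom], p.start, p.end))
    return peaks, summary


def _category_rgb(
    log_er: float, categories: Sequence[tuple[float, tuple[int, int, int]]]
) -> tuple[int, int, int]:
    rgb = categories[0][1]
    for edge, colour in categories:
        if log_er >= edge:
            rgb = colour
    return rgb


def write_bed(
    peaks: Sequence[Peak],
    fragment_length: int,
    threshold: float,
    sink: Union[str, Path, TextIO],
    categories: Sequence[tuple[float, tuple[int, int, int]]] = DEFAULT_CATEGORIES,
) -> None:
    """Write peaks as BED9.

    Columns: chrom, start, end, area (sum of overlapping tag lengths, bp),
    log10(ER) with two decimals, then ".", 0, 0 as unused placeholders and an
    RGB triple for the peak's ER category.  Header lines record the
    reconstructed fragment length and the applied threshold.
    """
    rows = [(p.chrom, p.start, p.end) for p in peaks]
    if rows != sorted(rows):
        raise ValueError("peaks must be sorted by (chrom, start, end)")
    if len(set(rows)) != len(rows):
        raise ValueError("duplicate peak intervals in BED output")

    own = not hasattr(sink, "write")
    fh: TextIO = open(sink, "w") if own else sink
    try:
        fh.write(f"# fragment_length={fragment_length}\n")
        fh.write(f"# log10_er_threshold={threshold:.2f}\n")
        fh.write('track name="occupeak" itemRgb="On"\n')
        for p in peaks:
            r, g, b = _category_rgb(p.log_er, categories)
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.area}\t{p.log_er:.2f}"
                f"\t.\t0\t0\t{r},{g},{b}\n"
            )
    finally:
        if own:
            fh.close()


def read_bed(source: Union[str, Path, TextIO]) -> tuple[list[Peak], dict]:
    """Read a BED file written by :func:`write_bed`; inverse of it.

    Returns the peaks plus a metadata dict with ``fragment_length`` and
    ``log10_er_threshold`` when present in the header.
    """
    own = not hasattr(source, "read")
    fh: TextIO = open(source) if own else source
    meta: dict = {}
    peaks: list[Peak] = []
    try:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line.lstrip("# ").partition("=")
                    meta[key.strip()] = float(value) if "." in value else int(value)
                continue
            if line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"BED peak row needs >= 5 columns: {line!r}")
            peaks.append(
                Peak(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    area=int(fields[3]),
                    log_er=float(fields[4]),
                )
            )
    finally:
        if own:
            fh.close()
    return peaks, meta
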