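"""Interval and binned-track data model with standard-format I/O.

Coordinates are 0-based, half-open ``[start, end)`` throughout (BED
convention). Fixed-width binned tracks carry one float per bin with
``NaN`` as the explicit missing-data sentinel, so uncovered bins can
never masquerade as zero coverage.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

VALUE_KINDS = ("raw_count", "depth_normalized", "log2_ratio")


class BedParseError(ValueError):
    """Raised for malformed BED/bedGraph lines; message names the line."""


def _open_text(path) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def is_standard_chrom(name: str) -> bool:
    """Random/alt/unplaced contigs (``chr1_random``, ``chrUn_...``) are
    non-standard; everything else passes."""
    return "_" not in name


@dataclass
class GenomicInterval:
    """A half-open genomic span ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.start = int(self.start)
        self.end = int(self.end)
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def __str__(self) -> str:
        label = f" ({self.name})" if self.name else ""
        return f"{self.chrom}:{self.start}-{self.end}{label}"


class ChromSizes:
    """Mapping chromosome name -> length in bp."""

    def __init__(self, sizes: dict[str, int]):
        if len(set(sizes)) != len(sizes):
            raise ValueError("duplicate chromosome names")
        for name, length in sizes.items():
            if int(length) <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")
        self._sizes = {str(k): int(v) for k, v in sizes.items()}

    @classmethod
    def from_file(cls, path) -> "ChromSizes":
        sizes: dict[str, int] = {}
        with _open_text(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise BedParseError(
                        f"{path}:{lineno}: expected 2 tab-separated columns"
                    )
                sizes[fields[0]] = int(fields[1])
        return cls(sizes)

    def __getitem__(self, chrom: str) -> int:
        return self._sizes[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def items(self):
        return self._sizes.items()

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    def validate_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self._sizes:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > self._sizes[iv.chrom]:
            raise ValueError(f"interval {iv} exceeds chromosome length")


class BinnedTrack:
    """Fixed-width genome bins carrying one float value each.

    Parameters
    ----------
    bin_size:
        Bin width in bp.
    chrom_sizes:
        The genome the bins tile; each chromosome gets
        ``ceil(length / bin_size)`` bins.
    value_kind:
        One of ``raw_count``, ``depth_normalized``, ``log2_ratio``.
        Declared, never inferred.
    """

    def __init__(
        self,
        bin_size: int,
        chrom_sizes: ChromSizes,
        value_kind: str,
        values: dict[str, np.ndarray] | None = None,
    ):
        if value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {VALUE_KINDS}")
        self.bin_size = int(bin_size)
        self.chrom_sizes = chrom_sizes
        self.value_kind = value_kind
        self.values: dict[str, np.ndarray] = {}
        for chrom, length in chrom_sizes.items():
            n = self.n_bins(chrom)
            if values is not None and chrom in values:
                arr = np.asarray(values[chrom], dtype=float)
                if arr.shape != (n,):
                    raise ValueError(
                        f"{chrom}: expected {n} bins, got {arr.shape}"
                    )
                self.values[chrom] = arr.copy()
            else:
                self.values[chrom] = np.full(n, np.nan)

    def n_bins(self, chrom: str) -> int:
        return math.ceil(self.chrom_sizes[chrom] / self.bin_size)

    def bin_span(self, chrom: str, index: int) -> GenomicInterval:
        start = index * self.bin_size
        end = min((index + 1) * self.bin_size, self.chrom_sizes[chrom])
        return GenomicInterval(chrom, start, end)

    def overlapping_bins(self, region: GenomicInterval) -> slice:
        """Slice of bin indices whose spans intersect ``region``."""
        if region.chrom not in self.values:
            raise ValueError(f"chromosome {region.chrom!r} absent from track")
        first = region.start // self.bin_size
        last = min(
            math.ceil(region.end / self.bin_size), self.n_bins(region.chrom)
        )
        return slice(first, last)

    def same_grid(self, other: "BinnedTrack") -> bool:
        return self.bin_size == other.bin_size and {
            c: len(v) for c, v in self.values.items()
        } == {c: len(v) for c, v in other.values.items()}

    def genome_mean(self) -> float:
        """Unweighted mean over all non-missing bins genome-wide."""
        pooled = np.concatenate(list(self.values.values()))
        if np.all(np.isnan(pooled)):
            return float("nan")
        return float(np.nanmean(pooled))

    def copy(self) -> "BinnedTrack":
        return BinnedTrack(
            self.bin_size, self.chrom_sizes, self.value_kind, self.values
        )


def read_bed(path, chrom_sizes: ChromSizes | None = None) -> list[GenomicInterval]:
    """Read a BED (3+ column, tab-separated) file of intervals.

    Coordinates are taken as 0-based half-open verbatim. An optional 4th
    column becomes the interval name. Non-standard chromosomes (and, when
    ``chrom_sizes`` is given, chromosomes absent from it) are dropped with
    a logged warning.
    """
    intervals: list[GenomicInterval] = []
    n_dropped = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise BedParseError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            if not is_standard_chrom(chrom) or (
                chrom_sizes is not None and chrom not in chrom_sizes
            ):
                n_dropped += 1
                continue
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            iv = GenomicInterval(chrom, start, end, name=name)
            if chrom_sizes is not None:
                chrom_sizes.validate_interval(iv)
            intervals.append(iv)
    if n_dropped:
        logger.warning(
            "%s: dropped %d interval(s) on non-standard/unknown chromosomes",
            path,
            n_dropped,
        )
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "wt") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def read_bedgraph(
    path,
    bin_size: int,
    chrom_sizes: ChromSizes,
    value_kind: str = "log2_ratio",
) -> BinnedTrack:
    """Read a bedGraph into a :class:`BinnedTrack`.

    Records must be non-overlapping within a chromosome and must lie
    within chromosome bounds. Records that do not align to the bin grid
    are resampled by coverage-weighted averaging; bins not covered by
    any record carry the missing sentinel (NaN).
    """
    track = BinnedTrack(bin_size, chrom_sizes, value_kind)
    # running coverage-weighted means; a bin covered by a single record
    # keeps that record's value bit-exactly (lossless round-trip)
    val: dict[str, np.ndarray] = {
        c: np.full(track.n_bins(c), np.nan) for c in chrom_sizes
    }
    wtot: dict[str, np.ndarray] = {
        c: np.zeros(track.n_bins(c)) for c in chrom_sizes
    }
    last_end: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(
                    f"{path}:{lineno}: expected 4 tab-separated columns"
                )
            chrom = fields[0]
            if not is_standard_chrom(chrom):
                continue
            if chrom not in chrom_sizes:
                raise BedParseError(
                    f"{path}:{lineno}: unknown chromosome {chrom!r}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: malformed record") from exc
            if start >= end:
                raise BedParseError(f"{path}:{lineno}: start >= end")
            if end > chrom_sizes[chrom]:
                raise BedParseError(
                    f"{path}:{lineno}: record beyond chromosome end"
                )
            last_end[chrom].append((start, end))
            b0 = start // bin_size
            b1 = math.ceil(end / bin_size)
            for b in range(b0, b1):
                span_lo = max(start, b * bin_size)
                span_hi = min(end, (b + 1) * bin_size)
                w = span_hi - span_lo
                if wtot[chrom][b] == 0:
                    val[chrom][b] = value
                else:
                    val[chrom][b] = (
                        val[chrom][b] * wtot[chrom][b] + value * w
                    ) / (wtot[chrom][b] + w)
                wtot[chrom][b] += w
    for chrom, spans in last_end.items():
        spans.sort()
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise BedParseError(
                    f"{path}: overlapping records on {chrom} at {s2}"
                )
    for chrom in chrom_sizes:
        covered = wtot[chrom] > 0
        track.values[chrom][covered] = val[chrom][covered]
    return track


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write a track as bedGraph, merging adjacent equal-valued bins."""
    with open(path, "wt") as fh:
        for chrom, values in track.values.items():
            run_start: int | None = None
            run_value = np.nan
            for b, v in enumerate(values):
                if np.isnan(v):
                    if run_start is not None:
                        fh.write(
                            f"{chrom}\t{run_start * track.bin_size}\t"
                            f"{min(b * track.bin_size, track.chrom_sizes[chrom])}\t"
                            f"{float(run_value)!r}\n"
                        )
                        run_start = None
                    continue
                if run_start is None or v != run_value:
                    if run_start is not None:
                        fh.write(
                            f"{chrom}\t{run_start * track.bin_size}\t"
                            f"{b * track.bin_size}\t{float(run_value)!r}\n"
                        )
                    run_start, run_value = b, v
            if run_start is not None:
                fh.write(
                    f"{chrom}\t{run_start * track.bin_size}\t"
                    f"{track.chrom_sizes[chrom]}\t{float(run_value)!r}\n"
                )


def overlap_query(
    intervals_a: list[GenomicInterval], intervals_b: list[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (i, j) index pairs whose half-open spans intersect on the same
    chromosome, sorted by a-index then b-index."""
    trees: dict[str, IntervalTree] = {}
    for j, iv in enumerate(intervals_b):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, j)
    pairs: list[tuple[int, int]] = []
    for i, iv in enumerate(intervals_a):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(iv.start, iv.end):
            pairs.append((i, hit.data))
    pairs.sort()
    return pairs


def mean_over_region(track: BinnedTrack, region: GenomicInterval) -> float:
    """Unweighted mean of all bins whose span intersects ``region``.

    A bin partially overlapped by the region counts with full weight.
    Missing bins are skipped; NaN is returned if no non-missing bin
    overlaps the region.
    """
    sl = track.overlapping_bins(region)
    vals = track.values[region.chrom][sl]
    if vals.size == 0 or np.all(np.isnan(vals)):
        return float("nan")
    return float(np.nanmean(vals))
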