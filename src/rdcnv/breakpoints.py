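"""Clustered permutation test for breakpoint-RDC enrichment.

Single-cell breakpoints carry positional uncertainty, so each coordinate
is expanded symmetrically into a 2-Mb window. A window scores a single
binary hit if it intersects at least one region of interest, and the
observed statistic is the total hit count over all cells. The null
redraws every breakpoint uniformly within its own chromosome, keeping
the per-cell and per-chromosome structure fixed (the "clustered"
permutation), and significance is the one-sided add-one permutation
p-value together with a z-score against the null sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ChromSizes, GenomicInterval

logger = logging.getLogger(__name__)

BREAKPOINT_COLUMNS = ["cell", "chrom", "pos"]


@dataclass
class EnrichmentResult:
    observed_hits: int
    null_hits: np.ndarray
    p_one_sided: float
    z_score: float
    n_perm: int
    seed: int | None
    n_windows: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_hits))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_hits, ddof=1))


def expand_breakpoints(
    breakpoints: pd.DataFrame,
    chrom_sizes: ChromSizes,
    half_width: int = 1_000_000,
) -> pd.DataFrame:
    """Expand each breakpoint into a symmetric window, clipped to the
    chromosome; the cell id is retained."""
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    rows = []
    for _, row in breakpoints.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        if chrom not in chrom_sizes:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (0 <= pos < chrom_sizes[chrom]):
            raise ValueError(f"breakpoint {chrom}:{pos} off chromosome")
        rows.append(
            {
                "cell": row["cell"],
                "chrom": chrom,
                "start": max(0, pos - half_width),
                "end": min(chrom_sizes[chrom], pos + half_width),
            }
        )
    return pd.DataFrame(rows, columns=["cell", "chrom", "start", "end"])


def _merge(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    spans = sorted(spans)
    out: list[list[int]] = []
    for s, e in spans:
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


class _RegionIndex:
    """Per-chromosome merged regions supporting O(log n) hit tests."""

    def __init__(self, regions: list[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in regions:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self.starts: dict[str, np.ndarray] = {}
        self.cummax_end: dict[str, np.ndarray] = {}
        for chrom, spans in by_chrom.items():
            merged = _merge(spans)
            self.starts[chrom] = np.array([s for s, _ in merged])
            self.cummax_end[chrom] = np.maximum.accumulate(
                np.array([e for _, e in merged])
            )

    def window_hits(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Boolean hit per half-open window [start, end)."""
        if chrom not in self.starts:
            return np.zeros(len(starts), dtype=bool)
        rs = self.starts[chrom]
        idx = np.searchsorted(rs, ends, side="left")
        hits = idx > 0
        safe = np.maximum(idx - 1, 0)
        hits &= self.cummax_end[chrom][safe] > starts
        hits &= idx > 0
        return hits


def count_region_hits(
    windows: pd.DataFrame, regions: list[GenomicInterval]
) -> int:
    """Number of windows intersecting >= 1 region (binary overlap logic:
    a window crossing several regions still counts once)."""
    index = _RegionIndex(regions)
    total = 0
    for chrom, sub in windows.groupby("chrom"):
        total += int(
            index.window_hits(
                chrom, sub["start"].to_numpy(), sub["end"].to_numpy()
            ).sum()
        )
    return total


def clustered_permutation_test(
    breakpoints: pd.DataFrame,
    regions: list[GenomicInterval],
    chrom_sizes: ChromSizes,
    n_perm: int = 10_000,
    seed: int | None = None,
    half_width: int = 1_000_000,
) -> EnrichmentResult:
    """Clustered per-cell, per-chromosome permutation test.

    Each permutation redraws every breakpoint's position uniformly on
    its own chromosome (cell and chromosome assignments fixed),
    re-expands the windows and re-counts binary hits. One-sided
    ``p = (1 + #{null >= observed}) / (1 + n_perm)`` and
    ``z = (observed - mean(null)) / sd(null)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    windows = expand_breakpoints(breakpoints, chrom_sizes, half_width)
    observed = count_region_hits(windows, regions)
    index = _RegionIndex(regions)
    rng = np.random.default_rng(seed)
    null = np.zeros(n_perm, dtype=int)
    # a clipped window [max(0,p-h), min(L,p+h)) hits a region iff
    # region.start < p+h and region.end > p-h, so hit-testing positions
    # against h-expanded regions is exact including chromosome ends
    for chrom, sub in breakpoints.groupby("chrom"):
        n_bp = len(sub)
        length = chrom_sizes[chrom]
        pos = rng.integers(0, length, size=(n_perm, n_bp))
        hits = index.window_hits(
            chrom,
            (pos - half_width).ravel(),
            (pos + half_width).ravel(),
        ).reshape(n_perm, n_bp)
        null += hits.sum(axis=1)
    p = (1 + int((null >= observed).sum())) / (1 + n_perm)
    sd = float(np.std(null, ddof=1)) if n_perm > 1 else 0.0
    if sd == 0:
        warnings.warn("null has zero variance; z-score undefined")
        z = float("nan")
    else:
        z = (observed - float(np.mean(null))) / sd
    return EnrichmentResult(
        observed_hits=observed,
        null_hits=null,
        p_one_sided=float(p),
        z_score=z,
        n_perm=n_perm,
        seed=seed,
        n_windows=len(windows),
    )


def ttr_subset_test(
    breakpoints: pd.DataFrame,
    rdc_regions: list[GenomicInterval],
    ttr_rdc_regions: list[GenomicInterval],
    chrom_sizes: ChromSizes,
    n_perm: int = 10_000,
    seed: int | None = None,
    half_width: int = 1_000_000,
) -> EnrichmentResult:
    """Enrichment of RDC-hitting breakpoints in the TTR-class subset.

    Restricts to breakpoints whose windows hit any RDC, then runs the
    clustered permutation of only those breakpoints against the
    TTR-class regions.
    """
    windows = expand_breakpoints(breakpoints, chrom_sizes, half_width)
    index = _RegionIndex(rdc_regions)
    keep = np.zeros(len(windows), dtype=bool)
    for chrom, sub in windows.groupby("chrom"):
        keep[sub.index] = index.window_hits(
            chrom, sub["start"].to_numpy(), sub["end"].to_numpy()
        )
    restricted = breakpoints.loc[keep].reset_index(drop=True)
    if restricted.empty:
        raise ValueError("no breakpoint windows hit the RDC set")
    return clustered_permutation_test(
        restricted,
        ttr_rdc_regions,
        chrom_sizes,
        n_perm=n_perm,
        seed=seed,
        half_width=half_width,
    )


def read_breakpoints(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(BREAKPOINT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"breakpoint table missing columns: {sorted(missing)}")
    return df
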