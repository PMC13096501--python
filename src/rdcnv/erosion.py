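"""Coverage-erosion scoring of RDC intervals against a shuffled-region null.

Replication stress erodes sequencing coverage at recurrent DNA-break
clusters (RDCs). The analysis computes per-RDC mean log2(treated/control)
read-depth ratios and scores each RDC in standard-deviation units of a
length-preserving shuffled null: the same interval lengths, randomly
repositioned across the genome, excluding the RDCs themselves. RDCs
falling at or below -3 SD are flagged as coverage-erosion (CNV) hits.
Companion statistics: the upper-tail hypergeometric probability that
recurrent CNVs all land in RDC genes, and the 2x2 chi-square association
between CNV-containing RDCs and lamina-associated domains (LADs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinnedTrack, ChromSizes, GenomicInterval, mean_over_region

logger = logging.getLogger(__name__)


@dataclass
class ShuffleNull:
    """Length-preserving shuffled interval sets and their null summary.

    ``region_means``, ``mu0`` and ``sigma0`` are populated once the null
    is evaluated against a ratio track (see :func:`erosion_table`).
    """

    sets: list[list[GenomicInterval]]
    seed: int | None
    region_means: np.ndarray | None = field(default=None, repr=False)
    mu0: float | None = None
    sigma0: float | None = None

    @property
    def regions(self) -> list[GenomicInterval]:
        return [iv for s in self.sets for iv in s]


def compute_log2_ratio(
    treat: BinnedTrack, control: BinnedTrack, pseudocount: float = 0.5
) -> BinnedTrack:
    """Depth-normalised log2 ratio track, bin by bin.

    The pseudocount (in raw-read units) is added to each bin count, each
    side is scaled by its genome-wide mean per-bin depth (the depth-ratio
    normalisation), and the ratio is logged:
    ``log2(((t_i + pc) / d_t) / ((c_i + pc) / d_c))``. Keeping the
    pseudocount on the read-count scale leaves the expected value of a
    planted heterozygous deletion at ``log2(1 - f/2)`` up to small-count
    bias. Bins missing in either input are missing in the output.
    """
    if treat.value_kind != "raw_count" or control.value_kind != "raw_count":
        raise ValueError("inputs must be raw_count tracks")
    if not treat.same_grid(control):
        raise ValueError("treat and control tracks have mismatched bin grids")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    d_t = treat.genome_mean()
    d_c = control.genome_mean()
    if not np.isfinite(d_t) or not np.isfinite(d_c) or d_t <= 0 or d_c <= 0:
        raise ValueError("cannot depth-normalise an empty or zero-depth track")
    out = BinnedTrack(treat.bin_size, treat.chrom_sizes, "log2_ratio")
    for chrom in treat.values:
        t = treat.values[chrom]
        c = control.values[chrom]
        out.values[chrom] = np.log2(
            ((t + pseudocount) / d_t) / ((c + pseudocount) / d_c)
        )
    return out


def _merged_starts_ends(
    regions: list[GenomicInterval],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in regions:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out: list[list[int]] = []
        for s, e in spans:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = (
            np.array([s for s, _ in out]),
            np.array([e for _, e in out]),
        )
    return merged


def _overlaps_any(
    merged: dict[str, tuple[np.ndarray, np.ndarray]],
    chrom: str,
    start: int,
    end: int,
) -> bool:
    if chrom not in merged:
        return False
    starts, ends = merged[chrom]
    i = np.searchsorted(starts, end, side="left")
    return i > 0 and ends[i - 1] > start


def shuffle_regions(
    regions: list[GenomicInterval],
    chrom_sizes: ChromSizes,
    n_sets: int = 10,
    exclude: list[GenomicInterval] | None = None,
    seed: int | None = None,
    max_attempts: int = 1000,
) -> ShuffleNull:
    """Generate ``n_sets`` length-preserving shuffles of ``regions``.

    Per shuffled interval the chromosome is drawn with probability
    proportional to its length (among chromosomes long enough to hold
    the interval) and the start uniformly in ``[0, L - len]``; placements
    overlapping ``exclude`` are rejection-resampled. Deterministic given
    ``seed``.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    chroms = list(chrom_sizes)
    lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    max_len = int(lengths.max())
    for iv in regions:
        if iv.length >= max_len:
            raise ValueError(f"region {iv} is as long as the longest chromosome")
    merged_excl = _merged_starts_ends(exclude) if exclude else {}
    rng = np.random.default_rng(seed)
    sets: list[list[GenomicInterval]] = []
    for set_idx in range(n_sets):
        placed: list[GenomicInterval] = []
        for iv in regions:
            eligible = lengths >= iv.length
            probs = np.where(eligible, lengths, 0.0)
            probs = probs / probs.sum()
            for _attempt in range(max_attempts):
                ci = rng.choice(len(chroms), p=probs)
                chrom = chroms[ci]
                start = int(rng.integers(0, chrom_sizes[chrom] - iv.length + 1))
                end = start + iv.length
                if not _overlaps_any(merged_excl, chrom, start, end):
                    placed.append(
                        GenomicInterval(chrom, start, end, name=iv.name)
                    )
                    break
            else:
                raise RuntimeError(
                    f"failed to place shuffled copy of {iv} after "
                    f"{max_attempts} attempts; exclude set too dense"
                )
        sets.append(placed)
    return ShuffleNull(sets=sets, seed=seed)


def erosion_table(
    ratio_track: BinnedTrack,
    rdcs: list[GenomicInterval],
    null: ShuffleNull,
    flag_sd: float = -3.0,
) -> pd.DataFrame:
    """Rank-ordered per-RDC erosion table scored against the null.

    The null summary pools the per-region means of all shuffled sets
    into a single mu0 and sigma0; each RDC's deviation is
    ``(mean - mu0) / sigma0`` and rows are sorted descending by mean
    (rank 1 = least eroded). ``flag_3sd`` marks deviations <= ``flag_sd``.
    """
    null_means = np.array(
        [mean_over_region(ratio_track, iv) for iv in null.regions]
    )
    n_missing = int(np.isnan(null_means).sum())
    if n_missing:
        logger.warning("%d shuffled region(s) had no covered bins", n_missing)
        null_means = null_means[~np.isnan(null_means)]
    if null_means.size < 2:
        raise ValueError("null has fewer than 2 evaluable regions")
    mu0 = float(np.mean(null_means))
    sigma0 = float(np.std(null_means, ddof=1))
    if sigma0 == 0:
        raise ValueError("degenerate null: sigma0 = 0")
    null.region_means, null.mu0, null.sigma0 = null_means, mu0, sigma0

    rows = []
    for iv in rdcs:
        m = mean_over_region(ratio_track, iv)
        rows.append(
            {
                "name": iv.name if iv.name is not None else str(iv),
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "mean_log2": m,
            }
        )
    table = pd.DataFrame(rows)
    table["sd_deviation"] = (table["mean_log2"] - mu0) / sigma0
    table = table.sort_values(
        "mean_log2", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    table["flag_3sd"] = table["sd_deviation"] <= flag_sd
    return table[
        [
            "name",
            "chrom",
            "start",
            "end",
            "mean_log2",
            "rank",
            "sd_deviation",
            "flag_3sd",
        ]
    ]


def hypergeom_rdc_enrichment(
    n_genes: int, n_rdc_genes: int, n_cnv: int, n_cnv_in_rdc: int
) -> float:
    """Upper-tail hypergeometric probability P(X >= n_cnv_in_rdc).

    Population ``n_genes`` genes of which ``n_rdc_genes`` are RDC genes;
    ``n_cnv`` recurrent CNVs drawn; probability that at least
    ``n_cnv_in_rdc`` fall in RDC genes by chance.
    """
    if not (0 <= n_cnv_in_rdc <= n_cnv <= n_genes):
        raise ValueError("require 0 <= n_cnv_in_rdc <= n_cnv <= n_genes")
    if not (0 <= n_rdc_genes <= n_genes):
        raise ValueError("require 0 <= n_rdc_genes <= n_genes")
    return float(stats.hypergeom.sf(n_cnv_in_rdc - 1, n_genes, n_rdc_genes, n_cnv))


def lad_association_test(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table.

    Returns ``(statistic, two_sided_p)`` with 1 degree of freedom.
    Used for the CNV-RDC x LAD association.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin in 2x2 table")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)
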