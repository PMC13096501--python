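"""Synthetic-data generators with ground truth for every pipeline stage.

The simulated study system is a reduced-scale diploid genome carrying a
set of RDC-like intervals: binned whole-genome coverage pairs with
planted subclonal heterozygous deletions, Strand-seq cohorts with
template-strand inheritance, sister-chromatid exchanges and
haplotype-specific deletions, per-cell breakpoint sets with tunable RDC
enrichment, and LAM-HTGTS junction tables with tunable microhomology
spectra and bait-end shortening. Every generator is deterministic given
a seed and returns a machine-readable truth record.

Default scale: 5 chromosomes x 60 Mb with 40 constant-length 375-kb
RDCs, i.e. RDC territory of 15 Mb = 5% of the genome.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BinnedTrack, ChromSizes, GenomicInterval

logger = logging.getLogger(__name__)

# Aph-like microhomology spectrum peaked at 2 bp (TMEJ signature); the
# direct-join spectrum peaks at 0 bp (NHEJ-like). Small negative mass
# models junctions with inserted nucleotides.
MH_PROBS_TMEJ = {
    -2: 0.02, -1: 0.03, 0: 0.14, 1: 0.16, 2: 0.30, 3: 0.14,
    4: 0.08, 5: 0.05, 6: 0.03, 7: 0.02, 8: 0.01, 9: 0.01, 10: 0.01,
}
MH_PROBS_DIRECT = {
    -2: 0.03, -1: 0.05, 0: 0.40, 1: 0.22, 2: 0.12, 3: 0.07,
    4: 0.04, 5: 0.03, 6: 0.02, 7: 0.01, 8: 0.005, 9: 0.003, 10: 0.002,
}


@dataclass
class SimGenomeConfig:
    """Geometry of the synthetic genome and its RDC/gene annotation."""

    n_chroms: int = 5
    chrom_length: int = 60_000_000
    wgs_bin_size: int = 10_000
    strand_bin_size: int = 200_000
    n_rdcs: int = 40
    rdc_length: int = 375_000
    gene_length: int = 2_000_000
    ttr_fraction: float = 0.6
    min_gap: int = 1_000_000
    lad_fraction: float = 0.3

    def chrom_sizes(self) -> ChromSizes:
        return ChromSizes(
            {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}
        )


@dataclass
class SimGenome:
    """A realised synthetic genome layout: sizes plus RDC intervals
    (labelled CTR/TTR in ``meta['timing_class']``), matching gene bodies
    and LAD intervals."""

    config: SimGenomeConfig
    chrom_sizes: ChromSizes
    rdcs: list[GenomicInterval]
    genes: list[GenomicInterval]
    lads: list[GenomicInterval]
    seed: int | None

    @property
    def rdc_territory(self) -> int:
        return sum(iv.length for iv in self.rdcs)

    def ttr_rdcs(self) -> list[GenomicInterval]:
        return [iv for iv in self.rdcs if iv.meta.get("timing_class") == "TTR"]

    def ctr_rdcs(self) -> list[GenomicInterval]:
        return [iv for iv in self.rdcs if iv.meta.get("timing_class") == "CTR"]


@dataclass
class SimTruth:
    """Ground-truth record emitted by every generator."""

    kind: str
    params: dict = field(default_factory=dict)
    events: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "wt") as fh:
            json.dump(
                {
                    "kind": self.kind,
                    "params": self.params,
                    "events": self.events,
                },
                fh,
                indent=1,
                default=str,
            )


def build_genome(
    config: SimGenomeConfig | None = None, seed: int | None = None
) -> SimGenome:
    """Place non-overlapping RDC intervals (with a minimum gap) uniformly
    across the genome and label a ``ttr_fraction`` of them TTR."""
    config = config or SimGenomeConfig()
    sizes = config.chrom_sizes()
    rng = np.random.default_rng(seed)
    chroms = list(sizes)
    lengths = np.array([sizes[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    placed: list[GenomicInterval] = []
    attempts = 0
    while len(placed) < config.n_rdcs:
        attempts += 1
        if attempts > 100 * config.n_rdcs:
            raise RuntimeError("could not place RDCs; genome too crowded")
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        start = int(rng.integers(0, sizes[chrom] - config.rdc_length + 1))
        end = start + config.rdc_length
        clash = any(
            iv.chrom == chrom
            and start < iv.end + config.min_gap
            and iv.start - config.min_gap < end
            for iv in placed
        )
        if not clash:
            placed.append(GenomicInterval(chrom, start, end))
    placed.sort(key=lambda iv: (iv.chrom, iv.start))
    n_ttr = int(round(config.ttr_fraction * config.n_rdcs))
    ttr_idx = set(rng.choice(config.n_rdcs, size=n_ttr, replace=False).tolist())
    rdcs, genes = [], []
    for i, iv in enumerate(placed):
        cls = "TTR" if i in ttr_idx else "CTR"
        name = f"Rdc{i + 1:02d}"
        rdcs.append(
            GenomicInterval(
                iv.chrom, iv.start, iv.end, name=name,
                meta={"timing_class": cls},
            )
        )
        # the host gene is a multi-megabase body containing the RDC,
        # mirroring the ultra-long neuronal genes RDCs live in
        pad = max(0, (config.gene_length - iv.length) // 2)
        g_start = max(0, iv.start - pad)
        g_end = min(sizes[iv.chrom], iv.end + pad)
        genes.append(
            GenomicInterval(
                iv.chrom, g_start, g_end, name=f"Gene{i + 1:02d}",
                meta={"rdc": name},
            )
        )
    # LADs: random megabase-scale blocks covering ~lad_fraction of the genome
    lads: list[GenomicInterval] = []
    target = config.lad_fraction * sizes.total_length
    covered = 0
    while covered < target:
        chrom = chroms[rng.choice(len(chroms), p=probs)]
        length = int(rng.integers(1_000_000, 5_000_000))
        start = int(rng.integers(0, sizes[chrom] - length + 1))
        lads.append(GenomicInterval(chrom, start, start + length, name=f"LAD{len(lads) + 1}"))
        covered += length
    return SimGenome(
        config=config, chrom_sizes=sizes, rdcs=rdcs, genes=genes,
        lads=lads, seed=seed,
    )


def gen_coverage_pair(
    genome: SimGenome,
    deletions: list[tuple[GenomicInterval, float]] | None = None,
    mean_depth: float = 30.0,
    seed: int | None = None,
) -> tuple[BinnedTrack, BinnedTrack, SimTruth]:
    """Poisson-distributed binned coverage for a treated/control pair.

    Control bins ~ Poisson(mean_depth). Treated bins inside a
    heterozygous deletion carried by a clone fraction ``f`` have rate
    ``mean_depth * (1 - f/2)`` (one of two alleles lost in fraction f of
    cells), scaled by the bin's overlap fraction with the deletion.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be > 0")
    deletions = deletions or []
    for iv, f in deletions:
        if not (0 < f <= 1):
            raise ValueError("clone fraction must be in (0, 1]")
        genome.chrom_sizes.validate_interval(iv)
    rng = np.random.default_rng(seed)
    bs = genome.config.wgs_bin_size
    control = BinnedTrack(bs, genome.chrom_sizes, "raw_count")
    treat = BinnedTrack(bs, genome.chrom_sizes, "raw_count")
    for chrom in genome.chrom_sizes:
        n = control.n_bins(chrom)
        rate = np.full(n, mean_depth)
        for iv, f in deletions:
            if iv.chrom != chrom:
                continue
            b0, b1 = iv.start // bs, -(-iv.end // bs)
            for b in range(b0, min(b1, n)):
                lo = max(iv.start, b * bs)
                hi = min(iv.end, (b + 1) * bs)
                frac = (hi - lo) / bs
                rate[b] *= 1 - frac * f / 2
        control.values[chrom] = rng.poisson(mean_depth, size=n).astype(float)
        treat.values[chrom] = rng.poisson(rate).astype(float)
    truth = SimTruth(
        kind="coverage_pair",
        params={"mean_depth": mean_depth, "seed": seed},
        events=[
            {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
             "name": iv.name, "clone_fraction": f}
            for iv, f in deletions
        ],
    )
    return treat, control, truth


@dataclass
class PlantedDeletion:
    """A haplotype-specific deletion planted in a subset of cells.

    Either list the affected cell indices explicitly (``cells``) or give
    ``n_cells`` to plant the deletion in that many cells drawn from the
    informative ones -- cells whose chromosome carrying the interval has
    mixed (WC) template inheritance, the only configuration in which a
    one-haplotype loss is visible to strand-resolved calling. The latter
    mirrors reporting deletions by the number of cells *showing* them.
    """

    interval: GenomicInterval
    cells: list[int] | None = None
    n_cells: int | None = None

    def __post_init__(self) -> None:
        if (self.cells is None) == (self.n_cells is None):
            raise ValueError("give exactly one of cells or n_cells")


def gen_strandseq_cohort(
    genome: SimGenome,
    n_cells: int,
    reads_per_bin: float = 50.0,
    sce_rate_per_cell: float = 2.0,
    deletion_plan: list[PlantedDeletion] | None = None,
    cell_prefix: str = "cell",
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a Strand-seq cohort of ``n_cells`` single cells.

    Each chromosome of each cell inherits two template strands drawn
    independently (so WW/CC/WC with probability 1/4 / 1/4 / 1/2).
    Sister-chromatid exchanges (Poisson-distributed per cell, placed
    uniformly) flip one haplotype's template downstream of the event.
    Per bin, each haplotype contributes Poisson(reads_per_bin / 2) reads
    to the strand dictated by its template. A planted deletion removes
    one randomly chosen haplotype's contribution over its span in the
    listed cells.
    """
    if reads_per_bin <= 0:
        raise ValueError("reads_per_bin must be > 0")
    deletion_plan = deletion_plan or []
    rng = np.random.default_rng(seed)
    bs = genome.config.strand_bin_size
    chroms = list(genome.chrom_sizes)
    lengths = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    hap_rate = reads_per_bin / 2.0
    # template inheritance is drawn up front so n_cells deletion plans
    # can target cells that are informative (WC) at their locus
    inheritance: list[dict[str, tuple[str, str]]] = [
        {
            chrom: (str(rng.choice(["W", "C"])), str(rng.choice(["W", "C"])))
            for chrom in chroms
        }
        for _ in range(n_cells)
    ]
    planned: list[tuple[GenomicInterval, list[int]]] = []
    for plant in deletion_plan:
        if plant.cells is not None:
            planned.append((plant.interval, list(plant.cells)))
            continue
        informative = [
            ci
            for ci in range(n_cells)
            if inheritance[ci][plant.interval.chrom][0]
            != inheritance[ci][plant.interval.chrom][1]
        ]
        if plant.n_cells > len(informative):
            raise ValueError(
                f"cannot plant {plant.interval} in {plant.n_cells} cells: "
                f"only {len(informative)} informative cells"
            )
        chosen = rng.choice(informative, size=plant.n_cells, replace=False)
        planned.append((plant.interval, sorted(int(c) for c in chosen)))
    rows = []
    truth_events = []
    for ci in range(n_cells):
        cell = f"{cell_prefix}{ci:03d}"
        n_sce = rng.poisson(sce_rate_per_cell)
        sces = []
        for _ in range(n_sce):
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            sces.append(
                (chrom, int(rng.integers(0, genome.chrom_sizes[chrom])),
                 int(rng.integers(0, 2)))
            )
        cell_dels = []
        for iv, cells in planned:
            if ci in cells:
                cell_dels.append((iv, int(rng.integers(0, 2))))
        for chrom in chroms:
            templates = list(inheritance[ci][chrom])
            n_bins = -(-genome.chrom_sizes[chrom] // bs)
            starts = np.arange(n_bins) * bs
            ends = np.minimum(starts + bs, genome.chrom_sizes[chrom])
            mids = (starts + ends) // 2
            # per-bin template per haplotype after SCE flips
            hap_templ = [
                np.full(n_bins, templates[0]),
                np.full(n_bins, templates[1]),
            ]
            for s_chrom, s_pos, s_hap in sces:
                if s_chrom != chrom:
                    continue
                downstream = mids >= s_pos
                cur = hap_templ[s_hap]
                hap_templ[s_hap] = np.where(
                    downstream, np.where(cur == "W", "C", "W"), cur
                )
            hap_rates = [np.full(n_bins, hap_rate), np.full(n_bins, hap_rate)]
            for iv, hap in cell_dels:
                if iv.chrom != chrom:
                    continue
                # deletions act at the assay's bin resolution: snap the
                # span outward to the 200-kb grid so edge bins are not
                # fractionally diluted
                del_lo = (iv.start // bs) * bs
                del_hi = -(-iv.end // bs) * bs
                covered = (starts >= del_lo) & (starts < del_hi)
                hap_rates[hap] = np.where(covered, 0.0, hap_rates[hap])
            watson = np.zeros(n_bins, dtype=int)
            crick = np.zeros(n_bins, dtype=int)
            for h in (0, 1):
                counts = rng.poisson(hap_rates[h])
                is_w = hap_templ[h] == "W"
                watson += np.where(is_w, counts, 0)
                crick += np.where(is_w, 0, counts)
            for b in range(n_bins):
                rows.append(
                    (cell, chrom, int(starts[b]), int(ends[b]),
                     int(watson[b]), int(crick[b]), True)
                )
        truth_events.append(
            {
                "cell": cell,
                "inheritance": {
                    chrom: "".join(inheritance[ci][chrom]) for chrom in chroms
                },
                "sces": [
                    {"chrom": c, "pos": p, "haplotype": h} for c, p, h in sces
                ],
                "deletions": [
                    {"chrom": iv.chrom, "start": iv.start, "end": iv.end,
                     "name": iv.name, "haplotype": hap}
                    for iv, hap in cell_dels
                ],
            }
        )
    cohort = pd.DataFrame(
        rows,
        columns=["cell", "chrom", "start", "end", "watson", "crick", "qc_pass"],
    )
    truth = SimTruth(
        kind="strandseq_cohort",
        params={
            "n_cells": n_cells,
            "reads_per_bin": reads_per_bin,
            "sce_rate_per_cell": sce_rate_per_cell,
            "seed": seed,
        },
        events=truth_events,
    )
    return cohort, truth


def gen_breakpoint_set(
    genome: SimGenome,
    n_cells: int = 29,
    breakpoints_per_cell: int = 10,
    rdc_hit_prob: float = 0.5,
    ttr_pref: float | None = None,
    n_total: int | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate per-cell breakpoints with tunable RDC enrichment.

    Each breakpoint lands uniformly inside a random RDC with probability
    ``rdc_hit_prob`` (a TTR-class RDC with probability ``ttr_pref`` when
    given) and otherwise uniformly outside all RDCs. ``n_total``
    overrides ``n_cells * breakpoints_per_cell``; breakpoints are dealt
    to cells round-robin.
    """
    if not (0 <= rdc_hit_prob <= 1):
        raise ValueError("rdc_hit_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    total = n_total if n_total is not None else n_cells * breakpoints_per_cell
    chroms = list(genome.chrom_sizes)
    lengths = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    ttr = genome.ttr_rdcs()
    ctr = genome.ctr_rdcs()
    rows, flags = [], []
    for i in range(total):
        cell = f"cell{i % n_cells:03d}"
        in_rdc = bool(rng.random() < rdc_hit_prob)
        if in_rdc:
            if ttr_pref is not None and ttr and ctr:
                pool = ttr if rng.random() < ttr_pref else ctr
            else:
                pool = genome.rdcs
            iv = pool[rng.integers(0, len(pool))]
            pos = int(rng.integers(iv.start, iv.end))
            chrom = iv.chrom
        else:
            while True:
                chrom = chroms[rng.choice(len(chroms), p=probs)]
                pos = int(rng.integers(0, genome.chrom_sizes[chrom]))
                if not any(
                    iv.chrom == chrom and iv.start <= pos < iv.end
                    for iv in genome.rdcs
                ):
                    break
        rows.append({"cell": cell, "chrom": chrom, "pos": pos})
        flags.append(in_rdc)
    bp = pd.DataFrame(rows, columns=["cell", "chrom", "pos"])
    truth = SimTruth(
        kind="breakpoints",
        params={
            "n_cells": n_cells,
            "n_total": total,
            "rdc_hit_prob": rdc_hit_prob,
            "ttr_pref": ttr_pref,
            "seed": seed,
        },
        events=[
            {"cell": r["cell"], "chrom": r["chrom"], "pos": r["pos"], "in_rdc": f}
            for r, f in zip(rows, flags)
        ],
    )
    return bp, truth


def gen_junction_table(
    genome: SimGenome,
    bait: tuple[str, int, str],
    n_junctions_per_library: int = 3000,
    n_libraries: int = 4,
    rdc_weight: float = 5.0,
    mh_probs: dict[int, float] | None = None,
    bait_shorten_bp: int = 0,
    base_bait_len: float = 55.0,
    bait_len_sd: float = 8.0,
    library_prefix: str = "lib",
    seed: int | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate tlx-like LAM-HTGTS junction tables.

    Prey positions are drawn genome-wide with RDC territory upweighted
    by ``rdc_weight``; the drawn microhomology ``MH`` is encoded into
    read-internal coordinates as ``Qstart = B_Qend + 1 - MH``; bait ends
    are shortened by ``bait_shorten_bp`` (reducing Blen accordingly).
    """
    if rdc_weight < 1:
        raise ValueError("rdc_weight must be >= 1")
    mh_probs = mh_probs or MH_PROBS_TMEJ
    support = np.array(sorted(mh_probs))
    pvec = np.array([mh_probs[m] for m in support], dtype=float)
    if not np.isclose(pvec.sum(), 1.0):
        raise ValueError("mh_probs must sum to 1")
    bait_chrom, bait_cut, bait_strand = bait
    if bait_strand not in ("+", "-"):
        raise ValueError("bait strand must be '+' or '-'")
    prim_start = 1_000
    rng = np.random.default_rng(seed)
    chroms = list(genome.chrom_sizes)
    lengths = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    territory = genome.rdc_territory
    genome_len = genome.chrom_sizes.total_length
    p_rdc = (rdc_weight * territory) / (
        rdc_weight * territory + (genome_len - territory)
    )
    frames = []
    drawn_all = []
    for li in range(n_libraries):
        lib = f"{library_prefix}{li + 1}"
        n = n_junctions_per_library
        mh = support[rng.choice(len(support), size=n, p=pvec)]
        # bait geometry: primer-anchored alignment of drawn length
        blen = np.maximum(
            20, np.round(rng.normal(base_bait_len, bait_len_sd, size=n))
        ).astype(int) - int(bait_shorten_bp)
        blen = np.maximum(blen, 12)
        if bait_strand == "+":
            b_rstart = np.full(n, prim_start)
            b_rend = prim_start + blen - 1
        else:
            b_rend = np.full(n, prim_start)
            b_rstart = prim_start - blen + 1
        b_qend = blen.copy()
        qstart = b_qend + 1 - mh
        # prey positions: RDC territory vs the rest
        in_rdc = rng.random(n) < p_rdc
        prey_chrom = np.empty(n, dtype=object)
        prey_pos = np.empty(n, dtype=int)
        for i in range(n):
            if in_rdc[i]:
                iv = genome.rdcs[rng.integers(0, len(genome.rdcs))]
                prey_chrom[i] = iv.chrom
                prey_pos[i] = int(rng.integers(iv.start, iv.end))
            else:
                while True:
                    c = chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]
                    pos = int(rng.integers(0, genome.chrom_sizes[c]))
                    if not any(
                        iv.chrom == c and iv.start <= pos < iv.end
                        for iv in genome.rdcs
                    ):
                        prey_chrom[i] = c
                        prey_pos[i] = pos
                        break
        frames.append(
            pd.DataFrame(
                {
                    "Library": lib,
                    "B_Rname": bait_chrom,
                    "B_Strand": bait_strand,
                    "B_Rstart": b_rstart,
                    "B_Rend": b_rend,
                    "B_Qend": b_qend,
                    "PrimStartCo": prim_start,
                    "Rname": prey_chrom,
                    "Junction": prey_pos,
                    "Strand": np.where(rng.random(n) < 0.5, "+", "-"),
                    "Qstart": qstart,
                }
            )
        )
        drawn_all.append(
            {
                "library": lib,
                "n": n,
                "n_in_rdc": int(in_rdc.sum()),
                "mh_counts": {
                    int(m): int((mh == m).sum()) for m in support
                },
            }
        )
    table = pd.concat(frames, ignore_index=True)
    truth = SimTruth(
        kind="junctions",
        params={
            "bait": {"chrom": bait_chrom, "cut": bait_cut, "strand": bait_strand},
            "rdc_weight": rdc_weight,
            "bait_shorten_bp": bait_shorten_bp,
            "base_bait_len": base_bait_len,
            "mh_probs": {int(k): float(v) for k, v in mh_probs.items()},
            "p_rdc": p_rdc,
            "seed": seed,
        },
        events=drawn_all,
    )
    return table, truth


def config_from_dict(d: dict) -> SimGenomeConfig:
    known = {f.name for f in dataclasses.fields(SimGenomeConfig)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimGenomeConfig(**d)
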