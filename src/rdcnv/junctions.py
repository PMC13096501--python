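"""LAM-HTGTS translocation-junction metrics.

LAM-HTGTS captures genome-wide "prey" double-strand breaks joined to an
engineered CRISPR bait break; each junction row of a tlx-like table
records the bait-side reference span (B_Rstart..B_Rend), the bait
alignment end within the read (B_Qend), the prey alignment start within
the read (Qstart), the nested LAM-PCR primer start (PrimStartCo), and
the prey coordinate. Three derived quantities:

* microhomology ``MH = -(Qstart - B_Qend - 1)`` -- bp shared by the two
  joined ends; MH = 0 is a direct (blunt) join, MH < 0 means inserted
  nucleotides. Read-internal coordinates are 1-based inclusive, which
  makes MH = 0 exactly the Qstart = B_Qend + 1 case.
* bait length ``Blen`` -- recovered bait sequence from the primer start
  to the junction: ``B_Rend - PrimStartCo + 1`` on a plus-strand bait,
  ``PrimStartCo - B_Rstart + 1`` on a minus-strand bait. Shortening
  across conditions indicates end resection / failed gap filling.
* JPTM -- junctions per thousand (total non-bait-chromosome junctions)
  per megabase of region, the DSB density unit.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomicInterval

logger = logging.getLogger(__name__)

TLX_REQUIRED_COLUMNS = [
    "B_Rname",
    "B_Strand",
    "B_Rstart",
    "B_Rend",
    "B_Qend",
    "PrimStartCo",
    "Rname",
    "Junction",
    "Strand",
    "Qstart",
]

INTERCHROMOSOMAL = "interchromosomal"
INTRA_NEAR_BAIT = "intra_near_bait"
INTRA_DISTAL = "intra_distal"

MH_RANGE = (0, 10)


def _normalise_strand(values: pd.Series) -> pd.Series:
    mapping = {"+": "+", "-": "-", "1": "+", "-1": "-", 1: "+", -1: "-"}
    out = values.map(lambda v: mapping.get(v, mapping.get(str(v))))
    if out.isna().any():
        raise ValueError("unrecognised strand values in tlx table")
    return out


def parse_tlx(path) -> pd.DataFrame:
    """Read a tlx-like tab-separated junction table.

    Rows violating the record invariants (B_Rstart > B_Rend, Qstart < 1,
    B_Qend < 1) are dropped with a logged count. A ``Library`` column is
    added (single default library) when absent.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(TLX_REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"tlx table missing columns: {sorted(missing)}")
    if "Library" not in df.columns:
        df["Library"] = "lib1"
    for col in ("B_Rstart", "B_Rend", "B_Qend", "PrimStartCo", "Junction", "Qstart"):
        df[col] = df[col].astype(int)
    df["B_Strand"] = _normalise_strand(df["B_Strand"])
    df["Strand"] = _normalise_strand(df["Strand"])
    ok = (
        (df["B_Rstart"] <= df["B_Rend"])
        & (df["Qstart"] >= 1)
        & (df["B_Qend"] >= 1)
    )
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("%s: dropped %d invalid junction row(s)", path, n_bad)
    return df.loc[ok].reset_index(drop=True)


def write_tlx(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def microhomology(qstart, b_qend):
    """MH = -(Qstart - B_Qend - 1), vectorised; positive = microhomology,
    zero = direct join, negative = inserted nucleotides."""
    return -(np.asarray(qstart) - np.asarray(b_qend) - 1)


def bait_length(b_rstart, b_rend, prim_start, strand):
    """Recovered bait length per record; NaN where non-positive (invalid)."""
    b_rstart = np.asarray(b_rstart, dtype=float)
    b_rend = np.asarray(b_rend, dtype=float)
    prim_start = np.asarray(prim_start, dtype=float)
    strand = np.asarray(strand)
    if not np.all(np.isin(strand, ["+", "-"])):
        raise ValueError("bait strand must be '+' or '-'")
    blen = np.where(
        strand == "+", b_rend - prim_start + 1, prim_start - b_rstart + 1
    )
    invalid = blen <= 0
    if np.any(invalid):
        logger.warning("%d junction(s) with non-positive bait length flagged", int(invalid.sum()))
    return np.where(invalid, np.nan, blen)


def classify_junctions(
    df: pd.DataFrame, bait_chrom: str, bait_cut: int, near_bp: int = 1_000_000
) -> pd.Series:
    """Junction class: interchromosomal, intra within ``near_bp`` of the
    bait cut, or intra beyond it (excluded from the paired analyses)."""
    same = df["Rname"] == bait_chrom
    near = same & ((df["Junction"] - bait_cut).abs() <= near_bp)
    out = pd.Series(INTERCHROMOSOMAL, index=df.index)
    out[same & ~near] = INTRA_DISTAL
    out[near] = INTRA_NEAR_BAIT
    return out


def add_junction_metrics(
    df: pd.DataFrame,
    bait_chrom: str | None = None,
    bait_cut: int | None = None,
) -> pd.DataFrame:
    """Annotate a parsed tlx table with MH, Blen and (optionally) class."""
    out = df.copy()
    out["MH"] = microhomology(out["Qstart"], out["B_Qend"])
    out["Blen"] = bait_length(
        out["B_Rstart"], out["B_Rend"], out["PrimStartCo"], out["B_Strand"]
    )
    if bait_chrom is not None and bait_cut is not None:
        out["Class"] = classify_junctions(out, bait_chrom, bait_cut)
    return out


def jptm(
    junction_count_in_region: float,
    total_nonbait_junctions: float,
    region_length_bp: float,
) -> float:
    """Junctions per thousand (non-bait junctions) per megabase."""
    if total_nonbait_junctions <= 0:
        raise ValueError("total_nonbait_junctions must be > 0")
    if region_length_bp <= 0:
        raise ValueError("region_length_bp must be > 0")
    return (
        (junction_count_in_region / total_nonbait_junctions)
        * 1000.0
        / (region_length_bp / 1e6)
    )


def rdc_density_table(
    df: pd.DataFrame,
    rdcs: list[GenomicInterval],
    bait_chrom: str,
) -> pd.DataFrame:
    """Per-library, per-RDC JPTM densities.

    Only prey junctions on non-bait chromosomes enter both the per-RDC
    counts and the normalising totals.
    """
    nonbait = df[df["Rname"] != bait_chrom]
    rows = []
    for lib, sub in nonbait.groupby("Library"):
        total = len(sub)
        if total == 0:
            logger.warning("library %s has no non-bait junctions; skipped", lib)
            continue
        for iv in rdcs:
            inside = (
                (sub["Rname"] == iv.chrom)
                & (sub["Junction"] >= iv.start)
                & (sub["Junction"] < iv.end)
            )
            rows.append(
                {
                    "library": lib,
                    "rdc": iv.name or str(iv),
                    "timing_class": iv.meta.get("timing_class"),
                    "count": int(inside.sum()),
                    "total_nonbait": total,
                    "length_bp": iv.length,
                    "jptm": jptm(int(inside.sum()), total, iv.length),
                }
            )
    return pd.DataFrame(rows)


def mh_spectrum(
    df: pd.DataFrame,
    class_filter: str | list[str] | None = None,
    mh_range: tuple[int, int] = MH_RANGE,
    include_insertions: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-library microhomology-length frequency spectrum.

    Junctions with MH in ``mh_range`` (0-10 bp by default) form the
    denominator; insertions (MH < 0) are excluded unless
    ``include_insertions`` adds an ``insertion`` bin. Returns
    ``(per_library_frequencies, summary)`` where the summary carries the
    across-library mean and SEM per bin.
    """
    if "MH" not in df.columns:
        df = add_junction_metrics(df)
    if class_filter is not None:
        wanted = (
            [class_filter] if isinstance(class_filter, str) else list(class_filter)
        )
        df = df[df["Class"].isin(wanted)]
    lo, hi = mh_range
    bins = list(range(lo, hi + 1))
    rows = {}
    for lib, sub in df.groupby("Library"):
        mh = sub["MH"].to_numpy()
        in_range = (mh >= lo) & (mh <= hi)
        eligible = in_range | (include_insertions & (mh < 0))
        n = int(eligible.sum())
        if n == 0:
            logger.warning("library %s has no eligible junctions; excluded", lib)
            continue
        freqs = {b: float((mh[eligible] == b).sum()) / n for b in bins}
        if include_insertions:
            freqs["insertion"] = float((mh[eligible] < 0).sum()) / n
        rows[lib] = freqs
    per_library = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    per_library.index.name = "library"
    summary = pd.DataFrame(
        {
            "mean": per_library.mean(axis=0),
            "sem": per_library.sem(axis=0, ddof=1),
        }
    )
    return per_library, summary


def binwise_group_test(
    freq_a: pd.DataFrame, freq_b: pd.DataFrame, fdr_q: float = 0.05
) -> pd.DataFrame:
    """Per-bin two-sided Welch t-test between two per-library frequency
    matrices, Benjamini-Hochberg adjusted across bins."""
    if len(freq_a) < 2 or len(freq_b) < 2:
        raise ValueError("need >= 2 libraries per condition")
    bins = [b for b in freq_a.columns if b in freq_b.columns]
    rows = []
    for b in bins:
        a = freq_a[b].to_numpy(dtype=float)
        bb = freq_b[b].to_numpy(dtype=float)
        if np.var(a) == 0 and np.var(bb) == 0 and a.mean() == bb.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, bb, equal_var=False)
        rows.append(
            {"bin": b, "mean_a": a.mean(), "mean_b": bb.mean(), "t": float(t), "p": float(p)}
        )
    table = pd.DataFrame(rows)
    table["q"] = stats.false_discovery_control(table["p"].to_numpy(), method="bh")
    table["significant"] = table["q"] <= fdr_q
    return table


def paired_rdc_density_test(dens_a, dens_b) -> tuple[float, float]:
    """Paired two-tailed t-test on per-RDC mean densities across two
    conditions (same RDC order in both). Returns ``(t, p)``; all-zero
    differences give p = 1 by convention."""
    a = np.asarray(dens_a, dtype=float)
    b = np.asarray(dens_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need matched arrays with n >= 2")
    diffs = a - b
    if np.all(diffs == 0):
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
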