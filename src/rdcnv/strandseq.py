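"""Strand-inheritance-based single-cell copy-number calling.

Strand-seq sequences only parental template strands, so each chromosome
of a single cell inherits one of three template combinations: WW, CC or
WC ("mixed"). Only WC segments permit strand-resolved CN calling: there,
Watson and Crick reads each tag one haplotype, so the loss of one
haplotype appears as a one-strand coverage dropout while the other
strand acts as an internal diploid reference.

The module classifies per-bin strand states, segments chromosomes into
inheritance blocks (sister-chromatid exchanges switch the state
downstream), calls gene-level and genome-wide copy number over mixed
segments, and provides the one-sided Welch-t label-permutation test used
to compare treated and control cell populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .core import GenomicInterval

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["cell", "chrom", "start", "end", "watson", "crick", "qc_pass"]


class SegmentState(Enum):
    WATSON_ONLY = "WATSON_ONLY"
    CRICK_ONLY = "CRICK_ONLY"
    MIXED = "MIXED"
    NO_SIGNAL = "NO_SIGNAL"


@dataclass
class StrandParams:
    """Thresholds for strand-state classification and CN calling.

    min_reads:
        Minimum pooled read count for a call (bins below are NO_SIGNAL).
    minor_frac:
        Minimum minor-strand fraction for "significant signal on both
        strands" (MIXED / CN 2).
    min_run:
        Minimum run length, in bins, for a strand-state segment; shorter
        runs are treated as noise and merged into a neighbour.
    embedded_cov_ratio:
        A single-strand run adjacent to MIXED segments is absorbed back
        into the mixed segment (as candidate one-haplotype loss rather
        than an SCE) when its median total coverage falls below this
        fraction of the chromosome's MIXED-bin median; a true SCE keeps
        full coverage on the single strand.
    """

    min_reads: int = 10
    minor_frac: float = 0.1
    min_run: int = 5
    embedded_cov_ratio: float = 0.75

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not (0 < self.minor_frac < 0.5):
            raise ValueError("minor_frac must be in (0, 0.5)")


def classify_strand_state(
    watson: int,
    crick: int,
    min_reads: int = 10,
    minor_frac: float = 0.1,
) -> SegmentState:
    """Classify one bin/segment from its Watson and Crick read counts."""
    if watson < 0 or crick < 0:
        raise ValueError("read counts must be non-negative")
    total = watson + crick
    if total < min_reads:
        return SegmentState.NO_SIGNAL
    if min(watson, crick) / total >= minor_frac:
        return SegmentState.MIXED
    return (
        SegmentState.WATSON_ONLY if watson >= crick else SegmentState.CRICK_ONLY
    )


def _run_length_encode(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """(start, stop, label) runs over an integer label array."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i, int(labels[start])))
            start = i
    return runs


_STATE_CODE = {
    SegmentState.NO_SIGNAL: -1,
    SegmentState.WATSON_ONLY: 0,
    SegmentState.CRICK_ONLY: 1,
    SegmentState.MIXED: 2,
}
_CODE_STATE = {v: k for k, v in _STATE_CODE.items()}


def segment_inheritance(
    watson: np.ndarray, crick: np.ndarray, params: StrandParams
) -> np.ndarray:
    """Per-bin inheritance labels for one chromosome of one cell.

    Returns an array of :class:`SegmentState` codes (see ``_STATE_CODE``)
    built in four steps: per-bin classification; gap filling of
    NO_SIGNAL bins by nearest informative state (for segmentation only;
    the NO_SIGNAL label is restored at the end); run-length smoothing
    that merges runs shorter than ``min_run`` into their longer
    neighbour; and absorption of low-coverage single-strand runs
    flanking MIXED segments back into MIXED, so a focal one-haplotype
    deletion is retained as CN evidence rather than mistaken for a
    sister-chromatid-exchange boundary.
    """
    watson = np.asarray(watson)
    crick = np.asarray(crick)
    n = len(watson)
    raw = np.array(
        [
            _STATE_CODE[
                classify_strand_state(
                    int(w), int(c), params.min_reads, params.minor_frac
                )
            ]
            for w, c in zip(watson, crick)
        ]
    )
    if np.all(raw == -1):
        return raw
    # fill NO_SIGNAL bins with the nearest informative state
    filled = raw.copy()
    informative = np.flatnonzero(raw != -1)
    for i in np.flatnonzero(raw == -1):
        j = informative[np.argmin(np.abs(informative - i))]
        filled[i] = raw[j]
    # merge sub-threshold runs into the larger neighbour until stable
    runs = _run_length_encode(filled)
    while len(runs) > 1:
        lengths = [stop - start for start, stop, _ in runs]
        shortest = int(np.argmin(lengths))
        if lengths[shortest] >= params.min_run:
            break
        start, stop, _label = runs[shortest]
        left = runs[shortest - 1] if shortest > 0 else None
        right = runs[shortest + 1] if shortest < len(runs) - 1 else None
        if right is None or (
            left is not None and (left[1] - left[0]) >= (right[1] - right[0])
        ):
            target = left
        else:
            target = right
        filled[start:stop] = target[2]
        runs = _run_length_encode(filled)
    # absorb deletion-like single-strand runs into flanking MIXED segments
    total = watson + crick
    mixed_bins = filled == _STATE_CODE[SegmentState.MIXED]
    if mixed_bins.any():
        mixed_median = float(np.median(total[mixed_bins]))
        changed = True
        while changed:
            changed = False
            runs = _run_length_encode(filled)
            for k, (start, stop, label) in enumerate(runs):
                if label not in (0, 1):
                    continue
                neighbours = []
                if k > 0:
                    neighbours.append(runs[k - 1][2])
                if k < len(runs) - 1:
                    neighbours.append(runs[k + 1][2])
                if _STATE_CODE[SegmentState.MIXED] not in neighbours:
                    continue
                run_median = float(np.median(total[start:stop]))
                if run_median < params.embedded_cov_ratio * mixed_median:
                    filled[start:stop] = _STATE_CODE[SegmentState.MIXED]
                    changed = True
                    break
    filled[raw == -1] = -1
    return filled


def _bin_cn(watson: int, crick: int, params: StrandParams) -> int | None:
    """CN call for one mixed-segment bin; None when below min_reads."""
    total = watson + crick
    if total < params.min_reads:
        return None
    if min(watson, crick) / total >= params.minor_frac:
        return 2
    return 1


class StrandCell:
    """One cell's 200-kb Watson/Crick count table with cached segmentation.

    ``df`` needs columns chrom, start, end, watson, crick, qc_pass and
    must tile each chromosome with a uniform bin grid.
    """

    def __init__(self, df: pd.DataFrame, params: StrandParams | None = None):
        self.params = params or StrandParams()
        self.df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        if (self.df["watson"] < 0).any() or (self.df["crick"] < 0).any():
            raise ValueError("read counts must be non-negative")
        self._labels: dict[str, np.ndarray] = {}

    def _chrom_frame(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"] == chrom]

    def inheritance_labels(self, chrom: str) -> np.ndarray:
        if chrom not in self._labels:
            sub = self._chrom_frame(chrom)
            self._labels[chrom] = segment_inheritance(
                sub["watson"].to_numpy(),
                sub["crick"].to_numpy(),
                self.params,
            )
        return self._labels[chrom]

    def _mixed_qc_mask(self, chrom: str) -> np.ndarray:
        sub = self._chrom_frame(chrom)
        labels = self.inheritance_labels(chrom)
        return (labels == _STATE_CODE[SegmentState.MIXED]) & sub[
            "qc_pass"
        ].to_numpy(dtype=bool)

    def gene_cn(self, gene: GenomicInterval) -> int | None:
        """Gene-level copy number in {1, 2} or None (missing).

        Pools Watson and Crick counts over qc-passing bins that overlap
        the gene and lie within MIXED-inheritance segments. CN 2 when
        both pooled strands carry significant signal, CN 1 when only
        one does, missing when no eligible bins (or too few reads).
        """
        sub = self._chrom_frame(gene.chrom)
        if sub.empty:
            return None
        mask = self._mixed_qc_mask(gene.chrom) & (
            (sub["start"].to_numpy() < gene.end)
            & (sub["end"].to_numpy() > gene.start)
        )
        if not mask.any():
            return None
        w = int(sub["watson"].to_numpy()[mask].sum())
        c = int(sub["crick"].to_numpy()[mask].sum())
        return _bin_cn(w, c, self.params)

    def genome_mean_cn(self) -> float | None:
        """Mean of per-bin CN calls over all MIXED qc-passing bins."""
        calls: list[int] = []
        for chrom in self.df["chrom"].unique():
            sub = self._chrom_frame(chrom)
            mask = self._mixed_qc_mask(chrom)
            for w, c in zip(
                sub["watson"].to_numpy()[mask], sub["crick"].to_numpy()[mask]
            ):
                cn = _bin_cn(int(w), int(c), self.params)
                if cn is not None:
                    calls.append(cn)
        if not calls:
            return None
        return float(np.mean(calls))


def call_gene_cn(
    cell_df: pd.DataFrame,
    gene: GenomicInterval,
    params: StrandParams | None = None,
) -> int | None:
    return StrandCell(cell_df, params).gene_cn(gene)


def genome_mean_cn(
    cell_df: pd.DataFrame, params: StrandParams | None = None
) -> float | None:
    return StrandCell(cell_df, params).genome_mean_cn()


def split_cells(cohort_df: pd.DataFrame) -> dict[str, pd.DataFrame]:
    return {
        str(cell): sub.drop(columns=["cell"]).reset_index(drop=True)
        for cell, sub in cohort_df.groupby("cell", sort=True)
    }


LOW_CN_THRESHOLD = 1.92


def gene_cn_table(
    cohort_df: pd.DataFrame,
    genes: list[GenomicInterval],
    params: StrandParams | None = None,
    low_cn_threshold: float = LOW_CN_THRESHOLD,
) -> pd.DataFrame:
    """Per-cell per-gene CN calls plus genome-wide mean CN.

    Returns one row per cell with one column per gene name (NaN where
    the call is missing), a ``genome_mean_cn`` column and a ``low_cn``
    flag marking cells with genome-wide mean CN below the threshold
    (default 1.92), the criterion for cells carrying large losses.
    """
    rows = []
    for cell, df in split_cells(cohort_df).items():
        sc = StrandCell(df, params)
        row: dict[str, object] = {"cell": cell}
        for g in genes:
            cn = sc.gene_cn(g)
            row[g.name or str(g)] = np.nan if cn is None else cn
        mean_cn = sc.genome_mean_cn()
        row["genome_mean_cn"] = mean_cn
        row["low_cn"] = mean_cn is not None and mean_cn < low_cn_threshold
        rows.append(row)
    return pd.DataFrame(rows)


def _welch_t(
    mean_a, var_a, n_a, mean_b, var_b, n_b
) -> np.ndarray:
    """Vectorised unequal-variance t; 0 for identical degenerate groups,
    +-inf when means differ but both variances are zero."""
    denom = np.sqrt(var_a / n_a + var_b / n_b)
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
        t = np.where(
            denom == 0, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t
        )
    return t


def welch_label_permutation(
    group_a,
    group_b,
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: str = "less",
) -> tuple[float, float]:
    """One-sided (or two-sided) Welch-t label-permutation test.

    Cell labels are shuffled between conditions preserving group sizes;
    the permutation p-value uses the add-one convention
    ``(1 + #{as extreme}) / (1 + n_perm)``, so the attainable floor with
    10,000 permutations is 1/10001 ~= 1e-4. ``alternative="less"`` tests
    group_a < group_b. Returns ``(p_value, observed_t)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError("alternative must be less, greater or two-sided")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    t_obs = float(
        _welch_t(
            a.mean(), a.var(ddof=1), n_a, b.mean(), b.var(ddof=1), n_b
        )
    )
    if np.isnan(t_obs):  # pragma: no cover - guarded by _welch_t
        t_obs = 0.0
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        logger.warning("degenerate groups (zero variance, equal means); p = 1")
        return 1.0, 0.0
    rng = np.random.default_rng(seed)
    # each row of `order` is a random permutation of the pooled values
    order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    perm = pooled[order]
    pa, pb = perm[:, :n_a], perm[:, n_a:]
    t_perm = _welch_t(
        pa.mean(axis=1),
        pa.var(axis=1, ddof=1),
        n_a,
        pb.mean(axis=1),
        pb.var(axis=1, ddof=1),
        n_b,
    )
    if alternative == "less":
        extreme = t_perm <= t_obs
    elif alternative == "greater":
        extreme = t_perm >= t_obs
    else:
        extreme = np.abs(t_perm) >= abs(t_obs)
    p = (1 + int(extreme.sum())) / (1 + n_perm)
    return float(p), t_obs


def condition_comparison(
    cn_table_a: pd.DataFrame,
    cn_table_b: pd.DataFrame,
    genes: list[str],
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: str = "less",
) -> pd.DataFrame:
    """Per-gene Welch-t label-permutation p-values between two cohorts.

    Cells with a missing call at a gene are excluded for that gene.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for gene in genes:
        a = cn_table_a[gene].dropna().to_numpy(dtype=float)
        b = cn_table_b[gene].dropna().to_numpy(dtype=float)
        if a.size < 2 or b.size < 2:
            rows.append(
                {"gene": gene, "n_a": a.size, "n_b": b.size, "t": np.nan, "p": np.nan}
            )
            continue
        p, t = welch_label_permutation(
            a,
            b,
            n_perm=n_perm,
            seed=int(rng.integers(2**31)),
            alternative=alternative,
        )
        rows.append({"gene": gene, "n_a": a.size, "n_b": b.size, "t": t, "p": p})
    return pd.DataFrame(rows)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    df["qc_pass"] = df["qc_pass"].astype(bool)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
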