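# Methods

This note documents the models and procedures `rdcnv` implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Coordinate and track model

All coordinates are 0-based, half-open `[start, end)` (BED convention);
1-based inputs must be converted at the reader boundary. Binned tracks
tile each chromosome with `ceil(L / bin_size)` fixed-width bins and
carry one float per bin; missing data is an explicit NaN sentinel, never
zero, so uncovered bins cannot masquerade as zero coverage. `value_kind`
(`raw_count`, `depth_normalized`, `log2_ratio`) is declared by the
producer, never inferred. Regional means are unweighted over all bins
whose span intersects the region — a partially overlapped bin counts
fully. bedGraph records that do not align to the bin grid are resampled
by coverage-weighted averaging; overlapping records are an error.
Non-standard contigs (names containing `_`) are dropped at read time
with a logged warning. The WGS bin width is a required parameter
(default 10 kb in the simulations); no single canonical value exists for
binned coverage ratios, so it is surfaced rather than hard-coded.

## Coverage-erosion scoring

Given treated and control raw-count tracks on the same grid, the ratio
track is

    r_i = log2( ((t_i + pc) / d_t) / ((c_i + pc) / d_c) )

with `d_t`, `d_c` the genome-wide mean per-bin depths (the depth-ratio
normalisation) and `pc` a pseudocount. The pseudocount is applied in
**raw-read units** (default 0.5 reads) *before* depth scaling: applied
after normalisation (where bin values are ≈1) it would shrink a planted
f = 0.8 heterozygous deletion from log2(0.6) ≈ −0.74 to −0.45 and bias
every effect size; in read units it only regularises near-empty bins.

The null model shuffles the RDC set `n_sets` times (default 10),
preserving each interval's length, drawing the chromosome with
probability proportional to its length, placing the start uniformly, and
rejection-resampling any placement that overlaps the exclusion set
(normally the RDCs themselves, optionally plus a blacklist). The pooled
per-region means of all shuffled sets give a single μ₀ and σ₀ (sample
SD); per-RDC deviations are (m − μ₀)/σ₀ and the erosion flag fires at
≤ −3. A single pooled band is used rather than per-rank or
length-stratified bands; with length-matched shuffles the pooled SD is
the natural single summary, and the synthetic genome uses
constant-length RDCs so the band has exactly one interpretation.

Calibration: on null synthetic genomes the flag rate per clean region
is ~0.2–0.3%, consistent with the normal −3 SD tail (≈0.13%) plus
estimation noise in σ₀ (400 pooled null means). This tail is
irreducible: any correctly calibrated −3 SD test will flag roughly 1 in
~700 clean regions, so analyses over many regions should expect
occasional single false flags.

The hypergeometric enrichment is upper-tail, P(X ≥ k) for k of n CNVs
landing in the K RDC genes of an N-gene population; with k = n the tail
equals the point mass, but the upper-tail reading is fixed for general
inputs. The gene-population size is a parameter, not a constant. The
LAD association uses the Pearson chi-square **without** Yates continuity
correction (1 df, two-sided); on the 2×2 table [[5, 1], [17, 40]] the
uncorrected statistic gives p = 0.0089, the corrected one ≈ 0.03 — the
uncorrected variant is the one whose p matches the published analysis
of that table.

## Strand-seq CNV calling

Strand-seq reads only parental template strands. Each chromosome of a
cell inherits WW, CC or WC templates (probabilities ¼/¼/½ under random
segregation); only WC ("mixed") segments are informative for CNV
calling, because there each strand tags one haplotype and the intact
strand is an internal diploid reference.

Per-bin classification uses two thresholds: `min_reads` (default 10
pooled reads; below it a bin is NO_SIGNAL) and `minor_frac` (default
0.1): a bin is MIXED when the minor strand holds ≥ `minor_frac` of
reads, otherwise Watson- or Crick-only. "Significant signal on both
strands" has no canonical definition; the minor-fraction rule is the
simplest scale-free choice and both knobs are surfaced.

Segmentation into inheritance blocks proceeds in four steps: per-bin
classification; nearest-neighbour filling of NO_SIGNAL bins (for
segmentation only); run-length smoothing that merges runs shorter than
`min_run` (default 5 bins = 1 Mb) into their longer neighbour; and a
coverage-guarded absorption step. The absorption step is the one
genuinely open design point: a focal one-haplotype deletion inside a WC
segment looks locally Watson- or Crick-only, exactly like a
sister-chromatid-exchange (SCE) segment. The two are distinguished by
total coverage — an SCE moves both haplotypes' reads onto one strand
(full coverage), a deletion loses one haplotype (≈half coverage) — so a
single-strand run adjacent to MIXED segments is folded back into the
mixed segment when its median total coverage is below
`embedded_cov_ratio` (default 0.75) of the chromosome's MIXED-bin
median. Without this guard every multi-bin deletion would be excluded
from calling as a "non-mixed segment", which would defeat the assay.

Gene-level CN pools Watson and Crick counts over qc-passing bins that
overlap the gene and lie in MIXED segments: CN 2 if both pooled strands
pass the presence test (minor fraction ≥ `minor_frac`, total ≥
`min_reads`), CN 1 if only one does, missing if no eligible bins.
Pooling (rather than per-bin voting) was chosen as the more powerful
aggregate for sparse single-cell counts. Genome-wide mean CN averages
per-bin CN calls over all MIXED qc bins — per-bin rather than
per-segment, as the finer, segmentation-order-free statistic — and
cells with mean CN < 1.92 are flagged `low_cn` (large-loss carriers).
Calls are symmetric under a global Watson/Crick swap.

The condition comparison is a label-permutation test on the Welch
(unequal-variance) t statistic, one-sided by default (treated <
control), with the add-one convention p = (1 + #{t\* ≤ t_obs})/(1 + N);
ties count as extreme. With N = 10,000 the attainable floor is
1/10001 ≈ 1e-4. A label permutation at cohort size ~40 + 40 cannot
reach p < 0.05 unless at least ~5 cells carry the event (the most
extreme relabelling still has probability > 0.05 otherwise); planted
cohorts in the tests therefore use detected-cell counts of {14, 8, 6}.

## Breakpoint–RDC enrichment

Breakpoint coordinates from single cells carry megabase-scale
uncertainty, so each expands into a symmetric window (default
half-width 1 Mb → 2-Mb windows), clipped at chromosome ends. Hits are
binary per window (a window crossing several RDCs counts once) and the
statistic is the total hit count over all cells. The null redraws each
breakpoint's position **uniformly** on its own chromosome — cell and
chromosome assignments fixed — re-expands and re-counts; uniform redraw
is the minimal choice where the within-chromosome law is otherwise
unspecified, and independent redraw (rather than a spacing-preserving
block shuffle) is used and noted. p uses the add-one convention;
z = (obs − mean(null))/sd(null), with z undefined (and warned) when the
null is degenerate. Window clipping does not distort the test: a
clipped window intersects a region iff the unclipped condition
`region.start < pos + h and region.end > pos − h` holds. The TTR
subset test restricts to breakpoints whose windows hit any RDC and
reruns the same permutation against the TTR-class regions only.

## Junction metrics

tlx-like tables are tab-separated with at least B_Rname, B_Strand,
B_Rstart, B_Rend, B_Qend, PrimStartCo, Rname, Junction, Strand, Qstart
(plus an optional Library column); rows violating B_Rstart ≤ B_Rend,
Qstart ≥ 1 or B_Qend ≥ 1 are dropped with a logged count.
Read-internal coordinates (Qstart, B_Qend) are 1-based inclusive — the
convention under which MH = −(Qstart − B_Qend − 1) yields exactly 0 for
a direct join at Qstart = B_Qend + 1.

JPTM normalises per-RDC junction counts by the library's total
junctions on non-bait chromosomes (×1000) and the RDC length in Mb;
bait-chromosome junctions are excluded from both numerator and
denominator to avoid bait-proximal pile-up. Junction classes are
interchromosomal, intra-chromosomal within 1 Mb of the bait cut, and
intra-distal (excluded from the near-bait analyses); the bait cut
position for the 1-Mb rule is supplied by the caller. MH spectra are
computed per library over MH ∈ 0–10 bp (insertions excluded from the
denominator unless requested) and summarised as mean ± SEM across
libraries — per-library-then-average, matching replicate-level error
bars, rather than pooling. Binwise condition contrasts use two-sided
Welch t-tests with Benjamini–Hochberg adjustment across bins; paired
per-RDC density contrasts use the paired two-tailed t-test, with p = 1
by convention when all differences are zero.

## Synthetic data

The generators emulate the statistical structure the analyses assume at
a reduced scale chosen to keep the full suite within desk-scale compute:
5 chromosomes × 60 Mb with 40 RDC intervals of constant 375 kb
(territory 15 Mb = 5.0% of the genome), 60% labelled TTR / 40% CTR, and
host genes of 2 Mb containing their RDC (mirroring the ultra-long
neuronal genes RDCs occupy, and giving gene bodies ≈10 strand bins).
Constant RDC length makes the shuffled null homoscedastic, so the ±3 SD
band is exact rather than a variance mixture.

* Coverage pairs: per-bin Poisson counts at `mean_depth` (default 30
  reads per 10-kb bin); a heterozygous deletion carried by clone
  fraction f scales the treated rate by 1 − f/2 over its span.
* Strand-seq cohorts: per-chromosome templates drawn ¼/¼/½; SCE counts
  Poisson per cell (default 2 at this genome size — scaled from ~8–9.5
  per cell on a full mammalian genome) with uniform positions flipping
  one haplotype downstream; per-haplotype Poisson(reads_per_bin/2)
  counts routed to Watson/Crick by template. Planted deletions zero one
  randomly chosen haplotype over their span, snapped outward to the
  200-kb grid (the assay's resolution); a plan may target k cells drawn
  from the informative (WC at the locus) cells, matching how per-gene
  cell counts are reported (cells *showing* the loss).
* Breakpoints: each lands inside a uniformly chosen RDC with
  probability `rdc_hit_prob` (TTR-class with probability `ttr_pref`),
  otherwise uniformly outside; cells are assigned round-robin.
* Junctions: prey positions genome-wide with RDC territory upweighted
  ×`rdc_weight`; microhomology drawn from a configurable spectrum
  (TMEJ-like default peaked at 2 bp; a direct-joining spectrum peaks at
  0) and encoded via Qstart = B_Qend + 1 − MH; bait alignments are
  primer-anchored with Normal(55, 8) lengths (floored at 12 bp),
  shortened by `bait_shorten_bp` to model end resection.

Every generator is deterministic given a seed and emits a
machine-readable truth record. What the generators do **not** emulate:
GC/mappability bias, overdispersion beyond Poisson, read-level
sequence, SCE hotspots, correlated breakpoints within a cell beyond the
cell/chromosome bookkeeping, and library-size variation between
junction libraries. Passing tests therefore demonstrate correctness of
the statistical machinery under the stated noise model, not robustness
to every artefact of real sequencing data.

## Problem sizes and known limitations

The test and acceptance runs use the reduced genome above with 10
shuffle sets, 10,000 permutations for headline p-values (199–2,000 for
calibration sweeps), 50 erosion replicates, 10–20 cohort replicates and
29-cell breakpoint sets — sizes chosen so the whole suite runs in a few
minutes on one CPU while keeping every statistic in its asymptotic
regime.

Known limitations: a −3 SD flag over many clean regions has an
irreducible ~0.1–0.3% per-region false-flag rate, so "zero false flags"
is only ever probable, not guaranteed, in any single run; terminal
single-strand runs at full coverage are read as SCEs, so a terminal
deletion of a *whole* haplotype chromosome arm with no flanking mixed
coverage is indistinguishable from an SCE near the centromere; the
clustered permutation assumes breakpoints are exchangeable within a
chromosome given the cell, which understates clustering of multiple
breakpoints from a single complex event; and the junction generator
draws library sizes as fixed counts, so JPTM sampling noise across
libraries is binomial only.
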