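"""Clustered permutation test: do single-cell breakpoints hit RDCs?

Simulates 29 cells with 300 breakpoints, 85% placed inside RDC intervals
covering 5% of the genome (the rest uniform), expands each breakpoint
into a 2-Mb window, counts binary RDC hits, and compares the total
against 10,000 permutations that redraw each breakpoint uniformly within
its own chromosome while keeping the per-cell, per-chromosome structure.
The TTR-class subset test then asks whether the RDC-hitting breakpoints
prefer timing-transition-region RDCs.
"""

from rdcnv import (
    build_genome,
    clustered_permutation_test,
    gen_breakpoint_set,
    ttr_subset_test,
)

genome = build_genome(seed=1)
breakpoints, truth = gen_breakpoint_set(
    genome, n_cells=29, rdc_hit_prob=0.85, ttr_pref=0.7, n_total=300, seed=2
)

res = clustered_permutation_test(
    breakpoints, genome.rdcs, genome.chrom_sizes, n_perm=10_000, seed=3
)
print(
    f"observed {res.observed_hits}/{res.n_windows} breakpoint windows hit "
    f"an RDC (null mean {res.null_mean:.1f} +- {res.null_sd:.1f})"
)
print(f"one-sided p = {res.p_one_sided:.3g}, z = {res.z_score:.1f}")

ttr = ttr_subset_test(
    breakpoints, genome.rdcs, genome.ttr_rdcs(), genome.chrom_sizes,
    n_perm=10_000, seed=4,
)
print(
    f"\nTTR subset: {ttr.observed_hits}/{ttr.n_windows} RDC-hitting windows "
    f"also hit a TTR-class RDC, p = {ttr.p_one_sided:.3g}, z = {ttr.z_score:.1f}"
)
# A p at the 1e-4 floor with strongly positive z mirrors genuine
# enrichment; the TTR preference (0.7 vs the 0.6 TTR territory share)
# yields a milder but positive signal.
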