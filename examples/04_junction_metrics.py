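"""LAM-HTGTS junction metrics: JPTM density, microhomology, bait length.

Simulates junction libraries for two conditions -- a TMEJ-like condition
whose joints prefer 2-bp microhomology, and a direct-joining condition
with blunt joints and 15-bp shorter recovered bait ends -- then computes
per-RDC junction densities (JPTM), per-library microhomology spectra
with the binwise Welch/FDR test, and the bait-length contrast.
"""

from rdcnv import (
    add_junction_metrics,
    binwise_group_test,
    build_genome,
    gen_junction_table,
    mh_spectrum,
    paired_rdc_density_test,
    rdc_density_table,
)
from rdcnv.simulate import MH_PROBS_DIRECT, MH_PROBS_TMEJ

genome = build_genome(seed=1)
bait = ("chr1", 30_000_000, "+")

tmej, _ = gen_junction_table(
    genome, bait, n_junctions_per_library=4000, n_libraries=4,
    rdc_weight=6.0, mh_probs=MH_PROBS_TMEJ, seed=2,
)
direct, _ = gen_junction_table(
    genome, bait, n_junctions_per_library=4000, n_libraries=4,
    rdc_weight=3.0, mh_probs=MH_PROBS_DIRECT, bait_shorten_bp=15, seed=3,
)

spec_a, summary_a = mh_spectrum(tmej)
spec_b, summary_b = mh_spectrum(direct)
print("microhomology spectrum (mean frequency per MH length):")
print("  TMEJ-like  :", [f"{v:.2f}" for v in summary_a['mean'][:6]])
print("  direct-join:", [f"{v:.2f}" for v in summary_b['mean'][:6]])
print(f"  TMEJ peak at {summary_a['mean'].idxmax()} bp; "
      f"direct-join peak at {summary_b['mean'].idxmax()} bp")

binwise = binwise_group_test(spec_a, spec_b, fdr_q=0.05)
shifted = binwise.loc[binwise["significant"], "bin"].tolist()
print(f"  bins differing at FDR q <= 0.05: {shifted}")

dens_a = rdc_density_table(tmej, genome.rdcs, bait[0])
dens_b = rdc_density_table(direct, genome.rdcs, bait[0])
mean_a = dens_a.groupby("rdc")["jptm"].mean()
mean_b = dens_b.groupby("rdc")["jptm"].mean()
t, p = paired_rdc_density_test(mean_a.to_numpy(), mean_b.loc[mean_a.index].to_numpy())
print(f"\nper-RDC DSB density (JPTM): {mean_a.mean():.2f} vs {mean_b.mean():.2f}, "
      f"paired t = {t:.1f}, p = {p:.2g}")

blen_a = add_junction_metrics(tmej).groupby("Library")["Blen"].mean().mean()
blen_b = add_junction_metrics(direct).groupby("Library")["Blen"].mean().mean()
print(f"mean recovered bait length: {blen_a:.1f} vs {blen_b:.1f} bp "
      f"(difference {blen_a - blen_b:.1f} bp; 15 bp planted)")
# The 2-bp microhomology preference, its reversion to direct joining,
# the drop in RDC junction density and the ~15-bp bait shortening are
# the four junction-level signatures the pipeline quantifies.
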