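"""Relate R-loop peaks to breakpoint junctions and replication timing.

Two junction classes are compared: TSS-proximal junctions in short active
genes, and clustered body junctions in long RDC-like genes. For each, the
fraction of junctions with an R-loop peak within 2 kb is computed, plus
bp-weighted median replication timing of peaks vs RDC genes.
"""
import numpy as np

from rloopscape import integrate as itg, peak_hmm
from rloopscape import simulate as sim

s = sim.simulate(sim.SimConfig(seed=1))
peaks = list(peak_hmm.call_peaks_from_tracks([s.drip], s.chrom_sizes,
                                             bin_size=100))

for jset in (s.junctions_tss, s.junctions_rdc):
    n_in, n_tot, frac = itg.junction_peak_proximity(jset, peaks, window=2000)
    print(f"{jset.label:13s}: {n_in:4d} of {n_tot} junctions within 2 kb of "
          f"a peak ({100 * frac:.2f}%)")

rdc_genes = [g for g in s.genes if s.truth.attrs[g.gene_id].is_rdc]
per_gene = itg.peaks_near_junctions_per_gene(peaks, s.junctions_rdc,
                                             rdc_genes, window=2000)
print("peaks near junctions per RDC-like gene:", per_gene)

peak_t = itg.peak_timing_values(peaks, s.timing)
rdc_t = [itg.interval_timing(g.span(), s.timing) for g in rdc_genes]
print(f"median timing ratio: peaks {np.median(peak_t):+.2f}, "
      f"RDC-like genes {np.median(rdc_t):+.2f}")
# The TSS-proximal junction class sits almost entirely within 2 kb of a
# peak while RDC junctions rarely do, and peaks replicate early (+) while
# RDC-like genes replicate late (-) — the planted contrast the method is
# designed to expose.
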