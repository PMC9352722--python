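"""Gene-set enrichment of promoter R-loop genes.

Hypergeometric over-representation of each term in the gene list, BH
q-values, the enrichment-factor filter (p < 0.01, >= 3 counts, factor
> 1.5), and kappa-similarity clustering of the surviving terms.
"""
from rloopscape import integrate as itg, peak_hmm
from rloopscape import simulate as sim
from rloopscape.stats import filter_and_cluster_terms, hypergeometric_enrichment

s = sim.simulate(sim.SimConfig(seed=1))
peaks = list(peak_hmm.call_peaks_from_tracks([s.drip], s.chrom_sizes,
                                             bin_size=100))
promoter_genes = {
    g.gene_id for g in s.genes
    if any(p.overlaps(g.promoter(2000)) for p in peaks)
}
universe = [g.gene_id for g in s.genes]
gene_sets = sim.generate_gene_sets(s.truth, s.config)
records = [hypergeometric_enrichment(promoter_genes, members, universe, term)
           for term, members in sorted(gene_sets.items())]
clustered = filter_and_cluster_terms(records)

print(f"gene list: {len(promoter_genes)} genes with promoter R-loop peaks")
print(f"{len(clustered)} of {len(records)} terms survive the filters\n")
for r in clustered:
    print(f"  {r.term:25s} k={r.k:3d} K={r.K:3d} p={r.p:.2e} "
          f"q={r.q:.2e} factor={r.factor:.2f} cluster={r.cluster}")
# The planted skewed-promoter term dominates (tiny p, factor > 1.5) while
# random terms are filtered out — the enrichment machinery separates the
# planted biology from noise.
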