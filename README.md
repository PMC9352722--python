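# rloopscape

Genome-wide R-loop landscape analysis for neural stem/progenitor-style
DRIP-seq experiments: HMM-based peak calling, four-state GC-skew gene
classification, transcription classing, genomic-feature annotation, and
integration of R-loop peaks with DNA double-strand-break (DSB) junction
classes and replication timing — all exercisable end-to-end on synthetic
genomes with planted ground truth.

## The scientific problem

R-loops are three-stranded structures (an RNA:DNA hybrid plus a displaced
single strand) that form co-transcriptionally, preferentially where the
non-template strand is G-rich (positive GC skew, (G−C)/(G+C) > 0).
DRIP-seq maps them genome-wide. In neural progenitors under mild
replication stress, two classes of recurrent DSBs are of interest:
junctions clustered within ±2 kb of active transcription start sites, and
recurrent DSB clusters (RDCs) in long, late-replicating neural genes. The
pipeline asks where R-loops form, which sequence (GC skew) and
transcription features predict them, and how they relate spatially to the
two breakpoint classes and to replication timing.

## What the package computes

- **Peak calling** (`rloopscape.peak_hmm`): binned DRIP coverage is
  log1p-transformed and segmented by a two-state Gaussian-emission hidden
  Markov model fitted with Baum–Welch; the Viterbi path (ties broken
  toward background) becomes peaks after gap merging and a minimum-length
  filter. Replicates are pooled by default; a per-replicate
  intersect-*k* mode is available.
- **GC-skew classification** (`rloopscape.gc_skew`): a four-state HMM
  over nucleotide emissions (STRONG / WEAK / NONE / REVERSE skew) decodes
  each gene's promoter (TSS ± 2 kb) on its coding-strand orientation;
  the gene takes the highest-priority state touching the promoter.
  Stringent (expected segment 10⁶ bp) and lenient (7.6 kb) presets.
- **Transcription** (`rloopscape.transcription`): GRO-seq RPKM per gene
  span; classes active (RPKM ≥ 0.025), ambiguous (≥ 0.0025), inactive;
  greedy nearest-log-rate matching builds transcription-controlled gene
  sets (±5 % preferred).
- **Annotation** (`rloopscape.annotation`): priority-resolved partition
  of the genome into promoter / 5′UTR / 3′UTR / exon / TTS / intron /
  intergenic; observed vs expected (bp-weighted) peak category fractions.
- **Break/timing integration** (`rloopscape.integrate`): peak→gene
  assignment, length-normalized peak density, junction–peak proximity
  (peak within 2 kb of a junction), per-gene peak-near-junction counts,
  bp-weighted median replication timing, common/unique gene-set (Venn)
  arithmetic, random peak down-sampling, metagene and TSS profiles.
- **Statistics & enrichment** (`rloopscape.stats`): Mann–Whitney U
  (exact by enumeration for n₁+n₂ ≤ 12, tie-free), one-way ANOVA with
  Tukey HSD, cumulative hypergeometric enrichment with BH q-values,
  enrichment-factor filters and kappa-similarity clustering of terms.
- **Synthetic data** (`rloopscape.simulate`): a 2 Mb toy genome with
  planted skewed promoters, planted peaks, junction classes and a timing
  track, plus recovery metrics scoring any stage against the manifest.

## Worked example

```bash
python examples/02_call_peaks.py
```

prints (seed 1):

```
called 261 peaks (model hash 28db3ffea28c, 6 EM iterations)
planted peaks recovered at Jaccard >= 0.5: 100.0% of 261
mean best per-peak Jaccard: 0.885
```

i.e. on the default toy genome every planted R-loop interval is found by
the HMM segmentation, with ~0.9 positional agreement (the loss is
bin-edge quantization at the 100 bp bin width). `examples/06_break_integration.py`
shows the breakpoint contrast:

```
TSS-proximal :  200 of 200 junctions within 2 kb of a peak (100.00%)
RDC          :   12 of 300 junctions within 2 kb of a peak (4.00%)
median timing ratio: peaks +1.50, RDC-like genes -1.50
```

TSS-proximal junctions sit in R-loop-rich, early-replicating promoters;
RDC-like gene bodies are R-loop-poor and late-replicating. The other
examples (`examples/01…07`) cover simulation, skew classes,
transcription matching, annotation and enrichment, one capability each.

A full pipeline run with one config:

```bash
rloopscape run-all --out out --seed 1    # writes out/report.md
```

## Command-line interface

`rloopscape simulate|callpeaks|skew|expression|annotate|integrate|enrich|run-all|report`
— thin wrappers over the library; see `rloopscape <cmd> --help`.
Formats: BED3/6, bedGraph, GTF (ensembl dialect), FASTA, UCSC
chrom.sizes, GMT. All coordinates are handled internally as 0-based
half-open; GTF is converted on read.
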