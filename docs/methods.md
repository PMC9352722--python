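# Methods

This note documents the models, parameter choices and known limitations
of the rloopscape pipeline. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Peak-calling HMM

DRIP coverage is averaged into fixed-width bins (default 500 bp at
mammalian scale; the bundled toy-genome pipeline uses 100 bp so that the
planted sub-kilobase peaks span several bins). Bin means are log1p
transformed — coverage is non-negative and right-skewed, and log1p keeps
zero bins finite — and modeled as a two-state hidden Markov chain with
Gaussian emissions: state 0 background, state 1 enriched, enforced after
every fit by relabeling so the enriched emission mean is the larger one.

Fitting is standard Baum–Welch over all chromosomes as independent
sequences sharing one parameter set (scaled forward–backward; emission
SDs floored at 1e-3 to prevent variance collapse; tolerance 1e-4 on the
log-likelihood; max 200 iterations). Initialization is a quantile split:
background moments from bins at or below the median, enriched moments
from the top decile. An all-equal-bins input is rejected with advice to
decode with fixed parameters, since EM is undefined there.

Decoding is Viterbi with ties broken toward background, making calls
conservative. Maximal enriched runs become peaks after (1) merging runs
separated by at most `merge_gap_bins` (default 1) background bins and
(2) dropping runs shorter than `min_bins` (default 3). Replicate
handling defaults to calling on the pooled (per-bp summed) track, which
matches combined-signal peak calling; an intersect-*k* mode (call per
replicate, keep bins supported by ≥ k replicates) is exposed for users
who prefer reproducibility-based calls. Input-control subtraction is not
performed by default; callers can subtract tracks upstream if desired.

## GC-skew HMM

Skew decoding uses a four-state chain over per-base emissions:

| state   | P(A) | P(C) | P(G) | P(T) |
|---------|------|------|------|------|
| STRONG  | 0.20 | 0.20 | 0.40 | 0.20 |
| WEAK    | 0.25 | 0.20 | 0.30 | 0.25 |
| NONE    | 0.25 | 0.25 | 0.25 | 0.25 |
| REVERSE | 0.20 | 0.40 | 0.20 | 0.20 |

Self-transition probability is 1 − 1/L with L the expected segment
length: L = 10⁶ for the stringent preset (used for gene classification)
and L = 7600 for the lenient preset (used for metaplot-style
segmentation); the off-diagonal mass splits evenly. **These numbers are
declared approximations**: the published skew-decoder model files imply
the two expected segment lengths through their names, but their exact
emissions and transitions are not public, so the defaults above are this
package's own calibration, overridable from YAML (`gc_skew.load_model`).
The training phase of the original two-phase pipeline (fitting emissions
on curated R-loop-forming regions) is out of scope; decoding uses fixed
parameters.

N bases emit with probability 1 under every state (likelihood-neutral).
Exact Viterbi ties resolve to NONE first, so an uninformative model
yields an all-NONE path. Gene classification decodes each gene's
promoter window (TSS ± 2 kb) on the coding-strand orientation —
minus-strand genes are decoded on the reverse complement — so STRONG
always means "G-rich non-template strand". This is required rather than
label-flipping a forward-strand decode because the WEAK emission row is
not mirror-symmetric. The gene's class is the highest-priority state
(strong > weak > reverse > none) whose segment touches the promoter; a
whole-gene mode (skew anywhere in gene span + promoter) is exposed as an
alternative, with the promoter anchoring chosen as the default because
promoter skew is the feature tied to R-loop initiation.

## Transcription quantification

GRO-seq measures nascent transcription, so RPKM is computed over the
full unspliced gene span on the gene's strand:
RPKM = counts × 10⁹ / (length_bp × library_size). Class thresholds are
inclusive at the lower bound: ≥ 0.025 active, ≥ 0.0025 ambiguous, else
inactive. Rate-matched control sets use greedy nearest-neighbour
matching in log10(RPKM + 1e-6) without replacement: targets are
processed in sorted rate order (making the result input-order
independent and deterministic), candidates within the ±5 % band are
preferred at any distance over out-of-band ones, and targets with no
candidate within 0.5 log10 units are dropped and reported. The matching
algorithm is this package's design; its audit is statistical — matched
and target rate distributions must be indistinguishable (Mann–Whitney
p ≫ 0.05), which the test suite checks on a balanced pool.

## Feature annotation

Categories are painted per-bp in increasing priority (intergenic fill →
intron → TTS → exon → 3′UTR → 5′UTR → promoter), so promoter > 5UTR >
3UTR > exon > TTS > intron > intergenic resolves every overlap and the
categories partition the genome exactly — the invariant is asserted per
run. Promoter is TSS ± 2 kb (the same definition used everywhere else in
the pipeline); the TTS window is TES ± 1 kb, a configurable default
since no canonical width exists. Peaks take their midpoint's category
(single-label, per-peak pie semantics). UTR intervals are optional
inputs; without them genes contribute exon/intron only. The per-bp
uint8 paint is chosen for auditability and costs 1 byte/bp — fine to
mammalian-chromosome scale.

## Integration conventions

- A gene "contains" a peak when the peak overlaps the gene span united
  with the promoter window by ≥ 1 bp (one peak may serve several
  overlapping genes); a body-only flag restricts to the span.
- A breakpoint region is a junction ± 2 kb: a junction is "near" a peak
  when the edge gap is ≤ 2000 bp (overlap counts; a gap of 2001 does
  not). The sorted-scan implementation is verified against an all-pairs
  oracle.
- Per-gene counts of peaks near junctions count distinct *peaks*, not
  junction-peak pairs.
- Replication-timing summaries are bp-weighted medians of the ratio
  track over reported positions only; unreported spans yield a missing
  value which is excluded, never zero-filled. Peak-group summaries are
  per-peak-median-then-pooled. The weighted median interpolates
  (midpoint of the two straddling values) at an exact 50 % split.
- Venn percentages and all other printed percentages are rounded at two
  decimals, round-half-even.
- Metagene profiles: fixed-width flanks (2 kb in 20 bins), gene body
  rescaled to 100 bins via exact fractional-overlap averaging of the
  per-bp step function; minus-strand genes are reversed, with the TSS
  window on the minus strand taken as [TSS−flank+1, TSS+flank+1) so that
  strand-mirrored signals give bin-identical profiles.

## Statistics

Mann–Whitney U uses exact enumeration of all C(n₁+n₂, n₁) labelings when
n₁+n₂ ≤ 12 and the pooled data are tie-free (two-sided p as the mass of
labelings at least as extreme in either tail, capped at 1); otherwise
the tie- and continuity-corrected normal approximation. The switchover
is configurable. ANOVA/Tukey delegate to scipy (the studentized-range
distribution); each Tukey result also carries the unadjusted
pooled-variance t-test p for the same pair, and adjusted ≥ unadjusted is
asserted. Enrichment p is the upper hypergeometric tail P(X ≥ k);
enrichment factor (k/n)/(K/N); q-values by Benjamini–Hochberg step-up
(implemented directly, cross-checked against statsmodels in tests).
Term filtering applies p < 0.01 and factor > 1.5 strictly and counts
≥ 3 inclusively, as worded. Surviving terms are clustered by Cohen's
kappa between binary membership vectors over the union of surviving-term
overlap genes, average-linkage on distance 1 − κ, cut so sub-trees with
similarity > 0.3 stay together; each cluster is represented by its
smallest-p term. Average linkage (rather than complete/maximum) is a
design choice where the reference procedure is underspecified.

## Synthetic-data generator

The toy genome is 2 Mb over two chromosomes with 200 non-overlapping
genes — small enough that the full pipeline runs in seconds, dense
enough that every gene class is populated. Length thresholds scale with
genome size (ratio to a 2.5 Gb mammalian genome lives in the config):
"long" RDC-like genes are > 30 kb at toy scale (vs > 300 kb at genome
scale). Defaults: 45 % of non-RDC genes get strongly skewed promoters;
transcription classes mix 70/15/15 % active/ambiguous/inactive with
active rates log-normal around RPKM ≈ 0.3; 10 RDC-like genes of
30–50 kb; 40 short skewed+active genes carry 5 TSS-proximal junctions
each; RDC-like genes carry 30 body junctions each (outside TSS ± 2 kb).

Sequence: i.i.d. uniform ACGT background; skewed genes get P(G) = 0.40,
P(C) = 0.20 on the non-template strand over the promoter and the first
25 % of the gene body (expected skew 1/3). DRIP signal: Poisson counts
per 10 bp step, background mean 2, ×10 inside planted peaks (a
signal-to-noise ratio at which the two log1p emission components are
separated by ~15 SD at 100 bp bins — recovery is then limited by bin
quantization, not noise); a noise-free mode emits the Poisson means
directly. Planted peaks: skewed+active genes get TSS (800 bp), mid-body
(600 bp) and TES (600 bp) peaks; non-skewed active genes a TES peak
only; RDC-like genes one body peak with probability 0.2; peaks separated
by sub-resolution gaps (≤ 300 bp) are fused at planting since no caller
could distinguish them. GRO coverage is uniform over the gene span at
per-bp density RPKM × library / 10⁹, which RPKM computation inverts
exactly — the planted rate is recovered to 1e-9. Timing: +1.5 over
skewed-active gene neighborhoods (span ± 2 kb), −1.5 over RDC-like gene
spans, unreported elsewhere. Gene gaps are ≥ 4.1 kb so promoters, skew
regions and timing neighborhoods of adjacent genes never overlap.

With planted peaks in ~130 of 200 genes at these widths, peaks cover
5–11 % of the 2 Mb toy genome — necessarily far above the ~1 % seen on a
real genome, because the toy genome is ~70 % genic while a mammalian
genome is mostly intergenic. The per-gene peak rules (which drive the
recovery checks) were kept and the coverage fraction is reported as
computed, not forced.

Reproducibility: each stochastic stage draws from its own substream of
the single seed (`default_rng([stage, seed])`), so stage functions
called standalone reproduce the bundled `simulate()` byte-for-byte, and
identical configs give byte-identical output files.

**What the simulator does not emulate** — mappability and GC bias,
restriction-fragment resolution of DRIP, read-level noise (no FASTQ),
overlapping/nested genes, weak/reverse skew classes (only strong/none
are planted; WEAK and REVERSE decoding is exercised by constructed
sequences in tests), continuous timing gradients, and any quantitative
R-loop/transcription dose–response (the paper-scale analyses report no
such curve; peak presence is tied to class membership, a deliberately
simple link). Passing recovery tests therefore demonstrates correctness
of the algorithms on planted structure, not performance on real
mammalian data.

## Pipeline

Stages run simulate → callpeaks → skew → expression → annotate →
integrate → enrich; any failure aborts with the stage name in the run
log. All stage outputs are hashed (sha256) into the report, and two runs
with the same config produce identical hashes. In simulated runs the
two-condition comparison surface is exercised as called-vs-planted gene
sets (both Venn identities asserted in the report); with real data a
second condition's peak set enters through `common_unique_gene_sets`
and `downsample_peaks` directly. Enrichment in simulated runs uses the
generated gene-set collection and the list of genes with
promoter-proximal peaks — a focused list analogous to
condition-specific R-loop genes; enriching "all genes with peaks" is
near-powerless on the toy genome because that list is ~70 % of the
universe.

## Limitations

- The GC-skew model parameters are calibrated approximations (above),
  not the original model files; absolute segment calls on real genomes
  will differ even though the four-class behavior is reproduced.
- bigWig is not read or written; bedGraph is the exchange format.
- The annotation paint is memory-linear in genome size (1 byte/bp).
- Exact Mann–Whitney is limited to tie-free samples with n₁+n₂ ≤ 12;
  beyond that the corrected normal approximation is used.
- The two-state peak HMM has no input-control channel; control
  subtraction must happen upstream if needed.
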