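# Methods

This note documents the models, defaults and design decisions behind
`agonet`, and what the synthetic-data validation does and does not
establish about real sequencing data.

## Study design emulated by the generator

The simulator (`agonet.simdata`) emulates a paired small-RNA-seq /
AGO2-RIP-seq experiment over two genotypes (wild type and a regulator
knockout), two treatments (treated / vehicle) and `n_replicates = 3`
biological replicates per cell, plus a transcript-space PAR-CLIP library
per treatment condition. All randomness flows from a single integer
`SimConfig.seed` through named sub-generators with fixed offsets, so the
same configuration yields byte-identical outputs regardless of which
operations run or in what order.

**Counts.** Per-miRNA baseline means are log-normal (σ = 1, the wide
dynamic range typical of small-RNA libraries), scaled to an expected
library size `depth` (default 2×10⁶ reads). Counts are negative binomial
with Var = μ + φμ², φ = `dispersion` (default 0.05, an ordinary
bulk-RNA-seq overdispersion). Planted effects multiply means by
2^±`effect_lfc` (default 1.0) in wild-type treated samples only:
association-only ('o') miRNAs shift the IP fraction alone, abundance
('&') miRNAs shift IP and total alike, and the knockout genotype carries
no effect. Class proportions default to 20% 'o', 10% '&', 70% unchanged
— a few dozen regulated miRNAs out of a few hundred detectable ones,
the scale such screens report. Directions are balanced within each class
so that planted effects perturb library sizes minimally (treated-IP
column sums still exceed `depth` by a few percent; CPM normalization
absorbs this, at the cost of a small compositional shrinkage of observed
fold changes).

**Transcriptome.** Each transcript is a contiguous 5′UTR + CDS (length
divisible by 3; no reading-frame semantics beyond that) + 3′UTR, with
per-region base composition targeting `t_freq` (defaults 0.24 / 0.22 /
0.30 — CDS less T-rich than 3′UTRs, as in human annotation). For every
miRNA, `sites_per_mirna = 4` exact canonical sites (8mer:7mer-m8:
7mer-A1:6mer at 3:3:2:2) are written into random regions (80% 3′UTR,
20% CDS), at least 150 nt apart so distinct sites yield distinct read
clusters. A crosslink-anchor T is forced 3 nt upstream of each site and
the footprint [start−5, start+3) is recorded: whichever footprint T
accumulates the most conversions, the site's first nucleotide lands in
the canonical −2..+5 window of the cluster's predominant transition.

Identical-seed family members (the generator always includes one
≥4-member family) produce literally identical site strings, so ownership
of a family site is undecidable from sequence alone; the generator
attributes such sites to the most expressed member — the same convention
the assignment stage's expression tie-break implements. A synthetic
per-base conservation track (background U(0, 0.5), planted sites
0.6–0.95) stands in for an external conservation input.

**PAR-CLIP reads.** Site reads start at the site start −3 with Gaussian
jitter (σ = 3 nt) and lengths uniform in `read_len_range` (20–40 nt,
post-RNase). Each reference T inside the footprint converts T→C
independently with `t2c_rate` (default 0.5 — crosslink positions convert
at high rates). Background reads are uniform over transcripts in
proportion to length and carry no conversions. With the per-condition
chimera rate (vehicle 0.05; treated derived from
`chimera_odds_ratio = 2` on the odds scale), a site read is emitted
instead as a ligation product: a ≥16 nt 5′ prefix of the owning mature
miRNA joined to a 12–26 nt unconverted fragment of the site
neighbourhood, with a configurable preference (`ligation_g_bias = 0.6`)
for G at the ligated ends and an optional target-first orientation
fraction (default 0: miRNA-first, with the orientation recorded either
way since detection searches both ends).

**What the generator does not model:** genome coordinates and splicing,
sequencing errors other than T→C, quality scores, PCR duplication/UMIs,
non-canonical (bulged / G:U) sites, and crosslink-independent background
conversions. Passing recovery tests therefore demonstrates the
pipeline's correctness and calibration under its own generative
assumptions, not robustness to artifacts absent from the model.

## Differential association

Normalization is log2(CPM + 0.5); the pseudocount bounds fold changes
for zero counts and its effect is negligible above ~10⁴ counts. Group
comparison is an unpaired two-sided Welch *t*-test on the log2 values
(Welch rather than pooled-variance Student for robustness to unequal
group variances; a `welch=False` toggle restores the pooled test).
Degenerate rows with zero variance in both groups get p = 1 when means
agree and p = 0 otherwise. Benjamini–Hochberg adjustment is computed
literally as the step-up definition (adj_(i) = min_{j≥i} p_(j)·m/j,
clipped at 1) and applied separately within the IP and within the total
comparison. Classification uses |log2FC| ≥ 0.35 and adjusted p < 0.05 in
each fraction; entities significant in both fractions with opposite
signs are rare and are kept as association-only (IP direction governs)
with an `opposite_sign` flag rather than dropped. The gene-level rule is
deliberately test-free (every IP replicate LFC beyond the cutoff, no
total replicate LFC beyond it), matching two-replicate mRNA designs.

**Power at the default design.** The per-sample sd of log2 counts under
NB(μ, φ = 0.05) is ≈ 0.33 for any well-expressed entity, so a 3 vs 3
*t*-test at a 1-log2-unit effect has ≈ 0.80 power at raw α = 0.05 and
much less after BH adjustment (the step-up threshold collapses when few
tests have small p). The suite quantifies this honestly: on 20 simulated
studies of 200 miRNAs, association-only sensitivity under the default
BH-adjusted rule is ~0.02–0.05, and the class is contaminated by '&'
miRNAs whose total-RNA test misses. Detecting such effects reliably at
3 replicates requires either larger effects (≥ ~1.2 log2 units at raw
α), more replicates, or variance-moderated testing — which this package
intentionally does not substitute for the plain *t*-test it documents.
The raw-p null calibration of the test is verified on the effect-free
knockout genotype (the *t*-test is mildly conservative at n = 3 on
skewed log counts: ~0.03 empirical size at nominal 0.05).

## Cluster calling and T normalization

Clustering is a transcript-space merge of overlapping reads with two
thresholds (`min_reads = 5`, `min_t2c_reads = 2`) rather than a
kernel-density segmentation: at desk scale, merged pile-ups with
conversion support are an adequate and fully transparent site model.
Consequences: abutting binding sites closer than a read length merge
into one cluster (the generator's 150 nt site separation avoids this),
and cluster boundaries are read-extent, not crosslink-extent. The
predominant T→C position is the per-position conversion argmax with
leftmost tie-breaking; it also decides the region label of
boundary-spanning clusters. Mismatch records whose reference base is not
T are counted as non-conversions, never errors.

T-frequency normalization divides each region's cluster fraction by the
T frequency of that region class (concatenated over transcripts) and
renormalizes. Under a null in which cluster counts are proportional to
region length × T frequency, normalized fractions are proportional to
length alone — i.e. uniform per-nucleotide density — which the suite
verifies at 10,000 sampled clusters (multinomial error ~0.005).

## MRE assignment

The canonical site strings are derived from the mature sequence (U → T):
6mer = revcomp(2–7), 7mer-m8 = revcomp(2–8), 7mer-A1 = 6mer + A,
8mer = 7mer-m8 + A. Candidates must start within −2..+5 of the
predominant transition. The total priority order — site length >
conservation > |offset| > expression > miRNA id > position — is this
package's decision; length and conservation are the primary biological
signals, offset encodes the crosslink geometry, and expression resolves
identical-seed families (the only information that can). `min_expression`
defaults to CPM ≥ 1 in matched total RNA. A missing conservation track
scores candidates 0 and flags them, leaving length/offset/expression to
decide.

## Chimera pipeline

Matching is exact on both parts (thresholds `min_mirna_prefix = 15`,
`min_target_len = 8`): ligation evidence is only useful when
unambiguous, and exact matching keeps the rejection taxonomy crisp
(no_mirna, ambiguous_mirna, short_remainder, ambiguous_target,
no_target). The miRNA part is searched at both read ends; reads whose
remainder is empty are bare miRNAs, not chimeras. Extension for
seed-match searching takes up to 10 nt of real flank per side (RNase
trimming shortens target parts); the control replaces the flanks with
seeded i.i.d. uniform bases of the same length. The 5mer class is
defined as revcomp(positions 2–6); classes are counted exclusively by
longest match, so they partition the chimera set. The per-seed-position
pairing profile picks, per chimera, the length-8 window minimizing
mismatches to revcomp(positions 1–8) (leftmost on ties) — at modest
planted mismatch rates the best window is almost surely the planted one,
and recovery error stays within ±0.05 at 1,000 chimeras. Condition
comparisons use the two-sided Fisher exact test per miRNA with BH across
miRNAs.

## Network

Edges collapse transcript isoforms to genes and merge evidence streams
(`both` when a pair is supported by an assigned MRE and a chimera). Motif
counting is edge-local: the damage response is taken as the apex
regulator of both the miRNA and its target, so an edge whose miRNA is
activated (up or more_associated) onto a down-regulated gene is a
coherent feedforward-style loop, onto an up-regulated gene incoherent,
and symmetrically for repressed miRNAs. Gene→miRNA feedback arrows are
not derivable from these data and are not counted.

## Numerical and validation choices

* Exact-agreement checks: BH against the step-up definition (bit-for-bit,
  1,000 random vectors; statsmodels serves as a second, independent
  cross-check in the tests), Fisher two-sided p against full
  hypergeometric summation (all 2×2 tables with margins ≤ 30, ≤ 1e-9),
  MRE assignment against an exhaustive pairwise-dominance oracle
  (500 random candidate sets).
* Recovery checks and their problem sizes: classifier recovery at 200
  miRNAs × 20 seeds; owner recovery over 20 default studies (~1,900
  sites); chimera detection at 1,000 planted chimeras among 100,000
  background reads; Fisher power at 5,000 reads per condition × 20
  seeds; positional profiles at ~1,000 chimeras. `scripts/acceptance.py`
  recomputes all of them from a single seed in a few minutes on one CPU.
* Determinism: all stochastic steps take explicit seeds; cluster calling
  and assignment are order-independent with documented tie-breaks.

## Known limitations

Transcript-space only; no mismatch-tolerant chimera alignment (3′-end
non-templated additions or sequencing errors in either part cause
rejection, which the exact-match recall figures on clean synthetic reads
do not reflect); no duplex folding energetics; conservation is consumed,
never computed; the cluster caller is not a kernel-density method and
will not reproduce counts from tools that are; and the differential
module's plain *t*-test is honest about its low power at 3 replicates
rather than silently moderated.
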