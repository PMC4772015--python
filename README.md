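# agonet

Tools for dissecting how a stimulus (such as DNA damage) remodels the
microRNA machinery at the level of **AGO2 association** rather than
expression, and for mapping the resulting miRNA–mRNA interaction network.
The package targets studies that pair small-RNA/RNA sequencing of total
RNA with AGO2 immunoprecipitation (RIP-seq) and PAR-CLIP, and it ships a
fully ground-truthed synthetic-data generator so that every stage of the
pipeline can be exercised and validated without any sequencing download.

## What it computes

**Joint total/IP differential classification.** For each miRNA, the
treatment response (treated vs vehicle) is tested separately in the
AGO2-IP and the total-RNA fraction: log2 CPM normalization, a two-sided
Welch *t*-test per fraction, and Benjamini–Hochberg adjustment within
each fraction. With significance defined as |log2FC| ≥ 0.35 and adjusted
*p* < 0.05, miRNAs are classified as

* `abundance_concordant` — both fractions change with the same sign
  (expression-level regulation),
* `association_only` — the IP fraction changes while total RNA does not
  (regulated loading onto the silencing complex),
* `total_only`, or `unchanged`.

A replicate-intersection rule gives the analogous gene-level calls
(`more_bound` / `less_bound`), and a one-sided hypergeometric test scores
seed-match enrichment of the differentially bound gene sets.

**PAR-CLIP cluster calling and T-content normalization.** Overlapping
reads are merged into transcript-space intervals; an interval is an AGO2
binding cluster when it has ≥ 5 reads of which ≥ 2 carry a diagnostic
T→C conversion. Because crosslink selection favours T-rich sequence, the
per-region cluster distribution (5′UTR / CDS / 3′UTR) is re-weighted by
each region's T frequency: `w_r = raw_r / tfreq_r`, renormalized.

**MRE assignment.** Canonical seed sites (8mer, 7mer-m8, 7mer-A1, 6mer —
the reverse complement of miRNA positions 2–8/2–7, with or without a
3′-flanking A) are searched inside each cluster; candidates whose first
nucleotide sits within −2..+5 of the cluster's predominant T→C position
are ranked by site length > conservation > |offset| > expression, and at
most one expressed miRNA is assigned per binding site.

**Chimera detection.** Endogenous ligation occasionally fuses a miRNA to
its target fragment in a single read. A read is accepted as a chimera
when one end exactly matches ≥ 15 nt of the 5′ end of exactly one mature
miRNA and the remainder (≥ 8 nt) maps to exactly one transcriptome
position. The module reproduces the standard characterization statistics:
seed-match class counts (down to 5mers) against a random-extension
control, the per-position 4-mer complementarity profile along the miRNA,
last-nucleotide composition at the ligated ends, per-seed-position pairing
profiles, and a two-sided Fisher exact comparison of chimera formation
rates between conditions.

**Network assembly.** MRE assignments and chimeras are merged into a
gene-level directed graph miRNA → gene with per-edge evidence
(`mre` / `chimera` / `both`), overlaid with the differential statuses, and
mined for damage-coregulation motifs (coherent / incoherent
feedforward-style loops).

## Worked example

```python
from agonet import SimConfig, generate_dataset
from agonet import clusters, diffassoc, mre, chimera, network

ds = generate_dataset(SimConfig(seed=1, chimera_rate=0.1))

# 1. joint total/IP classification (wild-type genotype)
res = diffassoc.run_mirna_classification(ds.counts, genotype="WT")
print(res["category"].value_counts().to_dict())

# 2. clusters and T-normalized region distribution
called = clusters.call_clusters(ds.alignments, ds.transcriptome)
raw = clusters.cluster_region_distribution(called)
tf = clusters.region_t_frequency(ds.transcriptome)
print({r: round(f, 3) for r, f in raw.items()})
print({r: round(f, 3) for r, f in
       clusters.normalize_region_distribution(
           {r: raw.get(r, 0.0) for r in tf}, tf).items()})

# 3. chimera detection against the planted truth
found, log = chimera.detect_chimeras(
    ds.raw_reads[["read_id", "sequence"]], ds.mirnas, ds.transcriptome)
print(len(found), "chimeras;", (ds.raw_reads.true_class == "chimera").sum(),
      "planted")
```

Output (seed 1):

```
{'unchanged': 24}
{'3UTR': 0.771, 'CDS': 0.229}
{'3UTR': 0.71, '5UTR': 0.0, 'CDS': 0.29}
563 chimeras; 568 planted
```

Read: none of the 24 simulated miRNAs clears the BH-adjusted threshold at
this small default design even though the generator planted 5
association-only effects — a 3-replicate *t*-test with multiple-testing
adjustment has limited power at one log2 unit (quantified in
`docs/methods.md`); the raw cluster distribution is 3′UTR-dominated and
T-normalization narrows the 3′UTR/CDS gap; 563 of 568 planted ligation
chimeras are recovered, with no false positives.

A command-line interface mirrors the library:
`agonet simulate | classify | call-clusters | assign-mre |
detect-chimeras | build-network` (see `--help` on each).

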