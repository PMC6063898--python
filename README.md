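# diffenh

Differential enhancer-activation analysis for two-condition histone-mark
ChIP-seq, with the surrounding bench-assay calculators and a
planted-truth simulator for validation.

## The problem

When a tumor line acquires drug resistance, part of the change can be
epigenetic: a distal enhancer that was merely *primed* (H3K4me1 only)
in the sensitive line becomes *active* (H3K4me1 + H3K27ac) in the
resistant line and switches on a nearby gene — for example a DNA-repair
gene whose expression neutralizes the drug. `diffenh` implements the
comparative analysis that finds such events from coverage data:

1. **Catalog.** Call enriched regions on the H3K4me1 tracks of both
   conditions with a local-Poisson test (per-bin p-value against
   λ = max(genome mean, 10 kb local mean), cutoff p < 0.001), take the
   union, drop regions that overlap an H3K4me3 peak or lie within 2 kb
   of a TSS (promoter signature), and merge peaks closer than 500 bp.
   The result is the putative-enhancer catalog.
2. **Cluster.** For every catalog enhancer compute
   log2((RPKM_B + c) / (RPKM_A + c)) for H3K4me1 and H3K27ac
   (pseudocount c = 0.5 RPKM), k-means the two-column matrix (k = 4),
   and select the *activated group*: the cluster whose centroid is
   positive in both marks (largest min coordinate). These are the
   enhancers that gained both priming and acetylation in condition B.
3. **Link and rank.** Assign each enhancer the gene with the nearest
   TSS, compute per-gene expression fold changes from RNA-seq counts
   (library-size normalized B/A ratio), attach an exact conditional
   binomial p-value and Benjamini–Hochberg adjusted p, and emit the
   top-N table of activated-group genes sorted by fold change.

Assay calculators cover the quantitative readouts used to confirm such
an enhancer at the bench: 3C interaction frequency
`2^(Ct(BAC) − Ct(3C))`, ChIP-qPCR percent input, dual-luciferase
reporter activity (Renilla- then empty-vector-normalized), ΔΔCt
expression fold change `2^−ΔΔCt`, per-nucleus immunofluorescence
signal (area × mean intensity) with positive-fraction gating
(e.g. Ki67+/CD45−), four-parameter-logistic IC50 fitting
`y = bottom + (top−bottom)/(1 + (dose/IC50)^hill)`, and per-day
proliferation fold change.

Because real two-condition resistance datasets are not reproducible at
desk scale, validation is property-based: the `simulate` module
generates genomes, state-labelled enhancers, Poisson mark tracks,
negative-binomial RNA-seq counts and assay tables with known ground
truth, and the test suite checks that the analysis recovers what was
planted.

## Worked example

Run the full pipeline on the default synthetic scenario (one 10 Mb
chromosome, 50 bp bins, 200 genes, 1000 enhancers of which 100 are
activated with a mean +1.5 log2 mark gain and 4-fold expression gain
at their nearest genes):

```sh
$ diffenh run --outdir demo --seed 1
catalog=974 activated_group=104 ranked_genes=10 -> demo
```

974 of the 1000 planted enhancers survive peak calling and the
distal filter; the clustering flags 104 as activated (the 100 planted
ones plus a few borderline rows — precision 0.98, recall 1.00 against
the planted truth on this seed). The ranked table starts:

```
rank  gene_id    fold_change  log2_fold_change  p_value  adjusted_p  enhancer_id  distance
1     gene_0058  14.84        3.89              0.0      0.0         enh_00674    30676
2     gene_0025  7.40         2.89              0.0      0.0         enh_00254    29782
3     gene_0003  5.71         2.51              0.0      0.0         enh_00905    29557
```

All ten rows are genes whose nearest enhancer is a planted activated
one. The rank-1 estimate (14.8×) exceeds the planted 4× because the
fold-change estimate at a moderately expressed gene carries
negative-binomial sampling noise; the *ordering* is what the analysis
guarantees. `demo/` also contains the catalog BED, the ratio matrix
with cluster labels, the activated-group BED, metaprofile TSVs and a
`manifest.json` that records the full configuration — the same config
and seed reproduce every file byte-for-byte.

The assay calculators are plain functions:

```python
>>> from diffenh import interaction_frequency, ddct_fold_change
>>> interaction_frequency(ct_3c=[23.0], ct_bac=[20.0]).frequency
0.125
>>> ddct_fold_change(22.0, 20.0, 24.0, 20.0)   # sample dCt 2, control dCt 4
4.0
```

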