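# Methods

This note documents the models, conventions and design choices behind
`diffenh`, in the order the pipeline applies them, followed by the
synthetic-data model used for validation and the package's known
limitations.

## Coordinates, coverage and normalization

All intervals are 0-based half-open (BED convention). Coverage is a
dense per-chromosome vector of bin values; reads are assigned to bins
by their 5′ position (the simplest convention; fragment-midpoint
assignment would shift peaks by half a fragment but changes nothing
structural). RPKM is the classical
`count / (bin_size/10^3) / (total_mapped/10^6)`; it is linear and,
given `total_mapped`, exactly invertible. Interval means weight
partially covered bins by the number of covered bases, so the value
equals the per-base average of the bin-step signal and is free of
bin-boundary artifacts. bedGraph is the canonical on-disk track format
(text, diff-able); a comment header carries `bin_size`,
`total_mapped` and units so round trips are lossless.

## Peak calling

The caller is a deliberately minimal local-Poisson scan, not a MACS2
reimplementation: for each bin, an upper-tail Poisson p-value
P(X ≥ count) against λ = max(genome-wide mean, centered 10 kb local
mean), a fixed cutoff p < 0.001 on raw counts with no multiple-testing
correction (peak calling here is a discretization step with a fixed
operating point, not an inference), adjacent significant bins joined,
summit at the maximum bin. The `max(global, local)` background damps
false calls inside locally dense regions; because the Poisson test is
discrete, the realized per-bin false-positive rate on null tracks sits
*below* the nominal cutoff (measured ≈6×10⁻⁴ at cutoff 10⁻³ on
Poisson(5) tracks), which the calibration test exploits. Users with
externally called peaks (e.g. MACS2 output as BED) can feed them
directly to the selection step and skip the internal caller.

## Enhancer catalog

Putative enhancers are regions with an H3K4me1 peak in *either*
condition (union; selecting the intersection is a stricter, supported
variant by passing pre-intersected peak lists) that carry no H3K4me3
peak and lie more than `tss_exclusion` (default 2 kb) from any
annotated TSS. "High H3K4me1 / low H3K4me3" is operationalized as peak
presence/absence — peak calls are the only discretization with a
stated operating point, and no signal threshold is defensible without
one. Surviving peaks closer than 500 bp are merged transitively
(strict `gap < 500`; overlapping and bookended intervals always
merge), giving sorted, non-adjacent catalog intervals. Each interval
then carries the mean RPKM of both enhancer marks in both conditions;
intervals outside a track's bounds are flagged and excluded rather
than imputed.

## State clustering and the activated group

Each enhancer is summarized as
`log2((RPKM_B + c)/(RPKM_A + c))` for H3K4me1 and H3K27ac with
pseudocount `c = 0.5` RPKM. The pseudocount keeps entries finite,
maps zero-coverage-in-both to exactly 0, and shrinks ratios at low
coverage where they are least reliable; the matrix is antisymmetric
under condition swap. Only the two enhancer marks are clustered —
repressive-mark behavior (H3K27me3/H3K9me3) is descriptive, not part
of the partition.

k-means (k-means++ initialization, 10 restarts, fixed seed, via
scikit-learn) partitions the matrix. k defaults to 4; the activated
group is selected by *rule*, not by cluster index: the cluster whose
centroid has the largest `min(log2 ratio H3K4me1, log2 ratio H3K27ac)`,
required positive in both. This makes the selection robust to the
choice of k (any k large enough to isolate the up-up population gives
the same group) and returns an explicit empty set with a warning when
no cluster gained both marks. Rows with non-finite ratios are dropped
with a warning.

Metaprofiles average RPKM around anchors in three modes: interval
centers, TSSs (minus-strand profiles reversed so transcription always
runs rightward), and gene bodies linearly rescaled to a fixed bin
count. Anchors whose window leaves the track are skipped and the
count of used anchors reported. Window and bin step are exposed as
parameters since no single choice suits all mark/feature combinations.

## Gene linkage, fold changes and ranking

Each enhancer is linked to the gene minimizing |enhancer midpoint −
TSS| on the same chromosome, with deterministic tie-breaks (lower TSS
coordinate, then lexicographic gene id). TSS distance — not gene-body
edge — is used because enhancer–promoter contact is the mechanism of
interest.

Expression change is the ratio of library-size-normalized counts with
a small pseudo-fraction (10⁻⁶ of the mean normalized count) so genes
silent in one condition get large-but-finite ratios. Significance
uses an exact conditional binomial test: given n = count_A + count_B,
count_B ~ Binomial(n, L_B/(L_A+L_B)) under the null, two-sided by the
minimum-likelihood method (scipy). An exact test was chosen because it
needs no dispersion estimate and is therefore honest for
single-library-per-condition designs; its p-values describe counting
noise only and understate biological variability — a caveat inherited
by the adjusted p column (Benjamini–Hochberg step-up, statsmodels).
Genes with zero counts in both conditions get p = 1. The final table
keeps the unique genes linked to the activated group (each attributed
to its closest linking enhancer), sorts by fold change descending with
gene-id tie-breaks, reports both linear and log2 fold change, and
truncates to `top_n`.

## Assay calculators

All Ct arithmetic assumes perfect per-cycle doubling (efficiency 2.0);
no efficiency correction is applied. Replicate Cts are summarized by
their mean. Consequences used as test invariants: Ct parity ⇒ ratio 1,
+1 cycle ⇒ halving, and invariance under a constant machine offset.

* 3C: frequency = 2^(mean Ct(BAC) − mean Ct(3C)), the BAC ligation
  control normalizing primer efficiency. The standard error is
  reported both with and without propagating the BAC replicate
  variance (delta method, σ_freq = freq·ln2·σ_Ct), since the control
  is shared across fragments and propagating it correlates their
  errors.
* Percent input: 100 · input_fraction · 2^(Ct(input) − Ct(chip)),
  equivalently 100 · 2^(adjusted Ct(input) − Ct(chip)) after shifting
  the input Ct by −log2(1/input_fraction).
* Dual luciferase: (firefly/Renilla)_test / (firefly/Renilla)_vector;
  scale-invariant in instrument units; zero Renilla is treated as a
  failed transfection, not a value.
* ΔΔCt: 2^−((Ct_gene−Ct_ref)_sample − (Ct_gene−Ct_ref)_control).
* Immunofluorescence: per-nucleus signal = area × mean intensity;
  positivity by threshold, default 3× the median of a negative-control
  channel (the bench criterion "uniform staining" is qualitative, so
  the threshold rule is explicit and configurable); Ki67+/CD45− gating
  isolates proliferating tumor cells before computing the
  target-positive fraction.
* Dose-response: four-parameter logistic fitted by unweighted least
  squares (curve_fit) in log-IC50 parametrization; the reported IC50
  is the relative (inflection) IC50. Initialization: bottom/top from
  the response extremes, hill 1, IC50 at the dose whose mean response
  is closest to midway. At least 4 distinct doses are required; a flat
  response or non-convergence raises a fit-failure error instead of
  returning a silent number.
* Proliferation: fold change in confluency at each day relative to
  Day 0; a log-linear fit (`growth_rate`) returns doublings/day.

## Synthetic-data model

The generator plants a known truth with the statistical structure the
analysis assumes, at desk scale (default: one 10 Mb chromosome, 50 bp
bins, 200 genes, 1000 enhancers, 100 activated).

*Placement.* Gene bodies (2–10 kb, random strand) are placed uniformly
with rejection so they never overlap; enhancer footprints (fixed 2 kb,
matching the scale of a minimal functional enhancer element) go into
intergenic space, at least 3 kb from any TSS and with at least 600 bp
between footprints. The last two constraints exist so that the
analysis parameters (2 kb TSS exclusion, 500 bp merge) interact
cleanly with the truth: no planted enhancer is silently removed by the
distal filter and no two planted enhancers fuse into one mixed-state
catalog interval. No positional structure beyond this is modelled.

*States and tracks.* The activated set goes primed→active in
condition B; the remainder splits 35% stably active, 35% stably
primed, 10% deactivated (active→primed), 10% poised, 10% inactive —
a landscape where most enhancers are stable or losing acetylation
while a minority gains both marks. H3K4me1 marks any non-inactive
enhancer, H3K27ac only active ones, H3K4me3 only TSS footprints
(1 kb). Bin counts are Poisson with mean `background_rate` (2
reads/bin) times `peak_enrichment` (8×) over footprints where the mark
is present, times 2^1.5 at activated enhancers in condition B
(`mark_effect_log2fc = 1.5`), times a per-(enhancer, mark, condition)
lognormal factor 2^N(0, 0.25). Enrichment and noise magnitudes are
not measurable from published figures; these values were chosen once
to make planted effects detectable but not trivial (the activated
population sits ≈4 within-group standard deviations from the stable
population in the H3K4me1 ratio coordinate).

*RNA-seq.* Baseline relative expression is lognormal (σ = 1) across
genes; genes nearest an activated enhancer carry the planted fold
change (default 2² = 4) in condition B; counts are negative binomial
with dispersion 0.1 at a configurable library size (default 10⁶).
Expected depth scales with the library-size parameter relative to the
baseline composition, so planted ratios are recovered up to the usual
compositional compression when many genes are up-regulated.

*Assays.* Ct values follow Ct = intercept − log2(template) +
N(0, σ), so every calculator inverts its table exactly at σ = 0.
Dose-response points come from the 4PL itself with multiplicative
noise of a given CV; the default hill slope is 2.0, the steep decline
typical of cytotoxic viability curves (at hill 1 and 5% CV the
information content of an 8-dose × 3-replicate design caps IC50
precision near ±7%, too loose for the ±10%-in-95% recovery this
scenario is designed to exhibit). Per-nucleus signals are a
two-component positive/negative lognormal mixture with a planted
positive fraction, drawn per nucleus (binomial), plus a matched
negative-control channel for thresholding.

Everything is deterministic for a fixed seed: independent named
`numpy` Generator streams (seeded as `[seed, stream]`) decouple
placement, noise factors, count draws and RNA-seq, so regenerating one
component does not perturb the others.

*What the simulator does not model* — and hence what passing tests do
not certify about real data: mappability and copy-number biases, GC
effects, fragment-size smearing, antibody efficiency differences
between marks or conditions (no spike-in normalization is attempted),
replicate structure in RNA-seq (the exact test models counting noise
only), inter-chromosomal structure, and enhancer–gene links other than
nearest-TSS (no contact-domain constraints).

## Pipeline and reproducibility

`run_pipeline` composes simulate/load → catalog → cluster → link →
metaprofiles, writing every artifact plus a manifest (package and
library versions, full configuration minus the output path, row counts
per stage). A configuration is validated up front with aggregated,
human-readable errors; an empty configuration means the default
synthetic scenario. Two runs of the same configuration and seed are
byte-identical file-for-file, and the manifest suffices to reproduce
any output. Validation problem sizes (5–10 seeds of the default
scenario, 100-run recovery experiments, 10⁶-bin null calibrations)
were chosen so the whole suite completes in well under a minute of
compute per component while keeping Monte-Carlo error far from the
asserted margins.

## Known limitations

* The peak caller is a calibrated toy: no fragment-shift model, no
  duplicate filtering, no broad-peak mode; it exists so the pipeline
  is self-contained and testable, and it accepts external peak files.
* Percent-input and ΔΔCt assume efficiency-2 amplification; real
  assays with efficiency ≠ 2 need a correction the package does not
  apply.
* The conditional binomial DE test understates variability whenever
  biological replicates exist; with replicates, a dispersion-aware
  model should replace it upstream of the ranking step.
* Cluster-then-select assumes the activated population is separable in
  the two-ratio plane; an activation signal smaller than the
  within-population spread will merge into the stable cluster and
  return an attenuated or empty group (with a warning).
* The relative IC50 is reported; for partial-response curves the
  absolute IC50 (dose at 50% of control) differs and must be derived
  from the fitted parameters by the caller.
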