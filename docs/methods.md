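# Methods

`flowdisp` quantifies cell-to-cell expression *dispersion* — variability at a
fixed mean — of surface proteins measured by single-stain flow cytometry on
immortalized B-cell lines (LCLs), and maps it to cis-acting DNA variants. This
note records the models, the tunable parameters, the numerical choices, and
what the synthetic-data generator does and does not establish.

## Gating model

Each acquisition sample is an events × channels table (FSC-A, SSC-A, FSC-W,
DAPI, FL) where FL is the log fluorescence intensity of the stained protein.
Batches ("sets" of experiments acquired together) are processed independently
and never share bounds, gates or outlier pools. Steps, in order:

1. **Saturation trimming.** Per channel, events outside the closed
   [5th, 95th] percentile interval of the *pooled* batch values are removed
   (linear-interpolation percentile convention; the convention is a package
   choice). Channels with a negative lower bound are shifted up by its
   absolute value so downstream values are non-negative.
2. **Unstained-DAPI debris.** The first peak–valley–peak motif of the
   per-sample DAPI kernel density locates a valley between a near-zero
   debris peak and the stained G1 mode; events below it are discarded. The
   valley is only accepted when the leading peak sits *left of the global
   mode* — otherwise there is no debris population and the filter is skipped
   (logged). In practice the saturation step often removes the debris first
   and this filter becomes a no-op.
3. **Size gate.** A 75%-mass highest-density region of the pooled FSC-A/SSC-A
   kernel density, applied identically to every sample of the batch.
4. **Doublet gate.** Same construction at 80% mass in FSC-A/FSC-W: doublets
   carry roughly doubled area signals at inflated pulse width and fall
   outside the dense singlet region.
5. **G1 selection.** Per sample, cells below a DAPI threshold are called G1.
   The threshold sits at the first density valley to the right of the global
   (G1) mode. The source description of this step — the point "minimizing the
   first derivative" of the density — is ambiguous: read literally as the
   most negative derivative it lands at mode+σ and would discard ~16% of G1
   cells; read as the point where the falling flank flattens out (derivative
   zero-crossing), it lands in the G1/G2 valley and retains essentially all
   G1 cells while excluding G2. The second reading is implemented; it is the
   only one consistent with retaining the G1 peak as a unit. A unimodal
   density (no G2) puts the threshold at the right edge of the support.
6. **Minimum events.** Samples with ≤ 1000 events after G1 selection are
   dropped.
7. **Size correction.** Per sample, a robust linear model
   FL ~ log(FSC-A) + log(SSC-A) (Huber M-estimator, tuning constant 1.345,
   ≤ 50 IRLS iterations, tolerance 1e-8) is fitted and each value replaced by
   `mean(FL) + residual`. The *arithmetic* mean is used, matching the printed
   transform, not the robust intercept; with robust weights the corrected
   mean can differ from the original mean by a negligible amount. A singular
   design (constant scatter) skips the correction, logged.
8. **Replicate warping.** Replicates of the same line and protein are
   registered by a monotone piecewise-linear warp mapping up to two FL
   density modes per sample onto their group-mean positions, with unit slope
   outside the landmark span. This is a simplification of landmark-based
   curve registration: it preserves within-sample rank order exactly and
   leaves the CV of an already-aligned unimodal sample essentially unchanged.
   Mismatched landmark counts fall back to aligning the leading landmark
   only (a shift), logged.
9. **Replicate outliers.** For groups of ≥ 3 replicates, each sample's
   reproducibility score K is the mean two-sample Kolmogorov–Smirnov
   statistic against its replicate partners. Samples with K above the 95th
   percentile of all K scores *in the batch* are discarded. Two open points
   were resolved as package choices: K pooling is per batch (not study-wide),
   and K is computed *after* warping, following the step order.

### Density estimation

All kernel densities are Gaussian-kernel estimates evaluated on fixed grids
(512 points in 1-D, 256×256 in 2-D) via histogram binning plus Gaussian
smoothing with Silverman's rule-of-thumb bandwidth. This is the standard fast
approximation to an exact KDE; it keeps the pooled 2-D gates linear-time and
makes every gate deterministic. The highest-density gate is the smallest
grid-level set whose pooled event mass reaches the target fraction, so the
achieved mass overshoots the target by at most one bin's worth of events
(≲ 3 percentage points in practice).

## Dispersion traits

Within-sample variability is CV = sd/mean with the n−1 SD convention,
computed on the **log-scale** FL values produced by the pipeline. The CV of
logs is not the CV of raw intensities; this order matches the processing
chain (size correction operates on log intensities) and is used consistently
everywhere, including the simulator's truth records.

Dispersion is CV|mean: the residual of a lowess regression of CV on mean
fitted across all samples of one protein and batch (span 0.75, 3 robustness
iterations; the method is named by the source, the span is a package
default). Evaluation interpolates between fitted points; means outside the
fitted range are assigned the nearest endpoint value and flagged.

Bimodal proteins are described by an unconstrained univariate two-component
Gaussian mixture (p1, μ1, μ2, σ²1, σ²2; components labelled so μ1 ≤ μ2,
resolving the "first component" ambiguity by ascending mean). The EM fit uses
a deterministic quantile-split initialisation plus 5 random restarts, keeps
the best log-likelihood, converges at relative log-likelihood change < 1e-8
or 500 iterations, and floors variances at 1e-6 × the data variance to block
degenerate single-point components. Restarts that collapse are discarded; if
all collapse the fit errors out rather than returning a degenerate answer.

Per-line values are replicate means (outlier-flagged samples excluded), with
standard errors. For the clustering layer the five mixture parameters are
centred and scaled across lines (n−1 SD) and clustered by complete-linkage
agglomeration on Euclidean distance; cluster labels come from cutting the
tree at a chosen k. Group comparisons use the Kruskal–Wallis rank test
(tie-corrected, χ² reference); pairwise dispersion correlations use Spearman
rank correlation (≥ 5 jointly measured lines); replicate-level line contrasts
use a two-sample t-test, Welch by default (replicate variances may differ; a
pooled-variance variant is available since the source does not state which
was used).

## Cis linkage

Variants within a ±2 Mb closed window of the gene's strand-aware TSS
(1-based, VCF convention) are deduplicated on (chrom, pos, ref, alt),
filtered to MAF ≥ 0.05 (computed over non-missing genotypes), and screened
with the exact conditional Hardy–Weinberg test at α = 0.001. The exact
conditional test (sum of heterozygote-count probabilities no more probable
than observed, conditional on allele counts) was chosen as the standard
"exact HWE test"; it matches full enumeration to 1e-10 for all tables up to
50 individuals in the test suite.

The association model is a per-variant simple linear regression of the trait
on alternate-allele count (0/1/2; phase ignored). Individuals with a missing
genotype are dropped variant-wise; missing trait values drop the individual
from the whole scan. An optional genotypic model adds a heterozygosity
indicator with a 2-df F test, falling back to additive when no heterozygotes
exist.

Family-wise error across the variants of one scan is controlled by max-T
permutation: for each of n_perm permutations of the trait the maximum |t|
across variants is recorded, and the corrected p of variant v is
(1 + #{max |t| ≥ |t_v|}) / (n_perm + 1). The +1 convention avoids zero
p-values; the smallest achievable corrected p is 1/(n_perm+1). Correction is
applied within one gene × trait scan only, and Benjamini–Hochberg FDR is
computed per trait independently — no correction across traits. Max-T was
chosen over adaptive per-SNP permutation as the reference procedure for
"family-wise error across all variants". Kinship is ignored (the motivating
cohort contains a single parent–child pair); this is a documented limitation,
not an option.

## Clonality

One unique CDR3 peptide marks one B-cell clone. Read-level filters (CDR3
found, VDJ frame present, top D gene present, CDR3 ≥ 5 aa, conserved
[FW]-G-X-G motif in the J-region translation, matched by a regular pattern
without alignment) are applied first; clonotypes covered by a single retained
read are then removed. Representativity is the percentage of retained reads
per clonotype. Verdicts follow the printed rule order with inclusive
thresholds: ≥ 2 clonotypes at ≥ 20% → polyclonal; otherwise a major clone at
≥ 80% → monoclonal; otherwise inconclusive. The 20% rule is evaluated per
replicate (not on pooled reads); a clonotype reaching 20% in only one of two
technical replicates is flagged as a suspected amplicon contamination,
excluded, and the consensus recomputed on the concordant clonotypes' pooled
counts; verdicts that still disagree yield an inconclusive consensus with
both calls reported.

## Synthetic data: what it emulates and what it does not

The generator draws, per sample: cell-cycle DAPI structure (G1 mode, G2 at
2× G1 with matching CV, an S-phase plateau between, near-zero unstained
debris), doublets as sums of two singlet events with pulse width inflated
1.8×, log-normal scatter, and log-scale fluorescence coupled to centred log
scatter plus a one- or two-component Gaussian mixture. Defaults: 62/14/14%
G1/S/G2, 5% debris, 5% doublets, DAPI CV 4%, size coupling (0.3, 0.1),
baseline log mean 5.0 and CV 0.1 — chosen once as typical of fixed LCL
acquisitions. Cohorts draw Hardy–Weinberg genotypes (causal MAF 0.25 by
default, null SNPs at MAFs uniform on [0.05, 0.5], no LD) and implement a
dispersion QTL by scaling the per-line log-SD by effect^(allele count) at a
strictly constant log mean — the cleanest realisation of "variability at a
fixed mean". The magnitude of the real dispersion effect is unknown; the
1.5× default used in power studies is an implementer choice and is labelled
as such wherever it appears. Replicate noise is a 2% log-normal jitter on the
SD and 0.01 additive jitter on the mean.

The generator does **not** emulate: instrument-specific saturation railing,
spectral spillover (the assay is single-stain by design), autofluorescence
structure, day effects beyond i.i.d. replicate jitter, or LD structure. A
green pipeline test therefore establishes that the algorithms recover planted
structure under idealised noise — not that they would reproduce any
particular real acquisition.

The per-replicate CD23 mixture-parameter table used by the clustering check
is a **synthetic stand-in** (`simulate_cd23_gmm_table`): the study's deposited
table is not shipped. It plants three line classes — majority-low with a
right tail, majority-high with a left tail, and clearly bimodal — with sizes
3/25/22 and within-class parameter jitter small relative to between-class
differences (location SD 0.08, weight SD 0.03, scale SD 0.04), consistent
with the separation regime under which cluster recovery is claimed. The
clustering test demonstrates that the averaging → z-scoring →
complete-linkage machinery recovers such structure exactly; it does not
reproduce the published cluster assignment.

## Degenerate inputs and tie-breaks

Constant channels abort percentile bounds; unimodal DAPI skips the debris
filter; a constant trait yields t = 0 and corrected p = 1; monomorphic
variants are skipped with reason; duplicate variant entries keep the first;
equal mixture means are ordered by the EM's internal component order after
the μ1 ≤ μ2 relabel; boundary events exactly on a percentile bound are
retained (closed intervals); representativity thresholds are inclusive.
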