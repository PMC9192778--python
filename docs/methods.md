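# Methods

`dcistraj` reconstructs a disease-progression continuum from bulk RNA-seq of
individually micro-dissected breast ductal lesions and derives patient-level
progression biomarkers from it. This note records the models, the numerical
choices, and what the synthetic validation does and does not establish.

## Data model and normalization

The unit of observation is one RNA-seq library from one micro-dissected
lesion section; a lesion contributes 1–3 adjacent sections, a patient 1–30
lesions, and each sample carries a tissue label (normal epithelium, benign,
atypia, DCIS, IDC), a patient outcome (*Pure DCIS* — no ipsilateral IDC over
long follow-up — vs *Not Pure*), a molecular subtype, and clinical receptor
calls.

Counts are normalized with trimmed-mean-of-M-values (TMM) factors computed
against a reference sample (the one whose 75th expression percentile is
closest to the cohort mean), trimming 30% of M-values and 5% of A-values on
each side and weighting the surviving M-values by inverse asymptotic
variance; factors are rescaled to geometric mean 1. Expression is expressed
as `log2((count + 0.5) / (effective_lib_size + 1) * 1e6)`; the 0.5/1 prior
is the voom convention and is stated explicitly because CPM offsets vary by
tool. Genes detected in fewer than `ceil(0.05 * n_samples)` samples are
dropped before any analysis.

## Sample quality control

Four stages, each applied to the survivors of the previous one and each
tissue class processed independently:

0. **Library metrics** — fail if raw reads < 1e6, uniquely-mapping < 15%, or
   reads-in-genes < 5% (strict inequalities; boundary values pass).
1. **Iterative cohort filter** — repeatedly remove the sample least
   Pearson-correlated (on log2-CPM) to the class mean profile until every
   remaining sample reaches the class threshold: 0.70 by default, 0.65 for
   IDC and for basal-subtype DCIS, 0.60 for basal IDC.
2. **Patient-vs-cohort filter** — remove samples more correlated to the
   cohort mean than to their own patient's mean; single-sample patients are
   exempt.
3. **Iterative patient filter** — as stage 1 against the per-patient mean,
   at 0.80 / 0.75 / 0.75 / 0.70 for the same classes.

Numerical conventions: the mean profile always excludes the sample being
scored (self-inclusion inflates correlations in small classes); undefined
(zero-variance) correlations count as failures, except that an all-identical
class trivially passes; ties for "worst sample" break to the
lexicographically smallest sample ID. The production implementation
expresses all leave-one-out correlations through the sample Gram matrix
(one O(g·n²) product, then O(n) per removal); the test suite asserts exact
agreement with a naive full-recomputation reference.

## Differential expression

Two-group contrasts are fitted per gene on log2-CPM in the limma-voom style:

* **Precision weights.** A lowess curve (span 0.5) of sqrt-residual-SD
  against average log-count is inverted to observation-level weights
  (predicted SD⁻⁴), evaluated at each observation's fitted log-count.
* **Patient blocking.** Replicate sections and lesions from one patient are
  correlated. A single consensus intra-patient correlation is estimated as
  the Fisher-z mean of per-gene one-way-ANOVA intraclass correlations over
  the 10% most-expressed genes, computed on residuals after removing the
  group effect; per-gene generalized least squares then uses the implied
  block-equicorrelated covariance. Because the blocks are equicorrelated,
  the GLS whitening has the closed form
  `R^{-1/2} v = (1-ρ)^{-1/2}(v - v̄·1) + (1+(n_b-1)ρ)^{-1/2} v̄·1`
  per patient block, which keeps the whole fit vectorized across genes.
  Weight estimation runs twice, bracketing the correlation estimate
  (weights → correlation → weights under GLS).
* **Moderation.** Residual variances are shrunk toward a scaled
  inverse-chi-square prior fitted by moment matching on log-variances
  (Newton inversion of the trigamma function); moderated t statistics use
  the residual-plus-prior degrees of freedom. With moderation, weights and
  correlation all disabled, the fit reduces *exactly* to the ordinary
  two-sample regression t-test, which the tests assert.

Sign convention: `log2_fc > 0` means higher in the second factor level.
Multiple testing uses Benjamini–Hochberg step-up, implemented directly and
tested against both a brute-force evaluation of the definition and
statsmodels. A contrast in which one group lies entirely within a single
patient is refused as confounded.

The discriminative panel for the pseudotime is selected from the DCIS-vs-IDC
contrast restricted to patients with usable samples of both tissues, at
adjusted p < 1e-5 (a flag switches to raw p; the adjusted scale is the
default because the panel-selection cutoff is used elsewhere with adjusted
values).

## Principal-curve pseudotime (PCP)

PCA is fitted by SVD on the column-centered panel-gene submatrix of the
co-occurring DCIS/IDC samples only; all samples (normal through IDC) are
then embedded with the fitting-set centering vector. A principal curve is
fitted in the first two PCs by Hastie–Stuetzle alternation: smooth each
coordinate against arc-length position with a lowess smoother (span 0.6,
zero robustness iterations), project all points onto the smoothed polyline,
re-parameterize by cumulative arc length, and iterate. Positions are
initialized along the leading principal axis of the embedded 2-D cloud
itself — identical to PC1 when the embedding is variance-ordered, but
well-defined when the out-of-sample embedding re-orients the cloud.
Convergence is declared when the mean squared projection distance changes by
less than 0.2% (relative); the smoother makes the alternation oscillate at
about the 0.1% level near its fixed point, so a tighter tolerance never
triggers. Non-convergence returns the last iterate with a warning flag.

The curve's orientation is fixed by convention: the normal/benign end is the
start (positions flipped if needed so that mean(normal+benign) <
mean(IDC)). Ties in position break by sample ID. Segment boundaries
E1/E2/L1/L2 partition the order at rank quantiles (default 0.15, 0.45,
0.55, 0.85, overridable) with left-closed intervals; the early (E1–E2) and
late (L1–L2) windows are the substrate for early-vs-late comparisons.
Group position differences (Pure vs Not-Pure DCIS) use Welch's unequal
variance t-test, two-sided. Per-gene tissue trends use Spearman correlation
against the ordinal tissue grade (normal < benign < atypia < DCIS < IDC),
uncorrected two-sided p, NaN for constant genes.

## Gene-set analysis along the continuum

* **ssGSEA** — per sample, genes are ranked by expression; the score is the
  summed difference between the rank^0.25-weighted empirical CDF of in-set
  genes and the unweighted CDF of out-of-set genes, normalized by the range
  (max − min) of raw scores across the whole matrix, the standard ssGSEA
  normalization (stated explicitly because the upstream tooling leaves it
  implicit). Sets with fewer than two expressed genes are skipped.
* **Sliding-window scan** — windows of 100 samples advance 50 at a time
  along the PCP order (the final partial window is dropped to keep power
  constant); each window is contrasted against all remaining samples with
  the DE engine, genes up-regulated at adjusted p < 0.05 form the hit list,
  and each gene set is tested by one-sided hypergeometric
  over-representation against all analyzed genes, BH-corrected across sets
  within the window; "significant" means adjusted p < 1e-5. The window DE
  cutoff and direction are explicit configuration because only the
  enrichment threshold is pinned down externally. The default engine omits
  patient blocking inside windows (the scan is descriptive; windows mix
  patients across both sides), with a flag to enable it.
* **Bootstrap trends** — any per-sample score is regressed on PCP position
  by OLS; residuals are resampled with replacement and re-fitted 10,000
  times; percentile intervals are reported for slope, r², and the fitted
  line on a 100-point grid.

## Biomarker decision tree

Receptor status is called per sample from log2-CPM at ESR1 ≥ 6, PGR ≥ 6,
ERBB2 ≥ 10.5 (boundary counts as positive); triple-negative means all three
negative. The hazard tree operates on per-patient calls over DCIS samples
only: a patient is IDC-associated for a gene iff at least two samples fall
on the IDC-associated side of the gene's expression cut (strictly below for
"low" genes, at-or-above for the "high" gene); patients with one usable
sample are Unassigned. Cuts default to pooled per-gene medians — the
reference cut table is a placeholder for user-supplied values via the
marker-config TSV, since validated per-gene cuts belong to the data at
hand. The tree: CAMK2N1 low → HigherHazard; else progressor tally (MNX1,
HOXC11, ANKRD22, ADCY5 down-calls) of 3–4 → HigherHazard, with THRSP high
recorded as a mitigating sub-label in that branch; tally 0–1 →
LowerHazard unless SCGB2A1 is high (its IDC-associated direction), which
pushes to HigherHazard; tally 2 is not covered by the published rules and
is deliberately Indeterminate rather than guessed. The exact layering of
the SCGB2A1 and THRSP levels is our formalization of a tree described in
prose; HOXC10 and HOTAIR are excluded from the tree (no added
discrimination) but remain available as annotations. Enrichment folds are
ratios of group-membership proportions between outcomes, reported to one
decimal; cumulative-distribution comparisons dichotomize at the pooled
median by default and use the two-sided Fisher exact test.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
ground truth for recovery tests. Defaults are the study conditions:

* 145 patients; truncated-geometric lesion counts (mean 10.5, range 1–30);
  sections per lesion 1/2/3 with probabilities 0.22/0.74/0.04 — about
  2,650 samples and 1,300 lesions.
* A latent progression coordinate t ~ U on tissue-specific bands (normal
  [0, 0.10], benign [0.02, 0.18], atypia [0.12, 0.35], DCIS [0.15, 0.85],
  IDC [0.70, 1.0]), drawn per lesion and shared by its sections (adjacent
  cuts of one lesion).
* Patient outcome (30% Pure) is drawn before tissues: Pure patients never
  carry IDC lesions, half of Not-Pure patients have IDC in the biopsy.
  Within the DCIS band the t distribution is identical across outcomes, so
  PCP position carries no outcome information (the Welch comparison is a
  true null, and its p-values are uniform across seeds by construction).
* Programs (5,000 genes total): 400 basal genes declining linearly by 2.5
  log2 over the continuum; 300 EMT genes as two Gaussian bumps (t = 0.25,
  width 0.07 and t = 0.90, width 0.05; amplitude 2.0); 300 proliferation
  genes as a logistic switch at t = 0.28 (just after the first EMT peak,
  scale 0.02, amplitude 0.5); 8 named marker genes; ESR1/PGR/ERBB2 bimodal
  by receptor status around the calling thresholds; the rest background.
  The proliferation switch saturates early in the DCIS band on purpose:
  its DCIS-vs-IDC contrast is then small relative to the basal and EMT
  programs, so the selected discriminative panel is dominated by
  basal/EMT genes — the composition the analysis downstream assumes. At
  the default scale panel precision against the planted basal∪EMT truth
  runs ≈ 0.90–0.96 across seeds.
* Marker bimodality is a patient-level low state (probability 0.70 for
  Not-Pure vs 0.25 for Pure patients; SCGB2A1 reversed because its
  IDC-associated state is high), shifting the gene by 3 log2 — a skewed
  mixture rather than a uniform shift.
* Counts are negative binomial (dispersion 0.1) around library-scaled
  program means (libraries U[0.6M, 2.5M]), on top of a per-patient,
  per-gene N(0, 0.7) log2 random effect. The strong patient effect is what
  makes the patient-blocked DE and the patient-vs-cohort QC stage
  meaningful; with a weaker effect the patient mean is a worse estimator
  than the cohort mean and stage 2 would over-remove.
* Low-quality samples are injected by permuting a sample's counts across
  genes and cutting depth 10-fold, which drives its correlation to the
  cohort mean below the 0.70 QC threshold.

What the synthetic validation shows: the pipeline recovers a planted
monotone ordering through QC, panel selection, out-of-sample PCA embedding
and curve fitting (|Spearman| ≥ 0.99 at full scale over 5 seeds); the DE
machinery is calibrated under a patient-blocked null; the QC filters remove
exactly the planted corruption while retaining ≥ 95% of clean samples; and
the marker tree enriches the Lower-Hazard group for Pure patients whenever
outcome-linked bimodal markers exist. What it does not show: robustness to
real-data features the generator omits — gene–gene correlation beyond the
block programs, compositional/batch artifacts, subtype-specific program
differences, copy-number effects, isoform structure, or mislabeled tissue
annotations.

## Problem sizes used in the checked runs

The test suite exercises reduced cohorts (40–60 patients, 800 genes,
program blocks scaled proportionally) for unit-level checks and the five
full default cohorts (~2,650 samples × 5,000 genes) for the ordering
recovery check. `scripts/acceptance.py` runs one full default cohort with
10% corruption, a 2,000-gene null DE simulation, and twenty 150-gene
marker cohorts; it completes in a few minutes on one CPU. The 20-seed
marker check uses small gene counts because the hazard tree reads only the
eight marker genes and the patient metadata; gene count does not enter the
statistic.

## Known limitations

* The principal curve is a single non-branching path by design; bifurcating
  trajectories are out of scope.
* The consensus-correlation estimator (ANOVA ICC, Fisher-z averaged) is a
  single-number contract; it matches the blocking intent but is not a
  numerical clone of any specific REML implementation, and no claim of
  per-gene numerical equality with external tools is made — calibration is
  established by simulation instead.
* E1/E2/L1/L2 placement is a rank-quantile convention, not an estimate; the
  biology constrains only their order.
* Marker cuts default to pooled medians; clinical use would require
  externally validated per-gene thresholds.
* With very few co-occurring patients (≲ 10) the panel PCA plane can be
  dominated by patient effects and the embedded continuum degrades; the
  pipeline surfaces this through the recovery diagnostics in the summary
  rather than guarding against it.
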