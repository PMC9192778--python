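# dcistraj

Pseudotime and progression-biomarker analysis for bulk RNA-seq of
individually micro-dissected breast ductal lesions.

Ductal carcinoma in situ (DCIS) is a non-invasive precursor of invasive
ductal carcinoma (IDC), but most DCIS never progresses, and morphology alone
separates the two poorly. When hundreds of lesions — normal epithelium,
benign ducts, atypia, DCIS and IDC, with replicate sections per lesion and
many lesions per patient — are profiled in one cohort, their transcriptomes
can be arranged on a single continuum from normal duct to invasive disease
and mined for processes and markers that track progression. `dcistraj`
implements that analysis path end to end for computational biologists
working with such cohorts (or wanting to stress-test the approach on
synthetic ones):

1. **Preprocessing** — TMM normalization factors and log₂-CPM
   (`log2((k + 0.5)/(L_eff + 1) · 10⁶)`), 5%-detection gene filter.
2. **Sample QC** — the four-stage filter used for micro-dissected libraries:
   library metrics, iterative correlation-to-cohort-mean, patient-vs-cohort
   correlation, iterative correlation-to-patient-mean, with per-tissue and
   per-subtype thresholds and exact bookkeeping.
3. **Differential expression** — per-gene linear models on log₂-CPM with
   voom-style precision weights, a consensus intra-patient correlation used
   in GLS (patient blocking), empirical-Bayes variance moderation, and BH
   correction; a DCIS-vs-IDC contrast on co-occurring patients yields the
   discriminative gene panel.
4. **Principal-curve pseudotime (PCP)** — PCA on the panel genes fitted on
   the co-occurring samples, out-of-sample embedding of all tissues, a
   Hastie–Stuetzle principal curve in PC1/PC2, and arc-length projection:
   each sample's PCP position is its pseudotime from normal epithelium to
   IDC. Segments (pre-E1, E1–E2, mid, L1–L2, post-L2) partition the order.
5. **Enrichment along the continuum** — per-sample ssGSEA scores, a sliding
   window (100 samples, step 50) over-representation scan of gene sets in
   window-vs-rest up-regulated genes, and residual-resampling bootstrap
   trends of any score against PCP position.
6. **Biomarker decision tree** — ESR1/PGR/ERBB2 receptor calls, per-patient
   marker calls (≥2 samples on the IDC-associated side of a cut), the
   progressor tally (MNX1, HOXC11, ANKRD22, ADCY5) anchored by CAMK2N1 and
   refined by SCGB2A1/THRSP, hazard-group assignment, enrichment folds and
   Fisher-exact cumulative-distribution comparisons.
7. **Synthetic cohorts** — a generator that plants a latent progression
   coordinate, a declining basal program, a two-peak EMT program, a
   late-onset proliferation switch, outcome-linked bimodal markers,
   negative-binomial noise, patient random effects and corrupted samples,
   with full ground truth for recovery testing.

The model in brief: for sample *i* with latent progression *tᵢ* ∈ [0, 1],
log-expression of gene *g* is μ_g + f_P(g)(tᵢ) + u_{p(i),g} + εᵢ_g, where
f_P is the program profile (monotone decline, two-bump EMT, logistic
proliferation), u is a per-patient random effect and counts are NB around
the library-scaled mean. The analysis never sees *t*; it reconstructs it as
arc length along a self-consistent curve through the panel-gene PC plane.

## Worked example

Run the full pipeline on a reduced synthetic cohort (60 patients, 800
genes, 5% corrupted samples):

```python
from dcistraj.pipeline import PipelineConfig, run_full_pipeline
from dcistraj.genesets import ScanConfig
from dcistraj.synthgen import CohortConfig

cfg = PipelineConfig(
    outdir="example_run", seed=7,
    simulate=CohortConfig(
        n_patients=60, lesions_range=(1, 15), lesions_mean=8.0, n_genes=800,
        program_sizes={"basal": 80, "emt": 60, "proliferation": 60, "marker": 8},
        frac_low_quality=0.05, seed=7),
    panel_alpha=1e-3,
    scan=ScanConfig(window=60, step=30, fdr_alpha=1e-3))
summary = run_full_pipeline(cfg)
```

The summary this prints (abridged):

```json
{
  "counts": {"input": 735, "removed_metrics": 15, "removed_cohort": 36,
             "removed_patient_vs_cohort": 0, "removed_patient": 0,
             "retained": 684},
  "panel_size": 131,
  "consensus_correlation": 0.618,
  "welch_mean_diff_pure_vs_notpure": -1.134,
  "welch_p": 0.062,
  "lower_hazard_fold": {"fold": 14.1, "prop_a": 0.353, "prop_b": 0.025},
  "n_windows": 21,
  "pcp_truth_spearman_abs": 0.988,
  "panel_precision_basal_emt": 0.992
}
```

Reading it: of 735 libraries, 15 failed raw metrics and 36 the iterative
cohort-correlation filter, leaving 684 (the counts always conserve). The
DCIS-vs-IDC contrast on co-occurring patients gave a 131-gene panel, 99% of
which lies in the planted basal/EMT programs; the consensus intra-patient
correlation of 0.62 reflects the strong planted patient effect. The
recovered PCP order matches the hidden progression coordinate at |ρ| = 0.99,
while the Welch test finds no significant positional difference between Pure
and Not-Pure DCIS (p = 0.062) — as planted, since outcome is independent of
position. The Lower-Hazard group is 14-fold enriched for Pure-DCIS patients
(35% vs 2.5% group membership), driven by the planted bimodal markers.
Per-stage artifacts (QC report, DE table, panel, PCP order with segments,
ssGSEA matrix, window scan, hazard groups) are written as TSVs under
`example_run/`.

The same stages are available from the shell:

```bash
dcistraj simulate --seed 7 --outdir cohort --n-patients 60 --n-genes 800
dcistraj qc --counts cohort/counts.tsv --meta cohort/meta.tsv
dcistraj run --seed 7 --outdir full_run
dcistraj config --dump
```

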