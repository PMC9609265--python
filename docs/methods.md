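# Methods

`microsurv` implements a survival-biomarker analysis for paired-tissue 16S
microbiome studies with a peripheral gene-expression panel: compositional
preprocessing, tumor-vs-normal community tests, elastic-net Cox stability
selection, and time-dependent AUC evaluation of nested risk models — plus a
synthetic cohort generator with planted ground truth for validating all of
it.

## Data model

* **Feature table** — integer counts, samples x ASVs, with an optional
  Greengenes-style 7-rank lineage per ASV (TSV or BIOM-JSON). Samples with
  fewer than `min_reads` total reads (default **6000**, inclusive) are
  excluded.
* **Sample metadata** — sample -> patient and tissue (`tumor`/`normal`);
  pairing uses patients with both tissues.
* **Survival records** — per patient: recurrence, new-primary, and death
  times (months), last follow-up, and vital status. A missing death date
  for a patient known to have died is imputed from the recurrence date.
  Composite endpoints: **RFS** (recurrence or death), **DFS** (RFS plus new
  primaries), **OS** (death only); derived times always satisfy
  DFS <= RFS <= OS.
* **Clinical covariates** — age, sex, race, smoking, histology,
  chemotherapy; dummy-coded against the lexicographically first level.
  `screen_covariates` retains covariates with unadjusted Cox p < 0.10 on
  any endpoint.

## Compositional preprocessing

* **Agglomeration** sums ASVs sharing the full lineage down to a rank;
  with `drop_unclassified=True`, groups unclassified at that rank are
  removed (the per-rank analyses use this).
* **clr transform**: `clr_j = ln(x_j + c) − mean_k ln(x_k + c)` per sample,
  pseudocount `c = 0.5`. Rows sum to zero exactly.
* **Alpha diversity**: richness and base-2 Shannon averaged over repeated
  rarefaction (multivariate hypergeometric subsampling) to depth **2468**
  with **100** iterations.
* **Beta diversity**: Jensen–Shannon divergence, base 2 (in [0, 1];
  sqrt(JSD) is a metric), embedded by classical PCoA (negative eigenvalues
  reported; axis signs fixed by making the first nonzero loading positive).

## Community tests

* **PERMANOVA** (one factor): pseudo-F on the distance matrix; with
  `strata` (patient id), permutations exchange labels only within strata,
  respecting the paired design. p is the add-one permutation estimate.
* **Paired-distance test**: is the mean within-pair distance smaller than
  under random tumor->normal bijections? Reported with the
  5th-percentile decision rule (default **5000** permutations).
* **Per-feature paired tests**: Wilcoxon signed-rank on paired clr values
  (exact for n <= 25 without ties, normal approximation with continuity
  correction otherwise), BH-adjusted within each rank.

## Biomarker selection

Features are clr taxa (per rank) or log2 genes; the endpoint enters as a
covariate-adjusted Cox model throughout.

* **Stability selection**: **R = 500** repetitions of **K = 10**-fold
  cross-validated elastic-net Cox (`alpha = 0.5` mixing; scikit-survival
  Coxnet) with the clinical covariates unpenalized (`penalty_factor = 0`).
  A single lambda path is computed on the full data and shared across
  folds; the cross-validated deviance is the Verweij–van Houwelingen
  difference `−2(ll_all − ll_train)`; the penalty minimizing mean CV
  deviance (or the `1se` rule) is refit on all data, and nonzero feature
  coefficients count as selections.
* **Selection rule**: selected in >= **25%** of repetitions AND adjusted
  BH **q < 0.20** from the per-feature covariate-adjusted Cox fit
  (lifelines; Efron ties; optional cluster-robust variance when multiple
  samples per patient enter).

## Risk prediction

Four nested Cox models — covariates only, +microbiome, +genes, +both — are
compared by **cumulative/dynamic AUC(t)** with inverse-probability-of-
censoring weights: cases (event by t) weighted `1/G(T−)`, controls (still
at risk) `1/G(t)`, where G is the Kaplan–Meier estimate of the censoring
distribution; tied risk scores count one half. Default horizon grid:
12–60 months in steps of 12.

* **Bootstrap**: percentile 95% CIs over **1000** patient resamples,
  refitting the model each time; degenerate resamples are skipped.
* **Permutation test of added value**: the biomarker block(s) added by the
  larger model are shuffled as whole rows across patients (**5000**
  permutations), keeping the covariate-outcome link intact; both add-one
  p-values and the 95th-percentile decision are reported.
* Resampling inner loops use an in-package vectorized Newton solver for
  the Breslow partial likelihood (`_coxfast`), verified against lifelines
  on tie-free data; user-facing fits always go through lifelines.

## Synthetic cohort generator

Defaults mirror a 46-patient paired-tissue study: 787 ASVs over
6 phyla / 10 classes / 19 orders / 27 families / 41 genera / 13 named
species; log-normal sequencing depth (median 16000 reads).

* **Compositions**: logistic-normal with clade-structured covariance
  (random effects at every internal taxonomy node), so related taxa
  co-vary. Tumor and normal latents mix a shared patient profile with
  tissue noise, `z = rho * patient + (1 − rho) * noise` with
  `rho_pair = 0.7`; counts are multinomial at the drawn depth.
* **Survival**: exponential-baseline Cox model. The planted taxon effects
  (default 3 genera, log-HR **0.8 per clr unit**) act on the *observed*
  clr of the normal-lung genus counts, so the fitted Cox model is the true
  model and coefficient recovery is attenuation-free. Gene effects
  (default −0.5 per log2 unit) and clinical covariate effects add to the
  linear predictor. Administrative censoring is uniform on 24–146 months;
  post-recurrence death follows after an exponential lag; unrelated
  background mortality and new primaries are kept rare (0.0005 and 0.001
  per month) so the planted model remains the true model of the composite
  endpoints. Roughly 15% of tumor and 11% of normal samples are masked
  as missing.
* **Limits**: no batch effects, no taxon-taxon interactions, proportional
  hazards hold exactly, and contaminants appear only via
  `inject_contaminants` (Poisson constant counts, i.e. depth-
  anticorrelated relative abundance). Planted effect sizes are chosen for
  statistical power in validation, not transferred from any tissue data.

## Numerical and reproducibility choices

* All stochastic stages draw from `numpy` Generators; the pipeline derives
  per-stage seeds from one master seed via `SeedSequence.spawn` (reduced
  mod 2^31), and a rerun with the same seed is byte-identical.
* Permutation p-values use the add-one estimator `(1 + #extreme) / (1 + M)`.
* Validation problem sizes (chosen in advance for power within a desktop
  CPU budget): null-calibration checks pool 200 cohorts (n = 150 for Cox
  Wald uniformity, where the asymptotics hold; n = 60 for the AUC
  permutation rejection rate; n = 25 pairs for the paired-distance test
  with 199 permutations); recovery checks use 3 planted genera among ~50
  at n = 150 with R = 100 (50 cohorts) and coefficient recovery at n = 500
  (200 cohorts).
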