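"""Survival biomarker screening by elastic-net Cox stability selection.

Each genus-level clr feature is scored two ways: how often the penalized
Cox model keeps it across repeated cross-validation, and a covariate-
adjusted Cox fit with BH-corrected p-values.  A feature is called
survival-related when both views agree (>= 25% selection AND q < 0.20).
Run:  python examples/03_biomarker_selection.py   (~1 min)
"""

from microsurv import composition, selection, tables_io
from microsurv.synthetic import CohortSpec, simulate_cohort

spec = CohortSpec(n_patients=100, n_asvs=200,
                  rank_sizes={"phylum": 3, "class": 4, "order": 6,
                              "family": 10, "genus": 25, "species": 5},
                  n_signal_taxa=2, beta_taxa=0.8,
                  p_missing_tumor=1.0, p_missing_normal=0.0, seed=3)
cohort = simulate_cohort(spec)

# Features: clr of the genus-agglomerated normal-lung counts, per patient.
agg = composition.agglomerate(cohort.tissue_table("normal"), "genus",
                              drop_unclassified=True)
clr = composition.clr_transform(agg, pseudocount=0.5).values
clr.index = cohort.metadata.table.loc[clr.index, "patient_id"]

surv = tables_io.endpoint_frame(cohort.records, "RFS")
design = cohort.covariates.design_matrix()   # never penalized

stab = selection.stability_select(surv, clr, design,
                                  R=100, K=10, alpha=0.5, seed=0)
stab = selection.attach_adjusted_cox(stab, surv, clr, design)
chosen = selection.select_features(stab, min_fraction=0.25, q_threshold=0.20)

frame = stab.frame().sort_values("selection_count", ascending=False)
print(frame[["selection_count", "HR", "ci_lower", "ci_upper", "q"]]
      .head(6).round(3))
print(f"\nselected features: {chosen}")
print(f"planted features:  {list(cohort.truth.signal_taxa)}")
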