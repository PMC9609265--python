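"""Diversity, ordination, and tumor-vs-normal community tests.

Workflow: rarefied alpha-diversity -> Jensen-Shannon divergence -> PCoA ->
PERMANOVA (with patient strata) and the paired-distance permutation test.
Run:  python examples/02_diversity_and_ordination.py
"""

from microsurv import community, composition
from microsurv.synthetic import CohortSpec, simulate_cohort

spec = CohortSpec(n_patients=25, n_asvs=150,
                  rank_sizes={"phylum": 3, "class": 4, "order": 6,
                              "family": 8, "genus": 15, "species": 4},
                  rho_pair=0.7, p_missing_tumor=0.0, p_missing_normal=0.0,
                  seed=2)
cohort = simulate_cohort(spec)
table = cohort.table
meta = cohort.metadata

# Alpha diversity, averaged over repeated rarefaction to a common depth.
alpha = composition.rarefied_alpha(table, depth=2000, iterations=50, seed=0)
by_tissue = alpha.table.join(meta.table).groupby("tissue_type")["shannon"]
print("mean Shannon (bits) by tissue:")
print(by_tissue.mean().round(3).to_string())

# Beta diversity: pairwise JSD, embedded with PCoA.
dmat = composition.jsd_matrix(table)
pc = composition.pcoa(dmat, k=2)
var = pc.proportion_explained
print(f"\nPCoA axis 1/2 variance explained: {var[0]:.1%} / {var[1]:.1%}")

# Does tissue type structure the communities?  Permutations stay within
# patient (strata), respecting the paired design.
res = community.permanova(dmat, meta.table["tissue_type"],
                          strata=meta.table["patient_id"],
                          n_perm=999, seed=0)
print(f"PERMANOVA tissue: pseudo-F={res.pseudo_f:.2f} "
      f"R2={res.r_squared:.3f} p={res.p_value:.3f}")

# Are a patient's own tumor and normal samples more alike than random
# tumor-normal pairings?
pdt = community.paired_distance_test(dmat, meta.pairs(), n_perm=999, seed=0)
print(f"paired-distance test: observed mean JSD={pdt.observed_mean:.3f}, "
      f"p={pdt.p_value:.3f}, more-alike-than-chance={pdt.more_alike}")
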