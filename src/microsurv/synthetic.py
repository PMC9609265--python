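"""Synthetic paired tumor/normal lung cohort with planted survival effects.

The generator emulates the structure of a low-biomass 16S tissue-microbiome
study with a peripheral gene-expression panel and recurrence/death follow-up:

* a Greengenes-style 7-rank taxonomy over the ASVs, sized by default like
  the study data (6 phyla, 10 classes, 19 orders, 27 families, 41 genera,
  13 classified species, 787 ASVs) and scalable down by config;
* logistic-normal compositions with clade-structured covariance (random
  effects at every internal taxonomy node), so related taxa co-vary;
* paired tumor and normal samples from the same patient mixed from a shared
  patient latent profile — within-patient similarity is controlled by
  ``rho_pair`` (1 = identical compositions, 0 = independent);
* multinomial counts at a log-normal sequencing depth;
* survival times from an exponential-baseline Cox model whose linear
  predictor combines planted clr-taxon effects (measured on the normal-lung
  sample, the tissue the study's strongest signals came from), planted
  log2-gene effects, and clinical covariate effects; censoring is an
  independent uniform administrative window;
* some patients randomly lack the tumor or the normal sample.

Planted effect sizes default to values chosen for test power (hazard ratios
per clr unit on real tissue data are not transferable to a simulation);
ground truth (signal ids, true linear predictor, pre-censoring event times)
is returned alongside every cohort so downstream recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .composition import agglomerate, clr_transform
from .tables_io import (RANKS, CovariateSet, FeatureTable, SampleMetadata,
                        SurvivalRecord, TableError)

DEFAULT_RANK_SIZES = {"phylum": 6, "class": 10, "order": 19, "family": 27,
                      "genus": 41, "species": 13}


@dataclass
class CohortSpec:
    n_patients: int = 46
    n_asvs: int = 787
    rank_sizes: dict = field(default_factory=lambda: dict(DEFAULT_RANK_SIZES))
    species_classified_prob: float = 0.15  # most ASVs lack species-level names
    depth_log_mean: float = np.log(16000.0)
    depth_log_sd: float = 0.8
    rho_pair: float = 0.7
    base_log_sd: float = 2.0          # spread of mean log abundances
    clade_sd: float = 0.6             # per-patient random effect at each node
    asv_sd: float = 0.8               # per-patient ASV-level deviation
    signal_rank: str = "genus"
    n_signal_taxa: int = 3
    beta_taxa: float = 0.8            # log-HR per clr unit of a signal genus
    n_genes: int = 100
    n_signal_genes: int = 4
    beta_genes: float = -0.5          # log-HR per log2 unit (protective)
    gene_log2_sd: float = 1.0
    gamma: dict = field(default_factory=lambda: {
        "age": 0.02, "sex_male": 0.3, "smoking_former": 0.3,
        "smoking_never": -0.3, "histology_squamous": 0.2,
        "chemotherapy_yes": -0.2, "race_white": 0.0})
    baseline_hazard: float = 0.010    # events per month
    censor_window: tuple = (24.0, 146.0)   # months, uniform administrative
    p_missing_tumor: float = 0.15
    p_missing_normal: float = 0.11
    pseudocount: float = 0.5          # used when measuring the planted clr signal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2 or self.n_asvs < 2:
            raise TableError("need at least 2 patients and 2 ASVs")
        if not 0.0 <= self.rho_pair <= 1.0:
            raise TableError("rho_pair must lie in [0, 1]")
        if self.depth_log_sd <= 0 or self.base_log_sd <= 0:
            raise TableError("scale parameters must be > 0")
        if self.censor_window[0] <= 0 or self.censor_window[1] <= self.censor_window[0]:
            raise TableError("censor window must be an increasing positive interval")


@dataclass
class GroundTruth:
    signal_taxa: dict            # feature id (at signal rank) -> beta
    signal_genes: dict           # gene id -> beta
    gamma: dict
    linear_predictor: pd.Series  # per patient
    event_time: pd.Series        # pre-censoring event (recurrence) time
    censor_time: pd.Series
    contaminants: list = field(default_factory=list)


@dataclass
class Cohort:
    table: FeatureTable          # all retained samples, ASV level
    metadata: SampleMetadata
    covariates: CovariateSet
    records: list
    genes: pd.DataFrame          # patients x genes (normalized linear scale)
    truth: GroundTruth

    def tissue_table(self, tissue: str) -> FeatureTable:
        ids = self.metadata.samples_of(tissue).index
        return self.table.subset_samples(ids)


def _build_taxonomy(spec: CohortSpec, rng: np.random.Generator):
    """Random rank tree: each taxon at a rank gets a parent one rank up;
    ASVs hang off genera, a minority carrying species names."""
    sizes = spec.rank_sizes
    names = {r: [f"{r[0].upper()}{i + 1}" for i in range(sizes[r])]
             for r in sizes}
    parent = {}
    order_of = ["phylum", "class", "order", "family", "genus"]
    for child_rank, parent_rank in zip(order_of[1:], order_of[:-1]):
        # every parent gets at least one child; the rest attach at random
        n_child, n_par = sizes[child_rank], sizes[parent_rank]
        assign = list(rng.permutation(n_par)) + \
            list(rng.integers(0, n_par, size=max(0, n_child - n_par)))
        for ci, pi in enumerate(assign[:n_child]):
            parent[(child_rank, ci)] = int(pi)
    lineages = {}
    asv_genus = rng.integers(0, sizes["genus"], size=spec.n_asvs)
    species_pool = rng.integers(0, sizes["species"], size=spec.n_asvs)
    has_species = rng.random(spec.n_asvs) < spec.species_classified_prob
    for a in range(spec.n_asvs):
        g = int(asv_genus[a])
        f = parent[("genus", g)]
        o = parent[("family", f)]
        c = parent[("order", o)]
        p = parent[("class", c)]
        lin = ["Bacteria", names["phylum"][p], names["class"][c],
               names["order"][o], names["family"][f], names["genus"][g],
               names["species"][species_pool[a]] if has_species[a] else ""]
        lineages[f"ASV{a + 1:04d}"] = tuple(lin)
    return lineages, asv_genus


def _covariates(spec: CohortSpec, rng: np.random.Generator,
                pids: list[str]) -> CovariateSet:
    n = len(pids)
    df = pd.DataFrame({
        "age": np.round(rng.normal(70, 9, size=n), 1),
        "sex": rng.choice(["male", "female"], size=n),
        "race": rng.choice(["white", "non-white"], size=n, p=[0.87, 0.13]),
        "smoking": rng.choice(["never", "former", "current"], size=n,
                              p=[0.15, 0.63, 0.22]),
        "histology": rng.choice(["adenocarcinoma", "squamous"], size=n),
        "chemotherapy": rng.choice(["yes", "no"], size=n, p=[0.33, 0.67]),
    }, index=pd.Index(pids, name="patient_id"))
    return CovariateSet(df)


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Draw one full synthetic cohort; byte-identical under a fixed seed."""
    streams = np.random.SeedSequence(spec.seed).spawn(7)
    rng_tax, rng_comp, rng_depth, rng_cov, rng_gene, rng_surv, rng_miss = (
        np.random.default_rng(s) for s in streams)

    lineages, asv_genus = _build_taxonomy(spec, rng_tax)
    asv_ids = list(lineages)
    n_asv = len(asv_ids)
    pids = [f"P{i + 1:03d}" for i in range(spec.n_patients)]
    n = spec.n_patients

    # latent log-abundances: shared mean + per-patient clade + ASV effects
    base = rng_comp.normal(0.0, spec.base_log_sd, size=n_asv)
    lin_arr = np.array([lineages[a][:6] for a in asv_ids])  # kingdom..genus
    node_members = {}
    for ri in range(1, 6):  # phylum..genus columns of lin_arr
        for name in np.unique(lin_arr[:, ri]):
            node_members[(ri, name)] = np.flatnonzero(lin_arr[:, ri] == name)
    patient_dev = np.zeros((n, n_asv))
    for _, members in sorted(node_members.items()):
        patient_dev[:, members] += rng_comp.normal(
            0.0, spec.clade_sd, size=n)[:, None]
    patient_dev += rng_comp.normal(0.0, spec.asv_sd, size=(n, n_asv))

    rho = spec.rho_pair
    sample_rows, sample_ids, meta_rows = [], [], []
    depths = np.maximum(
        np.exp(rng_depth.normal(spec.depth_log_mean, spec.depth_log_sd,
                                size=(n, 2))), 10).astype(int)
    counts_by_tissue = {}
    for ti, tissue in enumerate(("tumor", "normal")):
        noise = rng_comp.normal(0.0, spec.asv_sd + spec.clade_sd, size=(n, n_asv))
        z = base[None, :] + rho * patient_dev + (1 - rho) * noise
        z = z - z.max(axis=1, keepdims=True)
        prob = np.exp(z)
        prob /= prob.sum(axis=1, keepdims=True)
        counts = np.vstack([rng_comp.multinomial(depths[i, ti], prob[i])
                            for i in range(n)])
        counts_by_tissue[tissue] = counts
        for i, pid in enumerate(pids):
            sid = f"{pid}_{'T' if tissue == 'tumor' else 'N'}"
            sample_ids.append(sid)
            sample_rows.append(counts[i])
            meta_rows.append({"sample_id": sid, "patient_id": pid,
                              "tissue_type": tissue})

    full_counts = pd.DataFrame(np.vstack(sample_rows),
                               index=pd.Index(sample_ids, name="sample_id"),
                               columns=asv_ids)
    full_table = FeatureTable(full_counts, dict(lineages))

    covset = _covariates(spec, rng_cov, pids)
    design = covset.design_matrix()
    gamma_vec = np.array([spec.gamma.get(c, 0.0) for c in design.columns])
    cov_lp = (design.to_numpy() - design.to_numpy().mean(axis=0)) @ gamma_vec

    # planted taxon signal, measured where the analysis will measure it:
    # clr of the signal-rank agglomeration of the normal-lung counts
    normal_ids = [f"{p}_N" for p in pids]
    agg = agglomerate(full_table.subset_samples(normal_ids), spec.signal_rank,
                      drop_unclassified=True)
    clr_norm = clr_transform(agg, spec.pseudocount).values
    sig_cols = [str(c) for c in rng_surv.choice(
        clr_norm.columns, size=spec.n_signal_taxa,
        replace=False)] if spec.n_signal_taxa else []
    signal_taxa = {c: spec.beta_taxa for c in sig_cols}
    taxa_lp = np.zeros(n)
    for c, b in signal_taxa.items():
        v = clr_norm[c].to_numpy()
        taxa_lp += b * (v - v.mean())

    # gene panel: log-normal expression; planted effects act per log2 unit
    gene_ids = [f"GENE{i + 1:03d}" for i in range(spec.n_genes)]
    log2_expr = rng_gene.normal(8.0, spec.gene_log2_sd, size=(n, spec.n_genes))
    genes = pd.DataFrame(2.0 ** log2_expr, index=pd.Index(pids, name="patient_id"),
                         columns=gene_ids)
    sig_genes = [str(g) for g in rng_surv.choice(
        gene_ids, size=spec.n_signal_genes,
        replace=False)] if spec.n_signal_genes else []
    signal_genes = {g: spec.beta_genes for g in sig_genes}
    gene_lp = np.zeros(n)
    for g, b in signal_genes.items():
        v = log2_expr[:, gene_ids.index(g)]
        gene_lp += b * (v - v.mean())

    lp = taxa_lp + gene_lp + cov_lp
    rate = spec.baseline_hazard * np.exp(lp)
    t_event = rng_surv.exponential(1.0 / rate)
    censor = rng_surv.uniform(*spec.censor_window, size=n)
    # after recurrence most patients die after a lag; unrelated background
    # mortality is kept rare so the planted Cox model is the true model of
    # the composite endpoints
    death_lag = rng_surv.exponential(12.0, size=n)
    dies_after_rec = rng_surv.random(n) < 0.7
    t_background_death = rng_surv.exponential(1.0 / 0.0005, size=n)
    t_new_primary = rng_surv.exponential(1.0 / 0.001, size=n)

    records = []
    for i, pid in enumerate(pids):
        t_death = min(t_event[i] + death_lag[i] if dies_after_rec[i] else np.inf,
                      t_background_death[i])
        end = min(censor[i], t_death)
        died = t_death <= censor[i]
        rec = t_event[i] if t_event[i] <= end else None
        newp = t_new_primary[i] if t_new_primary[i] <= end else None
        records.append(SurvivalRecord(
            patient_id=pid,
            recurrence_time=None if rec is None else round(float(rec), 3),
            new_primary_time=None if newp is None else round(float(newp), 3),
            death_time=round(float(t_death), 3) if died else None,
            last_followup_time=round(float(end), 3),
            died=bool(died)))

    # mask randomly missing tissues (survival was generated pre-masking)
    keep = []
    for pid in pids:
        u_t, u_n = rng_miss.random(2)
        if u_t >= spec.p_missing_tumor:
            keep.append(f"{pid}_T")
        if u_n >= spec.p_missing_normal:
            keep.append(f"{pid}_N")
    table = full_table.subset_samples(keep)
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id")
                          .loc[keep])

    truth = GroundTruth(
        signal_taxa=signal_taxa, signal_genes=signal_genes,
        gamma=dict(spec.gamma),
        linear_predictor=pd.Series(lp, index=pids),
        event_time=pd.Series(t_event, index=pids),
        censor_time=pd.Series(censor, index=pids))
    return Cohort(table, meta, covset, records, genes, truth)


def inject_contaminants(table: FeatureTable, n_contaminants: int,
                        mean_count: float = 200.0,
                        seed: int | None = None,
                        truth: GroundTruth | None = None) -> FeatureTable:
    """Add frequency-style contaminant features.

    Reagent contaminants contribute a roughly constant absolute number of
    reads per sample, so their relative abundance falls as sequencing depth
    rises; counts are Poisson with a fixed mean, which reproduces that
    depth-anticorrelation.  Injected ids are recorded in ``truth`` when given.
    """
    if n_contaminants < 0:
        raise TableError("n_contaminants must be >= 0")
    if n_contaminants == 0:
        return table
    rng = np.random.default_rng(seed)
    n_samp = len(table.sample_ids)
    ids = [f"CONTAM{i + 1:03d}" for i in range(n_contaminants)]
    extra = pd.DataFrame(rng.poisson(mean_count, size=(n_samp, n_contaminants)),
                         index=table.counts.index, columns=ids)
    counts = pd.concat([table.counts, extra], axis=1)
    taxonomy = None
    if table.taxonomy is not None:
        taxonomy = dict(table.taxonomy)
        for cid in ids:
            taxonomy[cid] = ("Bacteria",) + ("",) * 6
    if truth is not None:
        truth.contaminants.extend(ids)
    return FeatureTable(counts, taxonomy)
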