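import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

# deterministic property tests: same examples on every run/machine
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from microsurv import composition, tables_io
from microsurv.synthetic import CohortSpec, simulate_cohort

warnings.filterwarnings("ignore", module="lifelines")

SMALL_RANKS = {"phylum": 3, "class": 4, "order": 5, "family": 6,
               "genus": 10, "species": 3}


def small_spec(seed=0, **kw):
    """A fast, paired cohort spec used across the unit tests."""
    defaults = dict(n_patients=30, n_asvs=40, rank_sizes=dict(SMALL_RANKS),
                    n_genes=6, n_signal_taxa=1, n_signal_genes=1,
                    p_missing_tumor=0.1, p_missing_normal=0.1, seed=seed)
    defaults.update(kw)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def cohort():
    return simulate_cohort(small_spec(seed=42))


@pytest.fixture(scope="session")
def survival_setup():
    """Cohort with one planted genus, plus the aligned clr matrix / design /
    endpoint frame downstream survival tests all need."""
    c = simulate_cohort(small_spec(
        seed=7, n_patients=80, beta_taxa=1.0, n_signal_taxa=2,
        n_signal_genes=2, beta_genes=-0.6,
        p_missing_tumor=1.0, p_missing_normal=0.0))
    surv = tables_io.endpoint_frame(c.records, "RFS")
    agg = composition.agglomerate(c.tissue_table("normal"), "genus",
                                  drop_unclassified=True)
    clr = composition.clr_transform(agg, 0.5).values
    clr.index = c.metadata.table.loc[clr.index, "patient_id"]
    design = c.covariates.design_matrix()
    return c, surv, clr, design


def toy_table(taxonomy=True):
    counts = pd.DataFrame(
        [[10, 0, 5], [3, 7, 2]],
        index=["S1", "S2"], columns=["F1", "F2", "F3"])
    tax = {
        "F1": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "", "", ""),
        "F2": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "", "", ""),
        "F3": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "", "", ""),
    } if taxonomy else None
    return tables_io.FeatureTable(counts, tax)
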