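"""Feature tables, sample metadata, covariates, and survival endpoints.

The in-memory containers mirror the conventions of amplicon-sequencing
pipelines: a feature table holds non-negative integer counts of amplicon
sequence variants (ASVs) or agglomerated taxa, samples x features, with an
optional Greengenes-style 7-rank lineage string per feature.  Survival
records carry per-patient event-history times (months from surgery) from
which the composite endpoints are derived:

* RFS (recurrence-free survival): recurrence or death, new primaries ignored
* DFS (disease-free survival): recurrence, new primary, or death
* OS  (overall survival): death only

Patients with no qualifying event are censored at last follow-up.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
UNCLASSIFIED = ""

ENDPOINTS = ("RFS", "DFS", "OS")

MISSING = "NA"


class TableError(ValueError):
    """Raised for malformed or inconsistent tabular inputs."""


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """Counts of features (ASVs / taxa / pathways / genes) per sample.

    ``counts`` is a samples x features DataFrame of non-negative integers;
    ``taxonomy`` optionally maps feature id -> 7-tuple of rank names
    (empty string = unclassified at that rank).
    """

    counts: pd.DataFrame
    taxonomy: dict[str, tuple[str, ...]] | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise TableError("duplicate sample ids")
        if c.columns.has_duplicates:
            raise TableError("duplicate feature ids")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise TableError("counts must be numeric")
        if np.any(arr < 0):
            raise TableError("negative counts")
        if not np.allclose(arr, np.round(arr)):
            raise TableError("counts must be integers")
        self.counts = c.astype(np.int64)
        if self.taxonomy is not None:
            missing = set(self.taxonomy) - set(c.columns)
            if missing:
                raise TableError(f"taxonomy for unknown features: {sorted(missing)[:3]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(self.counts.loc[list(sample_ids)], self.taxonomy)

    def relative_abundance(self) -> pd.DataFrame:
        tot = self.counts.sum(axis=1)
        if (tot == 0).any():
            raise TableError("all-zero sample(s); cannot form relative abundances")
        return self.counts.div(tot, axis=0)


def lineage_string(ranks: tuple[str, ...]) -> str:
    """Render a 7-tuple of rank names back to the ``k__...; p__...`` dialect."""
    return "; ".join(p + r for p, r in zip(_RANK_PREFIXES, ranks))


def parse_lineage(lineage: str | None) -> dict[str, str]:
    """Parse a Greengenes-style lineage string into a 7-rank map.

    Missing, empty, or malformed segments become unclassified (empty string).
    Rank prefixes (``k__`` .. ``s__``) are optional; segments are assigned to
    ranks positionally when unprefixed.
    """
    out = {r: UNCLASSIFIED for r in RANKS}
    if not lineage or not lineage.strip():
        return out
    segments = [s.strip() for s in lineage.split(";")]
    prefix_to_rank = dict(zip(_RANK_PREFIXES, RANKS))
    for i, seg in enumerate(segments):
        if not seg:
            continue
        if len(seg) >= 3 and seg[:3] in prefix_to_rank:
            rank = prefix_to_rank[seg[:3]]
            name = seg[3:].strip()
        elif i < len(RANKS):
            rank, name = RANKS[i], seg
        else:
            continue
        out[rank] = name if name else UNCLASSIFIED
    return out


def _lineage_tuple(lineage: str | None) -> tuple[str, ...]:
    d = parse_lineage(lineage)
    return tuple(d[r] for r in RANKS)


def read_feature_table(path, format: str = "tsv") -> FeatureTable:
    """Read a feature table from TSV (features as rows, samples as columns,
    optional trailing ``taxonomy`` column) or BIOM-JSON."""
    if format == "tsv":
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(header) != len(set(header)):  # pandas mangles duplicates
            raise TableError("duplicate sample columns")
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False, comment=None)
        if df.index.has_duplicates:
            raise TableError("duplicate feature ids")
        taxonomy = None
        if len(df.columns) and df.columns[-1].lower() == "taxonomy":
            tax_col = df.iloc[:, -1]
            df = df.iloc[:, :-1]
            taxonomy = {fid: _lineage_tuple(s) for fid, s in tax_col.items()}
        num = df.replace(MISSING, "0").apply(pd.to_numeric)
        counts = num.T  # -> samples x features
        return FeatureTable(counts, taxonomy)
    if format == "biom-json":
        with open(path) as fh:
            biom = json.load(fh)
        if biom.get("matrix_type") not in ("dense", "sparse"):
            raise TableError("unsupported BIOM matrix_type")
        feats = [r["id"] for r in biom["rows"]]
        samples = [c["id"] for c in biom["columns"]]
        mat = np.zeros((len(feats), len(samples)))
        if biom["matrix_type"] == "dense":
            mat[:] = np.asarray(biom["data"], dtype=float)
        else:
            for i, j, v in biom["data"]:
                mat[int(i), int(j)] = v
        taxonomy = None
        if any((r.get("metadata") or {}).get("taxonomy") for r in biom["rows"]):
            taxonomy = {}
            for r in biom["rows"]:
                tx = (r.get("metadata") or {}).get("taxonomy")
                if isinstance(tx, list):
                    tx = "; ".join(tx)
                taxonomy[r["id"]] = _lineage_tuple(tx)
        counts = pd.DataFrame(mat.T, index=samples, columns=feats)
        return FeatureTable(counts, taxonomy)
    raise TableError(f"unknown format: {format!r}")


def write_feature_table(table: FeatureTable, path) -> None:
    """Write the TSV dialect read by :func:`read_feature_table` (UTF-8)."""
    df = table.counts.T.astype(str)  # features x samples
    if table.taxonomy is not None:
        df["taxonomy"] = [lineage_string(table.taxonomy.get(f, ("",) * 7))
                          for f in df.index]
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", na_rep=MISSING, encoding="utf-8")


def filter_low_depth(table: FeatureTable, min_reads: int) -> FeatureTable:
    """Drop samples whose total read count is below ``min_reads``.

    Mirrors the negative-control-based exclusion of low-biomass specimens
    (samples resembling blanks); the feature set is unchanged.
    """
    if min_reads < 0:
        raise TableError("min_reads must be >= 0")
    keep = table.sample_totals() >= min_reads
    if not keep.any():
        raise TableError(f"all samples fall below the {min_reads}-read threshold")
    return FeatureTable(table.counts.loc[keep], table.taxonomy)


# ---------------------------------------------------------------------------
# metadata / covariates
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Per-sample patient linkage and tissue type (tumor vs normal lung)."""

    table: pd.DataFrame  # index=sample_id; columns: patient_id, tissue_type[, batch]

    def __post_init__(self) -> None:
        t = self.table
        for col in ("patient_id", "tissue_type"):
            if col not in t.columns:
                raise TableError(f"metadata missing column {col!r}")
        bad = set(t["tissue_type"]) - {"tumor", "normal"}
        if bad:
            raise TableError(f"unknown tissue types: {sorted(bad)}")
        dup = t.groupby(["patient_id", "tissue_type"]).size()
        if (dup > 1).any():
            raise TableError("a patient has more than one sample of the same tissue")

    def samples_of(self, tissue: str) -> pd.DataFrame:
        return self.table[self.table["tissue_type"] == tissue]

    def pairs(self) -> list[tuple[str, str]]:
        """(tumor_sample, normal_sample) per patient having both tissues."""
        out = []
        for pid, grp in self.table.groupby("patient_id", sort=True):
            by_tissue = grp.reset_index().set_index("tissue_type")
            if {"tumor", "normal"} <= set(by_tissue.index):
                out.append((by_tissue.loc["tumor"].iloc[0],
                            by_tissue.loc["normal"].iloc[0]))
        return out


CATEGORICAL_LEVELS = {
    "sex": ("female", "male"),
    "race": ("non-white", "white"),
    "smoking": ("current", "former", "never"),
    "histology": ("adenocarcinoma", "squamous"),
    "chemotherapy": ("no", "yes"),
}


@dataclass
class CovariateSet:
    """Per-patient clinical covariates with a deterministic dummy coding.

    Reference level for each categorical is the lexicographically first
    level, so Cox coefficients are reproducible across runs.
    """

    table: pd.DataFrame  # index=patient_id

    def __post_init__(self) -> None:
        for col, levels in CATEGORICAL_LEVELS.items():
            if col in self.table.columns:
                bad = set(self.table[col].dropna()) - set(levels)
                if bad:
                    raise TableError(f"covariate {col!r} has unknown levels {sorted(bad)}")

    def design_matrix(self, columns: list[str] | None = None) -> pd.DataFrame:
        """Dummy-coded design (reference = lexicographically first level)."""
        cols = columns if columns is not None else list(self.table.columns)
        parts = []
        for col in cols:
            s = self.table[col]
            if pd.api.types.is_numeric_dtype(s):
                parts.append(s.astype(float).to_frame(col))
            else:
                levels = sorted(s.dropna().unique())
                for lev in levels[1:]:
                    parts.append((s == lev).astype(float).to_frame(f"{col}_{lev}"))
        if not parts:
            return pd.DataFrame(index=self.table.index)
        return pd.concat(parts, axis=1)


# ---------------------------------------------------------------------------
# survival records and endpoints
# ---------------------------------------------------------------------------

MONTHS_PER_YEAR = 12.0


@dataclass
class SurvivalRecord:
    """Event-history times in months from surgery; None = did not occur /
    unknown."""

    patient_id: str
    recurrence_time: float | None = None
    new_primary_time: float | None = None
    death_time: float | None = None
    last_followup_time: float | None = None
    died: bool = False
    death_imputed: bool = False

    def __post_init__(self) -> None:
        for name in ("recurrence_time", "new_primary_time", "death_time",
                     "last_followup_time"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise TableError(f"{name} < 0 for patient {self.patient_id}")
        if self.last_followup_time is None:
            raise TableError(f"last_followup_time required (patient {self.patient_id})")


@dataclass(frozen=True)
class Endpoint:
    patient_id: str
    endpoint: str  # RFS | DFS | OS
    time: float    # months
    event: int     # 1 = event, 0 = censored


def impute_missing_death(record: SurvivalRecord) -> SurvivalRecord:
    """For a patient known to have died with no death date, assign the
    recurrence date as the date of death and flag the record so sensitivity
    analyses can exclude it."""
    if not record.died or record.death_time is not None:
        return record
    if record.recurrence_time is None:
        raise TableError(
            f"patient {record.patient_id}: died with neither death nor recurrence time")
    return replace(record, death_time=record.recurrence_time, death_imputed=True)


_EVENT_FIELDS = {
    "RFS": ("recurrence_time", "death_time"),
    "DFS": ("recurrence_time", "new_primary_time", "death_time"),
    "OS": ("death_time",),
}


def derive_endpoint(record: SurvivalRecord, endpoint: str) -> Endpoint:
    """Derive the (time, event) pair for RFS, DFS, or OS.

    Time is the minimum over qualifying event times if any occurred, else the
    censoring time at last follow-up.  A tie between event and censoring time
    counts as an event.
    """
    if endpoint not in _EVENT_FIELDS:
        raise TableError(f"unknown endpoint {endpoint!r}")
    if record.died and record.death_time is None:
        record = impute_missing_death(record)
    times = [getattr(record, f) for f in _EVENT_FIELDS[endpoint]]
    times = [t for t in times if t is not None]
    if times:
        return Endpoint(record.patient_id, endpoint, float(min(times)), 1)
    if record.last_followup_time is None:
        raise TableError(f"patient {record.patient_id}: no usable time")
    return Endpoint(record.patient_id, endpoint, float(record.last_followup_time), 0)


def endpoint_frame(records: list[SurvivalRecord], endpoint: str) -> pd.DataFrame:
    """DataFrame of (time, event) per patient for one endpoint."""
    eps = [derive_endpoint(r, endpoint) for r in records]
    return pd.DataFrame({"time": [e.time for e in eps],
                         "event": [e.event for e in eps]},
                        index=pd.Index([e.patient_id for e in eps], name="patient_id"))


def read_survival_records(path) -> list[SurvivalRecord]:
    """TSV with columns patient_id, recurrence_time, new_primary_time,
    death_time, last_followup_time, died; ``NA`` for missing."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)

    def _num(v):
        return None if v in (MISSING, "") else float(v)

    return [SurvivalRecord(
        patient_id=row["patient_id"],
        recurrence_time=_num(row.get("recurrence_time", MISSING)),
        new_primary_time=_num(row.get("new_primary_time", MISSING)),
        death_time=_num(row.get("death_time", MISSING)),
        last_followup_time=_num(row.get("last_followup_time", MISSING)),
        died=row.get("died", "0") in ("1", "true", "True"),
    ) for _, row in df.iterrows()]


def write_survival_records(records: list[SurvivalRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id,
            "recurrence_time": r.recurrence_time,
            "new_primary_time": r.new_primary_time,
            "death_time": r.death_time,
            "last_followup_time": r.last_followup_time,
            "died": int(r.died),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=MISSING,
                              encoding="utf-8")


# ---------------------------------------------------------------------------
# covariate screening
# ---------------------------------------------------------------------------


def screen_covariates(covariates: CovariateSet,
                      records: list[SurvivalRecord],
                      p_threshold: float = 0.10) -> list[str]:
    """Retain covariates associated with RFS, DFS, or OS at p < threshold in
    unadjusted or full multivariable Cox models (union over the three
    endpoints; for a multi-level categorical, the smallest dummy Wald p).

    A covariate whose Cox fit fails to converge is retained with a warning,
    the conservative choice for a screening step.
    """
    from lifelines import CoxPHFitter

    cols = list(covariates.table.columns)
    if not cols:
        raise TableError("no covariates to screen")
    full_design = covariates.design_matrix()
    keep: set[str] = set()
    for ep in ENDPOINTS:
        surv = endpoint_frame(records, ep)
        if surv["event"].nunique() < 2:
            raise TableError(f"endpoint {ep}: needs both events and censorings")
        for col in cols:
            design = covariates.design_matrix([col])
            dummy_cols = list(design.columns)
            for dsn in (design, full_design):
                df = dsn.join(surv, how="inner")
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fit = CoxPHFitter().fit(df, "time", "event")
                    pmin = fit.summary.loc[
                        fit.summary.index.intersection(dummy_cols), "p"].min()
                    if np.isfinite(pmin) and pmin < p_threshold:
                        keep.add(col)
                except Exception:
                    warnings.warn(
                        f"Cox screen did not converge for {col!r} ({ep}); retained")
                    keep.add(col)
    return [c for c in cols if c in keep]
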