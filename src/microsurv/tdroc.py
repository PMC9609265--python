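"""Time-dependent AUC risk prediction for nested Cox models.

The question: do the microbiome and/or gene-expression biomarkers improve
discrimination of recurrence/death risk beyond the standard clinical
covariates?  Four canonical nested models are compared:

1. covariates only,
2. covariates + clr-transformed microbiome features,
3. covariates + log2 gene expression,
4. covariates + both blocks.

Each model's risk score is the linear predictor of a Cox fit on the full
analysis set (apparent AUC; no optimism correction).  Discrimination at
horizon t uses the cumulative/dynamic time-dependent AUC with inverse
probability of censoring weights (IPCW) from the Kaplan-Meier estimate of
the censoring distribution: cases are subjects with an observed event by t,
controls are subjects still event-free past t; tied scores count one half.

Uncertainty: percentile bootstrap over patients (models refit per
resample).  Added discrimination is tested by permutation: the tested
biomarker block's rows are shuffled across patients while outcomes and
covariates stay linked, the augmented model is refit, and the observed
AUC difference is compared with the permutation null (add-one p, plus the
95th-percentile decision rule).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._coxfast import fit_cox
from .tables_io import TableError

DEFAULT_T_GRID = (12.0, 24.0, 36.0, 48.0, 60.0)  # months; annual from year 1


@dataclass
class ModelSpec:
    """A nested risk model: covariates always included, plus optional
    microbiome (clr) and gene (log2) blocks."""

    name: str
    use_microbiome: bool = False
    use_genes: bool = False


CANONICAL_MODELS = (
    ModelSpec("covariates"),
    ModelSpec("covariates+microbiome", use_microbiome=True),
    ModelSpec("covariates+genes", use_genes=True),
    ModelSpec("covariates+microbiome+genes", use_microbiome=True, use_genes=True),
)


@dataclass
class RiskData:
    """Complete-case analysis set: outcome plus the three predictor blocks,
    row-aligned on patient."""

    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray
    microbiome: np.ndarray
    genes: np.ndarray
    patient_ids: list[str] = field(default_factory=list)

    @classmethod
    def from_frames(cls, endpoints: pd.DataFrame, covariates: pd.DataFrame,
                    microbiome: pd.DataFrame | None = None,
                    genes: pd.DataFrame | None = None) -> "RiskData":
        idx = endpoints.index.intersection(covariates.index)
        for block in (microbiome, genes):
            if block is not None:
                idx = idx.intersection(block.index)
        idx = idx.sort_values()

        def _block(df):
            if df is None:
                return np.zeros((len(idx), 0))
            return df.loc[idx].to_numpy(dtype=float)

        return cls(endpoints.loc[idx, "time"].to_numpy(dtype=float),
                   endpoints.loc[idx, "event"].to_numpy(dtype=int),
                   _block(covariates), _block(microbiome), _block(genes),
                   list(idx))

    def design(self, model: ModelSpec) -> np.ndarray:
        blocks = [self.covariates]
        if model.use_microbiome:
            blocks.append(self.microbiome)
        if model.use_genes:
            blocks.append(self.genes)
        return np.hstack(blocks)

    def subset(self, rows: np.ndarray) -> "RiskData":
        return RiskData(self.time[rows], self.event[rows],
                        self.covariates[rows], self.microbiome[rows],
                        self.genes[rows],
                        [self.patient_ids[i] for i in rows])


def cox_risk_score(model: ModelSpec, data: RiskData) -> np.ndarray:
    """Per-patient risk score X @ beta-hat from the all-data Cox fit
    (higher = higher risk)."""
    x = data.design(model)
    x_c = x - x.mean(axis=0)
    beta, _, _, converged = fit_cox(data.time, data.event, x_c)
    if not converged:
        raise TableError(f"Cox model {model.name!r} did not converge")
    return x_c @ beta


def censoring_km(times: np.ndarray, events: np.ndarray):
    """Kaplan-Meier estimate of the censoring survival function G(t)
    (censorings are the 'events'); returns a right-continuous step function."""
    order = np.argsort(times, kind="stable")
    t_s = times[order]
    c_s = 1 - events[order]
    uniq = np.unique(t_s)
    n = len(t_s)
    surv = []
    g = 1.0
    at_risk = n
    for u in uniq:
        mask = t_s == u
        d_c = int(c_s[mask].sum())
        if at_risk > 0 and d_c:
            g *= 1.0 - d_c / at_risk
        surv.append(g)
        at_risk -= int(mask.sum())
    uniq_arr, surv_arr = uniq, np.array(surv)

    def G(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(uniq_arr, t, side="right") - 1
        out = np.where(idx >= 0, surv_arr[np.clip(idx, 0, None)], 1.0)
        return out

    def G_minus(t):
        # left limit G(t-): survival just before t
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(uniq_arr, t, side="left") - 1
        out = np.where(idx >= 0, surv_arr[np.clip(idx, 0, None)], 1.0)
        return out

    return G, G_minus


def td_auc(times, events, scores, t: float) -> float:
    """Cumulative/dynamic IPCW AUC at horizon t.

    Cases: observed event time <= t with event=1, weighted 1/G(T_i-);
    controls: observed time > t, weighted 1/G(t); G = censoring KM.
    Ties in scores contribute one half.  Returns NaN (flagged by warning)
    when there is no case or no control at t.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    scores = np.asarray(scores, dtype=float)
    case = (times <= t) & (events == 1)
    ctrl = times > t
    if not case.any() or not ctrl.any():
        warnings.warn(f"AUC undefined at t={t}: no case or no control")
        return np.nan
    G, G_minus = censoring_km(times, events)
    w_case = 1.0 / G_minus(times[case])
    w_ctrl = np.full(int(ctrl.sum()), 1.0 / float(G(t)[0]))
    sc = scores[case][:, None]
    st = scores[ctrl][None, :]
    conc = (sc > st) + 0.5 * (sc == st)
    w = w_case[:, None] * w_ctrl[None, :]
    return float((w * conc).sum() / w.sum())


@dataclass
class TdAucResult:
    t_grid: tuple
    auc: pd.DataFrame                 # models x times
    ci_lower: pd.DataFrame | None = None
    ci_upper: pd.DataFrame | None = None
    n_bootstrap: int = 0
    delta_auc: pd.DataFrame | None = None   # comparisons x times
    perm_p: pd.DataFrame | None = None
    perm_reject: pd.DataFrame | None = None  # 95th-percentile decision
    n_permutations: int = 0


def apparent_auc(data: RiskData, models=CANONICAL_MODELS,
                 t_grid=DEFAULT_T_GRID) -> pd.DataFrame:
    """In-sample AUC(t) for each model, fit on the full analysis set."""
    rows = {}
    for m in models:
        s = cox_risk_score(m, data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows[m.name] = [td_auc(data.time, data.event, s, t) for t in t_grid]
    return pd.DataFrame(rows, index=list(t_grid)).T


def bootstrap_auc_ci(data: RiskData, model: ModelSpec, t_grid=DEFAULT_T_GRID,
                     n_boot: int = 1000, seed: int | None = None,
                     refit: bool = True):
    """Percentile bootstrap 95% CI of AUC(t), resampling patients with
    replacement and (by default) refitting the model per resample.
    Degenerate resamples (no events, or a non-converging fit) are skipped."""
    if n_boot < 1:
        raise TableError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(data.time)
    fixed_beta = None
    if not refit:
        x_c = data.design(model) - data.design(model).mean(axis=0)
        fixed_beta, _, _, _ = fit_cox(data.time, data.event, x_c)
    aucs = []
    for _ in range(n_boot):
        rows = rng.integers(0, n, size=n)
        sub = data.subset(rows)
        if sub.event.sum() < 2:
            continue
        try:
            if refit:
                s = cox_risk_score(model, sub)
            else:
                xb = sub.design(model) - sub.design(model).mean(axis=0)
                s = xb @ fixed_beta
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                aucs.append([td_auc(sub.time, sub.event, s, t) for t in t_grid])
        except TableError:
            continue
    if not aucs:
        raise TableError("all bootstrap resamples degenerate")
    arr = np.array(aucs, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lo = np.nanpercentile(arr, 2.5, axis=0)
        hi = np.nanpercentile(arr, 97.5, axis=0)
    return lo, hi, arr.shape[0]


def auc_permutation_test(data: RiskData, base: ModelSpec, tested: ModelSpec,
                         t_grid=DEFAULT_T_GRID, n_perm: int = 5000,
                         seed: int | None = None):
    """Permutation test of added discrimination of ``tested`` over ``base``.

    The biomarker blocks present in ``tested`` but not in ``base`` are
    shuffled as whole rows across patients (microbiome and gene blocks
    independently when both are tested), breaking their link to outcome
    while the covariates-outcome link stays intact; both the observed and
    each permuted augmented model are refit.  Returns per-time observed
    delta AUC, add-one p-values, and the 95th-percentile decision.
    """
    perm_micro = tested.use_microbiome and not base.use_microbiome
    perm_genes = tested.use_genes and not base.use_genes
    if not (perm_micro or perm_genes):
        raise TableError("tested model adds no block over the base model")
    if n_perm < 19:
        warnings.warn("n_perm < 19: the 5% decision rule is unattainable")
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base_scores = cox_risk_score(base, data)
        auc_base = np.array([td_auc(data.time, data.event, base_scores, t)
                             for t in t_grid])
        tested_scores = cox_risk_score(tested, data)
        auc_tested = np.array([td_auc(data.time, data.event, tested_scores, t)
                               for t in t_grid])
    delta_obs = auc_tested - auc_base
    n = len(data.time)
    null = np.empty((n_perm, len(t_grid)))
    for k in range(n_perm):
        shuffled = RiskData(
            data.time, data.event, data.covariates,
            data.microbiome[rng.permutation(n)] if perm_micro else data.microbiome,
            data.genes[rng.permutation(n)] if perm_genes else data.genes,
            data.patient_ids)
        try:
            s = cox_risk_score(tested, shuffled)
        except TableError:
            null[k] = np.nan
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null[k] = [td_auc(data.time, data.event, s, t) for t in t_grid] \
                - auc_base
    valid = ~np.isnan(null).any(axis=1)
    nulls = null[valid]
    m = nulls.shape[0]
    p = (1 + (nulls >= delta_obs[None, :]).sum(axis=0)) / (1 + m)
    q95 = np.nanpercentile(nulls, 95, axis=0)
    reject = delta_obs > q95
    return delta_obs, p, reject, m


def run_td_auc(data: RiskData, t_grid=DEFAULT_T_GRID, n_boot: int = 1000,
               n_perm: int = 5000, seed: int | None = None,
               models=CANONICAL_MODELS) -> TdAucResult:
    """AUC(t) for the nested models with bootstrap CIs and permutation tests
    of each biomarker model against the covariates-only base."""
    rng = np.random.default_rng(seed)
    auc = apparent_auc(data, models, t_grid)
    lo_rows, hi_rows = {}, {}
    n_eff = 0
    for m in models:
        lo, hi, n_eff = bootstrap_auc_ci(
            data, m, t_grid, n_boot, seed=int(rng.integers(2 ** 31)))
        lo_rows[m.name], hi_rows[m.name] = lo, hi
    base = models[0]
    d_rows, p_rows, r_rows = {}, {}, {}
    m_eff = 0
    for m in models[1:]:
        d, p, rej, m_eff = auc_permutation_test(
            data, base, m, t_grid, n_perm, seed=int(rng.integers(2 ** 31)))
        key = f"{m.name} vs {base.name}"
        d_rows[key], p_rows[key], r_rows[key] = d, p, rej
    idx = list(t_grid)
    return TdAucResult(
        tuple(t_grid), auc,
        pd.DataFrame(lo_rows, index=idx).T, pd.DataFrame(hi_rows, index=idx).T,
        n_eff,
        pd.DataFrame(d_rows, index=idx).T, pd.DataFrame(p_rows, index=idx).T,
        pd.DataFrame(r_rows, index=idx).T, m_eff)
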