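"""Survival biomarker screening and stability selection.

Two complementary views of each candidate feature (clr-transformed taxon,
functional pathway, or log2 gene):

* a covariate-adjusted Cox proportional-hazards fit (hazard ratio, 95% CI,
  Wald p, with BH q computed within each feature family), and
* stability selection: R repetitions of K-fold cross-validated elastic-net
  penalized Cox regression in which the clinical covariates are never
  penalized; the per-repetition penalty is chosen at the minimum
  cross-validated partial-likelihood deviance, the model is refit on all
  data at that penalty, and the feature's selection count is the number of
  repetitions in which its coefficient is nonzero.

A feature is called survival-related when it is selected in at least
``min_fraction`` of repetitions (default 25%) AND its adjusted q-value is
below ``q_threshold`` (default 0.20).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._coxfast import cox_partial_loglik_multi
from .community import bh_fdr
from .tables_io import TableError


@dataclass
class CoxFit:
    feature: str
    coef: float
    hr: float
    ci_lower: float
    ci_upper: float
    p: float
    converged: bool
    cluster_robust: bool = False


def fit_cox_adjusted(endpoints: pd.DataFrame, feature_values: pd.Series,
                     covariate_design: pd.DataFrame,
                     cluster_ids: pd.Series | None = None) -> CoxFit:
    """Cox PH fit of one feature adjusted for clinical covariates.

    ``endpoints`` has columns time/event indexed like ``feature_values``.
    Efron tie handling (lifelines); with ``cluster_ids``, the variance is the
    cluster-robust sandwich estimator, appropriate when multiple samples per
    patient enter the model.  Non-convergence yields a flagged fit with an
    infinite CI rather than an exception, so screening loops keep going.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    name = feature_values.name or "feature"
    df = pd.concat([feature_values.rename(name), covariate_design,
                    endpoints[["time", "event"]]], axis=1, join="inner")
    # guard against rank deficiency: drop constant covariate columns
    for col in list(covariate_design.columns):
        if df[col].nunique() <= 1:
            warnings.warn(f"covariate {col!r} constant; dropped from adjustment")
            df = df.drop(columns=col)
    kwargs = {}
    if cluster_ids is not None:
        df = df.assign(_cluster=cluster_ids.reindex(df.index))
        kwargs["cluster_col"] = "_cluster"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = CoxPHFitter().fit(df, "time", "event", **kwargs)
        row = fit.summary.loc[name]
        return CoxFit(name, float(row["coef"]), float(np.exp(row["coef"])),
                      float(np.exp(row["coef lower 95%"])),
                      float(np.exp(row["coef upper 95%"])),
                      float(row["p"]), True, cluster_ids is not None)
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return CoxFit(name, np.nan, np.nan, 0.0, np.inf, 1.0, False,
                      cluster_ids is not None)


@dataclass
class StabilityResult:
    """Selection counts out of R repetitions plus the adjusted per-feature
    Cox fits for one endpoint x feature family."""

    counts: pd.Series          # per feature, 0..R
    R: int
    K: int
    alpha: float               # elastic-net mixing (1 = lasso, 0 = ridge)
    cox: pd.DataFrame = field(default_factory=pd.DataFrame)  # HR/CI/p/q per feature

    def frame(self) -> pd.DataFrame:
        out = self.cox.copy()
        out.insert(0, "selection_count", self.counts)
        out.insert(1, "R", self.R)
        out["selected_fraction"] = self.counts / self.R
        return out


def _event_stratified_folds(events: np.ndarray, k: int,
                            rng: np.random.Generator,
                            max_retries: int = 20) -> np.ndarray:
    """Fold assignment with events spread across folds; redraws (bounded)
    until every fold's training part contains at least one event."""
    n = events.size
    for _ in range(max_retries):
        folds = np.empty(n, dtype=int)
        for val in (0, 1):
            idx = rng.permutation(np.flatnonzero(events == val))
            folds[idx] = np.arange(idx.size) % k
        train_ok = all((events[folds != f] == 1).sum() >= 2 for f in range(k))
        if train_ok:
            return folds
    raise TableError("could not build folds with events in every training set")


def stability_select(endpoints: pd.DataFrame, feature_matrix: pd.DataFrame,
                     covariate_design: pd.DataFrame, R: int = 500, K: int = 10,
                     alpha: float = 0.5, seed: int | None = None,
                     n_lambdas: int = 50,
                     lambda_rule: str = "min") -> StabilityResult:
    """Repeated cross-validated elastic-net Cox stability selection.

    Features (clr taxa / pathways or log2 genes) are standardized internally
    for penalty fairness; clinical covariates enter every model with zero
    penalty.  Per repetition, K event-stratified folds choose the penalty
    minimizing CV partial-likelihood deviance along a shared lambda path
    (``lambda_rule='1se'`` instead takes the sparsest penalty within one
    standard error of the minimum); the model is refit on all data at that
    penalty and nonzero feature coefficients count as selections.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    if R < 1:
        raise TableError("R must be >= 1")
    n = len(feature_matrix)
    if not 2 <= K <= n:
        raise TableError("K must lie in [2, n]")
    if lambda_rule not in ("min", "1se"):
        raise TableError("lambda_rule must be 'min' or '1se'")
    # canonical row order: results are invariant to input sample ordering
    common = feature_matrix.index.sort_values()
    feature_matrix = feature_matrix.loc[common]
    surv_df = endpoints.loc[common]
    times = surv_df["time"].to_numpy(dtype=float)
    events = surv_df["event"].to_numpy(dtype=int)
    feats = feature_matrix.to_numpy(dtype=float)
    covs = covariate_design.loc[common].to_numpy(dtype=float) \
        if len(covariate_design.columns) else np.zeros((n, 0))
    mu, sd = feats.mean(axis=0), feats.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    feats_z = (feats - mu) / sd
    x = np.hstack([feats_z, covs])
    p_feat = feats.shape[1]
    penalty_factor = np.concatenate([np.ones(p_feat), np.zeros(covs.shape[1])])
    y = Surv.from_arrays(event=events.astype(bool), time=times)

    def _fit_path(xm, ym, alphas=None):
        model = CoxnetSurvivalAnalysis(
            l1_ratio=alpha, penalty_factor=penalty_factor,
            alphas=alphas, n_alphas=n_lambdas, alpha_min_ratio=0.01,
            normalize=False, fit_baseline_model=False, max_iter=100000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(xm, ym)
        return model

    # a single lambda path, computed on the full data, shared by all folds
    base = _fit_path(x, y)
    lambda_path = np.asarray(base.alphas_)

    rng = np.random.default_rng(seed)
    counts = pd.Series(0, index=feature_matrix.columns, dtype=int)
    for _ in range(R):
        folds = _event_stratified_folds(events, K, rng)
        dev = np.full((K, lambda_path.size), np.nan)
        for f in range(K):
            tr = folds != f
            model = _fit_path(x[tr], y[tr], alphas=lambda_path)
            coefs = model.coef_  # (p, n_fit_lambdas)
            fitted = np.asarray(model.alphas_)
            # CV deviance via Verweij-van Houwelingen: full-data minus
            # training partial log-likelihood at the training coefficients
            ll_all = cox_partial_loglik_multi(times, events, x @ coefs)
            ll_tr = cox_partial_loglik_multi(times[tr], events[tr],
                                             x[tr] @ coefs)
            dev_f = -2.0 * (ll_all - ll_tr)
            pos = np.searchsorted(-lambda_path, -fitted)
            ok = (pos < lambda_path.size) & np.isclose(
                lambda_path[np.clip(pos, 0, lambda_path.size - 1)], fitted,
                rtol=1e-8)
            dev[f, pos[ok]] = dev_f[ok]
        mean_dev = np.nanmean(dev, axis=0)
        if np.all(np.isnan(mean_dev)):
            continue
        best = int(np.nanargmin(mean_dev))
        if lambda_rule == "1se":
            se = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(K)
            within = np.flatnonzero(mean_dev <= mean_dev[best] + se[best])
            best = int(within.min())  # path is ordered large->small lambda
        refit = _fit_path(x, y, alphas=np.array([lambda_path[best]]))
        nz = np.abs(refit.coef_[:p_feat, 0]) > 0
        counts[nz] += 1
    return StabilityResult(counts, R, K, alpha)


def attach_adjusted_cox(stab: StabilityResult, endpoints: pd.DataFrame,
                        feature_matrix: pd.DataFrame,
                        covariate_design: pd.DataFrame,
                        cluster_ids: pd.Series | None = None) -> StabilityResult:
    """Fit the per-feature adjusted Cox models and BH-adjust their p-values
    within this feature family, storing HR/CI/p/q alongside the counts."""
    rows = []
    for feat in feature_matrix.columns:
        fit = fit_cox_adjusted(endpoints, feature_matrix[feat],
                               covariate_design, cluster_ids)
        rows.append({"feature": feat, "coef": fit.coef, "HR": fit.hr,
                     "ci_lower": fit.ci_lower, "ci_upper": fit.ci_upper,
                     "p": fit.p, "converged": fit.converged})
    cox = pd.DataFrame(rows).set_index("feature")
    cox["q"] = bh_fdr(cox["p"].fillna(1.0).to_numpy())
    stab.cox = cox
    return stab


def select_features(stab: StabilityResult, min_fraction: float = 0.25,
                    q_threshold: float = 0.20) -> list[str]:
    """Features selected in >= min_fraction of repetitions with q below the
    threshold (the 125-of-500, q<0.20 rule at the defaults)."""
    frac = stab.counts / stab.R
    ok = frac >= min_fraction
    if "q" in stab.cox.columns:
        ok &= stab.cox["q"].reindex(stab.counts.index) < q_threshold
    return list(stab.counts.index[ok])


def partial_spearman(x, y, covariate_design: pd.DataFrame | None = None
                     ) -> tuple[float, float]:
    """Spearman correlation of x and y after removing covariate effects.

    Both variables are rank-transformed, each is residualized on the
    covariate design (with intercept), and the Pearson correlation of the
    residuals is returned with a t-approximation p-value on
    n - 2 - #covariates degrees of freedom.  With no covariates this reduces
    to the ordinary Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise TableError("constant input to partial_spearman")
    n = x.size
    k = 0 if covariate_design is None else covariate_design.shape[1]
    if n <= k + 2:
        raise TableError("too few observations for the covariate set")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if k:
        z = np.column_stack([np.ones(n), covariate_design.to_numpy(dtype=float)])
        rx = rx - z @ np.linalg.lstsq(z, rx, rcond=None)[0]
        ry = ry - z @ np.linalg.lstsq(z, ry, rcond=None)[0]
    else:
        rx = rx - rx.mean()
        ry = ry - ry.mean()
    rho = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    df = n - 2 - k
    rho_c = min(max(rho, -0.9999999999), 0.9999999999)
    t = rho_c * np.sqrt(df / (1 - rho_c ** 2))
    p = float(2 * stats.t.sf(abs(t), df))
    return rho, p


def log2_gene_matrix(expr: pd.DataFrame, pseudocount: float = 0.0) -> pd.DataFrame:
    """Elementwise log2 of a normalized expression matrix."""
    arr = expr.to_numpy(dtype=float) + pseudocount
    if np.any(arr <= 0):
        raise TableError("non-positive expression values; supply a pseudocount")
    return pd.DataFrame(np.log2(arr), index=expr.index, columns=expr.columns)
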