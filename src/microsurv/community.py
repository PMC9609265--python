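"""Community-level comparisons of paired tumor and normal lung samples.

Three complementary questions:

* Does overall composition differ between groups?  One-factor PERMANOVA on a
  distance matrix, with optional strata (e.g. patient id) restricting
  permutations to within-block label exchanges — the right null when the
  samples are tumor/normal pairs from the same patients.
* Are paired samples from the same patient more alike than random pairings?
  The observed mean within-pair distance is compared with the means of
  random tumor-to-normal bijections; the decision rule flags pairs as "more
  alike" when the observed mean falls below the 5th percentile of the
  permuted means.
* Which individual taxa differ?  Wilcoxon signed-rank tests on paired clr
  differences, with Benjamini-Hochberg FDR applied within each taxonomic
  rank separately.

All permutation p-values use the add-one estimator
p = (1 + #{null at least as extreme}) / (1 + n_perm), which can never be
exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .composition import ClrMatrix, DistanceMatrix
from .tables_io import TableError


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    strata: bool


@dataclass
class PairedDistanceTestResult:
    observed_mean: float
    permuted_means: np.ndarray
    percentile: float      # percentile of observed within the permuted means
    p_value: float
    more_alike: bool       # observed below the 5th percentile of the null


def _group_ss(d2: np.ndarray, labels: np.ndarray) -> float:
    """Within-group sum of squared distances, Sum_g Sum_{i<j in g} d2/n_g."""
    ss = 0.0
    for lev in np.unique(labels):
        idx = np.flatnonzero(labels == lev)
        if idx.size < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss += sub.sum() / (2.0 * idx.size)
    return ss


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    n = d2.shape[0]
    a = np.unique(labels).size
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _group_ss(d2, labels)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(dmat: DistanceMatrix, labels, strata=None, n_perm: int = 999,
              seed: int | None = None) -> PermanovaResult:
    """One-factor PERMANOVA (pseudo-F on a distance matrix).

    With ``strata``, permutations shuffle labels only within each stratum —
    e.g. patient id as strata exchanges tumor/normal labels within patients.
    """
    if n_perm <= 0:
        raise TableError("n_perm must be positive")
    lab = np.asarray(pd.Series(labels).reindex(dmat.ids)
                     if isinstance(labels, (pd.Series, dict)) else labels)
    if lab.shape[0] != len(dmat.ids):
        raise TableError("labels do not align with the distance matrix")
    levels, lab_codes = np.unique(lab, return_inverse=True)
    if levels.size < 2:
        raise TableError("PERMANOVA needs at least two label levels")
    d2 = dmat.values.to_numpy() ** 2
    n = d2.shape[0]
    a = levels.size
    f_obs = _pseudo_f(d2, lab_codes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = _group_ss(d2, lab_codes)
    r2 = (ss_total - ss_within) / ss_total

    strat = None
    if strata is not None:
        strat = np.asarray(pd.Series(strata).reindex(dmat.ids)
                           if isinstance(strata, (pd.Series, dict)) else strata)
        sizes = pd.Series(strat).value_counts()
        if (sizes < 2).any():
            warnings.warn("stratum with a single sample: its label cannot permute")

    rng = np.random.default_rng(seed)
    hits = 0
    perm = lab_codes.copy()
    for _ in range(n_perm):
        if strat is None:
            perm = rng.permutation(lab_codes)
        else:
            perm = lab_codes.copy()
            for lev in np.unique(strat):
                idx = np.flatnonzero(strat == lev)
                perm[idx] = lab_codes[idx][rng.permutation(idx.size)]
        if np.unique(perm).size == a and _pseudo_f(d2, perm) >= f_obs:
            hits += 1
        elif np.unique(perm).size < a:
            # degenerate permutation (all one level) counts as non-extreme
            pass
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm,
                           strata is not None)


def paired_distance_test(dmat: DistanceMatrix, pairs: list[tuple[str, str]],
                         n_perm: int = 5000,
                         seed: int | None = None) -> PairedDistanceTestResult:
    """Are true tumor-normal pairs closer than random tumor-normal pairings?

    The null resamples bijections between the tumor members and the normal
    members of the pairs; p is the add-one left-tail probability that a
    random pairing is at least as close as the observed one.
    """
    if len(pairs) < 3:
        raise TableError("need at least 3 pairs for a meaningful null")
    flat = [s for pr in pairs for s in pr]
    if len(set(flat)) != len(flat):
        raise TableError("pairs must be disjoint")
    ids = {s: i for i, s in enumerate(dmat.ids)}
    try:
        ti = np.array([ids[a] for a, _ in pairs])
        ni = np.array([ids[b] for _, b in pairs])
    except KeyError as e:
        raise TableError(f"pair member {e} not in distance matrix") from None
    d = dmat.values.to_numpy()
    observed = float(d[ti, ni].mean())
    rng = np.random.default_rng(seed)
    perm_means = np.empty(n_perm)
    for k in range(n_perm):
        perm_means[k] = d[ti, ni[rng.permutation(ni.size)]].mean()
    p = (1 + int((perm_means <= observed).sum())) / (1 + n_perm)
    percentile = float(stats.percentileofscore(perm_means, observed, kind="mean"))
    more_alike = observed < np.percentile(perm_means, 5)
    return PairedDistanceTestResult(observed, perm_means, percentile, float(p),
                                    bool(more_alike))


def paired_feature_tests(clr_tumor: ClrMatrix, clr_normal: ClrMatrix,
                         pairs: list[tuple[str, str]],
                         rank: str | None = None) -> pd.DataFrame:
    """Per-feature Wilcoxon signed-rank tests on paired clr differences.

    Exact null distribution for n <= 25 non-zero pairs (no ties), normal
    approximation with continuity correction otherwise; zero differences are
    dropped (Wilcoxon convention).  Returns a tidy frame with BH q-values
    computed within this rank's family.
    """
    tv, nv = clr_tumor.values, clr_normal.values
    if list(tv.columns) != list(nv.columns):
        raise TableError("tumor and normal clr matrices must share features")
    ti = [a for a, _ in pairs]
    ni = [b for _, b in pairs]
    diffs = tv.loc[ti].to_numpy() - nv.loc[ni].to_numpy()
    rows = []
    for j, feat in enumerate(tv.columns):
        dcol = diffs[:, j]
        nz = dcol[dcol != 0]
        if nz.size == 0:
            warnings.warn(f"feature {feat!r}: zero-variance paired differences")
            rows.append((feat, 0.0, 1.0, 0.0))
            continue
        exact = nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(nz, zero_method="wilcox", correction=not exact,
                                 method="exact" if exact else "approx")
        rows.append((feat, float(res.statistic), float(res.pvalue),
                     float(np.sign(np.median(nz)))))
    out = pd.DataFrame(rows, columns=["feature", "statistic", "p", "direction"])
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["rank"] = rank
    return out.set_index("feature")


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_(i) = min_{j>=i} p_(j) m / j,
    clipped at 1, returned in the original order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise TableError("p must be a 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise TableError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
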