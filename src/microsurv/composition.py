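"""Compositional transforms, taxonomic agglomeration, and diversity.

Sequencing counts are compositional: only relative information is
interpretable.  The centered log-ratio (clr) transform maps a composition
x to ln(x_j) - mean_k ln(x_k), placing it in a Euclidean space where
ordinary linear models apply; a pseudocount handles sampling zeros.
Alpha diversity (richness and base-2 Shannon index) is computed by
averaging over repeated rarefaction so unequal sequencing depths do not
bias comparisons.  Beta diversity uses the Jensen-Shannon divergence
(base 2, bounded by 1); ordination is classical principal-coordinate
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .tables_io import RANKS, UNCLASSIFIED, FeatureTable, TableError, lineage_string


# ---------------------------------------------------------------------------
# agglomeration
# ---------------------------------------------------------------------------


def agglomerate(table: FeatureTable, rank: str,
                drop_unclassified: bool = False) -> FeatureTable:
    """Sum counts over features sharing the full lineage down to ``rank``.

    ``rank='asv'`` is the identity.  With ``drop_unclassified``, groups whose
    lineage is unclassified at ``rank`` are removed (total counts decrease),
    matching the exclusion of taxa lacking classification at the level
    under analysis.
    """
    if rank.lower() in ("asv", "feature"):
        return table
    if rank not in RANKS:
        raise TableError(f"unknown rank {rank!r}; expected one of {RANKS} or 'asv'")
    if table.taxonomy is None:
        raise TableError("agglomeration requires taxonomy")
    depth = RANKS.index(rank) + 1
    groups: dict[tuple[str, ...], list[str]] = {}
    for fid in table.feature_ids:
        key = tuple(table.taxonomy.get(fid, ("",) * 7))[:depth]
        groups.setdefault(key, []).append(fid)
    cols, names, tax = [], [], {}
    for key in sorted(groups):
        if drop_unclassified and key[-1] == UNCLASSIFIED:
            continue
        name = lineage_string(key + ("",) * (7 - depth)) or "unclassified"
        names.append(name)
        cols.append(table.counts[groups[key]].sum(axis=1))
        tax[name] = key + ("",) * (7 - depth)
    if not cols:
        raise TableError(f"no features classified at rank {rank!r}")
    counts = pd.concat(cols, axis=1)
    counts.columns = names
    return FeatureTable(counts, tax)


# ---------------------------------------------------------------------------
# clr
# ---------------------------------------------------------------------------


@dataclass
class ClrMatrix:
    """Centered log-ratio abundances; each row sums to zero."""

    values: pd.DataFrame  # samples x features
    pseudocount: float
    rank: str | None = None

    def __post_init__(self) -> None:
        rs = self.values.to_numpy().sum(axis=1)
        if self.values.shape[1] and np.max(np.abs(rs)) > 1e-9 * max(1, self.values.shape[1]):
            raise TableError("clr rows must sum to zero")


def clr_transform(table: FeatureTable | pd.DataFrame, pseudocount: float = 0.5,
                  rank: str | None = None) -> ClrMatrix:
    """clr_j = ln(x_j + c) - mean_k ln(x_k + c), per sample (row)."""
    counts = table.counts if isinstance(table, FeatureTable) else table
    if counts.shape[1] == 0:
        raise TableError("empty feature set")
    if pseudocount < 0 or (pseudocount == 0 and (counts.to_numpy() <= 0).any()):
        raise TableError("pseudocount must be > 0 when zeros are present")
    logx = np.log(counts.to_numpy(dtype=float) + pseudocount)
    vals = logx - logx.mean(axis=1, keepdims=True)
    return ClrMatrix(pd.DataFrame(vals, index=counts.index, columns=counts.columns),
                     pseudocount, rank)


# ---------------------------------------------------------------------------
# rarefied alpha diversity
# ---------------------------------------------------------------------------


@dataclass
class AlphaDiversity:
    table: pd.DataFrame  # index=sample, columns: richness, shannon
    depth: int
    iterations: int


def _shannon_bits(counts: np.ndarray) -> float:
    p = counts[counts > 0]
    p = p / p.sum()
    return float(-(p * np.log2(p)).sum())


def rarefied_alpha(table: FeatureTable, depth: int, iterations: int = 100,
                   seed: int | None = None) -> AlphaDiversity:
    """Richness and base-2 Shannon index averaged over repeated rarefaction.

    Each iteration subsamples every sample without replacement (multivariate
    hypergeometric) to ``depth`` reads.  Samples below ``depth`` are excluded
    with a warning, matching the usual handling of under-sequenced specimens.
    """
    if depth <= 0:
        raise TableError("rarefaction depth must be > 0")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    if not keep.all():
        import warnings
        warnings.warn(f"{(~keep).sum()} sample(s) below depth {depth} excluded")
    if not keep.any():
        raise TableError("no sample reaches the rarefaction depth")
    counts = table.counts.loc[keep].to_numpy()
    rich = np.zeros(counts.shape[0])
    shan = np.zeros(counts.shape[0])
    for i, row in enumerate(counts):
        if row.sum() == depth:  # rarefying to full depth is deterministic
            rich[i] = np.count_nonzero(row)
            shan[i] = _shannon_bits(row)
            continue
        r_acc = s_acc = 0.0
        for _ in range(iterations):
            sub = rng.multivariate_hypergeometric(row, depth)
            r_acc += np.count_nonzero(sub)
            s_acc += _shannon_bits(sub)
        rich[i] = r_acc / iterations
        shan[i] = s_acc / iterations
    df = pd.DataFrame({"richness": rich, "shannon": shan},
                      index=table.counts.index[keep])
    return AlphaDiversity(df, depth, iterations)


# ---------------------------------------------------------------------------
# Jensen-Shannon divergence
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    values: pd.DataFrame  # square, symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.shape[0] != v.shape[1]:
            raise TableError("distance matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise TableError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12) or np.any(v < -1e-12):
            raise TableError("distances must be non-negative with zero diagonal")

    @property
    def ids(self) -> list[str]:
        return list(self.values.index)

    def condensed(self) -> np.ndarray:
        from scipy.spatial.distance import squareform
        return squareform(self.values.to_numpy(), checks=False)


def jsd_matrix(table: FeatureTable | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Jensen-Shannon divergence (base 2) between samples.

    JSD(p, q) = 0.5 KL(p||m) + 0.5 KL(q||m) with m = (p+q)/2; entries lie in
    [0, 1], and sqrt(JSD) is a metric.  Rows are renormalized to probability
    vectors; an all-zero row is an error.
    """
    counts = table.counts if isinstance(table, FeatureTable) else table
    arr = counts.to_numpy(dtype=float)
    tot = arr.sum(axis=1)
    if np.any(tot <= 0):
        raise TableError("all-zero sample(s)")
    p = arr / tot[:, None]
    n = p.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        # jensenshannon returns the square root of the divergence
        root = jensenshannon(p[i + 1:].T, p[i][:, None], base=2, axis=0)
        d[i, i + 1:] = d[i + 1:, i] = np.nan_to_num(root, nan=0.0) ** 2
    return DistanceMatrix(pd.DataFrame(d, index=counts.index, columns=counts.index))


# ---------------------------------------------------------------------------
# principal coordinate analysis
# ---------------------------------------------------------------------------


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame    # n x k
    eigenvalues: np.ndarray      # all n, descending (negatives reported)
    proportion_explained: np.ndarray  # for the k retained axes


def pcoa(dmat: DistanceMatrix, k: int = 2) -> PcoaResult:
    """Classical multidimensional scaling of a distance matrix.

    Eigendecomposition of the double-centered matrix -0.5 * D^2; negative
    eigenvalues (non-Euclidean distances) are reported, not dropped.  The
    sign of each axis is fixed by making its first nonzero loading positive,
    so results are deterministic.
    """
    d = dmat.values.to_numpy()
    n = d.shape[0]
    if k > n - 1:
        raise TableError(f"k={k} exceeds n-1={n - 1}")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = np.clip(w[:k], 0, None)
    coords = v[:, :k] * np.sqrt(pos)
    for axis in range(k):
        col = coords[:, axis]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, axis] = -col
    denom = w[w > 0].sum()
    prop = pos / denom if denom > 0 else np.zeros(k)
    return PcoaResult(
        pd.DataFrame(coords, index=dmat.values.index,
                     columns=[f"PC{i + 1}" for i in range(k)]),
        w, prop)
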