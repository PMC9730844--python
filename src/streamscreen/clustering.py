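"""Source-related clustering of micropollutant occurrence patterns.

Compound (or feature) levels are z-score standardized across sites,
rank-correlated with watershed attributes (Spearman), and the rows of the
resulting correlation matrix are grouped by Ward/Euclidean hierarchical
clustering. With three clusters the groups are labeled A (agricultural),
B (developed/septic), and C (wastewater) according to which attribute
block carries the largest mean correlation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .types import (
    AGRICULTURAL_ATTRIBUTES,
    DEVELOPED_ATTRIBUTES,
    WASTEWATER_ATTRIBUTES,
    InvalidArgument,
)

#: Nondetect handling policies for z-scoring.
NONDETECT_POLICIES = ("exclude", "half_loq", "zero")


@dataclass
class CorrelationMatrix:
    """Spearman rho and two-sided p-values between items (rows) and
    watershed attributes (columns)."""

    rho: pd.DataFrame
    pvalue: pd.DataFrame

    def __post_init__(self) -> None:
        if self.rho.shape != self.pvalue.shape:
            raise InvalidArgument("rho and pvalue shapes differ")
        finite = self.rho.to_numpy()[np.isfinite(self.rho.to_numpy())]
        if finite.size and np.max(np.abs(finite)) > 1 + 1e-9:
            raise InvalidArgument("|rho| must not exceed 1")


@dataclass
class ClusterAssignment:
    """Result of cutting the Ward tree at k clusters."""

    labels: dict[str, str]          # item id -> cluster label ("1".."k" or A/B/C)
    method: str = "ward"
    metric: str = "euclidean"
    k: int = 3
    linkage_matrix: Optional[np.ndarray] = field(default=None, repr=False)


class ZeroVarianceError(InvalidArgument):
    """Standardization is undefined for a constant vector."""


def zscore_levels(values: pd.Series, log_transform: bool = False,
                  nondetect_policy: str = "exclude",
                  nondetect: Optional[pd.Series] = None,
                  loq: Optional[pd.Series] = None) -> pd.Series:
    """Z-score standardize per-site levels of one item.

    Parameters
    ----------
    values:
        Levels indexed by site; NaN marks a missing measurement.
    log_transform:
        Apply log10 before standardization (zeros/nondetect substitutes of
        zero are not log-transformable under this option).
    nondetect_policy:
        "exclude" drops nondetect sites, "half_loq" substitutes LOQ/2,
        "zero" substitutes 0.
    nondetect, loq:
        Optional boolean flags and per-site LOQs aligned with ``values``.

    Returns a Series with mean 0 and SD 1 (ddof=0) over included sites.
    Raises ZeroVarianceError for constant input.
    """
    if nondetect_policy not in NONDETECT_POLICIES:
        raise InvalidArgument(f"unknown nondetect policy {nondetect_policy!r}")
    v = values.astype(float).copy()
    if nondetect is not None:
        nd = nondetect.reindex(v.index).fillna(False).astype(bool)
        if nondetect_policy == "exclude":
            v[nd] = np.nan
        elif nondetect_policy == "half_loq":
            if loq is None:
                raise InvalidArgument("half_loq policy needs per-site LOQs")
            v[nd] = loq.reindex(v.index)[nd] / 2.0
        else:
            v[nd] = 0.0
    if log_transform:
        if (v.dropna() <= 0).any():
            raise InvalidArgument("log transform requires positive values")
        v = np.log10(v)
    included = v.dropna()
    if len(included) < 3:
        raise InvalidArgument("need at least 3 quantified sites")
    sd = included.std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ZeroVarianceError("constant vector cannot be standardized")
    return (v - included.mean()) / sd


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-sample p-values


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


# caches: n -> (n!, n) permutation index matrix; n -> |rho| null (no ties)
_PERM_INDEX_CACHE: dict[int, np.ndarray] = {}
_EXACT_NULL_CACHE: dict[int, np.ndarray] = {}


def _perm_indices(n: int) -> np.ndarray:
    if n not in _PERM_INDEX_CACHE:
        _PERM_INDEX_CACHE[n] = np.array(
            list(itertools.permutations(range(n))), dtype=np.int8)
    return _PERM_INDEX_CACHE[n]


def _exact_pvalue(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Two-sided p-value from the exhaustive permutation null (n <= 9).

    The centered norm of a rank vector is permutation-invariant, so the
    full null reduces to one matrix product over all n! pairings.
    """
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    tied = (len(np.unique(rx)) < n) or (len(np.unique(ry)) < n)
    if not tied and n in _EXACT_NULL_CACHE:
        null = _EXACT_NULL_CACHE[n]
    else:
        xc = (rx if tied else np.arange(1.0, n + 1)) - (n + 1) / 2.0
        xc = xc - xc.mean()
        yc = (ry if tied else np.arange(1.0, n + 1)) - (n + 1) / 2.0
        yc = yc - yc.mean()
        denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        if denom == 0:
            return np.nan
        dots = yc[_perm_indices(n)] @ xc
        null = np.abs(dots / denom)
        if not tied:
            _EXACT_NULL_CACHE[n] = null
    return float(np.mean(null >= abs(rho) - 1e-12))


def spearman_pair(x: Sequence[float], y: Sequence[float],
                  exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rho and two-sided p-value for one pair of vectors.

    Rho uses average (midrank) ties. The p-value comes from the exhaustive
    permutation null for n <= ``exact_max_n`` and from the t approximation
    with n-2 degrees of freedom otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        return np.nan, np.nan
    rho = _spearman_rho(x, y)
    if not np.isfinite(rho):
        return np.nan, np.nan
    if n <= exact_max_n:
        return rho, _exact_pvalue(x, y, rho)
    return rho, _t_pvalue(rho, n)


def _t_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def spearman_matrix(levels: pd.DataFrame, attributes: pd.DataFrame,
                    min_pairs: int = 4, exact_max_n: int = 9
                    ) -> CorrelationMatrix:
    """Spearman correlation of every item against every attribute.

    ``levels``: sites x items (columns = compound/feature ids, NaN allowed);
    ``attributes``: sites x watershed attributes. Rows are aligned on the
    site index. Cells with fewer than ``min_pairs`` complete pairs are NaN.
    """
    sites = levels.index.intersection(attributes.index)
    L = levels.loc[sites]
    A = attributes.loc[sites]
    items = list(L.columns)
    attrs = list(A.columns)
    rho = np.full((len(items), len(attrs)), np.nan)
    pval = np.full_like(rho, np.nan)

    complete_L = not L.isna().any().any()
    n = len(sites)
    if complete_L and not A.isna().any().any() and n > exact_max_n and n >= min_pairs:
        # fast path: rank once, Pearson on ranks, vectorized t p-values
        RL = np.apply_along_axis(stats.rankdata, 0, L.to_numpy(float))
        RA = np.apply_along_axis(stats.rankdata, 0, A.to_numpy(float))
        RL = RL - RL.mean(axis=0)
        RA = RA - RA.mean(axis=0)
        denom = np.sqrt(
            (RL ** 2).sum(axis=0)[:, None] * (RA ** 2).sum(axis=0)[None, :])
        with np.errstate(invalid="ignore", divide="ignore"):
            rho = (RL.T @ RA) / denom
            tstat = rho * np.sqrt((n - 2) / np.clip(1 - rho ** 2, 1e-300, None))
        pval = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
        pval = np.where(np.abs(rho) >= 1.0, 0.0, pval)
    else:
        for i, it in enumerate(items):
            for j, at in enumerate(attrs):
                x = L[it].to_numpy(float)
                y = A[at].to_numpy(float)
                ok = np.isfinite(x) & np.isfinite(y)
                if ok.sum() < min_pairs:
                    continue
                rho[i, j], pval[i, j] = spearman_pair(
                    x[ok], y[ok], exact_max_n=exact_max_n)
    return CorrelationMatrix(
        rho=pd.DataFrame(rho, index=items, columns=attrs),
        pvalue=pd.DataFrame(np.clip(pval, 0.0, 1.0), index=items, columns=attrs),
    )


def bh_qvalues(pvalues: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg adjusted q-values over all finite cells."""
    p = pvalues.to_numpy(float).ravel()
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    pv = p[ok]
    m = pv.size
    if m:
        order = np.argsort(pv)
        ranked = pv[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        qs = np.empty(m)
        qs[order] = np.clip(ranked, 0, 1)
        q[ok] = qs
    return pd.DataFrame(q.reshape(pvalues.shape),
                        index=pvalues.index, columns=pvalues.columns)


# ---------------------------------------------------------------------------
# Hierarchical clustering


def ward_cluster(matrix: CorrelationMatrix, k: int = 3,
                 impute_missing: bool = True) -> ClusterAssignment:
    """Ward/Euclidean agglomerative clustering of correlation-matrix rows.

    Rows are sorted lexicographically by item id before linkage so the
    result does not depend on input order. Missing cells are imputed as 0
    (no evidence of association) when ``impute_missing`` is set, otherwise
    rows with missing cells raise.
    """
    rho = matrix.rho.sort_index()
    if k < 1 or k > len(rho):
        raise InvalidArgument(f"k={k} outside [1, {len(rho)}]")
    X = rho.to_numpy(float)
    if np.isnan(X).any():
        if not impute_missing:
            raise InvalidArgument("missing correlation cells; impute first")
        X = np.nan_to_num(X, nan=0.0)
    if len(rho) == 1:
        return ClusterAssignment(labels={rho.index[0]: "1"}, k=1)
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = {item: str(c) for item, c in zip(rho.index, flat)}
    return ClusterAssignment(labels=labels, k=k, linkage_matrix=Z)


def label_clusters(assignment: ClusterAssignment, matrix: CorrelationMatrix
                   ) -> dict[str, str]:
    """Map the three clusters to the semantic labels A, B, C.

    The cluster whose mean rho over the agricultural attributes (ag_pct,
    cafo_count, rpi) is largest becomes A; over the developed/septic block
    becomes B; over wwtp_capacity becomes C. Assignment is greedy by
    descending block score with ties broken in priority order A > B > C.
    With k != 3 the raw cluster ids are returned unchanged.
    """
    if assignment.k != 3:
        return dict(assignment.labels)
    rho = matrix.rho
    blocks = {
        "A": [a for a in AGRICULTURAL_ATTRIBUTES if a in rho.columns],
        "B": [a for a in DEVELOPED_ATTRIBUTES if a in rho.columns],
        "C": [a for a in WASTEWATER_ATTRIBUTES if a in rho.columns],
    }
    clusters = sorted(set(assignment.labels.values()))
    scores = {}
    for c in clusters:
        items = [i for i, lab in assignment.labels.items() if lab == c]
        sub = rho.loc[items]
        for name in "ABC":
            cols = blocks[name]
            val = float(np.nanmean(sub[cols].to_numpy())) if cols else -np.inf
            scores[(c, name)] = val if np.isfinite(val) else -np.inf
    mapping: dict[str, str] = {}
    taken: set[str] = set()
    # greedy: best (cluster, semantic) pairs first; ties resolved A > B > C
    order = sorted(scores.items(),
                   key=lambda kv: (-kv[1], "ABC".index(kv[0][1]), kv[0][0]))
    for (c, name), _ in order:
        if c in mapping or name in taken:
            continue
        mapping[c] = name
        taken.add(name)
    return {item: mapping[c] for item, c in assignment.labels.items()}


def cluster_items(levels: pd.DataFrame, attributes: pd.DataFrame, k: int = 3,
                  alpha: float = 0.05) -> tuple[CorrelationMatrix, dict[str, str], pd.DataFrame]:
    """Convenience wrapper: z-score columns, correlate, cluster and label.

    Returns the correlation matrix, item -> A/B/C label mapping, and an
    annotation frame with per-cell significance (p < alpha, unadjusted)
    and BH q-values flattened alongside rho.
    """
    z = {}
    for col in levels.columns:
        try:
            z[col] = zscore_levels(levels[col])
        except InvalidArgument as exc:
            warnings.warn(f"excluding {col!r}: {exc}")
    Z = pd.DataFrame(z, index=levels.index)
    matrix = spearman_matrix(Z, attributes)
    assignment = ward_cluster(matrix, k=k)
    labels = label_clusters(assignment, matrix)
    q = bh_qvalues(matrix.pvalue)
    ann = matrix.rho.stack().rename("rho").to_frame()
    ann["pvalue"] = matrix.pvalue.stack()
    ann["qvalue"] = q.stack()
    ann["significant"] = ann["pvalue"] < alpha
    ann = ann.reset_index().rename(columns={"level_0": "item",
                                            "level_1": "attribute"})
    return matrix, labels, ann
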