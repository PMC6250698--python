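"""Permutation and autocorrelation statistics for phylosymbiosis.

Mantel tests and correlograms relate a community dissimilarity matrix to
host phylogenetic distance; Moran's I correlograms do the same for
univariate traits such as richness; single-factor PERMANOVA screens
metadata factors against beta-diversity matrices.  All permutation p-values
use the (count + 1) / (n_perm + 1) convention, except under exact
enumeration where the identity permutation plays that role.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix

__all__ = [
    "MantelResult",
    "PermanovaResult",
    "DistanceClassPartition",
    "mantel",
    "build_distance_classes",
    "mantel_correlogram",
    "morans_i",
    "phylo_correlogram",
    "permanova",
    "adjusted_r2",
    "zscore_columns",
    "bonferroni_adjust",
    "expand_host_distance",
    "average_by_host",
]

_EPS = 1e-12


def _as_square(d) -> tuple[np.ndarray, list]:
    if isinstance(d, DistanceMatrix):
        return d.data.astype(float), list(d.ids)
    arr = np.asarray(d, dtype=float)
    return arr, list(range(arr.shape[0]))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt((a * a).sum())
    nb = np.sqrt((b * b).sum())
    if na == 0 or nb == 0:
        raise ValueError("zero variance in off-diagonal distances")
    return float((a * b).sum() / (na * nb))


@dataclass
class MantelResult:
    r: float
    p: float
    n: int
    n_perm: int
    alternative: str
    seed: int | None = None


def mantel(da, db, n_perm: int = 999, seed: int | None = None,
           alternative: str = "greater", exact: bool = False) -> MantelResult:
    """Mantel test: Pearson correlation of off-diagonal distance pairs.

    ``alternative='greater'`` tests for positive association (the
    phylosymbiosis direction); ``'two-sided'`` uses |r|.  With
    ``exact=True`` all n! label permutations are enumerated (n <= 8) and
    the p-value is the exact fraction (the identity permutation included).
    """
    A, ids_a = _as_square(da)
    B, ids_b = _as_square(db)
    if isinstance(db, DistanceMatrix) and isinstance(da, DistanceMatrix):
        if set(ids_a) != set(ids_b):
            raise ValueError("distance matrices have different labels")
        order = [ids_b.index(i) for i in ids_a]
        B = B[np.ix_(order, order)]
    n = A.shape[0]
    if n < 4:
        raise ValueError("Mantel test requires n >= 4")
    va = squareform(A, checks=False)
    r = _pearson(va, squareform(B, checks=False))

    def stat(perm):
        return _pearson(va, squareform(B[np.ix_(perm, perm)], checks=False))

    if exact:
        perms = list(itertools.permutations(range(n)))
        rs = np.array([stat(np.array(p)) for p in perms])
        n_perm = len(perms)
        if alternative == "greater":
            p = float(np.mean(rs >= r - _EPS))
        else:
            p = float(np.mean(np.abs(rs) >= abs(r) - _EPS))
        return MantelResult(r, p, n, n_perm, alternative, seed)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        rp = stat(rng.permutation(n))
        if alternative == "greater":
            count += rp >= r - _EPS
        else:
            count += abs(rp) >= abs(r) - _EPS
    p = (count + 1) / (n_perm + 1)
    return MantelResult(r, float(p), n, n_perm, alternative, seed)


# -- distance classes ------------------------------------------------------


def sturges_classes(n: int) -> int:
    """Sturges' rule: about 1 + log2(n) classes for n observations.

    Used on the number of tips for univariate trait correlograms and on
    the number of tip pairs for community (Mantel) correlograms.
    """
    return max(2, int(math.ceil(1 + math.log2(max(n, 2)))))


@dataclass
class DistanceClassPartition:
    """Disjoint classes of tip pairs by phylogenetic distance.

    ``indicators[k]`` is a symmetric boolean matrix (zero diagonal) marking
    the pairs in class k; classes are ordered by distance and jointly cover
    every off-diagonal pair.
    """

    labels: tuple
    bounds: list
    indicators: list
    representatives: list

    @property
    def n_classes(self) -> int:
        return len(self.indicators)

    def n_pairs(self, k: int) -> int:
        return int(self.indicators[k].sum() // 2)


def build_distance_classes(dhost, n_classes: int = 11,
                           manual_breaks=None,
                           singleton_threshold: float | None = None,
                           ) -> DistanceClassPartition:
    """Partition tip pairs into ordered phylogenetic distance classes.

    With ``manual_breaks`` the breaks are used verbatim as lower class
    edges (half-open intervals, the last unbounded above).  Otherwise each
    distinct distance above ``singleton_threshold`` gets its own class
    (handling the discrete deep-divergence distances of a constrained host
    tree) and the remaining range is split into equal-width classes so the
    total equals ``n_classes``.
    """
    D, labels = _as_square(dhost)
    d = squareform(D, checks=False)
    distinct = np.unique(np.round(d, 9))

    def classes_from_assignment(assign, bounds, n_k):
        indicators, reps = [], []
        for k in range(n_k):
            mask = assign == k
            ind = squareform(mask.astype(float), checks=False) > 0
            indicators.append(ind)
            reps.append(float(d[mask].mean()) if mask.any() else np.nan)
        return DistanceClassPartition(tuple(labels), bounds, indicators, reps)

    if manual_breaks is not None:
        breaks = sorted(manual_breaks)
        edges = np.array(breaks + [np.inf])
        assign = np.digitize(d, edges[1:-1], right=False)
        bounds = [(edges[i], edges[i + 1]) for i in range(len(breaks))]
        return classes_from_assignment(assign, bounds, len(breaks))

    if n_classes < 2:
        raise ValueError("need at least 2 distance classes")
    if n_classes > distinct.size:
        raise ValueError(
            f"{n_classes} classes requested but only {distinct.size} "
            f"distinct distances exist")

    singles = []
    if singleton_threshold is not None:
        singles = [v for v in distinct if v > singleton_threshold]
    n_lower = n_classes - len(singles)
    if n_lower < 1:
        raise ValueError("singleton classes exceed requested class count")
    lower = d[np.round(d, 9) <= (singles[0] - _EPS if singles
                                 else np.inf)]
    lo, hi = (lower.min(), lower.max()) if lower.size else (0.0, 1.0)
    edges = np.linspace(lo, hi, n_lower + 1)
    assign = np.clip(np.digitize(d, edges[1:-1], right=False), 0, n_lower - 1)
    for j, v in enumerate(singles):
        assign[np.isclose(d, v, rtol=0, atol=1e-9)] = n_lower + j
    bounds = [(edges[i], edges[i + 1]) for i in range(n_lower)]
    bounds += [(v, v) for v in singles]
    return classes_from_assignment(assign, bounds, n_classes)


def _holm_adjust(vals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values for one family of tests."""
    m = vals.size
    order = np.argsort(vals)
    stepped = np.minimum((m - np.arange(m)) * vals[order], 1.0)
    stepped = np.maximum.accumulate(stepped)
    out = np.empty(m)
    out[order] = stepped
    return out


def _holm_progressive(p_raw: np.ndarray) -> np.ndarray:
    """vegan-style progressive Holm correction for ordered distance classes:
    class k's p is Holm-adjusted within the first k+1 raw p-values."""
    out = np.full_like(p_raw, np.nan)
    for k in range(p_raw.size):
        if not np.isfinite(p_raw[k]):
            continue
        sub = p_raw[: k + 1]
        ok = np.flatnonzero(np.isfinite(sub))
        adj = _holm_adjust(sub[ok])
        out[k] = adj[list(ok).index(k)]
    return out


def mantel_correlogram(dmicro, classes: DistanceClassPartition,
                       n_perm: int = 999, seed: int | None = None,
                       ) -> pd.DataFrame:
    """Mantel correlogram over phylogenetic distance classes.

    Per class, the statistic is the Mantel correlation between the
    community dissimilarities and the class indicator matrix, sign-flipped
    so positive values mean within-class pairs are *more similar* than
    expected.  Two-sided permutation p-values get a progressive Holm
    correction in class order.  Classes with fewer than 2 pairs are NaN.
    """
    D, ids = _as_square(dmicro)
    if isinstance(dmicro, DistanceMatrix):
        order = [ids.index(l) for l in classes.labels]
        D = D[np.ix_(order, order)]
    n = D.shape[0]
    dm = squareform(D, checks=False)
    dm_c = dm - dm.mean()
    dm_norm = np.sqrt((dm_c * dm_c).sum())
    if dm_norm == 0:
        raise ValueError("zero variance in community dissimilarities")

    inds, valid = [], []
    for k in range(classes.n_classes):
        v = squareform(classes.indicators[k].astype(float), checks=False)
        npairs = int(v.sum())
        if npairs < 2 or npairs == v.size:
            inds.append(None)
            valid.append(False)
        else:
            vc = v - v.mean()
            inds.append(vc / np.sqrt((vc * vc).sum()))
            valid.append(True)

    def stats_for(mat_condensed):
        c = mat_condensed - mat_condensed.mean()
        norm = np.sqrt((c * c).sum())
        return np.array([(-(ind @ c) / norm) if ind is not None else np.nan
                         for ind in inds])

    obs = stats_for(dm)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(classes.n_classes)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rp = stats_for(squareform(D[np.ix_(perm, perm)], checks=False))
        exceed += np.abs(rp) >= np.abs(obs) - _EPS
    p_raw = np.where(valid, (exceed + 1) / (n_perm + 1), np.nan)
    p_corr = _holm_progressive(p_raw)
    return pd.DataFrame({
        "class": np.arange(classes.n_classes),
        "representative": classes.representatives,
        "n_pairs": [classes.n_pairs(k) for k in range(classes.n_classes)],
        "statistic": obs,
        "p": p_raw,
        "p_corrected": p_corr,
    })


# -- Moran's I -------------------------------------------------------------


def morans_i(z, w) -> float:
    """Moran's I autocorrelation of a trait under a weight matrix.

    I = (n / S0) * sum_ij w_ij (z_i - zbar)(z_j - zbar) / sum_i (z_i - zbar)^2
    """
    z = np.asarray(z, dtype=float)
    W = np.asarray(w, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("Moran's I requires n >= 3")
    if np.any(W < 0) or not np.allclose(W, W.T) or np.any(np.diag(W) != 0):
        raise ValueError("weights must be symmetric, non-negative, "
                         "zero-diagonal")
    s0 = W.sum()
    if s0 == 0:
        raise ValueError("all-zero weight matrix")
    zc = z - z.mean()
    denom = (zc * zc).sum()
    if denom == 0:
        raise ValueError("constant trait has undefined autocorrelation")
    return float(n / s0 * (zc @ W @ zc) / denom)


def phylo_correlogram(trait: pd.Series, classes: DistanceClassPartition,
                      n_perm: int = 999, seed: int | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Moran's I correlogram of a per-tip trait over distance classes.

    Confidence intervals are recentred percentile intervals from the
    permutation distribution: the spread of I under trait-label permutation
    shifted to sit on the observed I.  A class is positive-significant when
    the CI lower bound exceeds the permutation-null expectation -1/(n-1),
    negative-significant when the upper bound is below it.
    """
    z = trait.reindex(list(classes.labels)).to_numpy(dtype=float)
    if np.isnan(z).any():
        raise ValueError("trait missing for some tree tips")
    n = z.size
    zc = z - z.mean()
    denom = (zc * zc).sum()
    if denom == 0:
        raise ValueError("constant trait has undefined autocorrelation")
    expectation = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Zp = zc[perms]  # n_perm x n

    rows = []
    for k in range(classes.n_classes):
        W = classes.indicators[k].astype(float)
        s0 = W.sum()
        if s0 == 0 or classes.n_pairs(k) < 2:
            rows.append((k, classes.representatives[k], classes.n_pairs(k),
                         np.nan, np.nan, np.nan, np.nan, False, False))
            continue
        i_obs = float(n / s0 * (zc @ W @ zc) / denom)
        num = np.einsum("pi,pi->p", Zp @ W, Zp)
        i_perm = n / s0 * num / denom
        lo_q, hi_q = np.quantile(i_perm, [alpha / 2, 1 - alpha / 2])
        center = i_perm.mean()
        ci_lo = i_obs + (lo_q - center)
        ci_hi = i_obs + (hi_q - center)
        p = float((np.sum(np.abs(i_perm - expectation)
                          >= abs(i_obs - expectation) - _EPS) + 1)
                  / (n_perm + 1))
        rows.append((k, classes.representatives[k], classes.n_pairs(k),
                     i_obs, p, ci_lo, ci_hi,
                     ci_lo > expectation, ci_hi < expectation))
    return pd.DataFrame(rows, columns=[
        "class", "representative", "n_pairs", "statistic", "p",
        "ci_lower", "ci_upper", "significant_positive",
        "significant_negative"])


# -- PERMANOVA -------------------------------------------------------------


@dataclass
class PermanovaResult:
    factor: str
    pseudo_f: float
    r2: float
    adjusted_r2: float
    p: float
    n_perm: int
    n_samples: int
    df: int
    seed: int | None = None


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D * D
    row = A.mean(axis=0)
    return A - row[:, None] - row[None, :] + A.mean()


def _design_matrix(values: pd.Series) -> tuple[np.ndarray, int]:
    numeric = pd.to_numeric(values, errors="coerce")
    if numeric.notna().all():
        X = np.column_stack([np.ones(len(values)), numeric.to_numpy(float)])
        return X, 1
    levels = pd.unique(values)
    if len(levels) < 2:
        raise ValueError(f"factor {values.name!r} has a single level")
    dummies = pd.get_dummies(values).to_numpy(float)
    X = np.column_stack([np.ones(len(values)), dummies[:, 1:]])
    return X, len(levels) - 1


def permanova(d, grouping, n_perm: int = 999, seed: int | None = None,
              factor_name: str | None = None,
              exact: bool = False) -> PermanovaResult:
    """Single-factor PERMANOVA (adonis-style) on a distance matrix.

    Categorical factors use one-way dummies; numeric values are treated as
    a single-df regression on the Gower-centered inner-product matrix.
    ``Unknown`` values are dropped before testing.  p is the one-sided
    fraction of label permutations with pseudo-F at least as large
    ((count + 1) / (n_perm + 1); exact enumeration when ``exact``).
    """
    D, ids = _as_square(d)
    g = pd.Series(grouping)
    if isinstance(d, DistanceMatrix) and not g.index.equals(
            pd.RangeIndex(len(g))):
        g = g.reindex(ids)
    g = g.reset_index(drop=True)
    from .tables import UNKNOWN

    keep = g.astype(str) != UNKNOWN
    g = g[keep].reset_index(drop=True)
    idx = np.flatnonzero(keep.to_numpy())
    D = D[np.ix_(idx, idx)]
    n = D.shape[0]
    if n < 3:
        raise ValueError("PERMANOVA needs at least 3 usable samples")
    X, df = _design_matrix(g.rename(factor_name))
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    G = _gower_center(D)
    ss_total = float(np.trace(G))
    ss_model = float(np.sum(H * G))  # trace(HG), H symmetric
    ss_resid = ss_total - ss_model
    df_resid = n - df - 1
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    f_obs = (ss_model / df) / (ss_resid / df_resid)
    r2 = ss_model / ss_total
    adj = adjusted_r2(r2, n, df)

    def f_for(perm):
        Gp = G[np.ix_(perm, perm)]
        ssm = float(np.sum(H * Gp))
        return (ssm / df) / ((ss_total - ssm) / df_resid)

    if exact:
        perms = list(itertools.permutations(range(n)))
        fs = np.array([f_for(np.array(p)) for p in perms])
        p = float(np.mean(fs >= f_obs - _EPS))
        n_perm = len(perms)
    else:
        rng = np.random.default_rng(seed)
        count = sum(f_for(rng.permutation(n)) >= f_obs - _EPS
                    for _ in range(n_perm))
        p = (count + 1) / (n_perm + 1)
    return PermanovaResult(factor_name or str(g.name), float(f_obs),
                           float(r2), float(adj), float(p), n_perm, n, df,
                           seed)


def adjusted_r2(r2: float, n: int, df: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - df - 1); penalizes many-level factors."""
    if df < 1 or df >= n - 1:
        raise ValueError("require 1 <= df <= n - 2")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - df - 1)


def zscore_columns(m: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column (sample sd); constant columns become 0 with a
    warning."""
    out = m.copy().astype(float)
    for col in out.columns:
        v = out[col]
        sd = v.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(f"column {col!r} has zero spread; set to 0")
            out[col] = 0.0
        else:
            out[col] = (v - v.mean()) / sd
    return out


def bonferroni_adjust(p, m: int | None = None) -> np.ndarray:
    """min(1, p * m) across the full family of tests."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)


# -- host <-> sample helpers ----------------------------------------------


def expand_host_distance(dhost: DistanceMatrix, host_of: pd.Series,
                         ) -> DistanceMatrix:
    """Distance between samples = cophenetic distance between their hosts
    (0 within the same host)."""
    samples = list(host_of.index)
    hosts = host_of.to_numpy()
    missing = sorted(set(hosts) - set(dhost.ids))
    if missing:
        raise ValueError(f"hosts absent from tree: {missing}")
    pos = np.array([dhost.index(h) for h in hosts])
    return DistanceMatrix(dhost.data[np.ix_(pos, pos)], samples)


def average_by_host(values: pd.Series, host_of: pd.Series) -> pd.Series:
    """Average a per-sample quantity within each host tip."""
    df = pd.DataFrame({"v": values, "h": host_of.reindex(values.index)})
    return df.groupby("h")["v"].mean()
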