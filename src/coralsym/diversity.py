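"""Alpha and beta diversity on rarefied feature tables.

Alpha: observed features, Pielou evenness (base-e Shannon over observed
features), Faith's phylogenetic diversity.  Beta: Bray-Curtis, binary
Jaccard, unweighted and weighted (raw or normalized) UniFrac.  Pairwise
metric values follow the standard definitions; matrix computation is
delegated to scikit-bio.  Features missing from the microbial tree are
dropped from tree-based metrics with a warning rather than an error.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .tables import FeatureTable

__all__ = [
    "observed_features",
    "pielou_evenness",
    "faith_pd",
    "bray_curtis",
    "binary_jaccard",
    "unweighted_unifrac",
    "weighted_unifrac",
    "alpha_diversity_table",
    "beta_matrix",
]


# -- alpha ----------------------------------------------------------------


def observed_features(t: FeatureTable) -> pd.Series:
    """Number of features with count > 0 per sample."""
    out = (t.counts > 0).sum(axis=0)
    out.name = "observed_features"
    return out


def pielou_evenness(t: FeatureTable) -> pd.Series:
    """Pielou's J = Shannon H (base e) / ln S over observed features.

    Samples with a single observed feature (ln S = 0) get NaN.
    """
    out = {}
    for s in t.sample_ids:
        x = t.counts[s].to_numpy(dtype=float)
        x = x[x > 0]
        if x.size == 0:
            raise ValueError(f"sample {s!r} has no observed features")
        if x.size == 1:
            out[s] = np.nan
            continue
        p = x / x.sum()
        h = -(p * np.log(p)).sum()
        out[s] = h / np.log(x.size)
    return pd.Series(out, name="pielou_evenness")


def _tree_feature_split(t: FeatureTable, tree: TreeNode):
    tip_names = {tip.name for tip in tree.tips()}
    on_tree = [f for f in t.feature_ids if f in tip_names]
    missing = [f for f in t.feature_ids if f not in tip_names]
    if missing:
        warnings.warn(
            f"{len(missing)} features absent from the tree were dropped "
            f"from phylogenetic diversity (e.g. {missing[:3]})")
    return on_tree


def faith_pd(t: FeatureTable, tree: TreeNode) -> pd.Series:
    """Faith's PD: branch length of the minimal rooted subtree spanning the
    present tips (root inclusive)."""
    on_tree = _tree_feature_split(t, tree)
    sub = t.counts.loc[on_tree]
    out = {}
    for s in t.sample_ids:
        counts = sub[s].to_numpy()
        if counts.sum() == 0:
            out[s] = 0.0
        else:
            out[s] = float(_skbio_faith_pd(counts, taxa=on_tree,
                                           tree=tree, validate=False))
    return pd.Series(out, name="faith_pd")


def alpha_diversity_table(t: FeatureTable,
                          tree: TreeNode | None = None) -> pd.DataFrame:
    """Observed features, Pielou evenness and (given a tree) Faith's PD."""
    cols = [observed_features(t), pielou_evenness(t)]
    if tree is not None:
        cols.append(faith_pd(t, tree))
    return pd.concat(cols, axis=1)


# -- pairwise beta --------------------------------------------------------


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y); NaN if both empty."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = (x + y).sum()
    if denom == 0:
        return np.nan
    return float(np.abs(x - y).sum() / denom)


def binary_jaccard(x, y) -> float:
    """1 - |support(x) & support(y)| / |support(x) | support(y)|."""
    a = np.asarray(x) > 0
    b = np.asarray(y) > 0
    union = (a | b).sum()
    if union == 0:
        return np.nan
    return float(1.0 - (a & b).sum() / union)


def unweighted_unifrac(x, y, feature_ids, tree: TreeNode) -> float:
    """Fraction of observed branch length unique to one sample's subtree."""
    a = np.asarray(x)
    b = np.asarray(y)
    if a.sum() == 0 and b.sum() == 0:
        return np.nan
    from skbio.diversity.beta import unweighted_unifrac as _uw

    return float(_uw(a, b, taxa=list(feature_ids), tree=tree,
                     validate=False))


def weighted_unifrac(x, y, feature_ids, tree: TreeNode,
                     normalized: bool = False) -> float:
    """Abundance-weighted UniFrac; raw variant by default."""
    a = np.asarray(x, dtype=float)
    b = np.asarray(y, dtype=float)
    if a.sum() == 0 or b.sum() == 0:
        return np.nan
    from skbio.diversity.beta import weighted_unifrac as _w

    return float(_w(a, b, taxa=list(feature_ids), tree=tree,
                    normalized=normalized, validate=False))


# -- beta matrices --------------------------------------------------------


def beta_matrix(t: FeatureTable, metric: str,
                tree: TreeNode | None = None,
                normalized: bool = False) -> DistanceMatrix:
    """Sample-by-sample distance matrix for one metric.

    ``metric`` is one of ``bray_curtis``, ``binary_jaccard``,
    ``unweighted_unifrac``, ``weighted_unifrac``.
    """
    data = t.counts.to_numpy().T  # samples x features
    ids = t.sample_ids
    if metric == "bray_curtis":
        return DistanceMatrix(squareform(pdist(data, "braycurtis")), ids)
    if metric == "binary_jaccard":
        return DistanceMatrix(squareform(pdist(data > 0, "jaccard")), ids)
    if metric in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None:
            raise ValueError(f"{metric} requires a tree")
        on_tree = _tree_feature_split(t, tree)
        sub = t.counts.loc[on_tree].to_numpy().T
        kwargs = {"taxa": on_tree, "tree": tree, "validate": False}
        if metric == "weighted_unifrac":
            kwargs["normalized"] = normalized
        return beta_diversity(metric, sub, ids=ids, **kwargs)
    raise ValueError(f"unknown beta-diversity metric {metric!r}")
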