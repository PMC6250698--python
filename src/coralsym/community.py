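"""Community-level Poisson GLMM for genus abundances.

Counts of each genus in each sample are modeled on the log scale with the
sample's total read count as an offset (sequencing depth), per-genus
intercepts and covariate slopes as fixed effects, and random effects for
sample (compositionality), geographic-area-by-genus, host-phylogeny-by-
genus (covariance from the host tree) and host-identity-by-genus.  Each
genus keeps an independent residual variance.

Sampling alternates a Metropolis update of the latent log-means (Poisson
likelihood against their Gaussian prior) with conjugate Gaussian updates of
every structured component and scaled-inverse-chi-squared updates of the
variances.  A per-genus covariate effect is called significant when its
95% HPD interval excludes zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import GlmmConfig, hpd_interval, effective_sample_size, _inv_psd
from .phylo import Tree, phylo_covariance, standardize_covariance, tip_labels
from .tables import UNKNOWN, FeatureTable

__all__ = ["CommunityPosterior", "fit_community_count_glmm"]


@dataclass
class CommunityPosterior:
    """Retained draws for the genus-level count model."""

    genera: tuple
    covariates: tuple
    intercept_draws: np.ndarray  # draws x genera
    effect_draws: np.ndarray     # draws x genera x covariates
    variance_draws: pd.DataFrame

    def effect_summary(self, prob: float = 0.95) -> pd.DataFrame:
        """Per genus x covariate: posterior mean, HPD bounds, significance
        (HPD excludes zero)."""
        rows = []
        for gi, g in enumerate(self.genera):
            for ci, c in enumerate(self.covariates):
                draws = self.effect_draws[:, gi, ci]
                lo, hi = hpd_interval(draws, prob)
                rows.append((g, c, draws.mean(), lo, hi,
                             lo > 0 or hi < 0))
        return pd.DataFrame(rows, columns=[
            "genus", "covariate", "mean", "hpd_lower", "hpd_upper",
            "significant"])

    def ess(self) -> pd.Series:
        out = {}
        for ci, c in enumerate(self.covariates):
            pooled = self.effect_draws[:, :, ci]
            out[c] = float(np.median([effective_sample_size(pooled[:, g])
                                      for g in range(pooled.shape[1])]))
        return pd.Series(out)


def fit_community_count_glmm(t: FeatureTable, fixed: list[str],
                             host_tree: Tree, config: GlmmConfig,
                             host_column: str = "host",
                             area_column: str = "area",
                             ) -> CommunityPosterior:
    """Fit the Poisson community model to a genus-collapsed table.

    ``fixed`` names numeric metadata columns used as per-genus covariates;
    they must be free of ``Unknown`` values.  Deterministic given
    ``config.seed``.
    """
    md = t.metadata
    for col in fixed + [host_column, area_column]:
        if col not in md.columns:
            raise ValueError(f"metadata column {col!r} missing")
        if (md[col].astype(str) == UNKNOWN).any():
            raise ValueError(f"column {col!r} contains Unknown values")
    covs = md[fixed].apply(pd.to_numeric).to_numpy(dtype=float)
    if any(np.unique(covs[:, j]).size < 2 for j in range(covs.shape[1])):
        raise ValueError("a covariate has a single level")

    genera = tuple(t.feature_ids)
    samples = t.sample_ids
    y = t.counts.to_numpy().T.astype(float)  # samples x genera
    n_s, n_g = y.shape
    n_c = len(fixed)
    offset = np.log(np.maximum(t.sample_totals().to_numpy(dtype=float), 1.0))

    hosts = tuple(h for h in tip_labels(host_tree)
                  if h in set(md[host_column]))
    bad = sorted(set(md[host_column]) - set(hosts))
    if bad:
        raise ValueError(f"samples map to hosts absent from host tree: {bad}")
    host_pos = {h: i for i, h in enumerate(hosts)}
    s_host = np.array([host_pos[md.loc[s, host_column]] for s in samples])
    areas = tuple(pd.unique(md[area_column]))
    area_pos = {a: i for i, a in enumerate(areas)}
    s_area = np.array([area_pos[md.loc[s, area_column]] for s in samples])
    n_h, n_a = len(hosts), len(areas)
    if n_h < 2:
        raise ValueError("need >= 2 host levels")

    A = standardize_covariance(phylo_covariance(host_tree))
    hi = [A.labels.index(h) for h in hosts]
    Ainv = _inv_psd(A.values[np.ix_(hi, hi)])

    rng = np.random.default_rng(config.seed)
    nu0, s02 = config.prior_df, config.prior_scale
    v0 = config.fixed_prior_var

    # state
    X = np.column_stack([np.ones(n_s), covs])     # per-genus fixed design
    B = np.zeros((n_g, 1 + n_c))                  # intercept + slopes
    B[:, 0] = np.log((y.mean(axis=0) + 0.5)) - offset.mean()
    u_s = np.zeros(n_s)
    v_ag = np.zeros((n_a, n_g))
    w_hg = np.zeros((n_h, n_g))
    q_hg = np.zeros((n_h, n_g))
    sig_e = np.ones(n_g)      # per-genus residual variance
    var_u = var_v = var_w = var_q = 1.0

    def mean_matrix():
        return (offset[:, None] + X @ B.T + u_s[:, None]
                + v_ag[s_area] + w_hg[s_host] + q_hg[s_host])

    m = mean_matrix()
    l = np.log(y + 0.5)
    l = np.where(np.abs(l - m) > 5, m, l)  # keep init near prior mean

    n_saved = config.n_saved
    eff_draws = np.empty((n_saved, n_g, n_c))
    int_draws = np.empty((n_saved, n_g))
    var_rows = []
    saved = 0

    host_counts = np.bincount(s_host, minlength=n_h).astype(float)
    area_counts = np.bincount(s_area, minlength=n_a).astype(float)
    XtX = X.T @ X

    for it in range(config.n_iter):
        # Metropolis update of latent log-means (vectorized over all cells)
        lam = np.exp(np.clip(l, -30, 30))
        step = 2.4 / np.sqrt(lam + 1.0 / sig_e[None, :])
        prop = l + step * rng.standard_normal(l.shape)
        lam_p = np.exp(np.clip(prop, -30, 30))
        log_acc = (y * (prop - l) - (lam_p - lam)
                   - 0.5 * ((prop - m) ** 2 - (l - m) ** 2)
                   / sig_e[None, :])
        acc = np.log(rng.random(l.shape) + 1e-300) < log_acc
        l = np.where(acc, prop, l)

        r = l - m  # current residuals
        # per-genus fixed effects (intercept + slopes)
        target = l - (offset[:, None] + u_s[:, None] + v_ag[s_area]
                      + w_hg[s_host] + q_hg[s_host])
        prec = XtX[None] / sig_e[:, None, None] \
            + np.eye(1 + n_c)[None] / v0
        rhs = (X.T @ target) / sig_e[None, :]       # (1+c) x genera
        L = np.linalg.cholesky(prec)
        z = rng.standard_normal((n_g, 1 + n_c))
        noise = np.einsum("gij,gj->gi", L, z)
        B = np.linalg.solve(prec, (rhs.T + noise)[:, :, None])[:, :, 0]

        # sample effect (compositionality)
        resid = l - mean_matrix() + u_s[:, None]
        pr = (1.0 / sig_e).sum() + 1.0 / var_u
        bs = (resid / sig_e[None, :]).sum(axis=1)
        u_s = bs / pr + rng.standard_normal(n_s) / math.sqrt(pr)

        # area x genus
        resid = l - mean_matrix() + v_ag[s_area]
        pr = area_counts[:, None] / sig_e[None, :] + 1.0 / var_v
        ba = np.zeros((n_a, n_g))
        np.add.at(ba, s_area, resid / sig_e[None, :])
        v_ag = ba / pr + rng.standard_normal((n_a, n_g)) / np.sqrt(pr)

        # host-phylogeny x genus: per-genus n_h-dimensional system
        resid = l - mean_matrix() + w_hg[s_host]
        bh = np.zeros((n_h, n_g))
        np.add.at(bh, s_host, resid / sig_e[None, :])
        Q = (Ainv[None] / var_w
             + (host_counts[:, None] / sig_e[None, :]).T[:, :, None]
             * np.eye(n_h)[None])
        Lq = np.linalg.cholesky(Q)
        z = rng.standard_normal((n_g, n_h))
        rhs = bh.T + np.einsum("gij,gj->gi", Lq, z)
        w_hg = np.linalg.solve(Q, rhs[:, :, None])[:, :, 0].T

        # host-identity x genus (iid)
        resid = l - mean_matrix() + q_hg[s_host]
        bq = np.zeros((n_h, n_g))
        np.add.at(bq, s_host, resid / sig_e[None, :])
        pr = host_counts[:, None] / sig_e[None, :] + 1.0 / var_q
        q_hg = bq / pr + rng.standard_normal((n_h, n_g)) / np.sqrt(pr)

        # variances
        m = mean_matrix()
        eps = l - m
        sig_e = ((nu0 * s02 + (eps * eps).sum(axis=0)) / 2.0
                 / rng.gamma((nu0 + n_s) / 2.0, size=n_g))
        var_u = ((nu0 * s02 + u_s @ u_s) / 2.0
                 / rng.gamma((nu0 + n_s) / 2.0))
        var_v = ((nu0 * s02 + (v_ag * v_ag).sum()) / 2.0
                 / rng.gamma((nu0 + n_a * n_g) / 2.0))
        quad_w = float(np.sum((Ainv @ w_hg) * w_hg))
        var_w = ((nu0 * s02 + quad_w) / 2.0
                 / rng.gamma((nu0 + n_h * n_g) / 2.0))
        var_q = ((nu0 * s02 + (q_hg * q_hg).sum()) / 2.0
                 / rng.gamma((nu0 + n_h * n_g) / 2.0))

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            int_draws[saved] = B[:, 0]
            eff_draws[saved] = B[:, 1:]
            var_rows.append((var_u, var_v, var_w, var_q,
                             float(sig_e.mean())))
            saved += 1

    vdf = pd.DataFrame(var_rows, columns=["sample", "area_x_genus",
                                          "hostphylo_x_genus",
                                          "hostid_x_genus",
                                          "residual_mean"])
    return CommunityPosterior(genera, tuple(fixed), int_draws[:saved],
                              eff_draws[:saved], vdf)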