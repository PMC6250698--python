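"""Synthetic hosts, microbes, and count tables with known ground truth.

Everything the pipeline consumes can be generated here: ultrametric Yule
trees, binary-occurrence datasets drawn from the cophylogenetic GLMM's own
generative model (so variance components and ICCs are known exactly),
Brownian-motion community tables that exhibit phylosymbiosis by
construction, per-tip traits for richness correlograms, and Poisson genus
tables with known covariate slopes for the community count model.

Occurrence is generated first (the cophylogeny models are binary); a
truncated-negative-binomial count layer is added only so that upstream
table operations (rarefaction, depth filters) can run on simulated data.
Sequencing depths are lognormal around 14,000 reads to mimic the scale of
a typical MiSeq amplicon survey.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .glmm import LINK_VARIANCE, RESIDUAL_VARIANCE, TERM_NAMES
from .phylo import (Tree, phylo_covariance, standardize_covariance,
                    tip_labels, write_newick)
from .tables import FeatureTable

__all__ = [
    "SimulationScenario",
    "SimulationTruth",
    "simulate_tree",
    "simulate_cophylo_dataset",
    "simulate_phylosymbiosis_table",
    "simulate_richness_trait",
    "simulate_genus_table",
    "recovery_scenario",
    "null_scenario",
    "canonical_scenario",
    "write_fixture",
]


def simulate_tree(n_tips: int, seed: int, prefix: str = "t",
                  model: str = "yule") -> Tree:
    """Ultrametric pure-birth (Yule) tree scaled to unit height."""
    if model != "yule":
        raise ValueError(f"unknown tree model {model!r}")
    if n_tips < 2:
        raise ValueError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    from skbio import TreeNode

    root = TreeNode(name="root", length=0.0)
    first = [TreeNode(length=0.0), TreeNode(length=0.0)]
    root.extend(first)
    active = [(c, 0.0) for c in first]  # root split defines time zero
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node, birth = active.pop(int(rng.integers(k)))
        node.length = t - birth
        left = TreeNode(length=0.0)
        right = TreeNode(length=0.0)
        node.extend([left, right])
        active.extend([(left, t), (right, t)])
    t_end = t + rng.exponential(1.0 / n_tips)
    for i, (node, birth) in enumerate(active):
        node.length = t_end - birth
        node.name = f"{prefix}{i + 1:02d}"
    # rescale to unit height
    for node in root.traverse(include_self=False):
        node.length = (node.length or 0.0) / t_end
    n_internal = 0
    for node in root.non_tips(include_self=True):
        if node.name is None:
            node.name = f"_n{n_internal}"
            n_internal += 1
    return root


@dataclass
class SimulationScenario:
    """Study conditions for binary cophylogenetic simulations.

    Defaults encode the canonical validation scenario: 12 hosts x 15
    microbes x 3 samples per host, a dominant cophylogeny variance of 4
    against 0.25 for every other term on the logit scale, intercept and
    depth slope of 0, and lognormal sequencing depths around 14,000 reads.
    """

    host_n_tips: int = 12
    microbe_n_tips: int = 15
    samples_per_host: int = 3
    n_areas: int = 3
    variances: dict = field(default_factory=lambda: {
        name: (4.0 if name == "hostphylo_x_microbephylo" else 0.25)
        for name in TERM_NAMES})
    intercept: float = 0.0
    depth_coef: float = 0.0
    depth_log_mean: float = math.log(14_000.0)
    depth_log_sd: float = 0.5
    count_dispersion: float = 0.5
    family_name: str = "familyA"
    compartment: str = "tissue"
    seed: int = 42

    def __post_init__(self):
        unknown = set(self.variances) - set(TERM_NAMES)
        if unknown:
            raise ValueError(f"unknown variance terms: {sorted(unknown)}")
        if any(v < 0 for v in self.variances.values()):
            raise ValueError("variances must be >= 0")
        if self.host_n_tips < 2 or self.microbe_n_tips < 2:
            raise ValueError("trees need >= 2 tips")

    def true_iccs(self) -> dict:
        total = (sum(self.variances.values()) + RESIDUAL_VARIANCE
                 + LINK_VARIANCE)
        return {k: v / total for k, v in self.variances.items()}


@dataclass
class SimulationTruth:
    """Realized effects and exact ICCs implied by the generating variances."""

    effects: dict
    true_iccs: dict
    probabilities: np.ndarray  # samples x microbes
    host_tree: Tree = None
    microbe_tree: Tree = None


def recovery_scenario(**overrides) -> SimulationScenario:
    """Dominant-cophylogeny scenario (variance 4 vs 0.25 elsewhere)."""
    return replace(SimulationScenario(), **overrides)


def null_scenario(**overrides) -> SimulationScenario:
    """All structured variances zero; occurrence driven by intercept only."""
    sc = SimulationScenario(variances={name: 0.0 for name in TERM_NAMES})
    return replace(sc, **overrides)


def canonical_scenario() -> SimulationScenario:
    """The small fixture scenario used throughout the test suite."""
    return SimulationScenario()


def _mvn(rng, cov_chol, sigma2):
    return math.sqrt(sigma2) * (cov_chol @ rng.standard_normal(
        cov_chol.shape[0]))


def simulate_cophylo_dataset(scenario: SimulationScenario,
                             seed: int | None = None,
                             ) -> tuple[FeatureTable, SimulationTruth]:
    """Draw a binary-occurrence dataset from the cophylogenetic GLMM.

    Latent logits are the intercept plus depth effect plus one draw per
    structured term from N(0, sigma2_k V_k); occurrence is Bernoulli and a
    truncated-negative-binomial count layer sits on top.  Deterministic
    given the seed.
    """
    if seed is None:
        seed = scenario.seed
    ss = np.random.SeedSequence(seed)
    s_host, s_microbe, s_main = [int(s.generate_state(1)[0] & 0x7FFFFFFF)
                                 for s in ss.spawn(3)]
    host_tree = simulate_tree(scenario.host_n_tips, s_host, prefix="h")
    microbe_tree = simulate_tree(scenario.microbe_n_tips, s_microbe,
                                 prefix="m")
    rng = np.random.default_rng(s_main)

    hosts = tip_labels(host_tree)
    microbes = tip_labels(microbe_tree)
    n_h, n_m = len(hosts), len(microbes)
    A_h = standardize_covariance(phylo_covariance(host_tree)).values
    A_m = standardize_covariance(phylo_covariance(microbe_tree)).values
    jit = 1e-8
    L_h = np.linalg.cholesky(A_h + jit * np.eye(n_h))
    L_m = np.linalg.cholesky(A_m + jit * np.eye(n_m))
    L_hm = np.kron(L_h, L_m)  # chol(A (x) B) = chol(A) (x) chol(B)

    n_s = n_h * scenario.samples_per_host
    sample_host = np.repeat(np.arange(n_h), scenario.samples_per_host)
    sample_area = rng.integers(scenario.n_areas, size=n_s)
    depths = np.maximum(rng.lognormal(scenario.depth_log_mean,
                                      scenario.depth_log_sd, n_s), 10
                        ).astype(np.int64)

    chols = {
        "host_phylo": (L_h, np.arange(n_h)),
        "host_id": (np.eye(n_h), np.arange(n_h)),
        "microbe_phylo": (L_m, None),
        "microbe_id": (np.eye(n_m), None),
        "hostphylo_x_microbephylo": (L_hm, None),
        "hostphylo_x_microbeid": (np.kron(L_h, np.eye(n_m)), None),
        "hostid_x_microbephylo": (np.kron(np.eye(n_h), L_m), None),
        "hostid_x_microbeid": (np.eye(n_h * n_m), None),
        "area_x_microbeid": (np.eye(scenario.n_areas * n_m), None),
    }

    eta = np.full((n_s, n_m), scenario.intercept, dtype=float)
    eta += scenario.depth_coef * np.log(depths)[:, None]
    effects = {}
    for name in TERM_NAMES:
        sigma2 = scenario.variances[name]
        L, _ = chols[name]
        u = _mvn(rng, L, sigma2) if sigma2 > 0 else np.zeros(L.shape[0])
        effects[name] = u
        if name in ("host_phylo", "host_id"):
            eta += u[sample_host][:, None]
        elif name in ("microbe_phylo", "microbe_id"):
            eta += u[None, :]
        elif name == "area_x_microbeid":
            eta += u.reshape(scenario.n_areas, n_m)[sample_area]
        else:
            eta += u.reshape(n_h, n_m)[sample_host]

    prob = expit(eta)
    occ = rng.random((n_s, n_m)) < prob
    mu = depths[:, None] / n_m
    r = scenario.count_dispersion
    nb = rng.negative_binomial(r, r / (r + mu), size=(n_s, n_m))
    counts = occ * (1 + nb)

    sample_ids = [f"s{i + 1:03d}" for i in range(n_s)]
    metadata = pd.DataFrame({
        "host": [hosts[h] for h in sample_host],
        "area": [f"area{a + 1}" for a in sample_area],
        "compartment": scenario.compartment,
    }, index=sample_ids)
    taxonomy = pd.Series(
        {m: ("Bacteria;phylumA;classA;orderA;"
             f"{scenario.family_name};genus_{m};") for m in microbes})
    table = FeatureTable(
        pd.DataFrame(counts.T.astype(np.int64), index=microbes,
                     columns=sample_ids),
        metadata=metadata, taxonomy=taxonomy)
    truth = SimulationTruth(effects, scenario.true_iccs(), prob,
                            host_tree, microbe_tree)
    return table, truth


def simulate_phylosymbiosis_table(host_tree: Tree, n_features: int = 50,
                                  brownian_sigma: float = 1.0,
                                  noise_sd: float = 0.1,
                                  n_reps_per_tip: int = 2,
                                  depth: int = 1000,
                                  seed: int = 0,
                                  compartment: str = "tissue",
                                  ) -> FeatureTable:
    """Count table whose composition tracks the host phylogeny.

    Per feature, log-weights evolve by Brownian motion on the host tree
    (variance ``brownian_sigma`` per unit branch); per sample, counts are
    multinomial over softmax(weights + iid noise).  ``brownian_sigma = 0``
    removes all phylogenetic signal.
    """
    if n_features < 2:
        raise ValueError("need >= 2 features")
    rng = np.random.default_rng(seed)
    tips = tip_labels(host_tree)
    n_t = len(tips)
    C = standardize_covariance(phylo_covariance(host_tree)).values
    L = np.linalg.cholesky(C + 1e-8 * np.eye(n_t))
    W = brownian_sigma * (L @ rng.standard_normal((n_t, n_features)))

    rows, hosts_col, sample_ids = [], [], []
    for i, tip in enumerate(tips):
        for r in range(n_reps_per_tip):
            logits = W[i] + noise_sd * rng.standard_normal(n_features)
            p = np.exp(logits - logits.max())
            p /= p.sum()
            rows.append(rng.multinomial(depth, p))
            hosts_col.append(tip)
            sample_ids.append(f"{tip}_r{r + 1}")
    features = [f"f{j + 1:03d}" for j in range(n_features)]
    counts = pd.DataFrame(np.array(rows).T.astype(np.int64),
                          index=features, columns=sample_ids)
    metadata = pd.DataFrame({"host": hosts_col,
                             "compartment": compartment},
                            index=sample_ids)
    return FeatureTable(counts, metadata=metadata)


def simulate_richness_trait(host_tree: Tree, brownian_sigma: float = 1.0,
                            noise_sd: float = 0.1,
                            seed: int = 0) -> pd.Series:
    """Brownian per-tip trait plus iid noise (a richness analog)."""
    rng = np.random.default_rng(seed)
    tips = tip_labels(host_tree)
    C = standardize_covariance(phylo_covariance(host_tree)).values
    L = np.linalg.cholesky(C + 1e-8 * np.eye(len(tips)))
    z = brownian_sigma * (L @ rng.standard_normal(len(tips)))
    z = z + noise_sd * rng.standard_normal(len(tips))
    return pd.Series(z, index=tips, name="trait")


def simulate_genus_table(host_tree: Tree, n_genera: int = 20,
                         samples_per_host: int = 3, n_areas: int = 3,
                         slopes: np.ndarray | None = None,
                         covariate_names: tuple = ("latitude",),
                         var_sample: float = 0.05, var_area: float = 0.05,
                         var_hostphylo: float = 0.1, var_hostid: float = 0.1,
                         resid_sd: float = 0.3,
                         depth_log_mean: float = math.log(14_000.0),
                         depth_log_sd: float = 0.5,
                         seed: int = 0) -> tuple[FeatureTable, dict]:
    """Poisson genus-level table with known per-genus covariate slopes.

    ``slopes`` is (n_genera x n_covariates); None means all-null.  Returns
    the table (metadata includes standardized covariates, host and area)
    and a truth dict with the slopes and realized effects.
    """
    rng = np.random.default_rng(seed)
    tips = tip_labels(host_tree)
    n_h = len(tips)
    n_s = n_h * samples_per_host
    n_c = len(covariate_names)
    if slopes is None:
        slopes = np.zeros((n_genera, n_c))
    slopes = np.asarray(slopes, dtype=float)

    sample_host = np.repeat(np.arange(n_h), samples_per_host)
    sample_area = rng.integers(n_areas, size=n_s)
    covs = rng.standard_normal((n_s, n_c))
    depths = np.maximum(rng.lognormal(depth_log_mean, depth_log_sd, n_s),
                        100).astype(np.int64)

    C = standardize_covariance(phylo_covariance(host_tree)).values
    L = np.linalg.cholesky(C + 1e-8 * np.eye(n_h))
    base = -math.log(n_genera) + 0.4 * rng.standard_normal(n_genera)
    u_s = math.sqrt(var_sample) * rng.standard_normal(n_s)
    v_ag = math.sqrt(var_area) * rng.standard_normal((n_areas, n_genera))
    w_hg = math.sqrt(var_hostphylo) * (
        L @ rng.standard_normal((n_h, n_genera)))
    q_hg = math.sqrt(var_hostid) * rng.standard_normal((n_h, n_genera))
    eps = resid_sd * rng.standard_normal((n_s, n_genera))

    log_mu = (np.log(depths)[:, None] + base[None, :]
              + covs @ slopes.T + u_s[:, None]
              + v_ag[sample_area] + w_hg[sample_host] + q_hg[sample_host]
              + eps)
    counts = rng.poisson(np.exp(log_mu))

    sample_ids = [f"s{i + 1:03d}" for i in range(n_s)]
    genera = [f"genus{g + 1:02d}" for g in range(n_genera)]
    md = pd.DataFrame({
        "host": [tips[h] for h in sample_host],
        "area": [f"area{a + 1}" for a in sample_area],
    }, index=sample_ids)
    for j, name in enumerate(covariate_names):
        md[name] = covs[:, j]
    table = FeatureTable(pd.DataFrame(counts.T.astype(np.int64),
                                      index=genera, columns=sample_ids),
                         metadata=md)
    truth = {"slopes": slopes, "base": base, "host_tree": host_tree,
             "covariate_names": covariate_names}
    return table, truth


def write_fixture(outdir, scenario: SimulationScenario | None = None,
                  null_family: bool = True) -> dict:
    """Write the canonical fixture scenario to disk as TSV/newick files.

    The table contains the scenario's family (cophylogeny variance
    injected) and, by default, a second all-null family on its own microbe
    tree, so the end-to-end pipeline can be checked for both detection and
    calibration.  Returns the paths written.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if scenario is None:
        scenario = canonical_scenario()
    tbl_a, truth_a = simulate_cophylo_dataset(scenario)
    parts = [tbl_a]
    trees = {"familyA": truth_a.microbe_tree}
    if null_family:
        sc_b = null_scenario(seed=scenario.seed + 1,
                             family_name="familyB",
                             host_n_tips=scenario.host_n_tips,
                             microbe_n_tips=scenario.microbe_n_tips,
                             samples_per_host=scenario.samples_per_host)
        tbl_b, truth_b = simulate_cophylo_dataset(sc_b)
        # align family B onto family A's samples/hosts; occurrence pattern
        # of B carries no structure so the relabeling is harmless
        tbl_b = FeatureTable(
            tbl_b.counts.rename(
                columns=dict(zip(tbl_b.sample_ids, tbl_a.sample_ids)),
                index=lambda m: f"B_{m}"),
            metadata=tbl_a.metadata,
            taxonomy=pd.Series({f"B_{m}": ("Bacteria;phylumA;classA;orderA;"
                                           f"familyB;genus_{m};")
                                for m in tbl_b.feature_ids}))
        mt = truth_b.microbe_tree
        for tip in mt.tips():
            tip.name = f"B_{tip.name}"
        trees["familyB"] = mt
        parts.append(tbl_b)

    counts = pd.concat([p.counts for p in parts])
    taxonomy = pd.concat([p.taxonomy for p in parts])
    table = FeatureTable(counts, metadata=tbl_a.metadata, taxonomy=taxonomy)

    paths = {}
    paths["table"] = outdir / "feature_table.tsv"
    out = table.counts.copy()
    out["taxonomy"] = table.taxonomy
    out.index.name = "#OTU ID"
    out.to_csv(paths["table"], sep="\t")
    paths["metadata"] = outdir / "metadata.tsv"
    md = table.metadata.copy()
    md.index.name = "#SampleID"
    md.to_csv(paths["metadata"], sep="\t")
    paths["host_tree"] = outdir / "host_tree.nwk"
    paths["host_tree"].write_text(write_newick(truth_a.host_tree) + "\n")
    merged = _merge_family_trees(trees)
    paths["microbe_tree"] = outdir / "microbe_tree.nwk"
    paths["microbe_tree"].write_text(write_newick(merged) + "\n")
    return paths


def write_phylosym_fixture(outdir, n_tips: int = 32, seed: int = 7,
                           depth: int = 2000) -> dict:
    """Write a two-compartment phylosymbiosis fixture.

    The tissue-analog compartment carries a strong Brownian host signal
    (sigma 1), the mucus-analog a weak one (sigma 0.1, noisier), matching
    the qualitative contrast the screen is meant to detect.  Metadata
    includes host, compartment, area, latitude and relative colony size so
    the PERMANOVA factor screen has factors to test.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    host_tree = simulate_tree(n_tips, seed, prefix="h")
    rng = np.random.default_rng(seed + 10)
    parts = []
    for comp, sigma, noise, sub_seed in [("tissue", 1.0, 0.1, seed + 1),
                                         ("mucus", 0.1, 0.5, seed + 2)]:
        # enough features that rarefied richness and binary overlap vary
        t = simulate_phylosymbiosis_table(
            host_tree, n_features=150, brownian_sigma=sigma,
            noise_sd=noise, n_reps_per_tip=2, depth=depth,
            seed=sub_seed, compartment=comp)
        t = FeatureTable(
            t.counts.rename(columns=lambda s: f"{s}_{comp[0]}"),
            metadata=t.metadata.rename(index=lambda s: f"{s}_{comp[0]}"))
        parts.append(t)
    counts = pd.concat([p.counts for p in parts], axis=1)
    md = pd.concat([p.metadata for p in parts])
    n_s = len(md)
    area = rng.integers(3, size=n_s)
    md["area"] = [f"area{a + 1}" for a in area]
    md["latitude"] = np.round(-10.0 - 4.0 * area
                              + rng.normal(0, 1, n_s), 3)
    md["colony_size"] = np.round(rng.uniform(0.1, 1.0, n_s), 3)

    paths = {}
    paths["table"] = outdir / "phylosym_table.tsv"
    out = counts.copy()
    out.index.name = "#OTU ID"
    out.to_csv(paths["table"], sep="\t")
    paths["metadata"] = outdir / "phylosym_metadata.tsv"
    md.index.name = "#SampleID"
    md.to_csv(paths["metadata"], sep="\t")
    paths["host_tree"] = outdir / "phylosym_host_tree.nwk"
    paths["host_tree"].write_text(write_newick(host_tree) + "\n")
    return paths


def _merge_family_trees(trees: dict) -> Tree:
    """Join per-family microbe trees under a common root."""
    from skbio import TreeNode

    if len(trees) == 1:
        return next(iter(trees.values()))
    root = TreeNode(name="root", length=0.0)
    for name, tr in trees.items():
        tr.length = 1.0  # deep stem between families
        root.append(tr)
    return root
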