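"""End-to-end orchestration: phylosymbiosis screen and cophylogeny scan.

``run_phylosymbiosis`` takes a feature table, sample metadata and a host
tree and produces, per anatomical compartment: rarefied beta-diversity
matrices, Mantel tests of community dissimilarity against host phylogenetic
distance, Mantel correlograms over phylogenetic distance classes, a Moran's
I correlogram of richness, and a single-factor PERMANOVA screen with
adjusted R-squared, Bonferroni correction and column Z-scores.

``run_cophylogeny`` gates microbial families on prevalence, builds the
binary cophylogenetic design for each qualifying family x compartment, fits
the GLMM and writes ICC-based significance calls.

Every run writes a JSON manifest (config hash, seed, package versions) and
is byte-identical given the same inputs, config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import alpha_diversity_table, beta_matrix
from .glmm import GlmmConfig, build_cophylo_design, call_significance, \
    fit_binary_glmm
from .phylo import cophenetic_distances, parse_newick
from .stats import (average_by_host, bonferroni_adjust,
                    build_distance_classes, expand_host_distance, mantel,
                    mantel_correlogram, permanova, phylo_correlogram,
                    sturges_classes, zscore_columns)
from .tables import (UNKNOWN, FeatureTable, filter_samples_by_depth,
                     rarefy, read_metadata_tsv, read_table_tsv)

__all__ = ["RunConfig", "run_phylosymbiosis", "run_cophylogeny"]

log = logging.getLogger("coralsym")


@dataclass
class RunConfig:
    """Configuration for a pipeline run; defaults follow the canonical
    protocol (rarefaction to 1000 reads, 50% prevalence gate, relative
    abundance cut 1e-4, 999 permutations, 11 distance classes)."""

    table: str = ""
    metadata: str = ""
    host_tree: str = ""
    microbe_tree: str = ""
    output_dir: str = "results"
    seed: int = 0

    compartment_column: str = "compartment"
    host_column: str = "host"
    area_column: str = "area"
    compartments: list = None

    rarefaction_depth: int = 1000
    min_sample_depth: int = 1000       # strictly-greater-than filter
    cophylo_min_retained: int = 10     # inclusive (>= 10 after merge)
    prevalence_threshold: float = 0.5
    rel_cut: float = 1e-4
    metrics: list = field(default_factory=lambda: [
        "bray_curtis", "binary_jaccard", "unweighted_unifrac",
        "weighted_unifrac"])
    permanova_metric: str = "weighted_unifrac"
    factors: list = field(default_factory=list)
    n_perm: int = 999
    n_classes: int = 11
    singleton_threshold: float = None
    glmm: dict = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        return cls(**doc)

    def glmm_config(self, seed: int) -> GlmmConfig:
        return GlmmConfig(seed=seed, **self.glmm)

    def config_hash(self) -> str:
        doc = asdict(self)
        doc.pop("output_dir", None)  # results must not depend on location
        blob = json.dumps(doc, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _check_inputs(cfg: RunConfig, need_microbe_tree: bool) -> None:
    paths = {"table": cfg.table, "metadata": cfg.metadata,
             "host_tree": cfg.host_tree}
    if need_microbe_tree:
        paths["microbe_tree"] = cfg.microbe_tree
    missing = {k: v for k, v in paths.items() if not Path(str(v)).exists()}
    if missing:
        raise FileNotFoundError(
            "missing input files: "
            + ", ".join(f"{k}={v!r}" for k, v in missing.items()))


def _load(cfg: RunConfig):
    table = read_table_tsv(cfg.table)
    md = read_metadata_tsv(cfg.metadata)
    table = FeatureTable(table.counts, metadata=md, taxonomy=table.taxonomy)
    host_tree = parse_newick(Path(cfg.host_tree).read_text())
    return table, host_tree


def _seed_stream(seed: int):
    """Deterministic stream of independent 31-bit task seeds."""
    state = np.random.SeedSequence(seed).generate_state(4096)
    return iter(int(s & 0x7FFFFFFF) for s in state)


def _manifest(cfg: RunConfig, outdir: Path, kind: str) -> None:
    import scipy
    import skbio

    config = asdict(cfg)
    config.pop("output_dir", None)
    doc = {
        "kind": kind,
        "coralsym": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-bio": skbio.__version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": config,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(doc, indent=2, sort_keys=True, default=str) + "\n")


def _compartments(table: FeatureTable, cfg: RunConfig) -> list[str]:
    col = cfg.compartment_column
    if cfg.compartments:
        return list(cfg.compartments)
    if col not in table.metadata.columns:
        return ["all"]
    levels = [c for c in pd.unique(table.metadata[col])
              if c not in (UNKNOWN, "reference")]
    return levels


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_phylosymbiosis(cfg: RunConfig) -> dict:
    """Phylosymbiosis screen per compartment; returns the paths written."""
    _check_inputs(cfg, need_microbe_tree=False)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, host_tree = _load(cfg)
    microbe_tree = None
    if cfg.microbe_tree and Path(cfg.microbe_tree).exists():
        microbe_tree = parse_newick(Path(cfg.microbe_tree).read_text())
    metrics = list(cfg.metrics)
    if microbe_tree is None:
        dropped = [m for m in metrics if m.endswith("unifrac")]
        if dropped:
            log.warning("no microbe tree supplied; skipping %s", dropped)
        metrics = [m for m in metrics if not m.endswith("unifrac")]
    seeds = _seed_stream(cfg.seed)
    dhost_tips = cophenetic_distances(host_tree)

    mantel_rows, perm_rows, paths = [], [], {}
    for comp in _compartments(table, cfg):
        if comp == "all":
            sub = table
        else:
            keep = table.metadata[cfg.compartment_column] == comp
            sub = table.select_samples(table.counts.columns[keep])
        sub = rarefy(filter_samples_by_depth(sub, 0),
                     cfg.rarefaction_depth, next(seeds))
        if sub.counts.shape[1] < 8:
            log.warning("compartment %s has <8 samples after rarefaction; "
                        "skipped", comp)
            continue
        host_of = sub.metadata[cfg.host_column]
        dhost = expand_host_distance(dhost_tips, host_of)
        classes = build_distance_classes(
            dhost, n_classes=cfg.n_classes,
            singleton_threshold=cfg.singleton_threshold)

        for metric in metrics:
            bm = beta_matrix(sub, metric, tree=microbe_tree)
            p = outdir / f"beta_{comp}_{metric}.tsv"
            pd.DataFrame(bm.data, index=bm.ids, columns=bm.ids).to_csv(
                p, sep="\t", float_format="%.10g")
            paths[p.name] = p
            seed_m, seed_c = next(seeds), next(seeds)
            try:
                mr = mantel(bm, dhost, n_perm=cfg.n_perm, seed=seed_m)
                mantel_rows.append((comp, metric, mr.r, mr.p, mr.n,
                                    mr.n_perm))
                cg = mantel_correlogram(bm, classes, n_perm=cfg.n_perm,
                                        seed=seed_c)
            except ValueError as exc:
                log.warning("%s in %s degenerate, skipped: %s", metric,
                            comp, exc)
                mantel_rows.append((comp, metric, np.nan, np.nan,
                                    bm.shape[0], cfg.n_perm))
                continue
            p = outdir / f"correlogram_{comp}_{metric}.tsv"
            _write_tsv(cg, p)
            paths[p.name] = p

        # richness correlogram on per-host-tip averages
        alpha = alpha_diversity_table(sub)
        trait = average_by_host(alpha["observed_features"], host_of)
        used = [h for h in dhost_tips.ids if h in trait.index]
        dsub = dhost_tips.filter(used)
        # Sturges on the number of tips for the univariate correlogram,
        # capped by the number of distinct distances
        n_distinct = len(np.unique(np.round(dsub.condensed_form(), 9)))
        ncl = min(sturges_classes(len(used)), max(2, n_distinct - 1))
        tip_classes = build_distance_classes(
            dsub, n_classes=ncl,
            singleton_threshold=cfg.singleton_threshold)
        try:
            rg = phylo_correlogram(trait, tip_classes, n_perm=cfg.n_perm,
                                   seed=next(seeds))
        except ValueError as exc:
            log.warning("richness correlogram in %s skipped: %s", comp,
                        exc)
        else:
            p = outdir / f"richness_correlogram_{comp}.tsv"
            _write_tsv(rg, p)
            paths[p.name] = p

        # PERMANOVA factor screen
        perm_metric = cfg.permanova_metric
        if perm_metric.endswith("unifrac") and microbe_tree is None:
            perm_metric = metrics[0]
            log.warning("no microbe tree; PERMANOVA screen uses %s",
                        perm_metric)
        bm = beta_matrix(sub, perm_metric, tree=microbe_tree)
        factors = cfg.factors or [
            c for c in sub.metadata.columns
            if c != cfg.compartment_column]
        for factor in factors:
            vals = sub.metadata[factor]
            if (vals.astype(str) == UNKNOWN).all():
                log.warning("factor %s all Unknown in %s; skipped",
                            factor, comp)
                continue
            try:
                pr = permanova(bm, vals, n_perm=cfg.n_perm,
                               seed=next(seeds), factor_name=factor)
            except ValueError as exc:
                log.warning("factor %s in %s skipped: %s", factor, comp, exc)
                continue
            perm_rows.append((factor, comp, pr.r2, pr.adjusted_r2, pr.p,
                              pr.n_samples, pr.df))

    mdf = pd.DataFrame(mantel_rows, columns=[
        "compartment", "metric", "r", "p", "n_samples", "n_perm"])
    p = outdir / "mantel_results.tsv"
    _write_tsv(mdf, p)
    paths[p.name] = p

    pdf = pd.DataFrame(perm_rows, columns=[
        "factor", "compartment", "r2", "adjusted_r2", "p", "n_samples",
        "df"])
    if len(pdf):
        pdf["p_bonferroni"] = bonferroni_adjust(pdf["p"], m=len(pdf))
        zmat = zscore_columns(
            pdf.pivot(index="compartment", columns="factor",
                      values="adjusted_r2"))
        p = outdir / "permanova_zscores.tsv"
        zmat.to_csv(p, sep="\t", float_format="%.10g")
        paths[p.name] = p
    p = outdir / "permanova_screen.tsv"
    _write_tsv(pdf, p)
    paths[p.name] = p
    _manifest(cfg, outdir, "phylosymbiosis")
    return paths


def prevalent_groups(table: FeatureTable, rank_value: str = "family",
                     threshold: float = 0.5,
                     compartment_column: str = "compartment",
                     ) -> dict[str, list]:
    """Families (groups at a taxonomy rank) present in more than
    ``threshold`` of samples in at least one compartment.

    Presence of a group in a sample means any member feature has count > 0.
    Returns group -> member feature ids.
    """
    from .tables import RANKS, _lineage_levels

    depth = RANKS.index(rank_value)
    members: dict[str, list] = {}
    for fid in table.feature_ids:
        levels = _lineage_levels(table.taxonomy.loc[fid])
        name = levels[depth] if len(levels) > depth and levels[depth] \
            else "unclassified"
        members.setdefault(name, []).append(fid)

    md = table.metadata
    comps = (pd.unique(md[compartment_column])
             if compartment_column in md.columns else ["all"])
    keep = {}
    for name, fids in members.items():
        present = (table.counts.loc[fids] > 0).any(axis=0)
        for comp in comps:
            if comp == UNKNOWN:
                continue
            sel = (md[compartment_column] == comp
                   if compartment_column in md.columns
                   else pd.Series(True, index=md.index))
            if sel.sum() and present[sel.index[sel]].mean() > threshold:
                keep[name] = fids
                break
    return keep


def run_cophylogeny(cfg: RunConfig) -> pd.DataFrame:
    """Cophylogenetic GLMM scan over prevalent families x compartments.

    Writes ``cophylo_calls.tsv`` with one row per (family, compartment,
    term): posterior-mean ICC, 95% HPD lower bound, ESS, the significance
    call (lower bound > 0.01) and the fit's convergence flag (all ESS >
    200).  Calls from non-converged fits are masked to False.
    """
    _check_inputs(cfg, need_microbe_tree=True)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    table, host_tree = _load(cfg)
    microbe_tree = parse_newick(Path(cfg.microbe_tree).read_text())
    seeds = _seed_stream(cfg.seed + 1)

    table = filter_samples_by_depth(table, cfg.min_sample_depth)
    groups = prevalent_groups(table, "family", cfg.prevalence_threshold,
                              cfg.compartment_column)
    microbe_tips = {t.name for t in microbe_tree.tips()}

    rows = []
    for comp in _compartments(table, cfg):
        if comp == "all":
            sub_c = table
        else:
            keep = table.metadata[cfg.compartment_column] == comp
            sub_c = table.select_samples(table.counts.columns[keep])
        for family in sorted(groups):
            fids = [f for f in groups[family] if f in microbe_tips]
            if len(fids) < 2:
                log.warning("family %s has <2 features on the tree; "
                            "skipped", family)
                continue
            sub = sub_c.select_features(fids)
            # post-merge depth filter: keep samples retaining >= threshold
            sub = filter_samples_by_depth(sub, cfg.cophylo_min_retained - 1)
            if sub.counts.shape[1] < 4:
                log.warning("family %s in %s has <4 usable samples; "
                            "skipped", family, comp)
                continue
            design = build_cophylo_design(
                sub, host_tree, microbe_tree,
                host_column=cfg.host_column, area_column=cfg.area_column)
            post = fit_binary_glmm(design, cfg.glmm_config(next(seeds)))
            calls = call_significance(post)
            for term, row in calls.iterrows():
                rows.append((family, comp, term, row.icc_mean,
                             row.icc_lower, row.ess,
                             bool(row.significant and row.converged),
                             bool(row.converged)))
    out = pd.DataFrame(rows, columns=[
        "group", "compartment", "term", "icc_mean", "icc_lower", "ess",
        "significant", "converged"])
    _write_tsv(out, outdir / "cophylo_calls.tsv")
    _manifest(cfg, outdir, "cophylogeny")
    return out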