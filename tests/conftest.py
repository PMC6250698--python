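"""Shared fixtures.

The expensive MCMC fixtures (null-calibration fits, dominant-term recovery
fits, the end-to-end pipeline run) are session-scoped so the module-level
example tests and the acceptance tests share one computation.
"""

import pytest

from coralsym.glmm import (GlmmConfig, build_cophylo_design,
                           call_significance, fit_binary_glmm)
from coralsym.phylo import parse_newick
from coralsym.simulate import (canonical_scenario, null_scenario,
                               recovery_scenario, simulate_cophylo_dataset,
                               simulate_tree, write_fixture)

N_CALIBRATION_FITS = 10


@pytest.fixture(scope="session")
def worked_tree():
    """The 3-tip tree used for hand-computed diversity values."""
    return parse_newick("((A:1,B:1):0.5,C:2);")


@pytest.fixture(scope="session")
def host_tree_32():
    return simulate_tree(32, seed=3, prefix="h")


@pytest.fixture(scope="session")
def null_binary_fits():
    """Ten 20k-iteration fits to all-null 12x15x3 occurrence data."""
    from coralsym.tables import filter_samples_by_depth

    out = []
    for i in range(N_CALIBRATION_FITS):
        table, truth = simulate_cophylo_dataset(null_scenario(),
                                                seed=100 + i)
        table = filter_samples_by_depth(table, 0)
        design = build_cophylo_design(table, truth.host_tree,
                                      truth.microbe_tree)
        post = fit_binary_glmm(design, GlmmConfig(
            n_iter=20_000, burn_in=5_000, thin=10, seed=i))
        out.append(call_significance(post))
    return out


@pytest.fixture(scope="session")
def recovery_binary_fits():
    """Ten fits to data with cophylogeny variance 4 vs 0.25 elsewhere."""
    from coralsym.tables import filter_samples_by_depth

    out = []
    for i in range(N_CALIBRATION_FITS):
        table, truth = simulate_cophylo_dataset(recovery_scenario(),
                                                seed=200 + i)
        table = filter_samples_by_depth(table, 0)
        design = build_cophylo_design(table, truth.host_tree,
                                      truth.microbe_tree)
        post = fit_binary_glmm(design, GlmmConfig(
            n_iter=6_000, burn_in=1_500, thin=3, seed=i))
        out.append(call_significance(post))
    return out


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """The bundled synthetic scenario written to disk (trees + table)."""
    outdir = tmp_path_factory.mktemp("fixture")
    return write_fixture(outdir, canonical_scenario())


@pytest.fixture(scope="session")
def cophylo_run(fixture_paths, tmp_path_factory):
    """One end-to-end cophylogeny scan over the bundled fixture."""
    from coralsym.pipeline import RunConfig, run_cophylogeny

    outdir = tmp_path_factory.mktemp("cophylo_out")
    cfg = RunConfig(
        table=str(fixture_paths["table"]),
        metadata=str(fixture_paths["metadata"]),
        host_tree=str(fixture_paths["host_tree"]),
        microbe_tree=str(fixture_paths["microbe_tree"]),
        output_dir=str(outdir), seed=7,
        glmm=dict(n_iter=8_000, burn_in=2_000, thin=4))
    calls = run_cophylogeny(cfg)
    return {"calls": calls, "outdir": outdir, "cfg": cfg}


@pytest.fixture(scope="session")
def null_family_fits(fixture_paths):
    """Ten seeded fits to the fixture's all-null family (familyB)."""
    from coralsym.pipeline import RunConfig, prevalent_groups
    from coralsym.tables import (FeatureTable, filter_samples_by_depth,
                                 read_metadata_tsv, read_table_tsv)

    table = read_table_tsv(fixture_paths["table"])
    md = read_metadata_tsv(fixture_paths["metadata"])
    table = FeatureTable(table.counts, metadata=md, taxonomy=table.taxonomy)
    table = filter_samples_by_depth(table, 1000)
    groups = prevalent_groups(table, "family", 0.5)
    assert "familyB" in groups
    sub = table.select_features(groups["familyB"])
    sub = filter_samples_by_depth(sub, 9)
    host_tree = parse_newick(fixture_paths["host_tree"].read_text())
    microbe_tree = parse_newick(fixture_paths["microbe_tree"].read_text())
    design = build_cophylo_design(sub, host_tree, microbe_tree)
    out = []
    for i in range(N_CALIBRATION_FITS):
        post = fit_binary_glmm(design, GlmmConfig(
            n_iter=3_000, burn_in=750, thin=2, seed=300 + i))
        out.append(call_significance(post))
    return out


@pytest.fixture(scope="session")
def community_null_fits():
    """Ten all-null community count fits (20 genera each)."""
    from coralsym.community import fit_community_count_glmm
    from coralsym.simulate import simulate_genus_table

    tree = simulate_tree(12, seed=5, prefix="h")
    out = []
    for i in range(N_CALIBRATION_FITS):
        table, _ = simulate_genus_table(tree, n_genera=20, seed=400 + i)
        post = fit_community_count_glmm(
            table, ["latitude"], tree,
            GlmmConfig(n_iter=4_000, burn_in=1_000, thin=3, seed=i))
        out.append(post.effect_summary())
    return out
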