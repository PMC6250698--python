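"""Cophylogenetic GLMM scan over the simulated microbial families.

Families present in more than half the samples of a compartment are fitted
with the binary cophylogenetic GLMM (nine structured random effects,
Kronecker host-by-microbe covariances).  The scan writes per-term ICC
summaries and significance calls; the family with injected cophylogeny
variance should carry the top-ranked host-phylogeny-by-microbe-phylogeny
ICC, the null family should stay clean.
Run analysis/01_simulate_data.py first.
"""

from pathlib import Path

from coralsym.pipeline import RunConfig, run_cophylogeny

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "cophylogeny"


def main() -> None:
    cfg = RunConfig(
        table=str(DATA / "feature_table.tsv"),
        metadata=str(DATA / "metadata.tsv"),
        host_tree=str(DATA / "host_tree.nwk"),
        microbe_tree=str(DATA / "microbe_tree.nwk"),
        output_dir=str(OUT), seed=7,
        glmm=dict(n_iter=8_000, burn_in=2_000, thin=4))
    calls = run_cophylogeny(cfg)

    inter = calls[calls.term.str.contains("_x_")]
    print("interaction-term ICC summaries:")
    print(inter.round(3).to_string(index=False))
    top = inter.loc[inter.icc_mean.idxmax()]
    print(f"\ntop-ranked interaction: {top.group} / {top.term} "
          f"(posterior-mean ICC {top.icc_mean:.3f}, "
          f"95% lower bound {top.icc_lower:.3f})")
    flagged = calls[calls.significant]
    if len(flagged):
        print("significant calls (ICC lower bound > 0.01):")
        print(flagged[["group", "compartment", "term", "icc_lower"]]
              .to_string(index=False))
    else:
        print("no term cleared the ICC lower-bound rule at this "
              "simulation size (posterior ranking above is the "
              "informative output)")


if __name__ == "__main__":
    main()
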