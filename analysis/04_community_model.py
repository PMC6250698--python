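"""Genus-level community model: covariate effects with phylogenetic control.

Simulates a genus table in which two genera respond to latitude (slopes
+0.8 and -0.8) on top of sample, area, host-phylogeny and host-identity
random effects, fits the Poisson GLMM with the sample total as offset, and
reports which genus-covariate effects have 95% HPD intervals excluding
zero.  Writes results/community/effects.tsv.
"""

from pathlib import Path

import numpy as np

from coralsym.community import fit_community_count_glmm
from coralsym.glmm import GlmmConfig
from coralsym.simulate import simulate_genus_table, simulate_tree

OUT = Path(__file__).resolve().parents[1] / "results" / "community"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(12, seed=5, prefix="h")
    slopes = np.zeros((20, 1))
    slopes[3, 0] = 0.8
    slopes[11, 0] = -0.8
    table, _ = simulate_genus_table(tree, n_genera=20, slopes=slopes,
                                    seed=9)
    post = fit_community_count_glmm(
        table, ["latitude"], tree,
        GlmmConfig(n_iter=8_000, burn_in=2_000, thin=4, seed=2))
    effects = post.effect_summary()
    effects.to_csv(OUT / "effects.tsv", sep="\t", index=False)

    sig = effects[effects.significant]
    print(f"{len(sig)}/{len(effects)} genus-latitude effects significant "
          "(95% HPD excludes zero):")
    print(sig.round(3).to_string(index=False))
    print("\ninjected truths: genus04 +0.8, genus12 -0.8; "
          "all other genera null")


if __name__ == "__main__":
    main()
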