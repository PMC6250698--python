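"""Generate the synthetic study datasets used by the downstream analyses.

Writes two fixtures under results/data/:

* the cophylogeny fixture — 12 hosts x 3 samples, one 15-variant microbial
  family with cophylogeny variance 4 injected on the logit scale and one
  all-null family, with host and microbe trees; and
* the phylosymbiosis fixture — 32 hosts x 2 samples in two anatomical
  compartments, community composition evolving by Brownian motion on the
  host tree (strong signal in the tissue analog, weak in the mucus analog).
"""

from pathlib import Path

from coralsym.simulate import (canonical_scenario, write_fixture,
                               write_phylosym_fixture)

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sc = canonical_scenario()
    paths = write_fixture(OUT, sc)
    print("cophylogeny fixture "
          f"({sc.host_n_tips} hosts x {sc.samples_per_host} samples, "
          f"{sc.microbe_n_tips} variants/family, "
          f"cophylogeny variance {sc.variances['hostphylo_x_microbephylo']}"
          "):")
    for k, v in paths.items():
        print(f"  {k}: {v}")
    paths = write_phylosym_fixture(OUT, n_tips=32, seed=7)
    print("phylosymbiosis fixture (32 hosts x 2 samples x 2 compartments):")
    for k, v in paths.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
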