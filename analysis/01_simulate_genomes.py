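#!/usr/bin/env python
"""Simulate truth-labelled genomes carrying the stand-in satellite families.

Builds three study genomes and writes each as FASTA plus a truth TSV under
results/genomes/:

* duck-like  — 500 copies of the 190-bp monomer (HaeIII-released), 8%
  per-copy divergence, site conservation 0.9, CpG methylation 0.8, in
  100 kb of random background;
* goose-like — two co-resident HinfI families (101-bp and 192-bp monomers),
  mirroring a screen that yields two prominent bands;
* swan-like  — 300 copies of the 290-bp ApaI monomer, hypermethylated.
"""

import pathlib
import sys

from satarray import TandemArrayModel, get_enzyme, simulate_genome
from satarray.standins import standin_monomers

OUT = pathlib.Path("results/genomes")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    mono = standin_monomers(SEED)
    genomes = {
        "duck_like": ([
            TandemArrayModel(name="APL-HaeIII-like",
                             monomer=mono["APL-HaeIII-like"], copy_number=500,
                             sub_rate=0.08, enzyme=get_enzyme("HaeIII"),
                             site_conservation=0.9, methylation_fraction=0.8),
        ], 100_000),
        "goose_like": ([
            TandemArrayModel(name="AFA-HinfI-S-like",
                             monomer=mono["AFA-HinfI-S-like"], copy_number=400,
                             sub_rate=0.03, enzyme=get_enzyme("HinfI"),
                             site_conservation=0.97,
                             methylation_fraction=0.2),
            TandemArrayModel(name="AFA-HinfI-L-like",
                             monomer=mono["AFA-HinfI-L-like"], copy_number=300,
                             sub_rate=0.03, enzyme=get_enzyme("HinfI"),
                             site_conservation=0.95,
                             methylation_fraction=0.95),
        ], 100_000),
        "swan_like": ([
            TandemArrayModel(name="CCY-ApaI-like",
                             monomer=mono["CCY-ApaI-like"], copy_number=300,
                             sub_rate=0.02, enzyme=get_enzyme("ApaI"),
                             site_conservation=0.95,
                             methylation_fraction=0.95),
        ], 100_000),
    }
    for name, (families, background) in genomes.items():
        g = simulate_genome(families, background, seed=SEED)
        g.write_fasta(OUT / f"{name}.fa")
        g.write_truth(OUT / f"{name}.truth.tsv")
        print(f"{name}: {len(g.sequence):,} bp, {len(g.copies)} repeat copies "
              f"-> {OUT}/{name}.fa")


if __name__ == "__main__":
    main()
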