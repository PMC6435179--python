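#!/usr/bin/env python
"""Multimer-ladder inversion and CpG methylation calls.

For each study genome (rebuilt deterministically with the same models and
seed as step 01, so the per-position methylation mask is available): digest
with the family's releasing enzyme and with the MspI/HpaII isoschizomer
pair, restrict each ladder to probe-hybridizing fragments, classify its
shape, invert the band intensities to a per-junction cleavage probability,
and contrast the isoschizomers into a methylation estimate.  Every estimate
is printed next to the simulator's ground truth.  Writes
results/ladders/ladders.tsv.
"""

import pathlib
import sys
import warnings

import pandas as pd

from satarray import (TandemArrayModel, classify_ladder, digest_fragments,
                      estimate_cleavage, get_enzyme, infer_methylation,
                      ladder_from_lengths, select_hybridizing,
                      simulate_genome)
from satarray.standins import standin_monomers

OUT = pathlib.Path("results/ladders")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0

#: genome -> (probed family, releasing enzyme, truth c, truth m)
CASES = {
    "duck_like": ("APL-HaeIII-like", "HaeIII", 0.9, 0.8),
    "goose_like": ("AFA-HinfI-L-like", "HinfI", 0.95, 0.95),
    "swan_like": ("CCY-ApaI-like", "ApaI", 0.95, 0.95),
}


def genome_models(mono):
    """The same family models and background as analysis step 01."""
    return {
        "duck_like": ([TandemArrayModel(
            name="APL-HaeIII-like", monomer=mono["APL-HaeIII-like"],
            copy_number=500, sub_rate=0.08, enzyme=get_enzyme("HaeIII"),
            site_conservation=0.9, methylation_fraction=0.8)], 100_000),
        "goose_like": ([
            TandemArrayModel(name="AFA-HinfI-S-like",
                             monomer=mono["AFA-HinfI-S-like"], copy_number=400,
                             sub_rate=0.03, enzyme=get_enzyme("HinfI"),
                             site_conservation=0.97, methylation_fraction=0.2),
            TandemArrayModel(name="AFA-HinfI-L-like",
                             monomer=mono["AFA-HinfI-L-like"], copy_number=300,
                             sub_rate=0.03, enzyme=get_enzyme("HinfI"),
                             site_conservation=0.95,
                             methylation_fraction=0.95)], 100_000),
        "swan_like": ([TandemArrayModel(
            name="CCY-ApaI-like", monomer=mono["CCY-ApaI-like"],
            copy_number=300, sub_rate=0.02, enzyme=get_enzyme("ApaI"),
            site_conservation=0.95, methylation_fraction=0.95)], 100_000),
    }


def main() -> None:
    warnings.filterwarnings("ignore")
    OUT.mkdir(parents=True, exist_ok=True)
    mono = standin_monomers(SEED)
    configs = genome_models(mono)
    rows = []
    for genome, (family, enzyme_name, true_c, true_m) in CASES.items():
        families, background = configs[genome]
        g = simulate_genome(families, background, seed=SEED)
        probe = mono[family]
        monomer = len(probe)
        mask = g.methylation_mask()

        frags = select_hybridizing(
            digest_fragments(g.sequence, get_enzyme(enzyme_name), mask), probe)
        obs = ladder_from_lengths([len(f) for f in frags], monomer, k_max=6)
        est = estimate_cleavage(obs)
        shape = classify_ladder(obs)
        rows.append(dict(genome=genome, enzyme=enzyme_name, ladder=shape,
                         c_hat=round(est.c_hat, 3), c_true=true_c,
                         m_hat=None, m_true=None))
        print(f"{genome} / {enzyme_name}: ladder {shape}, "
              f"c = {est.c_hat:.3f} (truth {true_c})")

        msp = select_hybridizing(
            digest_fragments(g.sequence, get_enzyme("MspI"), mask), probe)
        hpa = select_hybridizing(
            digest_fragments(g.sequence, get_enzyme("HpaII"), mask), probe)
        try:
            call = infer_methylation(
                ladder_from_lengths([len(f) for f in msp], monomer, k_max=6),
                ladder_from_lengths([len(f) for f in hpa], monomer, k_max=6))
            rows.append(dict(genome=genome, enzyme="MspI/HpaII",
                             ladder=call.label, c_hat=round(call.c_msp, 3),
                             c_true=true_c, m_hat=round(call.m_hat, 3),
                             m_true=true_m))
            print(f"{genome} / MspI vs HpaII: m = {call.m_hat:.3f} "
                  f"({call.label}; truth {true_m})")
        except Exception as exc:
            print(f"{genome}: methylation call unavailable ({exc})")
    pd.DataFrame(rows).to_csv(OUT / "ladders.tsv", sep="\t", index=False)
    print(f"wrote {OUT}/ladders.tsv")


if __name__ == "__main__":
    main()
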