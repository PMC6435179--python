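#!/usr/bin/env python
"""Dot-matrix structure of the stand-in families: internal units, homology.

Self dot-matrix of the 101-bp monomer (two diverged 42-43-bp internal
units), cross-family comparison of the 190-bp and 192-bp monomers (two
homologous segments), comparison against the RBMII-like relative, and the
centromeric A/T motif scan of all monomers.  Writes results/structure/.
"""

import pathlib
import sys
import warnings

import pandas as pd

from satarray import (cross_family_segments, dot_matrix, internal_repeat_units,
                      scan_cnm_motif, summarize_family)
from satarray.standins import standin_fragment_sets, standin_monomers

OUT = pathlib.Path("results/structure")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    warnings.filterwarnings("ignore")
    OUT.mkdir(parents=True, exist_ok=True)
    mono = standin_monomers(SEED)
    sets = standin_fragment_sets(SEED)
    cons = {fam: summarize_family(frags).consensus
            for fam, frags in sets.items()}

    units = internal_repeat_units(cons["AFA-HinfI-S-like"])
    print(f"AFA-HinfI-S-like internal repeat: "
          f"{units[0]} bp x {units[1]}" if units else "no internal repeat")
    dm = dot_matrix(cons["AFA-HinfI-S-like"], cons["AFA-HinfI-S-like"])
    pd.DataFrame(sorted(dm.hits), columns=["i", "j"]).to_csv(
        OUT / "afa_hinfi_s.self_dotplot.tsv", sep="\t", index=False)

    seg_rows = []
    for b_name, b_seq in (("AFA-HinfI-L-like", cons["AFA-HinfI-L-like"]),
                          ("RBMII-like", mono["RBMII-like"])):
        for s in cross_family_segments(cons["APL-HaeIII-like"], b_seq):
            seg_rows.append(dict(a="APL-HaeIII-like", b=b_name,
                                 a_start=s.a_start, a_end=s.a_end,
                                 b_start=s.b_start, b_end=s.b_end,
                                 identity=round(s.identity, 1)))
            print(f"APL-HaeIII-like {s.a_start}-{s.a_end} ~ {b_name} "
                  f"{s.b_start}-{s.b_end}: {s.identity:.1f}% identity")
    pd.DataFrame(seg_rows).to_csv(OUT / "homology_segments.tsv", sep="\t",
                                  index=False)

    motif_rows = []
    for fam, seq in mono.items():
        for h in scan_cnm_motif(seq):
            motif_rows.append(dict(family=fam, start=h.start, end=h.end,
                                   a_run=h.a_run_length, t_run=h.t_run_length,
                                   spacer=h.spacer_length, order=h.order))
        n = len(scan_cnm_motif(seq))
        print(f"A/T motif in {fam}: {n} hit(s)")
    pd.DataFrame(motif_rows).to_csv(OUT / "at_motifs.tsv", sep="\t",
                                    index=False)
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
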