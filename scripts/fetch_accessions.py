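#!/usr/bin/env python
"""Download the deposited repeat-family records (requires network access).

Fetches the cloned repeat fragments of the four Anseriformes centromeric
families plus the RBMII and ACH-Sau3AI comparison sequences from NCBI
nucleotide (which mirrors DDBJ) and writes one multi-FASTA per family under
data/accessions/.  The characterization pipeline can then be run on the
real records, e.g.:

    satarray characterize --fasta data/accessions/APL-HaeIII.fa \
        --family-name APL-HaeIII

The analysis and test suite do not depend on these files; offline runs use
the synthetic stand-in families instead (satarray.standins).
"""

import pathlib
import sys
import time
import urllib.request

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&rettype=fasta&retmode=text&id={ids}")

FAMILIES = {
    "AFA-HinfI-S": [f"LC4167{i}" for i in range(70, 74)],
    "AFA-HinfI-L": ["LC416774", "LC416775"],
    "CCY-ApaI": [f"LC4167{i}" for i in range(76, 91)],
    "APL-HaeIII": [f"LC4167{i}" for i in range(91, 96)],
    "RBMII": ["X61424", "X61410"],
    "ACH-Sau3AI": ["AB872160"],
}


def main() -> None:
    out_dir = pathlib.Path("data/accessions")
    out_dir.mkdir(parents=True, exist_ok=True)
    for family, accessions in FAMILIES.items():
        url = EFETCH.format(ids=",".join(accessions))
        try:
            with urllib.request.urlopen(url, timeout=30) as response:
                text = response.read().decode()
        except Exception as exc:
            sys.exit(f"download failed for {family}: {exc}\n"
                     "(this script needs network access)")
        path = out_dir / f"{family}.fa"
        path.write_text(text)
        print(f"{family}: {len(accessions)} records -> {path}")
        time.sleep(0.5)  # NCBI rate limit courtesy


if __name__ == "__main__":
    main()
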