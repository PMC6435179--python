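"""Small sequence utilities: alphabets, IUPAC degeneracy, reverse complement."""

from __future__ import annotations

import itertools
import re

DNA = "ACGT"

# IUPAC nucleotide codes -> set of concrete bases
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return not set(seq) - set(DNA)


def validate_dna(seq: str, *, what: str = "sequence") -> str:
    """Return ``seq`` if it is non-empty A/C/G/T, else raise with position info."""
    from satarray.errors import SequenceAlphabetError

    if not seq:
        raise SequenceAlphabetError(f"empty {what}")
    for i, ch in enumerate(seq):
        if ch not in "ACGT":
            raise SequenceAlphabetError(
                f"illegal character {ch!r} at position {i + 1} in {what}"
            )
    return seq


def iupac_to_regex(pattern: str) -> str:
    """Translate an IUPAC pattern into a plain regex character-class pattern."""
    from satarray.errors import EnzymeError

    parts = []
    for ch in pattern:
        try:
            bases = IUPAC[ch]
        except KeyError:
            raise EnzymeError(f"non-IUPAC character {ch!r} in pattern {pattern!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def expand_iupac(pattern: str) -> list[str]:
    """All concrete A/C/G/T words matching an IUPAC pattern (exhaustive)."""
    from satarray.errors import EnzymeError

    pools = []
    for ch in pattern:
        if ch not in IUPAC:
            raise EnzymeError(f"non-IUPAC character {ch!r} in pattern {pattern!r}")
        pools.append(IUPAC[ch])
    return ["".join(w) for w in itertools.product(*pools)]


def find_overlapping(seq: str, regex: str) -> list[int]:
    """0-based start positions of all (possibly overlapping) regex matches."""
    return [m.start() for m in re.finditer(f"(?={regex})", seq)]


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)
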