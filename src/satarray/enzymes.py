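"""Restriction enzyme definitions.

An :class:`Enzyme` is a named recognition site in IUPAC code plus a cut offset
(the caret position in conventional notation, e.g. ``G^ANTC`` for HinfI) and a
methylation-block predicate.  All enzymes in the shipped panel are palindromic,
so a forward-strand scan finds every double-strand cut site.

The methylation-block rule models the classic HpaII/MspI isoschizomer pair:
both recognize CCGG, but HpaII does not cleave when the cytosine of the
internal CpG is methylated, whereas MspI does.  The rule is implemented
generically: a methylation-blocked enzyme skips any site occurrence in which a
methylated C is immediately followed by G within the recognition sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

from satarray.errors import EnzymeError
from satarray.sequtils import IUPAC, iupac_to_regex


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease.

    Parameters
    ----------
    name:
        Conventional enzyme name, e.g. ``"HaeIII"``.
    site:
        Recognition site in IUPAC code, e.g. ``"GGCC"``.
    cut_offset:
        The enzyme cuts after the ``cut_offset``-th base of the site
        (``0 <= cut_offset <= len(site)``); ``GG^CC`` has offset 2.
    methylation_blocked:
        If true, an occurrence is not cleaved when a CpG inside the site
        carries a methylated C (per-position methylation flags are supplied
        to the digestion functions).
    """

    name: str
    site: str
    cut_offset: int
    methylation_blocked: bool = False

    def __post_init__(self) -> None:
        if not self.site:
            raise EnzymeError(f"{self.name}: empty recognition site")
        for ch in self.site:
            if ch not in IUPAC:
                raise EnzymeError(
                    f"{self.name}: non-IUPAC character {ch!r} in site {self.site!r}"
                )
        if not 0 <= self.cut_offset <= len(self.site):
            raise EnzymeError(
                f"{self.name}: cut offset {self.cut_offset} outside site "
                f"of length {len(self.site)}"
            )

    @property
    def regex(self) -> re.Pattern:
        return re.compile(f"(?={iupac_to_regex(self.site)})")

    @classmethod
    def from_caret(cls, name: str, caret_site: str,
                   methylation_blocked: bool = False) -> "Enzyme":
        """Build from caret notation, e.g. ``Enzyme.from_caret("HinfI", "G^ANTC")``."""
        if caret_site.count("^") != 1:
            raise EnzymeError(f"{name}: caret notation needs exactly one '^'")
        offset = caret_site.index("^")
        return cls(name, caret_site.replace("^", ""), offset, methylation_blocked)

    def caret_site(self) -> str:
        return self.site[: self.cut_offset] + "^" + self.site[self.cut_offset:]


def load_enzyme_table(path: str | None = None) -> dict[str, Enzyme]:
    """Load the enzyme panel from a TSV (name, caret site, methylation flag).

    Without a path the packaged default panel (the enzymes used in the
    genomic screens, plus HpaII) is loaded.
    """
    if path is None:
        text = (resources.files("satarray") / "data" / "enzymes.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, Enzyme] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise EnzymeError(f"enzyme table line {lineno}: expected 3 columns")
        name, caret, flag = fields
        if flag not in ("yes", "no"):
            raise EnzymeError(
                f"enzyme table line {lineno}: methylation flag must be yes/no"
            )
        table[name] = Enzyme.from_caret(name, caret, flag == "yes")
    return table


_DEFAULT_TABLE: dict[str, Enzyme] | None = None


def get_enzyme(name: str) -> Enzyme:
    """Look up an enzyme by name in the packaged default panel."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = load_enzyme_table()
    try:
        return _DEFAULT_TABLE[name]
    except KeyError:
        raise EnzymeError(f"unknown enzyme {name!r}") from None
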