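"""In-silico restriction digestion and gel electrophoresis.

Reproduces the experimental screen: digest genomic DNA with a restriction
enzyme (methylation-aware), bin the fragment lengths into a mass-weighted
histogram (the "gel"), and detect prominent bands — the signature of a
tandem repeat monomer.  Fragments from a band can then be "eluted and
cloned" (:func:`extract_band_fragments`) to feed family characterization.

Digestion is linear: the sheared genomic molecule is cut at every unblocked
site, so fragment lengths always sum to the input length.  All panel enzymes
are palindromic, so a forward-strand scan suffices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from satarray.enzymes import Enzyme
from satarray.errors import ProfileError
from satarray.sequtils import validate_dna


def find_sites(sequence: str, enzyme: Enzyme,
               methylation: np.ndarray | None = None) -> list[int]:
    """1-based start positions of all cleavable enzyme sites.

    ``methylation`` is an optional boolean per-position array (0-based) marking
    methylated cytosines.  For a methylation-blocked enzyme (HpaII), a site
    occurrence is skipped when a methylated C immediately followed by G lies
    inside the recognition sequence.
    """
    validate_dna(sequence)
    sites = []
    slen = len(enzyme.site)
    for m in enzyme.regex.finditer(sequence):
        start = m.start()
        if enzyme.methylation_blocked and methylation is not None:
            blocked = any(
                methylation[p] and sequence[p] == "C"
                and p + 1 < len(sequence) and sequence[p + 1] == "G"
                for p in range(start, min(start + slen, len(sequence)))
            )
            if blocked:
                continue
        sites.append(start + 1)
    return sites


@dataclass(frozen=True)
class Fragment:
    """A digestion product: 1-based inclusive genomic interval plus sequence."""

    start: int
    end: int
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start + 1


def _cut_positions(sequence: str, enzyme: Enzyme,
                   methylation: np.ndarray | None) -> list[int]:
    """0-based positions after which the molecule is cut, deduplicated."""
    cuts = {
        (s - 1) + enzyme.cut_offset
        for s in find_sites(sequence, enzyme, methylation)
    }
    # cuts at the very ends produce empty fragments; drop them
    return sorted(c for c in cuts if 0 < c < len(sequence))


def digest_fragments(sequence: str, enzyme: Enzyme,
                     methylation: np.ndarray | None = None) -> list[Fragment]:
    """Digest a linear sequence; fragments returned left to right."""
    cuts = _cut_positions(sequence, enzyme, methylation)
    bounds = [0] + cuts + [len(sequence)]
    return [
        Fragment(a + 1, b, sequence[a:b])
        for a, b in zip(bounds[:-1], bounds[1:])
    ]


def digest(sequence: str, enzyme: Enzyme,
           methylation: np.ndarray | None = None) -> list[int]:
    """Fragment lengths from a complete digest, in genomic order.

    Lengths always sum to ``len(sequence)``.
    """
    cuts = _cut_positions(sequence, enzyme, methylation)
    bounds = [0] + cuts + [len(sequence)]
    return [b - a for a, b in zip(bounds[:-1], bounds[1:])]


@dataclass(frozen=True)
class Band:
    """A prominent gel band: bin center (bp), mass, prominence over median."""

    center: float
    bin_start: int
    bin_end: int
    mass: int
    prominence: float


@dataclass(frozen=True)
class GelProfile:
    """Mass-weighted fragment-length histogram with detected bands.

    ``mass[b]`` is the total nucleotide mass (sum of fragment lengths) of
    fragments whose length falls in bin ``b`` (bins of ``bin_width`` bp,
    bin ``b`` covering lengths ``[b*bin_width + 1, (b+1)*bin_width]``).
    Band detection mimics spotting prominent bands on an ethidium-stained
    gel: local maxima whose mass exceeds the median non-empty bin mass by a
    prominence factor.
    """

    bin_width: int
    mass: dict[int, int]
    bands: tuple[Band, ...]

    @property
    def total_mass(self) -> int:
        return sum(self.mass.values())

    def to_rows(self) -> list[tuple[int, int, int, bool]]:
        """(bin_start, bin_end, mass, is_band) rows, ascending."""
        band_bins = {self._bin_of(b.center) for b in self.bands}
        return [
            (b * self.bin_width + 1, (b + 1) * self.bin_width, m, b in band_bins)
            for b, m in sorted(self.mass.items())
        ]

    def _bin_of(self, length: float) -> int:
        return int((length - 1) // self.bin_width)


def gel_profile(fragment_lengths: list[int], bin_width: int = 10,
                prominence_factor: float = 5.0) -> GelProfile:
    """Bin fragment lengths into a mass histogram and detect prominent bands.

    A band is a local maximum (strictly greater than the neighbouring bins)
    whose mass is at least ``prominence_factor`` times the median mass of
    non-empty bins.  The band center is the mass-weighted mean fragment
    length within the bin.
    """
    if bin_width < 1:
        raise ProfileError("bin_width must be >= 1")
    mass: dict[int, int] = {}
    centers_num: dict[int, int] = {}
    for L in fragment_lengths:
        if L <= 0:
            continue
        b = (L - 1) // bin_width
        mass[b] = mass.get(b, 0) + L
        centers_num[b] = centers_num.get(b, 0) + L * L
    if not mass:
        return GelProfile(bin_width, {}, ())
    bands = []
    for b, m in sorted(mass.items()):
        if mass.get(b - 1, 0) >= m or mass.get(b + 1, 0) > m:
            continue  # not a local maximum (ties broken toward the left bin)
        # background level: median mass of the other non-empty bins
        others = [m2 for b2, m2 in mass.items() if b2 != b]
        med = float(np.median(others)) if others else 0.0
        prominence = m / med if med > 0 else float("inf")
        if prominence < prominence_factor:
            continue
        center = centers_num[b] / m
        bands.append(Band(center=center, bin_start=b * bin_width + 1,
                          bin_end=(b + 1) * bin_width, mass=m,
                          prominence=prominence))
    bands.sort(key=lambda band: band.mass, reverse=True)
    return GelProfile(bin_width, mass, tuple(bands))


def extract_band_fragments(fragments: list[Fragment], band: Band,
                           profile: GelProfile) -> list[Fragment]:
    """Return the fragments "eluted" from a gel band.

    Selects fragments whose length falls within the band's bin plus or minus
    one bin — the in-silico analogue of cutting a band out of the gel.  An
    empty selection is returned as an empty list; a band that does not
    belong to the profile is an error.
    """
    if band not in profile.bands:
        raise ProfileError("band does not belong to the given profile")
    lo = band.bin_start - profile.bin_width
    hi = band.bin_end + profile.bin_width
    return [f for f in fragments if lo <= len(f) <= hi]
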