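"""Typed exceptions shared across the package."""


class SatarrayError(Exception):
    """Base class for all package errors."""


class FastaFormatError(SatarrayError):
    """Malformed FASTA input (empty file, bad header, illegal characters)."""


class SequenceAlphabetError(SatarrayError):
    """A sequence contains characters outside the accepted alphabet."""


class EnzymeError(SatarrayError):
    """Invalid enzyme definition (non-IUPAC site, cut offset out of range)."""


class ModelError(SatarrayError):
    """Invalid simulation model parameters."""


class ProfileError(SatarrayError):
    """Invalid gel-profile or ladder input (e.g. band not in profile)."""
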