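"""FASTA reading/writing with strict validation.

Thin wrappers over Bio.SeqIO: records are uppercased, RNA ``U`` is mapped to
``T``, and any character outside the IUPAC nucleotide alphabet is rejected with
a position report.  Downstream analysis modules additionally require plain
A/C/G/T; degenerate codes are accepted here only so that enzyme-site FASTA
snippets survive a round trip.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from satarray.errors import FastaFormatError
from satarray.sequtils import IUPAC


def read_fasta(path: str | os.PathLike, *, strict_dna: bool = False) -> list[tuple[str, str]]:
    """Read a (multi-)FASTA file into ``[(id, sequence), ...]``.

    Sequences are uppercased and U->T mapped.  ``strict_dna=True`` restricts the
    alphabet to A/C/G/T; otherwise any IUPAC nucleotide code is accepted.
    Raises :class:`FastaFormatError` on empty files, records without an
    identifier, empty sequences, or illegal characters (with position).
    """
    path = os.fspath(path)
    try:
        records = list(SeqIO.parse(path, "fasta"))
    except FileNotFoundError:
        raise
    except Exception as exc:  # Bio raises ValueError subclasses on bad input
        raise FastaFormatError(f"{path}: cannot parse FASTA: {exc}") from exc
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    allowed = set("ACGT") if strict_dna else set(IUPAC)
    out: list[tuple[str, str]] = []
    for rec in records:
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty header")
        seq = str(rec.seq).upper().replace("U", "T")
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has empty sequence")
        for i, ch in enumerate(seq):
            if ch not in allowed:
                raise FastaFormatError(
                    f"{path}: record {rec.id!r}: illegal character {ch!r} "
                    f"at position {i + 1}"
                )
        out.append((rec.id, seq))
    return out


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]],
                *, description: str = "") -> None:
    """Write ``(id, sequence)`` pairs to a FASTA file (60-column wrapping)."""
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description=description)
        for name, seq in records
    ]
    SeqIO.write(seqrecords, os.fspath(path), "fasta")
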