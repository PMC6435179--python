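"""Scanner for the centromeric A/T motif of the CNM-type repeat families.

The Galliformes CNM-type satellite families share a 12-17-bp signature in
which a maximal run of 3-5 adenines and a maximal run of 3-5 thymines are
separated by a 6-7-bp spacer, in either order.  Maximality means the run is
not extendable: an A-run may not be preceded or followed by another A (and
likewise for T), which also prevents double counting of longer runs.

Because the motif's reverse complement has the same A-run/spacer/T-run
structure at the same coordinates (an A-first hit on one strand is a T-first
hit on the other), scanning the forward strand for both orders is equivalent
to scanning both strands and deduplicating palindromic coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from satarray.sequtils import validate_dna

MIN_RUN, MAX_RUN = 3, 5
MIN_SPACER, MAX_SPACER = 6, 7


@dataclass(frozen=True)
class MotifHit:
    """One A/T-motif occurrence (1-based inclusive coordinates)."""

    start: int
    end: int
    a_run_length: int
    t_run_length: int
    spacer_length: int
    order: str  # "A-first" or "T-first"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _maximal_runs(sequence: str, base: str) -> list[tuple[int, int]]:
    """0-based (start, length) of maximal runs of ``base`` with length 3-5."""
    return [
        (m.start(), m.end() - m.start())
        for m in re.finditer(f"{base}+", sequence)
        if MIN_RUN <= m.end() - m.start() <= MAX_RUN
    ]


def scan_cnm_motif(sequence: str) -> list[MotifHit]:
    """All A/T-motif occurrences in a sequence, both run orders.

    Every pairing of a maximal A-run (3-5 nt) and a maximal T-run (3-5 nt)
    separated by 6-7 arbitrary bases is reported; overlapping hits are all
    kept.  Hits are sorted by (start, end, order).
    """
    validate_dna(sequence)
    a_runs = _maximal_runs(sequence, "A")
    t_runs = _maximal_runs(sequence, "T")
    hits: list[MotifHit] = []
    for first_runs, second_runs, order in (
        (a_runs, t_runs, "A-first"),
        (t_runs, a_runs, "T-first"),
    ):
        for fs, fl in first_runs:
            for ss, sl in second_runs:
                spacer = ss - (fs + fl)
                if MIN_SPACER <= spacer <= MAX_SPACER:
                    a_len, t_len = (fl, sl) if order == "A-first" else (sl, fl)
                    hits.append(MotifHit(
                        start=fs + 1,
                        end=ss + sl,
                        a_run_length=a_len,
                        t_run_length=t_len,
                        spacer_length=spacer,
                        order=order,
                    ))
    hits.sort(key=lambda h: (h.start, h.end, h.order))
    return hits
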