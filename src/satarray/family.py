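"""Repeat-family characterization: alignment, consensus, identity, GC.

Implements the statistics conventionally reported for a cloned satellite
repeat family: fragment count, length range, consensus sequence, all-pairs
percent identity, and GC content.

Percent identity follows the single-gap convention used for satellite
monomer comparisons: insertions/deletions are eliminated from the
calculation — alignment gap runs of length >= 2 are excluded from the
denominator — but an isolated one-nucleotide gap is kept and counted as a
difference.  Both the run-length threshold and the counting rule are
configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio import Align

from satarray.sequtils import validate_dna

#: Default global-alignment scores (match, mismatch, gap open, gap extend).
#: A gap of length L costs gap_open + gap_extend * (L - 1).
DEFAULT_MATCH = 1.0
DEFAULT_MISMATCH = -1.0
DEFAULT_GAP_OPEN = -2.0
DEFAULT_GAP_EXTEND = -0.5
#: End gaps get a reduced affine penalty: cloned monomers are arbitrary-phase
#: excisions of different lengths, so terminal overhangs are near-expected and
#: must stay contiguous (a free end gap would instead tie with interior gaps,
#: and a full interior penalty fragments long truncations into gap/match
#: mosaics that harvest chance matches).
DEFAULT_END_OPEN = -1.0
DEFAULT_END_EXTEND = -0.1


@dataclass(frozen=True)
class RepeatFragment:
    """One cloned/extracted repeat monomer sequence."""

    id: str
    sequence: str
    family: str = ""

    def __post_init__(self) -> None:
        validate_dna(self.sequence, what=f"fragment {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class RepeatFamilySummary:
    """One family's summary row: counts, lengths, consensus, identity, GC."""

    family: str
    n_fragments: int
    length_range: tuple[int, int]
    consensus: str
    consensus_length: int
    identity_mean: float
    identity_range: tuple[float, float]
    gc_mean: float
    gc_range: tuple[float, float]


def _aligner(match: float, mismatch: float, gap_open: float,
             gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    aligner.open_end_gap_score = DEFAULT_END_OPEN
    aligner.extend_end_gap_score = DEFAULT_END_EXTEND
    return aligner


def align_pair(a: str, b: str, *, match: float = DEFAULT_MATCH,
               mismatch: float = DEFAULT_MISMATCH,
               gap_open: float = DEFAULT_GAP_OPEN,
               gap_extend: float = DEFAULT_GAP_EXTEND,
               ) -> tuple[str, str, float]:
    """Optimal global alignment of two sequences.

    Returns the two gapped rows and the alignment score.  Affine gap model:
    a gap of length L costs ``gap_open + gap_extend * (L - 1)``.  Among
    co-optimal alignments the aligner's first traceback is returned, which
    is deterministic for fixed inputs.
    """
    validate_dna(a, what="sequence a")
    validate_dna(b, what="sequence b")
    aligner = _aligner(match, mismatch, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1]), float(aln.score)


def identity_from_alignment(row_a: str, row_b: str, *,
                            gap_run_threshold: int = 2,
                            count_short_gaps: bool = True) -> float:
    """Percent identity of an aligned pair under the single-gap convention.

    Columns are grouped into maximal runs of gap columns (a column where
    either row is gapped).  Runs of length >= ``gap_run_threshold`` are
    excluded from the denominator entirely; shorter runs (isolated
    one-nucleotide gaps at the default threshold) stay in the denominator
    and count as differences when ``count_short_gaps`` is true, and are
    excluded otherwise.
    """
    n = len(row_a)
    assert n == len(row_b)
    is_gap = [row_a[i] == "-" or row_b[i] == "-" for i in range(n)]
    matches = 0
    counted = 0
    i = 0
    while i < n:
        if not is_gap[i]:
            counted += 1
            if row_a[i] == row_b[i]:
                matches += 1
            i += 1
            continue
        j = i
        while j < n and is_gap[j]:
            j += 1
        run = j - i
        if run < gap_run_threshold and count_short_gaps:
            counted += run  # short gap columns count as differences
        i = j
    if counted == 0:
        return 0.0
    return matches / counted * 100.0


def pairwise_identity(a: str, b: str, *, gap_run_threshold: int = 2,
                      count_short_gaps: bool = True,
                      **align_kwargs) -> float:
    """Percent identity between two sequences (single-gap convention).

    Symmetric; identical sequences score 100.  The pair is aligned in a
    canonical order so that co-optimal traceback choices cannot make the
    measure depend on argument order.
    """
    if b < a:
        a, b = b, a
    row_a, row_b, _ = align_pair(a, b, **align_kwargs)
    return identity_from_alignment(row_a, row_b,
                                   gap_run_threshold=gap_run_threshold,
                                   count_short_gaps=count_short_gaps)


def gc_content(sequence: str) -> float:
    """GC content as a percentage of sequence length."""
    validate_dna(sequence)
    return (sequence.count("G") + sequence.count("C")) / len(sequence) * 100.0


def consensus(fragments: list[RepeatFragment], *,
              guide: RepeatFragment | None = None, **align_kwargs) -> str:
    """Majority-rule consensus of a fragment set.

    Fragments are stacked by star alignment: every fragment is globally
    aligned to the guide (by default the longest fragment, ties broken by
    id; a caller may supply a more representative guide), and the columns
    of the guide plus any insertions are voted on.  Per column the most
    frequent base wins (ties broken in A<C<G<T order); columns in which
    gaps hold the majority are dropped, so fragments carrying large
    terminal deletions do not shorten the consensus as long as they are a
    minority.
    """
    if not fragments:
        raise ValueError("consensus of an empty fragment set")
    if len(fragments) == 1:
        warnings.warn("consensus of a single fragment is the fragment itself")
        return fragments[0].sequence
    order = sorted(fragments, key=lambda f: (-len(f), f.id))
    if guide is not None:
        order = [guide] + [f for f in order if f is not guide]
    guide = order[0]
    n = len(fragments)
    # votes[key][base]; key = (guide_pos, insert_idx); insert_idx 0 is the
    # guide column itself, >0 are insertion columns after it
    votes: dict[tuple[int, int], dict[str, int]] = {}

    def vote(key: tuple[int, int], base: str) -> None:
        votes.setdefault(key, {}).setdefault(base, 0)
        votes[key][base] += 1

    for gpos, base in enumerate(guide.sequence):
        vote((gpos, 0), base)
    for frag in order[1:]:
        row_g, row_f, _ = align_pair(guide.sequence, frag.sequence, **align_kwargs)
        gpos = -1
        ins = 0
        for cg, cf in zip(row_g, row_f):
            if cg != "-":
                gpos += 1
                ins = 0
                vote((gpos, 0), cf)  # cf may be '-' (deletion in fragment)
            else:
                ins += 1
                vote((gpos, ins), cf)
    out = []
    for key in sorted(votes):
        counts = votes[key]
        n_votes = sum(counts.values())
        gap_votes = counts.get("-", 0) + (n - n_votes)  # absent = gap
        base_counts = {b: c for b, c in counts.items() if b != "-"}
        if not base_counts or gap_votes > sum(base_counts.values()):
            continue  # gap-majority column dropped
        best = max(sorted(base_counts), key=lambda b: base_counts[b])
        out.append(best)
    return "".join(out)


def identity_matrix(fragments: list[RepeatFragment], *,
                    gap_run_threshold: int = 2, count_short_gaps: bool = True,
                    **align_kwargs) -> list[list[float]]:
    """Symmetric all-pairs identity matrix (diagonal 100)."""
    n = len(fragments)
    mat = [[100.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(
                fragments[i].sequence, fragments[j].sequence,
                gap_run_threshold=gap_run_threshold,
                count_short_gaps=count_short_gaps, **align_kwargs)
            mat[i][j] = mat[j][i] = ident
    return mat


def summarize_family(fragments: list[RepeatFragment], *, family: str = "",
                     gap_run_threshold: int = 2, count_short_gaps: bool = True,
                     **align_kwargs) -> RepeatFamilySummary:
    """Characterize a fragment set: the family's summary-table row.

    Identity statistics are means/ranges over all unordered fragment pairs
    under the single-gap convention; GC statistics are over fragments.
    """
    if len(fragments) < 2:
        raise ValueError("summarize_family needs at least 2 fragments")
    fam = family or fragments[0].family
    mat = identity_matrix(fragments, gap_run_threshold=gap_run_threshold,
                          count_short_gaps=count_short_gaps, **align_kwargs)
    pairs = [mat[i][j] for i in range(len(fragments))
             for j in range(i + 1, len(fragments))]
    gcs = [gc_content(f.sequence) for f in fragments]
    # guide = identity medoid among the longest fragments, so an aberrant
    # clone (a co-migrating unrelated fragment) cannot anchor the star
    max_len = max(len(f) for f in fragments)
    medoid = max(
        (i for i, f in enumerate(fragments) if len(f) == max_len),
        key=lambda i: (sum(mat[i]), fragments[i].id))
    cons = consensus(fragments, guide=fragments[medoid], **align_kwargs)
    lengths = [len(f) for f in fragments]
    return RepeatFamilySummary(
        family=fam,
        n_fragments=len(fragments),
        length_range=(min(lengths), max(lengths)),
        consensus=cons,
        consensus_length=len(cons),
        identity_mean=sum(pairs) / len(pairs),
        identity_range=(min(pairs), max(pairs)),
        gc_mean=sum(gcs) / len(gcs),
        gc_range=(min(gcs), max(gcs)),
    )
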