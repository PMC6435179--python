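"""Dot-matrix sequence comparison and repeat-structure detection.

A dot matrix compares every length-``w`` window of sequence A against every
window of sequence B under a nucleotide scoring matrix; positions scoring at
least the threshold ``T`` are "dots".  In a self-comparison, runs of dots
parallel to the main diagonal reveal internal repeat units; in a cross
comparison, diagonal runs mark homologous segments, which are then
re-aligned to report interval coordinates and percent identity.

The scoring matrix is the log-odds matrix of the Kimura two-parameter (K80)
substitution model at evolutionary distance ``d`` substitutions/site with
transition/transversion rate ratio ``kappa``:

    s(i, j) = scale * log2( P_ij(d) / 0.25 )

with the standard K80 closed form for the transition probabilities
``P_ij(d)``.  The defaults ``d = 2.0`` (200 PAM), ``kappa = 2`` and
``scale = 10`` put the conventional window-20 threshold of 22 at roughly 55%
window identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from satarray.family import identity_from_alignment, align_pair
from satarray.sequtils import validate_dna

_ORDER = "ACGT"
_IDX = {b: i for i, b in enumerate(_ORDER)}
#: pairs differing by a transition (purine<->purine, pyrimidine<->pyrimidine)
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}


@dataclass(frozen=True)
class ScoringMatrix:
    """4x4 log-odds nucleotide scoring matrix (base order A, C, G, T)."""

    d: float
    kappa: float
    scale: float
    scores: tuple[tuple[float, ...], ...]

    def as_array(self) -> np.ndarray:
        return np.array(self.scores, dtype=float)

    def score(self, a: str, b: str) -> float:
        return self.scores[_IDX[a]][_IDX[b]]

    @property
    def match_score(self) -> float:
        return self.scores[0][0]


def k80_transition_probabilities(d: float, kappa: float) -> np.ndarray:
    """K80 substitution probabilities P_ij at distance ``d`` subs/site.

    With transition rate alpha and transversion rate beta (kappa = alpha/beta)
    and branch length d = (alpha + 2 beta) t:

        P_same         = 1/4 + 1/4 e^{-4 beta t} + 1/2 e^{-2 (alpha+beta) t}
        P_transition   = 1/4 + 1/4 e^{-4 beta t} - 1/2 e^{-2 (alpha+beta) t}
        P_transversion = 1/4 - 1/4 e^{-4 beta t}        (each of the two)
    """
    if d <= 0 or kappa <= 0:
        raise ValueError("d and kappa must be positive")
    beta_t = d / (kappa + 2.0)
    alpha_t = kappa * beta_t
    e1 = math.exp(-4.0 * beta_t)
    e2 = math.exp(-2.0 * (alpha_t + beta_t))
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    P = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                P[i, j] = p_same
            elif (i, j) in _TRANSITIONS:
                P[i, j] = p_ts
            else:
                P[i, j] = p_tv
    return P


def k80_scoring_matrix(d: float = 2.0, kappa: float = 2.0,
                       scale: float = 10.0) -> ScoringMatrix:
    """Log-odds scoring matrix from the K80 model (uniform base frequencies)."""
    P = k80_transition_probabilities(d, kappa)
    scores = scale * np.log2(P / 0.25)
    return ScoringMatrix(d=d, kappa=kappa, scale=scale,
                         scores=tuple(tuple(row) for row in scores))


DEFAULT_MATRIX = k80_scoring_matrix()
DEFAULT_WINDOW = 20
DEFAULT_THRESHOLD = 22.0


@dataclass(frozen=True)
class DotMatrix:
    """Dot-matrix hits: 1-based window start pairs with window score >= T."""

    window: int
    threshold: float
    shape: tuple[int, int]  # (len a, len b)
    hits: frozenset[tuple[int, int]]


def _window_scores(a: str, b: str, w: int, matrix: ScoringMatrix) -> np.ndarray:
    ea = np.frombuffer(a.encode(), dtype=np.uint8)
    eb = np.frombuffer(b.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for base, i in _IDX.items():
        lut[ord(base)] = i
    S = matrix.as_array()[lut[ea][:, None], lut[eb][None, :]]
    na, nb = len(a) - w + 1, len(b) - w + 1
    W = np.zeros((na, nb))
    for k in range(w):
        W += S[k:k + na, k:k + nb]
    return W


def dot_matrix(a: str, b: str, w: int = DEFAULT_WINDOW,
               T: float = DEFAULT_THRESHOLD,
               matrix: ScoringMatrix = DEFAULT_MATRIX) -> DotMatrix:
    """Windowed dot-matrix comparison of two sequences.

    A hit at 1-based ``(i, j)`` means the ``w``-windows of A at ``i`` and of
    B at ``j`` score at least ``T`` under ``matrix``.
    """
    validate_dna(a, what="sequence a")
    validate_dna(b, what="sequence b")
    if not 1 <= w <= min(len(a), len(b)):
        raise ValueError(f"window {w} out of range for sequence lengths "
                         f"{len(a)}, {len(b)}")
    W = _window_scores(a, b, w, matrix)
    ii, jj = np.nonzero(W >= T)
    hits = frozenset((int(i) + 1, int(j) + 1) for i, j in zip(ii, jj))
    return DotMatrix(window=w, threshold=T, shape=(len(a), len(b)), hits=hits)


def _diagonal_runs(hits: frozenset[tuple[int, int]], *, max_gap: int = 0,
                   ) -> dict[int, list[tuple[int, int]]]:
    """Group hits per diagonal offset (j - i) into runs of window starts.

    Returns {offset: [(i_first, i_last), ...]}; consecutive hits on the same
    diagonal are merged when the step in i is <= max_gap + 1.
    """
    per_diag: dict[int, list[int]] = {}
    for i, j in hits:
        per_diag.setdefault(j - i, []).append(i)
    runs: dict[int, list[tuple[int, int]]] = {}
    for off, starts in per_diag.items():
        starts.sort()
        out = []
        first = prev = starts[0]
        for i in starts[1:]:
            if i - prev <= max_gap + 1:
                prev = i
            else:
                out.append((first, prev))
                first = prev = i
        out.append((first, prev))
        runs[off] = out
    return runs


def internal_repeat_units(sequence: str, w: int = DEFAULT_WINDOW,
                          T: float = DEFAULT_THRESHOLD,
                          matrix: ScoringMatrix = DEFAULT_MATRIX,
                          ) -> tuple[int, int] | None:
    """Detect a tandem internal repeat unit from a self dot-matrix.

    Off-main-diagonal hit runs parallel to the diagonal indicate that the
    sequence matches itself shifted by the unit length.  The unit length is
    the modal diagonal offset among hits in qualifying runs (runs of at
    least w/2 hits); the unit count is ``len(sequence) // unit``.  Returns
    ``None`` when no qualifying off-diagonal run exists.
    """
    dm = dot_matrix(sequence, sequence, w, T, matrix)
    # a tandem unit must recur, so its length is at most half the sequence
    off_hits = frozenset(
        (i, j) for i, j in dm.hits if 0 < j - i <= len(sequence) // 2)
    if not off_hits:
        return None
    runs = _diagonal_runs(off_hits)
    weight: dict[int, int] = {}
    for off, run_list in runs.items():
        for first, last in run_list:
            n_hits = last - first + 1
            if n_hits >= w / 2:
                weight[off] = weight.get(off, 0) + n_hits
    if not weight:
        return None
    unit = min(sorted(weight), key=lambda o: (-weight[o], o))
    return unit, len(sequence) // unit


def _refine_segment(row_a: str, row_b: str, a_start: int, b_start: int,
                    ) -> "HomologySegment | None":
    """Trim an aligned candidate segment to its best-supported core.

    Window-based detection overshoots the true homology boundary by up to a
    window of flanking, unrelated sequence.  Scoring each alignment column
    +1 (match) / -1 (mismatch or gap) and keeping the maximal-sum contiguous
    column run clips those flanks: unrelated flanking columns average ~-0.5
    while genuinely homologous runs average positive.
    """
    scores = [
        1 if (x == y and x != "-") else -1
        for x, y in zip(row_a, row_b)
    ]
    # maximal-sum contiguous subarray; earliest-longest on ties
    best_sum = cur = -1
    best = (0, 0)
    start = 0
    for i, s in enumerate(scores):
        if cur < 0:
            cur, start = s, i
        else:
            cur += s
        if cur > best_sum:
            best_sum, best = cur, (start, i + 1)
    if best_sum <= 0:
        return None
    lo, hi = best
    a_off = sum(1 for ch in row_a[:lo] if ch != "-")
    b_off = sum(1 for ch in row_b[:lo] if ch != "-")
    a_len = sum(1 for ch in row_a[lo:hi] if ch != "-")
    b_len = sum(1 for ch in row_b[lo:hi] if ch != "-")
    if a_len == 0 or b_len == 0:
        return None
    ident = identity_from_alignment(row_a[lo:hi], row_b[lo:hi])
    return HomologySegment(
        a_start=a_start + a_off, a_end=a_start + a_off + a_len - 1,
        b_start=b_start + b_off, b_end=b_start + b_off + b_len - 1,
        identity=ident)


@dataclass(frozen=True)
class HomologySegment:
    """A homologous segment pair (1-based inclusive intervals, % identity)."""

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    identity: float

    @property
    def length(self) -> int:
        return self.a_end - self.a_start + 1


def cross_family_segments(a: str, b: str, min_length: int = 40,
                          w: int = DEFAULT_WINDOW, T: float = DEFAULT_THRESHOLD,
                          matrix: ScoringMatrix = DEFAULT_MATRIX,
                          gap_windows: int = 2) -> list[HomologySegment]:
    """Homologous segments between two sequences from merged dot-matrix runs.

    Hit runs on the same diagonal are merged across gaps of at most
    ``gap_windows * w`` window starts; each merged run spanning at least
    ``min_length`` bp is re-aligned globally and reported with its percent
    identity under the single-gap convention.  Overlapping reports from
    neighbouring diagonals are deduplicated, keeping the longest.
    """
    dm = dot_matrix(a, b, w, T, matrix)
    if not dm.hits:
        return []
    # dense runs (>= 3 consecutive hits) seed segments; isolated hits are
    # window noise and may not seed or bridge a segment on their own
    dense = _diagonal_runs(dm.hits, max_gap=0)
    runs: dict[int, list[tuple[int, int]]] = {}
    for off, run_list in dense.items():
        seeds = [r for r in run_list if r[1] - r[0] + 1 >= 3]
        if not seeds:
            continue
        merged = [seeds[0]]
        for first, last in seeds[1:]:
            if first - merged[-1][1] <= gap_windows * w:
                merged[-1] = (merged[-1][0], last)
            else:
                merged.append((first, last))
        runs[off] = merged
    candidates: list[HomologySegment] = []
    for off, run_list in runs.items():
        for first, last in run_list:
            a_start, a_end = first, last + w - 1
            b_start, b_end = first + off, last + off + w - 1
            if a_end - a_start + 1 < min_length:
                continue
            sub_a = a[a_start - 1:a_end]
            sub_b = b[b_start - 1:b_end]
            row_a, row_b, _ = align_pair(sub_a, sub_b)
            seg = _refine_segment(row_a, row_b, a_start, b_start)
            if seg is not None and seg.length >= min_length:
                candidates.append(seg)
    candidates.sort(key=lambda s: (-s.length, s.a_start))
    kept: list[HomologySegment] = []
    for seg in candidates:
        redundant = False
        for k in kept:
            ov = min(seg.a_end, k.a_end) - max(seg.a_start, k.a_start) + 1
            if ov > 0.5 * seg.length:
                redundant = True
                break
        if not redundant:
            kept.append(seg)
    kept.sort(key=lambda s: s.a_start)
    return kept
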