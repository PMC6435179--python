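import itertools

import numpy as np
import pytest

from satarray import (align_pair, consensus, gc_content, pairwise_identity,
                      summarize_family)
from satarray.family import (DEFAULT_END_EXTEND, DEFAULT_END_OPEN,
                             DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN,
                             DEFAULT_MATCH, DEFAULT_MISMATCH, RepeatFragment)
from satarray.standins import apl_monomer


def _brute_force_best_score(a: str, b: str) -> float:
    """Enumerate every global alignment and score it directly.

    Interior gaps are affine (open -2, extend -0.5 per additional base);
    end-gap runs use the reduced end penalty, matching the package's
    alignment convention.
    """
    best = -np.inf
    n, m = len(a), len(b)

    def score(cols):
        # each row's maximal gap runs are scored affinely; a run touching
        # either alignment end uses the reduced end-gap rates
        total = 0.0
        ncol = len(cols)
        for row in (0, 1):
            i = 0
            while i < ncol:
                if cols[i][row] != "-":
                    i += 1
                    continue
                j = i
                while j < ncol and cols[j][row] == "-":
                    j += 1
                if i == 0 or j == ncol:
                    total += DEFAULT_END_OPEN + DEFAULT_END_EXTEND * (j - i - 1)
                else:
                    total += DEFAULT_GAP_OPEN + DEFAULT_GAP_EXTEND * (j - i - 1)
                i = j
        for x, y in cols:
            if x != "-" and y != "-":
                total += DEFAULT_MATCH if x == y else DEFAULT_MISMATCH
        return total

    def walk(i, j, cols):
        nonlocal best
        if i == n and j == m:
            best = max(best, score(cols))
            return
        if i < n:
            walk(i + 1, j, cols + [(a[i], "-")])
        if j < m:
            walk(i, j + 1, cols + [("-", b[j])])
        if i < n and j < m:
            walk(i + 1, j + 1, cols + [(a[i], b[j])])

    walk(0, 0, [])
    return best


def test_alignment_score_matches_brute_force_enumeration():
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    for trial in range(25):
        la, lb = rng.integers(1, 7, size=2)
        a = "".join(bases[rng.integers(0, 4, la)])
        b = "".join(bases[rng.integers(0, 4, lb)])
        _, _, got = align_pair(a, b)
        assert got == pytest.approx(_brute_force_best_score(a, b)), (a, b)


def test_identical_sequences_align_without_gaps():
    s = apl_monomer(0)[:20]
    ra, rb, score = align_pair(s, s)
    assert ra == rb == s
    assert score == 20.0


def test_single_gap_alignment():
    ra, rb, _ = align_pair("ACGT", "AGT")
    assert ra.replace("-", "") == "ACGT"
    assert rb.count("-") == 1


@pytest.mark.parametrize("a,b,expected", [
    ("ACGTACGT", "ACGTACGT", 100.0),
    ("AAAA", "AATA", 75.0),
    ("ACGT", "AGT", 75.0),   # single gap column counted as a difference
])
def test_pairwise_identity_examples(a, b, expected):
    assert pairwise_identity(a, b) == pytest.approx(expected)


def test_long_gap_runs_are_eliminated_from_identity():
    # a 29-bp terminal deletion must not depress identity: the gap run is
    # excluded, so only the substitutions in the shared region count
    mono = apl_monomer(0)
    truncated = mono[:161]
    assert pairwise_identity(mono, truncated) == pytest.approx(100.0)
    # interior 2-bp deletion: run length 2 also excluded
    interior = mono[:80] + mono[82:]
    assert pairwise_identity(mono, interior) == pytest.approx(100.0)
    # but a 1-bp deletion counts as one difference
    one_del = mono[:80] + mono[81:]
    assert pairwise_identity(mono, one_del) == pytest.approx(
        189 / 190 * 100)


def test_identity_is_symmetric_and_bounded():
    rng = np.random.default_rng(1)
    bases = np.array(list("ACGT"))
    for trial in range(10):
        a = "".join(bases[rng.integers(0, 4, 60)])
        b = "".join(bases[rng.integers(0, 4, 55)])
        ab = pairwise_identity(a, b)
        assert ab == pytest.approx(pairwise_identity(b, a))
        assert 0.0 <= ab <= 100.0
        assert pairwise_identity(a, a) == pytest.approx(100.0)


def test_consensus_of_identical_copies():
    frags = [RepeatFragment(id=str(i), sequence="ACGTACGTAA") for i in range(5)]
    assert consensus(frags) == "ACGTACGTAA"


def test_consensus_column_majority():
    frags = [RepeatFragment(id=str(i), sequence=s)
             for i, s in enumerate(["AAGT", "AAGT", "AACT"])]
    assert consensus(frags) == "AAGT"


def test_consensus_single_fragment_warns():
    with pytest.warns(UserWarning):
        out = consensus([RepeatFragment(id="x", sequence="ACGT")])
    assert out == "ACGT"


def test_consensus_recovers_true_monomer_from_variants():
    from satarray import mutate_monomer

    mono = apl_monomer(0)
    hits = []
    for seed in range(50):
        frags = [
            RepeatFragment(id=f"{seed}-{i}",
                           sequence=mutate_monomer(mono, 0.08, 0.0,
                                                   seed=1000 * seed + i))
            for i in range(20)
        ]
        hits.append(pairwise_identity(consensus(frags), mono))
    assert min(hits) >= 99.0


def test_consensus_accuracy_improves_with_lower_divergence():
    from satarray import mutate_monomer

    mono = apl_monomer(0)

    def mean_recovery(q):
        vals = []
        for seed in range(10):
            frags = [
                RepeatFragment(id=f"{seed}-{i}",
                               sequence=mutate_monomer(mono, q, 0.0,
                                                       seed=7000 * seed + i))
                for i in range(9)
            ]
            vals.append(pairwise_identity(consensus(frags), mono))
        return float(np.mean(vals))

    assert mean_recovery(0.02) >= mean_recovery(0.20)


@pytest.mark.parametrize("seq,expected", [
    ("ATGC", 50.0),
    ("AAAA", 0.0),
    ("GGCC", 100.0),
])
def test_gc_content_examples(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


def test_gc_content_strand_invariance():
    from satarray.sequtils import reverse_complement

    rng = np.random.default_rng(2)
    bases = np.array(list("ACGT"))
    for trial in range(20):
        s = "".join(bases[rng.integers(0, 4, 50)])
        assert gc_content(s) == pytest.approx(gc_content(s[::-1]))
        assert gc_content(s) == pytest.approx(gc_content(reverse_complement(s)))


def test_summary_of_identical_fragments():
    frags = [RepeatFragment(id=str(i), sequence="ACGTAC" * 10, family="f")
             for i in range(3)]
    s = summarize_family(frags)
    assert s.identity_mean == pytest.approx(100.0)
    assert s.identity_range == (100.0, 100.0)
    assert s.consensus_length == 60


def test_summary_matches_closed_form_divergence():
    from satarray import mutate_monomer

    mono = apl_monomer(0)
    q = 0.05
    expected = ((1 - q) ** 2 + q ** 2 / 3) * 100
    means = []
    for seed in range(5):
        frags = [
            RepeatFragment(id=f"{seed}-{i}",
                           sequence=mutate_monomer(mono, q, 0.0,
                                                   seed=3000 * seed + i))
            for i in range(8)
        ]
        means.append(summarize_family(frags).identity_mean)
    assert abs(float(np.mean(means)) - expected) < 1.5


def test_removing_a_fragment_preserves_other_identities():
    from satarray.family import identity_matrix

    frags = [RepeatFragment(id=str(i), sequence=apl_monomer(i)) for i in range(4)]
    full = identity_matrix(frags)
    reduced = identity_matrix(frags[:3])
    for i, j in itertools.combinations(range(3), 2):
        assert full[i][j] == pytest.approx(reduced[i][j])
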