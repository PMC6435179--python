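"""Synthetic stand-in repeat families (not the deposited sequences).

The four Anseriformes centromeric repeat families this package analyses are
deposited in public sequence databases; analysing the real records requires
a download (see ``scripts/fetch_accessions.py``).  This module constructs
*synthetic stand-ins*: deterministic, seeded sequences that embody the
documented structure of each family so that the full analysis pipeline can
be exercised and validated offline:

* ``APL-HaeIII-like`` — 190-bp monomer, GC ~51.6%, one HaeIII / MspI(HpaII)
  / BamHI / TaqI site each, no centromeric A/T motif; a 5-fragment set whose
  all-pairs identities are designed to mean ~84.7% (range ~78.4-89.4%),
  including two 161-bp fragments carrying a 29-bp terminal deletion.
* ``AFA-HinfI-S-like`` — 101-bp monomer built from two diverged 42-43-bp
  internal units, GC ~60%, a single HinfI site, no BamHI/HaeIII/RsaI/MspI
  site; 4 fragments with identity mean ~94.6% (range ~91.1-98.0%).
* ``AFA-HinfI-L-like`` — 192-bp monomer sharing two designed homology
  segments with the APL-like monomer (positions 26-117 of APL vs 1-92,
  ~84.8% identity; 118-159 vs 149-190, ~76.2%), carrying the A/T motif and
  single HinfI/AluI/RsaI/MspI sites; 2 fragments at ~98.4% identity.
* ``CCY-ApaI-like`` — 290-bp monomer with an ApaI site plus HinfI, MspI and
  multiple HaeIII sites; 15 fragments, lengths 286-294 (single-base indels),
  identity mean ~97.5% (range ~94.8-100%).
* ``RBMII-like`` — the APL-like monomer at ~87.9% identity (whole length).

Fragment divergence is built from substitutions at mutually disjoint
positions (GC-preserving complement swaps), so the designed identity and GC
statistics are exact rational numbers independent of the seed, and the
majority consensus of each fragment set equals its monomer.  All
constructions are validated against their structural constraints by
deterministic rejection sampling over sub-seeds.
"""

from __future__ import annotations

import numpy as np

from satarray.family import RepeatFragment
from satarray.motif import scan_cnm_motif
from satarray.sequtils import find_overlapping

_MAX_TRIES = 20000

#: designed per-fragment substitution counts (see module docstring)
APL_SUB_COUNTS = (12, 18, 23, 7, 10)   # last two fragments are 161 bp
APL_DELETED = (False, False, False, True, True)
AFA_S_SUB_COUNTS = (1, 1, 4, 5)
AFA_L_SUB_COUNTS = (1, 2)
#: (substitutions, deletions, insertions) per CCY fragment
CCY_EDITS = (
    (0, 0, 0), (0, 0, 0), (2, 0, 0), (2, 0, 0), (3, 0, 0),
    (2, 1, 0), (2, 0, 1), (4, 0, 0), (4, 0, 0), (0, 4, 0),
    (0, 0, 4), (5, 0, 0), (5, 0, 0), (7, 0, 0), (8, 0, 0),
)

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _rng(seed: int, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *salt]))


def _random_filled(length: int, gc_count: int, plants: list[tuple[int, str]],
                   rng: np.random.Generator) -> str:
    """Random sequence of exact GC composition with fixed motifs planted."""
    template: list[str | None] = [None] * length
    for off, text in plants:
        assert off + len(text) <= length
        for i, ch in enumerate(text):
            template[off + i] = ch
    planted_gc = sum(1 for ch in template if ch in ("G", "C"))
    free = [i for i, ch in enumerate(template) if ch is None]
    n_gc = gc_count - planted_gc
    assert 0 <= n_gc <= len(free)
    pool = (["G", "C"] * ((n_gc + 1) // 2))[:n_gc]
    n_at = len(free) - n_gc
    pool += (["A", "T"] * ((n_at + 1) // 2))[:n_at]
    pool = list(rng.permutation(pool))
    for i, base in zip(free, pool):
        template[i] = base
    return "".join(template)  # type: ignore[arg-type]


def _count(seq: str, word: str) -> int:
    return len(find_overlapping(seq, word))


def _spaced_positions(k: int, *, lo: int, hi: int, min_gap: int,
                      rng: np.random.Generator) -> list[int]:
    """k sorted positions in [lo, hi) pairwise at least ``min_gap`` apart."""
    span = hi - lo - (min_gap - 1) * (k - 1)
    assert span >= k, "not enough room for spaced positions"
    base = np.sort(rng.choice(span, size=k, replace=False))
    return [int(lo + b + (min_gap - 1) * i) for i, b in enumerate(base)]


def _substitute(seq: str, positions: list[int], rng: np.random.Generator,
                mode: str = "uniform") -> str:
    out = list(seq)
    for p in positions:
        if mode == "complement":
            out[p] = _COMPLEMENT[out[p]]
        else:
            out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


def apl_monomer(seed: int = 0) -> str:
    """190-bp APL-HaeIII-like stand-in monomer (synthetic)."""
    for attempt in range(_MAX_TRIES):
        rng = _rng(seed, 101, attempt)
        seq = _random_filled(190, 98, [(0, "GGCC"), (8, "TCGA"),
                                       (166, "CCGG"), (172, "GGATCC")], rng)
        if (_count(seq, "GGCC") == 1 and _count(seq, "CCGG") == 1
                and _count(seq, "TCGA") == 1 and _count(seq, "GGATCC") == 1
                and not scan_cnm_motif(seq)
                and seq[:161].count("G") + seq[:161].count("C") == 83):
            return seq
    raise RuntimeError("APL stand-in construction failed")


def afa_l_monomer(apl: str, seed: int = 0) -> str:
    """192-bp AFA-HinfI-L-like stand-in monomer (synthetic).

    Positions 1-92 are a ~84.8%-identical copy of APL 26-117, positions
    149-190 a ~76.2%-identical copy of APL 118-159; the middle carries the
    A/T motif and the HinfI, AluI, RsaI and MspI sites.
    """
    for attempt in range(_MAX_TRIES):
        rng = _rng(seed, 202, attempt)
        seg1 = _substitute(apl[25:117],
                           _spaced_positions(14, lo=0, hi=92, min_gap=3, rng=rng),
                           rng)
        middle = _random_filled(
            56, 29,
            [(3, "GAATC"), (8, "AGCT"), (12, "AAAAGCAGCAGTTTT"),
             (27, "GTAC"), (31, "CCGG")],
            rng)
        seg2 = _substitute(apl[117:159],
                           _spaced_positions(10, lo=0, hi=42, min_gap=4, rng=rng),
                           rng)
        tail = _random_filled(2, 1, [], rng)
        seq = seg1 + middle + seg2 + tail
        gantc = sum(_count(seq, w) for w in ("GAATC", "GACTC", "GAGTC", "GATTC"))
        if (gantc == 1 and _count(seq, "AGCT") == 1 and _count(seq, "GTAC") == 1
                and _count(seq, "CCGG") == 1
                and len(scan_cnm_motif(seq)) == 1
                and seq.count("G") + seq.count("C") == 99):
            return seq
    raise RuntimeError("AFA-L stand-in construction failed")


def afa_s_monomer(seed: int = 0) -> str:
    """101-bp AFA-HinfI-S-like stand-in monomer (synthetic).

    Two 43-bp internal units at ~86% identity plus a 15-bp tail with the
    single HinfI site; GC-rich; no BamHI/HaeIII/RsaI/MspI site.
    """
    for attempt in range(_MAX_TRIES):
        rng = _rng(seed, 303, attempt)
        unit1 = _random_filled(43, 26, [], rng)
        unit2 = _substitute(unit1,
                            _spaced_positions(6, lo=0, hi=43, min_gap=3, rng=rng),
                            rng)
        tail = _random_filled(15, 9, [(10, "GAATC")], rng)
        seq = unit1 + unit2 + tail
        gantc = sum(_count(seq, w) for w in ("GAATC", "GACTC", "GAGTC", "GATTC"))
        if (gantc == 1 and _count(seq, "GGCC") == 0 and _count(seq, "CCGG") == 0
                and _count(seq, "GTAC") == 0 and _count(seq, "GGATCC") == 0
                and not scan_cnm_motif(seq)
                and seq.count("G") + seq.count("C") == 61):
            return seq
    raise RuntimeError("AFA-S stand-in construction failed")


def ccy_monomer(seed: int = 0) -> str:
    """290-bp CCY-ApaI-like stand-in monomer (synthetic)."""
    for attempt in range(_MAX_TRIES):
        rng = _rng(seed, 404, attempt)
        seq = _random_filled(290, 157, [(0, "GGGCCC"), (60, "GAATC"),
                                        (120, "CCGG"), (180, "GGCC"),
                                        (230, "GGCC")], rng)
        gantc = sum(_count(seq, w) for w in ("GAATC", "GACTC", "GAGTC", "GATTC"))
        if (_count(seq, "GGGCCC") == 1 and gantc == 1
                and _count(seq, "CCGG") == 1 and _count(seq, "GGCC") == 3
                and not scan_cnm_motif(seq)):
            return seq
    raise RuntimeError("CCY stand-in construction failed")


def rbmii_monomer(apl: str, seed: int = 0) -> str:
    """RBMII-like stand-in: the APL-like monomer at ~87.9% identity."""
    rng = _rng(seed, 505)
    return _substitute(apl, _spaced_positions(23, lo=0, hi=190, min_gap=4,
                                              rng=rng), rng)


def _disjoint_position_sets(counts: tuple[int, ...], *, hi: int,
                            rng: np.random.Generator) -> list[list[int]]:
    """Mutually disjoint position sets of the given sizes within [0, hi).

    Positions (across sets) are never adjacent: two neighbouring edits in
    locally self-similar sequence can otherwise be re-explained by the
    aligner as a cheap single-base slip, perturbing the designed identities.
    """
    total = sum(counts)
    pool = _spaced_positions(total, lo=0, hi=hi, min_gap=2, rng=rng)
    pool = [pool[i] for i in rng.permutation(total)]
    sets, at = [], 0
    for k in counts:
        sets.append(sorted(int(p) for p in pool[at:at + k]))
        at += k
    return sets


def apl_fragments(apl: str, seed: int = 0) -> list[RepeatFragment]:
    """Five APL-like stand-in fragments (synthetic); two carry the 29-bp
    terminal deletion (161 bp).  Designed all-pairs identity: mean ~83.6%,
    range ~78.4-89.4%."""
    rng = _rng(seed, 111)
    pos_sets = _disjoint_position_sets(APL_SUB_COUNTS, hi=161, rng=rng)
    frags = []
    for i, (k_pos, deleted) in enumerate(zip(pos_sets, APL_DELETED), start=1):
        base = apl[:161] if deleted else apl
        frags.append(RepeatFragment(
            id=f"APL-HaeIII-synth-{i:02d}",
            sequence=_substitute(base, k_pos, rng, mode="complement"),
            family="APL-HaeIII-like"))
    return frags


def afa_s_fragments(mono: str, seed: int = 0) -> list[RepeatFragment]:
    """Four AFA-HinfI-S-like stand-in fragments (synthetic)."""
    rng = _rng(seed, 222)
    pos_sets = _disjoint_position_sets(AFA_S_SUB_COUNTS, hi=len(mono), rng=rng)
    return [
        RepeatFragment(id=f"AFA-HinfI-S-synth-{i:02d}",
                       sequence=_substitute(mono, pos, rng, mode="complement"),
                       family="AFA-HinfI-S-like")
        for i, pos in enumerate(pos_sets, start=1)
    ]


def afa_l_fragments(mono: str, seed: int = 0) -> list[RepeatFragment]:
    """Two AFA-HinfI-L-like stand-in fragments (synthetic), ~98.4% identical."""
    rng = _rng(seed, 333)
    pos_sets = _disjoint_position_sets(AFA_L_SUB_COUNTS, hi=len(mono), rng=rng)
    return [
        RepeatFragment(id=f"AFA-HinfI-L-synth-{i:02d}",
                       sequence=_substitute(mono, pos, rng, mode="complement"),
                       family="AFA-HinfI-L-like")
        for i, pos in enumerate(pos_sets, start=1)
    ]


def ccy_fragments(mono: str, seed: int = 0) -> list[RepeatFragment]:
    """Fifteen CCY-ApaI-like stand-in fragments (synthetic), 286-294 bp."""
    rng = _rng(seed, 444)
    sub_counts = tuple(s for s, _, _ in CCY_EDITS)
    pos_sets = _disjoint_position_sets(sub_counts, hi=len(mono), rng=rng)
    frags = []
    for i, ((n_sub, n_del, n_ins), subs) in enumerate(zip(CCY_EDITS, pos_sets),
                                                      start=1):
        seq = _substitute(mono, subs, rng, mode="complement")
        if n_del:
            # isolated single-base deletions, GC-balanced
            for j, p in enumerate(_spaced_positions(n_del, lo=20, hi=len(seq) - 20,
                                                    min_gap=8, rng=rng)):
                want = "GC" if j % 2 == 0 else "AT"
                q = p - j  # account for previously removed bases
                while seq[q] not in want:
                    q += 1
                seq = seq[:q] + seq[q + 1:]
        if n_ins:
            for j, p in enumerate(_spaced_positions(n_ins, lo=20, hi=len(seq) - 20,
                                                    min_gap=8, rng=rng)):
                base = ("G", "A", "C", "T")[j % 4]
                seq = seq[:p + j] + base + seq[p + j:]
        frags.append(RepeatFragment(id=f"CCY-ApaI-synth-{i:02d}", sequence=seq,
                                    family="CCY-ApaI-like"))
    return frags


def standin_monomers(seed: int = 0) -> dict[str, str]:
    """All stand-in monomer consensuses keyed by family label."""
    apl = apl_monomer(seed)
    return {
        "APL-HaeIII-like": apl,
        "AFA-HinfI-S-like": afa_s_monomer(seed),
        "AFA-HinfI-L-like": afa_l_monomer(apl, seed),
        "CCY-ApaI-like": ccy_monomer(seed),
        "RBMII-like": rbmii_monomer(apl, seed),
    }


def standin_fragment_sets(seed: int = 0) -> dict[str, list[RepeatFragment]]:
    """All stand-in fragment sets keyed by family label."""
    mono = standin_monomers(seed)
    return {
        "APL-HaeIII-like": apl_fragments(mono["APL-HaeIII-like"], seed),
        "AFA-HinfI-S-like": afa_s_fragments(mono["AFA-HinfI-S-like"], seed),
        "AFA-HinfI-L-like": afa_l_fragments(mono["AFA-HinfI-L-like"], seed),
        "CCY-ApaI-like": ccy_fragments(mono["CCY-ApaI-like"], seed),
    }


def rotate_to_cut(monomer: str, cut_offset_in_monomer: int) -> str:
    """Monomer rotated so that digestion fragments of a perfect array match.

    An enzyme cutting after position ``cut_offset_in_monomer`` (0-based)
    inside the monomer releases fragments that are this rotation of it.
    """
    c = cut_offset_in_monomer % len(monomer)
    return monomer[c:] + monomer[:c]
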