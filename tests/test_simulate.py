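import numpy as np
import pytest

from satarray import (TandemArrayModel, build_tandem_array, get_enzyme,
                      mutate_monomer, simulate_genome)
from satarray.errors import ModelError
from satarray.standins import apl_monomer


def _hamming_identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    return sum(x == y for x, y in zip(a, b)) / len(a) * 100.0


def test_zero_rates_are_identity():
    mono = apl_monomer(0)
    assert mutate_monomer(mono, 0.0, 0.0, seed=1) == mono


def test_mutation_is_reproducible_and_seed_sensitive():
    mono = apl_monomer(0)
    v1 = mutate_monomer(mono, 0.1, 0.02, seed=7)
    v2 = mutate_monomer(mono, 0.1, 0.02, seed=7)
    v3 = mutate_monomer(mono, 0.1, 0.02, seed=8)
    assert v1 == v2
    assert v1 != v3


def test_substitution_rate_matches_expected_identity():
    # per-site survival 1-q: mean identity to the source ~ 95% at q=0.05
    mono = apl_monomer(0)
    idents = [
        _hamming_identity(mutate_monomer(mono, 0.05, 0.0, seed=s), mono)
        for s in range(1000)
    ]
    assert abs(float(np.mean(idents)) - 95.0) < 0.5


def test_pairwise_identity_of_two_variants_matches_closed_form():
    # two independent variants at rate q agree per site with probability
    # (1-q)^2 + q^2/3; at q = 0.10 that is ~81.33%
    mono = apl_monomer(0)
    q = 0.10
    expected = ((1 - q) ** 2 + q ** 2 / 3) * 100
    idents = [
        _hamming_identity(mutate_monomer(mono, q, 0.0, seed=2 * s),
                          mutate_monomer(mono, q, 0.0, seed=2 * s + 1))
        for s in range(1000)
    ]
    assert abs(float(np.mean(idents)) - expected) < 0.5


@pytest.mark.parametrize("q,indel", [(-0.1, 0.0), (1.0, 0.0), (0.0, 1.0)])
def test_mutation_rejects_bad_rates(q, indel):
    with pytest.raises(ModelError):
        mutate_monomer("ACGT", q, indel, seed=0)


def test_mutation_rejects_empty_monomer():
    with pytest.raises(Exception):
        mutate_monomer("", 0.1, 0.0, seed=0)


def test_perfect_array_is_periodic():
    mono = apl_monomer(0)
    model = TandemArrayModel(name="f", monomer=mono, copy_number=10)
    seq, annots = build_tandem_array(model, seed=0)
    assert seq == mono * 10
    assert len(annots) == 10
    assert [(c.start, c.end) for c in annots] == [
        (i * 190 + 1, (i + 1) * 190) for i in range(10)
    ]


def test_full_conservation_keeps_every_site():
    mono = apl_monomer(0)
    enzyme = get_enzyme("HaeIII")
    model = TandemArrayModel(name="f", monomer=mono, copy_number=200,
                             sub_rate=0.05, enzyme=enzyme,
                             site_conservation=1.0)
    seq, annots = build_tandem_array(model, seed=3)
    assert all(c.site_intact for c in annots)
    for c in annots:
        copy = seq[c.start - 1:c.end]
        assert enzyme.regex.search(copy) is not None


def test_site_conservation_fraction_is_binomial():
    mono = apl_monomer(0)
    model = TandemArrayModel(name="f", monomer=mono, copy_number=10_000,
                             enzyme=get_enzyme("HaeIII"),
                             site_conservation=0.8)
    seq, annots = build_tandem_array(model, seed=5)
    frac = np.mean([c.site_intact for c in annots])
    assert abs(frac - 0.8) < 0.01
    # ablated copies genuinely lost the recognition site
    broken = next(c for c in annots if not c.site_intact)
    assert get_enzyme("HaeIII").regex.search(
        seq[broken.start - 1:broken.end]) is None


def test_methylation_fraction_is_binomial():
    mono = apl_monomer(0)
    model = TandemArrayModel(name="f", monomer=mono, copy_number=5000,
                             enzyme=get_enzyme("MspI"),
                             methylation_fraction=0.8)
    _, annots = build_tandem_array(model, seed=1)
    flags = [f for c in annots for f in c.methylated]
    assert len(flags) > 0
    assert abs(np.mean(flags) - 0.8) < 0.02


def test_empty_family_list_gives_pure_background():
    g = simulate_genome([], background_length=1000, seed=0)
    assert len(g.sequence) == 1000
    assert g.truth == []


def test_zero_background_gives_bare_array():
    mono = apl_monomer(0)
    model = TandemArrayModel(name="f", monomer=mono, copy_number=5)
    g = simulate_genome([model], background_length=0, seed=0)
    assert len(g.sequence) == 5 * len(mono)
    assert len(g.copies) == 5


def test_genome_determinism():
    mono = apl_monomer(0)
    model = TandemArrayModel(name="f", monomer=mono, copy_number=20,
                             sub_rate=0.05, enzyme=get_enzyme("HaeIII"),
                             site_conservation=0.9, methylation_fraction=0.5)
    g1 = simulate_genome([model], background_length=5000, seed=11)
    g2 = simulate_genome([model], background_length=5000, seed=11)
    g3 = simulate_genome([model], background_length=5000, seed=12)
    assert g1.sequence == g2.sequence
    assert g1.truth == g2.truth
    assert g1.sequence != g3.sequence


def test_truth_intervals_cover_copies():
    mono = apl_monomer(0)
    model = TandemArrayModel(name="f", monomer=mono, copy_number=50,
                             sub_rate=0.02, indel_rate=0.01)
    g = simulate_genome([model], background_length=3000, seed=2)
    # intervals sorted, non-overlapping, within bounds (validated on build),
    # and the array region concatenates exactly to the copies
    for c in g.copies:
        assert 1 <= c.start <= c.end <= len(g.sequence)
    starts = [c.start for c in g.copies]
    assert starts == sorted(starts)


def test_truth_file_round_trip(tmp_path):
    mono = apl_monomer(0)
    model = TandemArrayModel(name="fam", monomer=mono, copy_number=10,
                             enzyme=get_enzyme("MspI"),
                             methylation_fraction=0.5)
    g = simulate_genome([model], background_length=500, seed=4)
    fasta = tmp_path / "g.fa"
    truth = tmp_path / "g.truth.tsv"
    g.write_fasta(fasta)
    g.write_truth(truth)
    from satarray import read_fasta
    (_, seq), = read_fasta(fasta)
    assert seq == g.sequence
    lines = truth.read_text().strip().splitlines()
    assert len(lines) == 1 + len(g.copies)
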