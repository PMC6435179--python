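import numpy as np
import pytest

from satarray import (digest, digest_fragments, extract_band_fragments,
                      find_sites, gel_profile, get_enzyme, load_enzyme_table)
from satarray.enzymes import Enzyme
from satarray.errors import EnzymeError, ProfileError
from satarray.sequtils import expand_iupac


def _random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def test_single_literal_site():
    assert find_sites("AAGGCCAA", get_enzyme("HaeIII")) == [3]


def test_isoschizomer_methylation_contrast():
    # CCGG with the internal CpG cytosine methylated: HpaII blocked, MspI not
    meth = np.array([False, True, False, False])
    assert find_sites("CCGG", get_enzyme("HpaII"), meth) == []
    assert find_sites("CCGG", get_enzyme("MspI"), meth) == [1]
    # unmethylated: both cleave
    assert find_sites("CCGG", get_enzyme("HpaII")) == [1]


def test_site_finding_matches_iupac_expansion_oracle():
    rng = np.random.default_rng(0)
    table = load_enzyme_table()
    for trial in range(5):
        seq = _random_seq(rng, 1000)
        for enzyme in table.values():
            words = set(expand_iupac(enzyme.site))
            k = len(enzyme.site)
            expected = [
                i + 1 for i in range(len(seq) - k + 1)
                if seq[i:i + k] in words
            ]
            assert find_sites(seq, enzyme) == expected, enzyme.name


def test_no_sites_gives_full_length_fragment():
    assert digest("AAAATTTT", get_enzyme("HaeIII")) == [8]


def test_perfect_array_digest_is_periodic(monomers):
    mono = monomers["APL-HaeIII-like"]
    seq = mono * 10
    lengths = digest(seq, get_enzyme("HaeIII"))
    assert sum(lengths) == len(seq)
    assert lengths.count(190) == 9
    assert lengths[0] + lengths[-1] == 190


def test_partial_conservation_gives_geometric_monomer_fraction(monomers):
    from satarray import TandemArrayModel, build_tandem_array

    model = TandemArrayModel(name="f", monomer=monomers["APL-HaeIII-like"],
                             copy_number=10_000, enzyme=get_enzyme("HaeIII"),
                             site_conservation=0.8)
    seq, _ = build_tandem_array(model, seed=9)
    lengths = digest(seq, get_enzyme("HaeIII"))
    frac = lengths.count(190) / len(lengths)
    assert abs(frac - 0.8) < 0.01


def test_digest_length_conservation_random():
    rng = np.random.default_rng(3)
    table = load_enzyme_table()
    for trial in range(3):
        seq = _random_seq(rng, 5000)
        for enzyme in table.values():
            lengths = digest(seq, enzyme)
            assert sum(lengths) == len(seq)
            assert all(ln > 0 for ln in lengths)


def test_hpaii_sites_subset_of_mspi():
    rng = np.random.default_rng(5)
    for trial in range(10):
        seq = _random_seq(rng, 2000)
        meth = rng.random(2000) < 0.5
        hpa = set(find_sites(seq, get_enzyme("HpaII"), meth))
        msp = set(find_sites(seq, get_enzyme("MspI"), meth))
        assert hpa <= msp
        assert set(find_sites(seq, get_enzyme("HpaII"))) == msp


def test_enzyme_validation():
    with pytest.raises(EnzymeError):
        Enzyme("bad", "GGXC", 2)
    with pytest.raises(EnzymeError):
        Enzyme("bad", "GGCC", 7)
    with pytest.raises(EnzymeError):
        get_enzyme("NoSuchEnzyme")


def test_uniform_fragments_make_single_band():
    profile = gel_profile([190] * 50, bin_width=10)
    assert len(profile.bands) == 1
    assert abs(profile.bands[0].center - 190) < 10
    assert profile.total_mass == 190 * 50


def test_empty_fragment_list_gives_empty_profile():
    profile = gel_profile([], bin_width=10)
    assert profile.mass == {}
    assert profile.bands == ()


def test_band_extraction_and_errors():
    frags = digest_fragments("A" * 40 + "GGCC" + "A" * 40, get_enzyme("HaeIII"))
    lengths = [len(f) for f in frags]
    profile = gel_profile(lengths * 30, bin_width=10)
    assert profile.bands
    band = profile.bands[0]
    got = extract_band_fragments(frags, band, profile)
    assert all(band.bin_start - 10 <= len(f) <= band.bin_end + 10 for f in got)
    other = gel_profile([500] * 10)
    with pytest.raises(ProfileError):
        extract_band_fragments(frags, other.bands[0], profile)


def test_simulated_genome_band_at_monomer_length(monomers):
    from satarray import TandemArrayModel, simulate_genome

    model = TandemArrayModel(name="f", monomer=monomers["APL-HaeIII-like"],
                             copy_number=500, sub_rate=0.08,
                             enzyme=get_enzyme("HaeIII"),
                             site_conservation=0.9)
    g = simulate_genome([model], background_length=100_000, seed=1)
    profile = gel_profile(digest(g.sequence, get_enzyme("HaeIII")))
    assert profile.bands
    assert abs(profile.bands[0].center - 190) <= profile.bin_width


def test_random_genome_has_no_prominent_band():
    rng = np.random.default_rng(0)
    for trial in range(20):
        seq = _random_seq(rng, 100_000)
        profile = gel_profile(digest(seq, get_enzyme("HaeIII")))
        assert not profile.bands
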