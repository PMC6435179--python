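import numpy as np
import pytest

from satarray import (LadderObservation, TandemArrayModel, classify_ladder,
                      digest, digest_fragments, estimate_cleavage, get_enzyme,
                      infer_methylation, ladder_from_lengths, predict_ladder,
                      select_hybridizing, simulate_genome)
from satarray.errors import ProfileError
from satarray.standins import apl_monomer


def test_complete_digestion_is_monomer_only():
    obs = predict_ladder(1.0, k_max=5)
    assert obs.intensities[0] == pytest.approx(1.0)
    assert all(x == 0.0 for x in obs.intensities[1:])
    assert classify_ladder(obs) == "monomer_only"


def test_predicted_ladder_closed_form():
    obs = predict_ladder(0.8, k_max=3)
    assert obs.intensities == pytest.approx((0.658, 0.263, 0.079), abs=5e-4)
    assert classify_ladder(obs) == "decreasing"


def test_low_conservation_ladder_is_increasing():
    obs = predict_ladder(0.2, k_max=3)
    assert classify_ladder(obs) == "increasing"


def test_ladder_normalization_and_positivity():
    for c in (0.1, 0.5, 0.9):
        obs = predict_ladder(c, k_max=8)
        assert sum(obs.intensities) == pytest.approx(1.0)
        assert all(x > 0 for x in obs.intensities)


def test_zero_cleavage_is_rejected():
    with pytest.raises(ProfileError):
        predict_ladder(0.0, 5)


def test_estimate_from_band_ratio():
    obs = LadderObservation((1.0, 0.4, 0.0))
    assert estimate_cleavage(obs).c_hat == pytest.approx(0.8)


def test_estimate_inverts_prediction_exactly():
    for c in np.arange(0.1, 1.0001, 0.1):
        obs = predict_ladder(float(c), k_max=6)
        assert abs(estimate_cleavage(obs).c_hat - c) < 1e-10


def test_pure_monomer_signal_means_complete_cleavage():
    est = estimate_cleavage(LadderObservation((1.0, 0.0, 0.0)))
    assert est.c_hat == 1.0
    assert est.se == 0.0


def test_classification_boundary_at_one_half():
    # I(2)/I(1) = 2(1-c): strictly decreasing ladders require c > 1/2
    for c in np.arange(0.05, 0.99, 0.05):
        expected = ("decreasing" if c > 0.5
                    else "increasing" if all(
                        (k + 1) / k * (1 - c) > 1 for k in range(1, 5))
                    else "flat")
        assert classify_ladder(predict_ladder(float(c), k_max=5)) == expected


def test_monte_carlo_digestion_matches_closed_form(monomers):
    # simulate a long array at c = 0.8 and compare the empirical
    # mass-weighted multimer distribution with the geometric model
    model = TandemArrayModel(name="f", monomer=monomers["APL-HaeIII-like"],
                             copy_number=100_000,
                             enzyme=get_enzyme("HaeIII"),
                             site_conservation=0.8)
    g = simulate_genome([model], 0, seed=13)
    obs = ladder_from_lengths(digest(g.sequence, get_enzyme("HaeIII")),
                              monomer_length=190, k_max=6)
    expected = predict_ladder(0.8, k_max=6)
    for got, want in zip(obs.intensities, expected.intensities):
        assert got == pytest.approx(want, abs=0.01)


def test_cleavage_recovery_from_simulation(monomers):
    chats = []
    for seed in range(5):
        model = TandemArrayModel(name="f", monomer=monomers["APL-HaeIII-like"],
                                 copy_number=5000,
                                 enzyme=get_enzyme("HaeIII"),
                                 site_conservation=0.7)
        g = simulate_genome([model], 0, seed=seed)
        obs = ladder_from_lengths(digest(g.sequence, get_enzyme("HaeIII")),
                                  190, k_max=6)
        chats.append(estimate_cleavage(obs).c_hat)
    assert abs(float(np.mean(chats)) - 0.7) < 0.02


def test_identical_isoschizomer_ladders_are_unmethylated():
    obs = predict_ladder(0.9, 5)
    call = infer_methylation(obs, obs)
    assert call.m_hat == pytest.approx(0.0)
    assert call.label == "unmethylated"


def test_methylation_algebra_and_labels():
    call = infer_methylation(predict_ladder(0.9, 6), predict_ladder(0.09, 6))
    assert call.m_hat == pytest.approx(0.9, abs=1e-9)
    assert call.label == "hypermethylated"
    weak = infer_methylation(predict_ladder(0.9, 6), predict_ladder(0.72, 6))
    assert weak.m_hat == pytest.approx(0.2, abs=1e-9)
    assert weak.label == "weakly methylated"


def test_undetectable_hpaii_monomer_is_hypermethylated():
    obs_m = predict_ladder(0.9, 4)
    obs_h = LadderObservation((0.0, 0.0, 0.1, 0.9))
    call = infer_methylation(obs_m, obs_h)
    assert call.m_hat == 1.0
    assert call.label == "hypermethylated"


def test_ladder_from_lengths_assigns_multimer_orders():
    obs = ladder_from_lengths([190] * 8 + [380] * 2 + [383] + [5000], 190,
                              k_max=4)
    # 5000 is no multimer of 190 within 5%; 383 joins the dimer rung
    assert obs.intensities[0] == pytest.approx(
        190 * 8 / (190 * 8 + 380 * 2 + 383))
    assert obs.intensities[2] == 0.0


def test_probe_filter_keeps_array_fragments_only(monomers):
    mono = monomers["APL-HaeIII-like"]
    model = TandemArrayModel(name="f", monomer=mono, copy_number=50,
                             sub_rate=0.08, enzyme=get_enzyme("HaeIII"),
                             site_conservation=0.9)
    g = simulate_genome([model], 20_000, seed=3)
    frags = digest_fragments(g.sequence, get_enzyme("HaeIII"))
    kept = select_hybridizing(frags, mono)
    copy_span = (min(c.start for c in g.copies), max(c.end for c in g.copies))
    assert kept
    for f in kept:
        assert f.start <= copy_span[1] and f.end >= copy_span[0]


def test_end_to_end_methylation_recovery(monomers):
    mhats = []
    for seed in range(5):
        model = TandemArrayModel(name="f", monomer=monomers["APL-HaeIII-like"],
                                 copy_number=5000, enzyme=get_enzyme("MspI"),
                                 site_conservation=0.9,
                                 methylation_fraction=0.8)
        g = simulate_genome([model], 0, seed=seed)
        mask = g.methylation_mask()
        obs_m = ladder_from_lengths(
            digest(g.sequence, get_enzyme("MspI"), mask), 190, k_max=6)
        obs_h = ladder_from_lengths(
            digest(g.sequence, get_enzyme("HpaII"), mask), 190, k_max=6)
        mhats.append(infer_methylation(obs_m, obs_h).m_hat)
    assert abs(float(np.mean(mhats)) - 0.8) < 0.05
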