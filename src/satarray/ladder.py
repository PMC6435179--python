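"""Quantitative model of Southern multimer ladders from tandem arrays.

When a probe for a tandem repeat monomer is hybridized against genomic DNA
digested with an enzyme cutting once per monomer, the blot shows a ladder of
bands at 1x, 2x, 3x ... the monomer length.  Treating cleavage of each
monomer junction as an independent Bernoulli event with probability ``c``
(the per-junction cleavage probability — site conservation times enzymatic
accessibility), the number of monomers in a fragment of a long array is
geometric, and the *mass* (hybridization signal) carried by k-mers is

    I(k)  proportional to  k * c^2 * (1 - c)^(k - 1)

The factor k enters because Southern signal scales with target mass, not
molecule count.  This closed form yields:

* a classification of ladder patterns — intensities decrease with k exactly
  when c > 1/2 (since I(2)/I(1) = 2(1-c)), separating conserved sites
  (descending ladder) from poorly conserved ones (ascending ladder);
* an inversion: from consecutive band intensities,
  c_hat(k) = 1 - (k / (k+1)) * I(k+1) / I(k);
* a methylation readout from the HpaII/MspI isoschizomer contrast: MspI
  sees c_M = c, HpaII sees c_H = c * (1 - m) where m is the fraction of
  methylated sites, so m_hat = 1 - c_H / c_M.

End fragments of a finite array are ignored (long-array approximation; the
relative error is below 1/copy_number).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from satarray.errors import ProfileError

#: m_hat thresholds mapping to the qualitative methylation vocabulary
METHYLATION_LABELS = (
    (0.1, "unmethylated"),
    (0.5, "weakly methylated"),
    (0.9, "highly methylated"),
    (float("inf"), "hypermethylated"),
)

#: intensity below which a band is considered undetectable
DETECTION_FLOOR = 1e-6


@dataclass(frozen=True)
class LadderObservation:
    """Relative band intensities I(k) for multimer orders k = 1..k_max."""

    intensities: tuple[float, ...]
    monomer_length: int | None = None

    def __post_init__(self) -> None:
        if not self.intensities:
            raise ProfileError("ladder needs at least one intensity")
        arr = np.asarray(self.intensities)
        if np.any(arr < 0):
            raise ProfileError("intensities must be non-negative")
        total = float(arr.sum())
        if total <= 0:
            raise ProfileError("ladder has zero total intensity")
        object.__setattr__(self, "intensities",
                           tuple(float(x) / total for x in self.intensities))

    @property
    def k_max(self) -> int:
        return len(self.intensities)

    def intensity(self, k: int) -> float:
        return self.intensities[k - 1]


@dataclass(frozen=True)
class CleavageEstimate:
    """Estimated per-junction cleavage probability with bootstrap SE."""

    c_hat: float
    se: float

    def __post_init__(self) -> None:
        if not 0 <= self.c_hat <= 1:
            raise ProfileError("c_hat must lie in [0, 1]")


@dataclass(frozen=True)
class MethylationCall:
    """Estimated methylation fraction and its qualitative label."""

    m_hat: float
    label: str
    c_msp: float
    c_hpa: float


def predict_ladder(c: float, k_max: int,
                   monomer_length: int | None = None) -> LadderObservation:
    """Predicted ladder I(k) ∝ k c² (1-c)^(k-1), normalized over k <= k_max."""
    if not 0 < c <= 1:
        raise ProfileError("cleavage probability must lie in (0, 1]")
    if k_max < 1:
        raise ProfileError("k_max must be >= 1")
    ks = np.arange(1, k_max + 1)
    raw = ks * c**2 * (1.0 - c)**(ks - 1)
    return LadderObservation(tuple(raw / raw.sum()), monomer_length)


def classify_ladder(obs: LadderObservation, *, monomer_threshold: float = 0.99,
                    ) -> str:
    """Classify a ladder: monomer_only | decreasing | increasing | flat.

    Trailing rungs below the detection floor are ignored: on a real blot a
    band that produced no signal does not enter the visual comparison.
    """
    if obs.k_max < 2:
        raise ProfileError("classification needs k_max >= 2")
    I = list(obs.intensities)
    while len(I) > 1 and I[-1] <= DETECTION_FLOOR:
        I.pop()
    if obs.intensities[0] > monomer_threshold or len(I) < 2:
        return "monomer_only"
    n = len(I)
    if all(I[k + 1] < I[k] for k in range(n - 1)):
        return "decreasing"
    if all(I[k + 1] > I[k] for k in range(n - 1)):
        return "increasing"
    return "flat"


def select_hybridizing(fragments, probe: str, *, kmer: int = 12,
                       min_fraction: float = 0.1):
    """Fragments that would light up under a probe on a Southern blot.

    A fragment "hybridizes" when at least ``min_fraction`` of its k-mers
    occur in the probe or its reverse complement.  Unrelated background
    fragments share essentially no 12-mers with a satellite probe, while
    true multimer fragments share many even at ~10% per-copy divergence.
    """
    from satarray.sequtils import reverse_complement

    probe_kmers = {probe[i:i + kmer] for i in range(len(probe) - kmer + 1)}
    probe_kmers |= {reverse_complement(p) for p in probe_kmers}
    out = []
    for f in fragments:
        seq = f.sequence if hasattr(f, "sequence") else f
        n = len(seq) - kmer + 1
        if n < 1:
            continue
        shared = sum(seq[i:i + kmer] in probe_kmers for i in range(n))
        if shared / n >= min_fraction:
            out.append(f)
    return out


def estimate_cleavage(obs: LadderObservation, *, n_bootstrap: int = 200,
                      seed: int = 0) -> CleavageEstimate:
    """Invert a ladder to the per-junction cleavage probability.

    Each consecutive band pair gives c_hat(k) = 1 - (k/(k+1)) I(k+1)/I(k);
    the estimate is their mean (clipped to [0, 1]) with a bootstrap standard
    error over the pairs.  A pure monomer signal means complete cleavage.
    """
    I = obs.intensities
    detectable = [k for k in range(obs.k_max) if I[k] > DETECTION_FLOOR]
    if detectable == [0]:  # pure monomer signal: complete cleavage
        return CleavageEstimate(1.0, 0.0)
    pairs = [
        1.0 - (k / (k + 1.0)) * I[k] / I[k - 1]
        for k in range(1, obs.k_max)
        if I[k - 1] > DETECTION_FLOOR and I[k] > DETECTION_FLOOR
    ]
    if not pairs:
        raise ProfileError("need at least two detectable consecutive bands")
    est = np.clip(pairs, 0.0, 1.0)
    c_hat = float(est.mean())
    if len(est) == 1:
        return CleavageEstimate(c_hat, 0.0)
    rng = np.random.default_rng(seed)
    boots = [
        float(np.mean(rng.choice(est, size=len(est), replace=True)))
        for _ in range(n_bootstrap)
    ]
    return CleavageEstimate(c_hat, float(np.std(boots)))


def infer_methylation(obs_msp: LadderObservation, obs_hpa: LadderObservation,
                      *, seed: int = 0) -> MethylationCall:
    """Estimate CpG methylation from the MspI/HpaII isoschizomer contrast.

    MspI cleaves CCGG regardless of internal CpG methylation, HpaII only
    when unmethylated; with per-site methylation fraction m, the apparent
    cleavage probabilities satisfy c_H = c_M (1 - m), hence
    m_hat = 1 - c_H / c_M (clipped to [0, 1]).  An HpaII ladder with no
    detectable low-order bands is called hypermethylated (m_hat = 1).
    """
    c_msp = estimate_cleavage(obs_msp, seed=seed)
    if c_msp.c_hat <= DETECTION_FLOOR:
        raise ProfileError(
            "MspI cleavage is ~0: the site itself is unconserved, "
            "methylation undetermined")
    lowest = obs_hpa.intensities[0]
    if lowest <= DETECTION_FLOOR:
        m_hat = 1.0
        c_hpa = 0.0
    else:
        c_hpa = estimate_cleavage(obs_hpa, seed=seed).c_hat
        m_hat = float(np.clip(1.0 - c_hpa / c_msp.c_hat, 0.0, 1.0))
    for threshold, label in METHYLATION_LABELS:
        if m_hat < threshold or threshold == float("inf"):
            return MethylationCall(m_hat=m_hat, label=label,
                                   c_msp=c_msp.c_hat, c_hpa=c_hpa)
    raise AssertionError("unreachable")


def ladder_from_lengths(fragment_lengths: list[int], monomer_length: int,
                        k_max: int = 6, tolerance: float = 0.05,
                        ) -> LadderObservation:
    """Build a ladder observation from digested fragment lengths.

    Fragment mass within ``tolerance`` (relative) of k * monomer_length is
    assigned to multimer order k; this is the hand-off from the in-silico
    gel to the ladder model.
    """
    if monomer_length < 1:
        raise ProfileError("monomer_length must be >= 1")
    intensities = np.zeros(k_max)
    for L in fragment_lengths:
        k = int(round(L / monomer_length))
        if 1 <= k <= k_max and abs(L - k * monomer_length) <= tolerance * k * monomer_length:
            intensities[k - 1] += L
    if intensities.sum() <= 0:
        raise ProfileError("no fragments near multiples of the monomer length")
    return LadderObservation(tuple(intensities), monomer_length)
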