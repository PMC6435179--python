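# Methods

This note documents the models, conventions and numerical choices behind
`satarray`, in the order the pipeline applies them.

## Scope and data

The package re-creates, in silico, the classical workflow for isolating and
characterizing centromeric satellite DNA: restriction digestion of genomic
DNA, gel electrophoresis and prominent-band excision, cloning and sequencing
of band fragments, family-level sequence statistics, dot-matrix structure
analysis, and Southern-blot multimer-ladder interpretation including the
HpaII/MspI methylation assay.  The concrete study system is the set of four
Anseriformes centromeric repeat families (the 190-bp duck *Hae*III family,
the 101-bp and 192-bp goose *Hinf*I families, and the 290-bp swan *Apa*I
family) together with their RBMII and CNM-type relatives.

The deposited records for these families live in the public nucleotide
databases and can be fetched with `scripts/fetch_accessions.py` when network
access is available.  Everything else in the repository runs offline: the
stand-in module (`satarray.standins`) constructs **synthetic** sequences
that embody the documented structure of each family (lengths, GC, designed
pairwise divergence, restriction-site content, internal repeat units,
cross-family homology segments, the A/T motif), and the simulator
(`satarray.simulate`) generates truth-labelled genomes around them.  All
tests and the acceptance script therefore measure whether the *analysis
machinery* recovers designed ground truth — they do not, and cannot,
re-measure the deposited sequences themselves.

## Tandem-array simulator

A family is modelled as `copy_number` tandem copies of a monomer.  Each copy
is mutated independently: per-site substitution with probability `q`
(uniform over the three alternative bases) and single-base deletion or
duplication with probability `indel_rate/2` each.  Two features of real
satellite arrays get dedicated parameters rather than emerging from the
site-wise process:

* **Designated restriction site.**  The first occurrence of the releasing
  enzyme's site in the monomer is excluded from background mutation and is
  instead kept intact with probability `c` per copy, otherwise ablated by a
  single substitution at a fixed position inside the site (the minimal
  change destroying the IUPAC match).  This gives exact binomial control of
  site conservation — the quantity the ladder model later inverts.
* **CpG methylation.**  Every CpG in a copy is methylated independently
  with probability `m`.  Methylation is consumed only by
  methylation-blocked enzymes (HpaII); its observable effect is an apparent
  cleavage probability `c·(1−m)` at CCGG sites.

Arrays are embedded at random non-overlapping positions in i.i.d. uniform
background; every copy is annotated with 1-based coordinates, site status
and per-CpG methylation flags.  All randomness flows from integer seeds
through `numpy.random.SeedSequence`; identical inputs give byte-identical
genomes.  The i.i.d. divergence model is an assumption — real satellite
arrays evolve by homogenization processes (unequal crossover, gene
conversion) that correlate copies; the simulator reproduces marginal
divergence levels, not haplotype structure.  Higher-order repeat structure
and recombination dynamics are out of scope.

## Digestion, gel, band excision

Digestion is linear and complete: every unblocked site occurrence is cut at
the enzyme's offset, so fragment lengths always sum to the input length.
All panel enzymes are palindromic, so forward-strand scanning suffices.
The gel is a mass-weighted histogram of fragment lengths (default 10-bp
bins, resolving the 100/200/300-bp region of a 3% agarose gel); a
*prominent band* is a local maximum whose mass is at least 5× the median
mass of the other non-empty bins.  The prominence rule is this package's
operationalization of "prominent band on an ethidium gel"; both the bin
width and the factor are configuration values.  Band excision takes
fragments within one bin of the band, and the in-silico "cloning" step
prefers fragments nearest the band center (the densest part of the band),
up to 30 clones.

## Family statistics

Pairwise identity uses a single-gap convention suited to satellite monomer
comparisons: after global alignment, maximal runs of gap columns of length
≥ 2 are excluded from the calculation entirely (insertions/deletions are
"eliminated"), while an isolated one-nucleotide gap stays in the
denominator and counts as a difference.  Both the run-length threshold and
the counting rule are configurable.

Alignment scores are match +1, mismatch −1, gap open −2, gap extend −0.5.
End gaps get a reduced affine penalty (open −1, extend −0.1): cloned
monomers are arbitrary-phase excisions of different lengths, so terminal
overhangs are near-expected.  Fully free end gaps would tie with interior
gaps on short sequences, and full-priced end gaps cause the aligner to
fragment a long terminal truncation into interior-gap/match mosaics that
harvest chance matches — both distort the identity convention.  Identity is
computed with the pair in a canonical order so co-optimal traceback choices
cannot make it asymmetric.

The consensus is a majority-rule star alignment: every fragment is aligned
to a guide and columns are voted on; gap-majority columns are dropped (so a
minority of fragments with a large terminal deletion does not shorten the
consensus), ties break in A<C<G<T order.  `summarize_family` chooses the
guide as the identity-matrix medoid among the longest fragments, which
keeps an aberrant co-migrating clone from anchoring the star.  A full
progressive profile alignment was not needed at the divergence levels of
satellite families (≥ ~75% identity); the star approximation recovers a
190-bp monomer from 20 copies at 8% per-copy divergence with ≥ 99%
accuracy (tested over 50 seeds).

GC content is (G+C)/length per fragment; family values are means/ranges
over fragments.

## Dot-matrix analysis

Windows of length `w` are scored under the log-odds matrix of the Kimura
two-parameter model at distance `d` substitutions/site with
transition/transversion ratio `kappa`, uniform base frequencies:

    s(i, j) = scale · log2( P_ij(d) / 0.25 )

with the standard K80 closed form for `P_ij` (verified against a
matrix-exponential evaluation of the rate matrix).  Defaults are `d = 2.0`
(200 PAM), `kappa = 2`, `w = 20`, threshold `T = 22`.  The published
window-20/threshold-22 convention is only meaningful for a scaled matrix;
with `scale = 10` the threshold corresponds to roughly 55% identity within
a window, which is consistent with the ~47–59%-identity segments such
analyses are expected to detect.  The scale is exposed as a parameter.

*Internal repeat units*: in a self comparison, hits strictly above the main
diagonal are grouped by diagonal offset; offsets supported by runs of at
least `w/2` consecutive hits qualify, the modal qualifying offset is the
unit length, and the count is `floor(length/unit)`.  A unit must recur, so
offsets above half the sequence length are ignored.

*Cross-family segments*: dense hit runs (≥ 3 consecutive hits) on a
diagonal are merged across gaps of at most two windows, re-aligned
globally, and trimmed to the maximal-scoring contiguous column run
(+1 match / −1 mismatch-or-gap).  The trimming clips the up-to-one-window
overshoot into unrelated flanking sequence that window-based detection
produces; without it, segment identity is diluted by flanking noise.
Isolated single hits neither seed nor bridge segments — on unrelated random
200-mers this keeps spurious ≥ 40-bp, ≥ 70%-identity segments below ~5% of
comparisons.

*A/T motif*: the CNM-type signature is a maximal A-run of 3–5 nt and a
maximal T-run of 3–5 nt separated by a 6–7-bp spacer, in either order
(total 12–17 bp).  Run maximality (no A adjacent to an A-run) prevents
double counting.  The motif family is closed under reverse complement at
identical coordinates, so scanning the forward strand for both orders
equals scanning both strands; the scanner is verified against an exhaustive
per-decomposition regex oracle.

## Multimer-ladder model

Treating cleavage of each monomer junction in a long tandem array as an
independent Bernoulli event with probability `c`, a released fragment spans
`k` monomers with probability `c(1−c)^(k−1)` (geometric), and the *mass*
observed on a Southern blot at rung `k` is

    I(k) ∝ k · c² · (1−c)^(k−1)

The factor `k` is there because hybridization signal scales with target
mass, not molecule count.  End fragments of finite arrays are ignored (the
long-array approximation; relative error below `1/copy_number`).  The model
is this package's formalization of the qualitative ladder reasoning used in
satellite Southern blots; it assumes independent junctions and complete
digestion.

Consequences used throughout:

* `I(2)/I(1) = 2(1−c)`, so intensities strictly decrease with `k` exactly
  when `c > 1/2`: conserved sites give descending ladders, poorly conserved
  sites ascending ones.  (Strict ascent through rung `k` requires
  `c < 1/(k+1)`; between `1/4` and `1/2` a truncated 4-rung ladder is
  humped, classified "flat".)
* Inversion: `ĉ_k = 1 − (k/(k+1)) · I(k+1)/I(k)` for each consecutive
  rung pair; the estimate is the unweighted mean over pairs with a
  bootstrap standard error.  On exact model input the inversion is the
  identity to machine precision.  On finite simulations the ratio of noisy
  masses is slightly biased, so recovered `c` sits ~0.01 below truth at
  5000 copies — within the ±0.02 tolerance used in validation.
* Methylation: with MspI blind to CpG methylation and HpaII blocked by it,
  `c_M = c` and `c_H = c(1−m)`, so `m̂ = 1 − c_H/c_M` (clipped to [0, 1]).
  Labels: < 0.1 unmethylated, 0.1–0.5 weakly, 0.5–0.9 highly, > 0.9
  hypermethylated; an HpaII ladder with no detectable monomer rung is
  called hypermethylated outright.  Recovery degrades with per-copy
  divergence (weakly populated high rungs make the ratio estimates noisy);
  at zero divergence `m = 0.8` is recovered within ±0.05 over 20 seeds.

Ladders are measured on *probe-hybridizing* fragments only: a fragment
counts if at least 10% of its 12-mers occur in the probe (or its reverse
complement), mirroring the probe specificity of a Southern blot.  Without
this filter, background fragments that happen to fall near multimer lengths
contaminate the upper rungs.  Rungs are fragment masses within 5% of
`k × monomer length`, `k ≤ 6` by default; classification ignores trailing
rungs below the detection floor.

## Stand-in construction details

Fragment sets are built from monomers by substitutions at mutually disjoint,
never-adjacent positions using GC-preserving complement swaps, so the
designed identity and GC statistics are exact rationals independent of the
seed, and the family consensus equals the monomer.  Per-family substitution
counts were chosen analytically so that all-pairs identity mean and range
land on the documented family values (e.g. for the five 190-bp-family
fragments, counts (12, 18, 23) on the full monomers and (7, 10) on the two
161-bp truncated fragments give mean 83.6%, range 78.4–89.4%).  Monomer
composition is drawn with exact GC counts, required sites are planted at
fixed offsets, and deterministic rejection over derived sub-seeds enforces
the structural constraints (site uniqueness/absence, motif presence only in
the 192-bp family, exact GC).  Never-adjacent substitution positions avoid
a subtle artifact: two neighbouring edits inside locally self-similar
sequence can be re-explained by the aligner as a cheap single-base slip,
perturbing the designed identities.

What passing on stand-ins shows — and what it does not: the pipeline
measures divergence, GC, consensus length, internal units and homology
segments correctly on sequences with realistic satellite structure; it does
not certify the numerical values of the real deposited records, which
require the download path.

## Validation problem sizes

Chosen to exercise the asymptotics the models assume while keeping the full
suite around half a minute: binomial checks at 10⁴ copies; ladder
closed-form vs Monte-Carlo at 10⁵ junctions; parameter recovery at 5000
copies × 20 seeds; genome screens on 500 copies in 100 kb background;
scanner-vs-oracle equivalence on 10⁴ random kilobase sequences.

## Known limitations

* Partial digestion kinetics, star activity and gel-migration physics are
  not modelled; "band intensity" is exact fragment mass.
* The ladder model assumes independent junctions; clustered methylation or
  correlated site loss would bias `ĉ` in ways the bootstrap SE does not
  capture.
* The identity convention interprets "eliminating insertions and deletions
  but including one nucleotide gap" literally (runs ≥ 2 excluded, single
  gaps counted as differences); other readings are reachable through the
  configuration.
* Dot-plot hit significance (E-values) is not calibrated; the threshold
  score is the operative parameter.
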