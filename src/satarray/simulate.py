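"""Truth-labelled tandem-array genome simulator.

Generates the in-silico stand-in for genomic DNA carrying centromeric
satellite arrays: ``copy_number`` mutated copies of a monomer concatenated
head-to-tail, with (optionally) a designated restriction site whose survival
is controlled by a per-copy conservation probability ``c``, per-copy CpG
methylation drawn with probability ``m``, and the array embedded in i.i.d.
uniform-base background sequence.  Every copy is annotated so downstream
stages (digestion, band extraction, family characterization, ladder
inference) can be scored against ground truth.

Mutation model: per-site independent substitution with probability ``q``
(uniformly to one of the three other bases) and single-base deletion or
duplication with probability ``indel_rate/2`` each.  The designated
restriction site is never hit by this background process; instead it is kept
intact with probability ``c`` and otherwise ablated by a single substitution
at a fixed position inside the site — the minimal change destroying the
IUPAC match.  This gives exact binomial control of site conservation, which
is what the multimer-ladder model downstream inverts.

All randomness flows from integer seeds through ``numpy.random.SeedSequence``,
so identical inputs produce byte-identical genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from satarray.enzymes import Enzyme
from satarray.errors import ModelError
from satarray.sequtils import IUPAC, validate_dna

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode()


def _mutate_array(arr: np.ndarray, q: float, indel_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply the per-site substitution/indel process to an encoded sequence."""
    n = arr.size
    if n == 0:
        return arr
    out = arr
    if q > 0:
        mask = rng.random(n) < q
        shift = rng.integers(1, 4, size=n)
        out = (out + shift * mask) % 4
    if indel_rate > 0:
        r = rng.random(n)
        counts = np.ones(n, dtype=np.int64)
        counts[r < indel_rate / 2] = 0            # deletion
        counts[(r >= indel_rate / 2) & (r < indel_rate)] = 2  # duplication
        out = np.repeat(out, counts)
    return out.astype(np.uint8)


def mutate_monomer(monomer: str, q: float, indel_rate: float, seed: int) -> str:
    """Return a mutated variant of ``monomer``; reproducible from ``seed``.

    Each site is independently substituted with probability ``q`` (uniformly
    to one of the three other bases) and deleted or duplicated with
    probability ``indel_rate/2`` each.
    """
    validate_dna(monomer, what="monomer")
    if not (0 <= q < 1) or not (0 <= indel_rate < 1):
        raise ModelError("mutation rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    return _decode(_mutate_array(_encode(monomer), q, indel_rate, rng))


@dataclass(frozen=True)
class TandemArrayModel:
    """Generative model for one satellite repeat family.

    Parameters
    ----------
    name:
        Family label recorded in the truth annotations.
    monomer:
        Consensus monomer sequence (A/C/G/T), typically 50-500 bp.
    copy_number:
        Number of tandem copies (>= 1).
    sub_rate:
        Per-site substitution probability per copy, in [0, 1).
    indel_rate:
        Per-site single-base insertion/deletion probability per copy, in [0, 1).
    enzyme:
        Optional enzyme whose first recognition-site occurrence in the monomer
        becomes the designated, conservation-controlled site.
    site_conservation:
        Probability the designated site survives in a copy, in [0, 1].
    methylation_fraction:
        Probability each CpG in a copy is methylated, in [0, 1].
    block_deletion_length / block_deletion_prob:
        Optional terminal block deletion applied per copy (off by default);
        models the occasional large internal deletion seen in cloned repeat
        fragments, as opposed to the single-base indel background.
    """

    name: str
    monomer: str
    copy_number: int
    sub_rate: float = 0.0
    indel_rate: float = 0.0
    enzyme: Enzyme | None = None
    site_conservation: float = 1.0
    methylation_fraction: float = 0.0
    block_deletion_length: int = 0
    block_deletion_prob: float = 0.0

    def __post_init__(self) -> None:
        validate_dna(self.monomer, what=f"monomer of {self.name!r}")
        if self.copy_number < 1:
            raise ModelError(f"{self.name}: copy_number must be >= 1")
        if not (0 <= self.sub_rate < 1) or not (0 <= self.indel_rate < 1):
            raise ModelError(f"{self.name}: mutation rates must lie in [0, 1)")
        if self.sub_rate + self.indel_rate >= 1:
            raise ModelError(f"{self.name}: sub_rate + indel_rate must be < 1")
        if not (0 <= self.site_conservation <= 1):
            raise ModelError(f"{self.name}: site_conservation must lie in [0, 1]")
        if not (0 <= self.methylation_fraction <= 1):
            raise ModelError(f"{self.name}: methylation_fraction must lie in [0, 1]")
        if self.enzyme is not None and self.designated_site() is None:
            raise ModelError(
                f"{self.name}: monomer contains no {self.enzyme.name} site"
            )

    def designated_site(self) -> tuple[int, int] | None:
        """(0-based start, length) of the first enzyme site in the monomer."""
        if self.enzyme is None:
            return None
        m = self.enzyme.regex.search(self.monomer)
        if m is None:
            return None
        return m.start(), len(self.enzyme.site)

    def ablation(self) -> tuple[int, str]:
        """Fixed (offset within site, replacement base) destroying the match.

        The most central non-fully-degenerate site position is substituted to
        the alphabetically first base excluded by its IUPAC code.
        """
        assert self.enzyme is not None
        site = self.enzyme.site
        candidates = [i for i, ch in enumerate(site) if len(IUPAC[ch]) < 4]
        if not candidates:
            raise ModelError(f"{self.name}: site {site!r} cannot be ablated")
        mid = (len(site) - 1) / 2
        pos = min(candidates, key=lambda i: (abs(i - mid), i))
        base = next(b for b in "ACGT" if b not in IUPAC[site[pos]])
        return pos, base


@dataclass(frozen=True)
class CopyAnnotation:
    """Ground truth for one repeat copy (1-based inclusive coordinates)."""

    family: str
    start: int
    end: int
    site_intact: bool | None
    cpg_positions: tuple[int, ...]   # global 1-based position of each CpG 'C'
    methylated: tuple[bool, ...]     # parallel to cpg_positions


@dataclass(frozen=True)
class SimulatedGenome:
    """A simulated genome with per-copy truth annotations."""

    sequence: str
    copies: tuple[CopyAnnotation, ...]
    seed: int

    def __post_init__(self) -> None:
        n = len(self.sequence)
        prev_end = 0
        for c in sorted(self.copies, key=lambda c: c.start):
            if not (1 <= c.start <= c.end <= n):
                raise ModelError("truth interval outside sequence bounds")
            if c.start <= prev_end:
                raise ModelError("truth intervals overlap")
            prev_end = c.end

    @property
    def truth(self) -> list[tuple[str, int, int, tuple[bool, ...]]]:
        return [(c.family, c.start, c.end, c.methylated) for c in self.copies]

    def methylated_positions(self) -> frozenset[int]:
        """Global 1-based positions of methylated CpG cytosines."""
        return frozenset(
            p for c in self.copies
            for p, f in zip(c.cpg_positions, c.methylated) if f
        )

    def methylation_mask(self) -> np.ndarray:
        """Boolean per-position (0-based) methylation flags for digestion."""
        mask = np.zeros(len(self.sequence), dtype=bool)
        for p in self.methylated_positions():
            mask[p - 1] = True
        return mask

    def write_fasta(self, path) -> None:
        from satarray.fastaio import write_fasta

        write_fasta(path, [("simulated_genome", self.sequence)],
                    description=f"seed={self.seed}")

    def write_truth(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("family\tstart\tend\tsite_intact\tmethylation\n")
            for c in self.copies:
                meth = "".join("1" if f else "0" for f in c.methylated) or "-"
                intact = "-" if c.site_intact is None else str(int(c.site_intact))
                fh.write(f"{c.family}\t{c.start}\t{c.end}\t{intact}\t{meth}\n")


def _cpg_positions(seq: str) -> list[int]:
    """0-based positions i with seq[i:i+2] == 'CG'."""
    out = []
    i = seq.find("CG")
    while i != -1:
        out.append(i)
        i = seq.find("CG", i + 1)
    return out


def build_tandem_array(model: TandemArrayModel, seed: int,
                       ) -> tuple[str, list[CopyAnnotation]]:
    """Concatenate ``copy_number`` independently mutated monomer copies.

    The designated restriction site (if any) is kept intact with probability
    ``site_conservation`` per copy and otherwise ablated by one substitution;
    CpG methylation flags are drawn per copy with ``methylation_fraction``.
    Coordinates in the returned annotations are 1-based inclusive within the
    array.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    mono = _encode(model.monomer)
    site = model.designated_site()
    if site is not None:
        site_start, site_len = site
        abl_off, abl_base = model.ablation()
        abl_code = int(_ENCODE[ord(abl_base)])
    parts: list[str] = []
    annots: list[CopyAnnotation] = []
    offset = 0
    for _ in range(model.copy_number):
        if site is None:
            arr = _mutate_array(mono, model.sub_rate, model.indel_rate, rng)
            intact: bool | None = None
        else:
            prefix = _mutate_array(mono[:site_start], model.sub_rate,
                                   model.indel_rate, rng)
            core = mono[site_start:site_start + site_len].copy()
            suffix = _mutate_array(mono[site_start + site_len:], model.sub_rate,
                                   model.indel_rate, rng)
            intact = bool(rng.random() < model.site_conservation)
            if not intact:
                core[abl_off] = abl_code
            arr = np.concatenate([prefix, core, suffix])
        if model.block_deletion_prob > 0 and model.block_deletion_length > 0:
            if rng.random() < model.block_deletion_prob:
                arr = arr[: max(1, arr.size - model.block_deletion_length)]
        copy_seq = _decode(arr)
        cpg_local = _cpg_positions(copy_seq)
        if model.methylation_fraction > 0 and cpg_local:
            flags = rng.random(len(cpg_local)) < model.methylation_fraction
        else:
            flags = np.zeros(len(cpg_local), dtype=bool)
        annots.append(CopyAnnotation(
            family=model.name,
            start=offset + 1,
            end=offset + len(copy_seq),
            site_intact=intact,
            cpg_positions=tuple(offset + p + 1 for p in cpg_local),
            methylated=tuple(bool(f) for f in flags),
        ))
        parts.append(copy_seq)
        offset += len(copy_seq)
    return "".join(parts), annots


def simulate_genome(families: list[TandemArrayModel], background_length: int,
                    seed: int) -> SimulatedGenome:
    """Embed family arrays at random non-overlapping positions in background.

    Background bases are i.i.d. uniform A/C/G/T.  Array placement splits the
    background into random gaps, so arrays can never overlap; adjacency is
    allowed.  Deterministic given ``seed``.
    """
    if background_length < 0:
        raise ModelError("background_length must be >= 0")
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(len(families) + 2)
    placement_rng = np.random.default_rng(child[0])
    bg_rng = np.random.default_rng(child[1])
    arrays = [
        build_tandem_array(fam, seed=int(child[i + 2].generate_state(1)[0] % (2**31)))
        for i, fam in enumerate(families)
    ]
    k = len(arrays)
    if k:
        cuts = np.sort(placement_rng.integers(0, background_length + 1, size=k))
        gaps = np.diff(np.concatenate([[0], cuts, [background_length]]))
    else:
        gaps = np.array([background_length])
    background = _decode(bg_rng.integers(0, 4, size=background_length).astype(np.uint8))
    pieces: list[str] = []
    copies: list[CopyAnnotation] = []
    pos = 0       # consumed background
    offset = 0    # genome length built so far
    for i, (arr_seq, annots) in enumerate(arrays):
        g = int(gaps[i])
        pieces.append(background[pos:pos + g])
        pos += g
        offset += g
        for c in annots:
            copies.append(CopyAnnotation(
                family=c.family,
                start=c.start + offset,
                end=c.end + offset,
                site_intact=c.site_intact,
                cpg_positions=tuple(p + offset for p in c.cpg_positions),
                methylated=c.methylated,
            ))
        pieces.append(arr_seq)
        offset += len(arr_seq)
    pieces.append(background[pos:])
    return SimulatedGenome("".join(pieces), tuple(copies), seed)
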