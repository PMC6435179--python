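"""End-to-end in-silico screen: digest → gel → clone → characterize → interpret.

Mirrors the wet-lab path from genomic DNA to a characterized satellite
family: for every enzyme in the panel the genome is digested, the fragment
lengths are run on an in-silico gel, prominent bands are detected, the
fragments under each band are "cloned" and summarized as a repeat family,
the consensus is scanned for the centromeric A/T motif, and the multimer
ladder around the band is inverted to a per-junction cleavage estimate.
If the panel contains both MspI and HpaII, their ladders for the same band
are contrasted into a CpG methylation call.

Stage failures are logged and skipped; the pipeline continues with the
remaining enzymes.  Given the same genome, configuration and seed, the
emitted report is byte-identical.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from satarray.config import PipelineConfig
from satarray.digest import Band, GelProfile, digest_fragments, gel_profile
from satarray.digest import extract_band_fragments
from satarray.enzymes import get_enzyme
from satarray.errors import SatarrayError
from satarray.family import RepeatFragment, RepeatFamilySummary, summarize_family
from satarray.ladder import (classify_ladder, estimate_cleavage,
                             infer_methylation, ladder_from_lengths,
                             select_hybridizing)
from satarray.motif import scan_cnm_motif

log = logging.getLogger("satarray.pipeline")


@dataclass
class FamilyReport:
    """One characterized band: family summary plus ladder interpretation."""

    enzyme: str
    band_center: float
    band_mass: int
    n_clones: int
    summary: RepeatFamilySummary | None
    n_motif_hits: int
    ladder_class: str | None
    cleavage_estimate: float | None
    cleavage_se: float | None


@dataclass
class PipelineReport:
    families: list[FamilyReport] = field(default_factory=list)
    profiles: dict[str, GelProfile] = field(default_factory=dict)
    methylation: dict[float, tuple[float, str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.families:
            s = r.summary
            rows.append({
                "enzyme": r.enzyme,
                "band_bp": round(r.band_center, 1),
                "band_mass": r.band_mass,
                "n_clones": r.n_clones,
                "consensus_bp": s.consensus_length if s else None,
                "identity_mean": round(s.identity_mean, 1) if s else None,
                "identity_min": round(s.identity_range[0], 1) if s else None,
                "identity_max": round(s.identity_range[1], 1) if s else None,
                "gc_mean": round(s.gc_mean, 1) if s else None,
                "motif_hits": r.n_motif_hits,
                "ladder": r.ladder_class,
                "cleavage_c": (round(r.cleavage_estimate, 3)
                               if r.cleavage_estimate is not None else None),
            })
        return pd.DataFrame(rows)


def _characterize_band(sequence: str, enzyme_name: str, band: Band,
                       profile: GelProfile, fragments, config: PipelineConfig,
                       ) -> FamilyReport:
    clones = extract_band_fragments(fragments, band, profile)
    # clone preferentially from the densest part of the band
    clones = sorted(clones, key=lambda f: (abs(len(f) - band.center), f.start))
    clones = clones[: config.max_clones_per_band]
    repeat_frags = [
        RepeatFragment(id=f"{enzyme_name}-{band.bin_start}-{i:03d}",
                       sequence=f.sequence,
                       family=f"{enzyme_name}-{round(band.center)}bp")
        for i, f in enumerate(clones, start=1)
    ]
    summary = None
    n_motifs = 0
    if len(repeat_frags) >= 2:
        summary = summarize_family(
            repeat_frags, gap_run_threshold=config.gap_run_threshold,
            count_short_gaps=config.count_short_gaps, **config.align_kwargs())
        n_motifs = len(scan_cnm_motif(summary.consensus))
    ladder_class = None
    c_hat = c_se = None
    try:
        # a Southern ladder only shows probe-homologous fragments
        probe = summary.consensus if summary else (
            repeat_frags[0].sequence if repeat_frags else None)
        blot = (select_hybridizing(fragments, probe) if probe else fragments)
        obs = ladder_from_lengths([len(f) for f in blot],
                                  monomer_length=round(band.center),
                                  k_max=config.k_max,
                                  tolerance=config.multimer_tolerance)
        ladder_class = classify_ladder(
            obs, monomer_threshold=config.monomer_only_threshold)
        est = estimate_cleavage(obs, seed=config.seed)
        c_hat, c_se = est.c_hat, est.se
    except SatarrayError as exc:
        log.info("ladder inference skipped for %s @%.0f bp: %s",
                 enzyme_name, band.center, exc)
    return FamilyReport(
        enzyme=enzyme_name, band_center=band.center, band_mass=band.mass,
        n_clones=len(repeat_frags), summary=summary, n_motif_hits=n_motifs,
        ladder_class=ladder_class, cleavage_estimate=c_hat, cleavage_se=c_se)


def run_pipeline(sequence: str, config: PipelineConfig | None = None,
                 methylation: np.ndarray | None = None,
                 out_dir: str | None = None) -> PipelineReport:
    """Run the full screen on a genome sequence.

    ``methylation`` is an optional boolean per-position array (e.g. from a
    simulated genome's truth) consumed by methylation-blocked enzymes.
    When ``out_dir`` is given, one TSV per stage plus a combined report are
    written there.
    """
    config = config or PipelineConfig()
    report = PipelineReport()
    if not sequence:
        log.info("empty genome: empty report")
        if out_dir:
            _write_outputs(report, out_dir)
        return report
    ladders_by_band: dict[str, dict[int, object]] = {}
    for enzyme_name in config.enzymes:
        try:
            enzyme = get_enzyme(enzyme_name)
            fragments = digest_fragments(sequence, enzyme, methylation)
            profile = gel_profile([len(f) for f in fragments],
                                  bin_width=config.bin_width,
                                  prominence_factor=config.prominence_factor)
            report.profiles[enzyme_name] = profile
            log.info("%s: %d fragments, %d bands", enzyme_name,
                     len(fragments), len(profile.bands))
            for band in profile.bands[: config.max_bands]:
                rep = _characterize_band(sequence, enzyme_name, band, profile,
                                         fragments, config)
                report.families.append(rep)
                probe = rep.summary.consensus if rep.summary else None
                ladders_by_band.setdefault(enzyme_name, {})[
                    round(band.center)] = (fragments, probe)
        except SatarrayError as exc:
            log.warning("enzyme %s failed: %s — continuing", enzyme_name, exc)
    # isoschizomer contrast wherever both MspI and HpaII saw a band
    if "MspI" in ladders_by_band and "HpaII" in config.enzymes:
        hpa = get_enzyme("HpaII")
        hpa_fragments = digest_fragments(sequence, hpa, methylation)
        for monomer, (msp_fragments, probe) in ladders_by_band["MspI"].items():
            try:
                msp_blot = (select_hybridizing(msp_fragments, probe)
                            if probe else msp_fragments)
                hpa_blot = (select_hybridizing(hpa_fragments, probe)
                            if probe else hpa_fragments)
                obs_m = ladder_from_lengths([len(f) for f in msp_blot],
                                            monomer, k_max=config.k_max,
                                            tolerance=config.multimer_tolerance)
                obs_h = ladder_from_lengths([len(f) for f in hpa_blot],
                                            monomer, k_max=config.k_max,
                                            tolerance=config.multimer_tolerance)
                call = infer_methylation(obs_m, obs_h, seed=config.seed)
                report.methylation[monomer] = (call.m_hat, call.label)
            except SatarrayError as exc:
                log.info("methylation call skipped @%d bp: %s", monomer, exc)
    if out_dir:
        _write_outputs(report, out_dir)
    return report


def _write_outputs(report: PipelineReport, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    report.to_frame().to_csv(os.path.join(out_dir, "families.tsv"),
                             sep="\t", index=False)
    rows = []
    for enzyme, profile in report.profiles.items():
        for bin_start, bin_end, mass, is_band in profile.to_rows():
            rows.append({"enzyme": enzyme, "bin_start": bin_start,
                         "bin_end": bin_end, "mass": mass, "is_band": is_band})
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "gel_profiles.tsv"),
                              sep="\t", index=False)
    meth_rows = [
        {"monomer_bp": k, "m_hat": round(m, 3), "label": label}
        for k, (m, label) in report.methylation.items()
    ]
    pd.DataFrame(meth_rows).to_csv(os.path.join(out_dir, "methylation.tsv"),
                                   sep="\t", index=False)
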