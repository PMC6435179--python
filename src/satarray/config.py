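"""Pipeline configuration: every tunable constant in one validated place."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field

from satarray.errors import SatarrayError


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end screen → characterize → interpret run.

    Defaults reproduce the documented behaviour of every module: 10-bp gel
    bins with 5x band prominence, the +1/-1/-2/-0.5 alignment scores with
    the single-gap identity convention (gap runs >= 2 excluded), the
    window-20 / threshold-22 dot-matrix under the K80 200PAM matrix, and
    6-rung ladders with a 5% multimer-length tolerance.
    """

    # digestion / gel
    enzymes: list[str] = field(default_factory=lambda: ["HaeIII", "HinfI", "ApaI"])
    bin_width: int = 10
    prominence_factor: float = 5.0
    max_bands: int = 3
    max_clones_per_band: int = 30
    # alignment / identity convention
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5
    gap_run_threshold: int = 2
    count_short_gaps: bool = True
    # dot matrix
    window: int = 20
    threshold: float = 22.0
    pam_distance: float = 2.0
    kappa: float = 2.0
    matrix_scale: float = 10.0
    # ladder model
    k_max: int = 6
    multimer_tolerance: float = 0.05
    monomer_only_threshold: float = 0.99
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise SatarrayError("bin_width must be >= 1")
        if self.prominence_factor <= 0:
            raise SatarrayError("prominence_factor must be positive")
        if self.gap_run_threshold < 1:
            raise SatarrayError("gap_run_threshold must be >= 1")
        if self.window < 1:
            raise SatarrayError("window must be >= 1")
        if self.k_max < 2:
            raise SatarrayError("k_max must be >= 2")
        if not 0 < self.multimer_tolerance < 0.5:
            raise SatarrayError("multimer_tolerance must lie in (0, 0.5)")

    @classmethod
    def from_toml(cls, path: str) -> "PipelineConfig":
        """Load a flat key = value TOML config; unknown keys are an error."""
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SatarrayError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def align_kwargs(self) -> dict:
        return dict(match=self.match, mismatch=self.mismatch,
                    gap_open=self.gap_open, gap_extend=self.gap_extend)
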