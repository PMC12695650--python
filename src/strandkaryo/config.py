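"""Run configuration with documented defaults.

Every tunable parameter of the pipeline lives here so that CLI subcommands,
library calls and the synthetic generator share one source of defaults.
Unknown keys in a YAML config are rejected rather than silently ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import yaml

__all__ = ["RunConfig", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # -- binning / detection
    bin_size: int = 200_000          # bp per bin
    min_event_size: int = 200_000    # bp; calls below this are filtered
    # -- per-cell QC
    min_fragments: int = 50_000      # cells with fewer mapped fragments fail QC
    # -- generator
    depth: int = 285_000             # median mapped fragments per cell
    nb_dispersion: float = 2.0       # NB variance = dispersion * mean
    background_flip: float = 0.02    # fraction of reads mapping to the wrong strand
    tag_fraction: float = 0.15       # fraction of reads carrying a haplotype tag
    sce_mean: float = 6.0            # Poisson mean of SCEs per cell, genome-wide
    daughter_sce_mean: float = 0.0   # SCEs private to one daughter of a sister pair
    event_rate: float = 1.0          # injected CA events per cell (Poisson)
    min_event_bins: int = 2          # minimum injected event size, in bins
    # -- segmentation
    penalty: float = 10.0            # per-breakpoint cost, standardized units
    max_copies: int = 6              # state-space cap on total copy number
    mask_coverage_frac: float = 0.25  # blacklist bins below this fraction of median
    # -- classification
    event_group_gap_bins: int = 2    # deviations further apart are separate events
    chromothripsis_min_switches: int = 5
    whole_arm_frac: float = 0.90
    isoacentric_alpha: float = 0.01
    locus_tolerance_bins: int = 1
    # -- sister pairing
    reciprocity_threshold: float = 0.95
    sce_tolerance_bins: int = 1
    full_reciprocity_coverage: float = 0.90
    # -- misc
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_config(path) -> RunConfig:
    """Load a YAML config file; missing keys take defaults, unknown keys error."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config file must contain a mapping")
    return RunConfig.from_dict(data)
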