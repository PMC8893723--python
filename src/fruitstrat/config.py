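"""Pipeline configuration.

All numeric thresholds used anywhere in the pipeline live here, with
defaults equal to the reference thresholds of the analysis, so that a
default run needs no overrides. The config serializes losslessly to/from YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, plus seed and I/O paths.

    Attributes are grouped by stage; see the field comments for legal
    ranges. ``validate()`` enforces the ranges and is called by
    ``from_yaml``.
    """

    # global
    seed: int = 0
    input_dir: str = "."
    output_dir: str = "results"

    # devexpr
    fc_threshold: float = 4.0          # >= 1
    min_fpkm: float = 4.0              # peak group mean must exceed this
    zero_floor: float = 0.1            # pseudo-floor for zero group means

    # phylostrat
    tai_log_mode: str = "log2p1"       # "log2p1" | "log2drop"
    age_scale: str = "raw"             # "raw" | "minmax"

    # variant partition / editing candidates
    min_phred: int = 30
    min_vrs: int = 3                   # editing: min variant read support
    min_rs: int = 10                   # editing: min total read support
    min_rvf: float = 0.1               # editing: min relative variant frequency

    # allele-specific expression
    max_hd: int = 15                   # reads more divergent are indecisive
    divergent_rule: str = "any"        # "any" | "closer" (which genome Hd>15 applies to)
    ase_min_fpkm: float = 2.0
    min_decisive: int = 16
    max_indecisive_frac: float = 0.8
    s2_lo: float = 0.31
    s2_hi: float = 0.68
    s4_lo: float = 0.2
    s4_hi: float = 0.8
    gm_mode: str = "mirrored"          # "mirrored" | "direct" geometric-mean rule

    # orthology
    evalue_cutoff: float = 1e-5
    long_cov: float = 0.2
    short_cov: float = 0.8
    mcl_inflation: float = 2.0
    mcl_tol: float = 1e-8
    mcl_max_iter: int = 200
    min_dev_species: int = 4
    min_dev_prop: float = 0.5
    prop_denominator: str = "present"  # "present" | "all"

    # synthetic data
    n_genes: int = 2000
    frac_dev: float = 0.2
    fc_low: float = 4.0
    fc_high: float = 16.0
    noise_sd: float = 0.25
    depth_mean: float = 200.0
    indecisive_frac: float = 0.1
    loss_prob: float = 0.2

    def validate(self) -> None:
        def _in(name: str, lo: float, hi: float) -> None:
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ConfigError(f"{name}={v!r} outside legal range [{lo}, {hi}]")

        if self.fc_threshold < 1:
            raise ConfigError("fc_threshold must be >= 1")
        for name in ("min_rvf", "max_indecisive_frac", "s2_lo", "s2_hi", "s4_lo",
                     "s4_hi", "long_cov", "short_cov", "min_dev_prop", "frac_dev",
                     "indecisive_frac"):
            _in(name, 0.0, 1.0)
        if not (0 <= self.loss_prob < 1):
            raise ConfigError("loss_prob must be in [0, 1)")
        if self.mcl_inflation <= 1:
            raise ConfigError("mcl_inflation must be > 1")
        if self.tai_log_mode not in ("log2p1", "log2drop"):
            raise ConfigError(f"unknown tai_log_mode {self.tai_log_mode!r}")
        if self.age_scale not in ("raw", "minmax"):
            raise ConfigError(f"unknown age_scale {self.age_scale!r}")
        if self.divergent_rule not in ("any", "closer"):
            raise ConfigError(f"unknown divergent_rule {self.divergent_rule!r}")
        if self.gm_mode not in ("mirrored", "direct"):
            raise ConfigError(f"unknown gm_mode {self.gm_mode!r}")
        if self.prop_denominator not in ("present", "all"):
            raise ConfigError(f"unknown prop_denominator {self.prop_denominator!r}")
        if self.min_phred < 0 or self.max_hd < 0:
            raise ConfigError("min_phred and max_hd must be nonnegative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
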