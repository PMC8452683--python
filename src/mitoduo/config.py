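"""Configuration for the synthetic-data generators.

One :class:`SynthConfig` drives every generator; the seed fixes all
randomness, so identical configs give bit-identical outputs. Defaults
emulate the study system: two circular ~17.4 kb mitogenome lineages at
~5.5% nucleotide divergence with rate hotspots, a 127-bp insertion in the
male-type 16S rRNA and a 10-residue cox1 extension, plus qPCR plates and
enzyme-activity tables with the reported effect sizes.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class QpcrConfig:
    """qPCR plate simulation block.

    efficiency: per-cycle amplification factor E in (1, 2].
    ct_at_1ng: curve anchor, the Ct a 1-ng template produces.
    noise_sd: Gaussian Ct noise, cycles.
    standard_amounts: dilution series for the standard curve, ng.
    replicates: wells per (sample, target); assays are run in duplicate.
    """

    efficiency: float = 1.9
    ct_at_1ng: float = 21.0
    noise_sd: float = 0.15
    standard_amounts: tuple[float, ...] = (10.0, 1.0, 0.1, 0.01, 0.001)
    replicates: int = 2

    def validate(self) -> None:
        if not 1.0 < self.efficiency <= 2.0:
            raise ValueError(f"efficiency must be in (1, 2], got {self.efficiency}")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if len(set(self.standard_amounts)) < 3:
            raise ValueError("standard curve needs >= 3 distinct amounts")
        if any(a <= 0 for a in self.standard_amounts):
            raise ValueError("standard amounts must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class EffectConfig:
    """Phenotype simulation block.

    Group means are multiplicative: male-mitotype (M) carriers have
    ETS and COX scaled by the mitotype factors in both sexes; females
    have CS scaled by the sex factor in both mitotypes. Activities are
    lognormal with the configured arithmetic means (U per g tissue).
    """

    ets_base: float = 15.0          # F-carrier mean ETS, U/g
    cox_base: float = 8.0           # F-carrier mean COX, U/g
    cs_base_male: float = 10.0      # male mean CS, U/g fresh weight
    ets_mito_factor: float = 0.69   # 31% reduction in M-carriers
    cox_mito_factor: float = 0.67   # 33% reduction in M-carriers
    cs_sex_factor: float = 0.58     # 42% reduction in females
    copy_number_fold: float = 3.0   # M-carrier mtDNA copy number fold-up (2-5x band)
    sigma_log: float = 0.25         # lognormal shape, log scale
    n_per_cell: int = 1000          # per sex x mitotype cell (2000 per marginal group)

    def validate(self) -> None:
        for name in ("ets_base", "cox_base", "cs_base_male", "ets_mito_factor",
                     "cox_mito_factor", "cs_sex_factor", "copy_number_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"effect parameter {name} must be > 0")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        if self.n_per_cell < 1:
            raise ValueError("group sizes must be >= 1")


@dataclass
class SynthConfig:
    """Top-level generator configuration."""

    seed: int = 1
    genome_length: int = 17428
    divergence_target: float = 0.055
    hotspot_multiplier: float = 3.0
    conserved_multiplier: float = 0.2
    indel_16S_length: int = 127
    cox1_extension_aa: int = 10
    structural_events: bool = True
    # read simulation
    read_length: int = 100
    coverage: float = 30.0
    error_rate: float = 0.0
    mixture: float = 0.0  # fraction of reads drawn from the M genome
    qpcr: QpcrConfig = field(default_factory=QpcrConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 <= self.divergence_target < 0.75:
            raise ValueError(f"divergence_target must be in [0, 0.75), got {self.divergence_target}")
        for name in ("hotspot_multiplier", "conserved_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.indel_16S_length < 0 or self.cox1_extension_aa < 0:
            raise ValueError("structural event sizes must be >= 0")
        if not 0 <= self.mixture <= 1:
            raise ValueError("mixture must be in [0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        self.qpcr.validate()
        self.effects.validate()

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        qpcr = d.pop("qpcr", {}) or {}
        effects = d.pop("effects", {}) or {}
        if "standard_amounts" in qpcr:
            qpcr["standard_amounts"] = tuple(qpcr["standard_amounts"])
        return cls(qpcr=QpcrConfig(**qpcr), effects=EffectConfig(**effects), **d)

    def to_yaml(self, path: str | Path) -> None:
        d = self.to_dict()
        d["qpcr"]["standard_amounts"] = list(d["qpcr"]["standard_amounts"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
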