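"""Simulation and pipeline configuration objects."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

ZONES = ("upstream", "midstream", "downstream")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic riparian study generator.

    The defaults emulate the study design the pipeline targets: 20 sites
    split 2/8/10 over three river zones, carbon use efficiency rising and
    the metabolic quotient falling downstream, block-correlated ASV
    tables with planted modules, and a negative latent path from enzyme
    activities to metabolic efficiency.

    Attributes
    ----------
    n_sites_per_zone:
        Sites per zone; an int (same count everywhere) or one count per
        zone. Default ``(2, 8, 10)``.
    zones:
        Ordered zone labels, upstream to downstream.
    n_asvs_bacteria, n_asvs_fungi:
        ASV richness of the two marker-gene tables.
    n_planted_modules:
        Correlation blocks planted in each ASV table (≥ 2).
    within_module_rho:
        Target within-module Spearman correlation in [0, 1].
    cue_gradient:
        Per-zone mean carbon use efficiency, each strictly in (0, 1).
    mbc_gradient:
        Per-zone mean microbial biomass carbon, µg C g⁻¹ dry soil.
    qco2_gradient:
        Per-zone mean metabolic quotient, µg CO₂-C (µg MBC)⁻¹ h⁻¹.
    enzyme_efficiency_beta:
        True standardized latent path coefficient from enzyme activity to
        metabolic efficiency, in [−1, 1].
    site_sd:
        Site-level SD of CUE around its zone mean (biological variation,
        part of the planted truth).
    noise_sd:
        Relative measurement-noise SD applied to raw measurements
        (headspace CO₂, atom percents, extract C, enzyme assays); 0 gives
        noise-free data that round-trips exactly.
    seed:
        Master seed; every generator stage derives a named substream.
    """

    n_sites_per_zone: int | tuple[int, ...] = (2, 8, 10)
    zones: tuple[str, ...] = ZONES
    n_asvs_bacteria: int = 120
    n_asvs_fungi: int = 80
    n_planted_modules: int = 5
    within_module_rho: float = 0.9
    cue_gradient: tuple[float, ...] = (0.2, 0.35, 0.5)
    mbc_gradient: tuple[float, ...] = (200.0, 350.0, 500.0)
    qco2_gradient: tuple[float, ...] = (0.0020, 0.0012, 0.0008)
    enzyme_efficiency_beta: float = -0.65
    site_sd: float = 0.03
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_sites_per_zone, int):
            self.n_sites_per_zone = tuple([self.n_sites_per_zone] * len(self.zones))
        else:
            self.n_sites_per_zone = tuple(int(n) for n in self.n_sites_per_zone)
        if len(self.n_sites_per_zone) != len(self.zones):
            raise ValueError("n_sites_per_zone length must match zones")
        if any(n <= 0 for n in self.n_sites_per_zone):
            raise ValueError("site counts must be positive")
        for grad, name in ((self.cue_gradient, "cue_gradient"),):
            if len(grad) != len(self.zones):
                raise ValueError(f"{name} needs one value per zone")
            if any(not 0.0 < v < 1.0 for v in grad):
                raise ValueError(f"{name} values must be strictly in (0, 1)")
        for grad, name in ((self.mbc_gradient, "mbc_gradient"),
                           (self.qco2_gradient, "qco2_gradient")):
            if len(grad) != len(self.zones):
                raise ValueError(f"{name} needs one value per zone")
            if any(v <= 0 for v in grad):
                raise ValueError(f"{name} values must be positive")
        if not 0.0 <= self.within_module_rho <= 1.0:
            raise ValueError("within_module_rho must be in [0, 1]")
        if not -1.0 <= self.enzyme_efficiency_beta <= 1.0:
            raise ValueError("enzyme_efficiency_beta must be in [-1, 1]")
        if self.noise_sd < 0 or self.site_sd < 0:
            raise ValueError("noise_sd and site_sd must be non-negative")
        if self.n_asvs_bacteria <= 0 or self.n_asvs_fungi <= 0:
            raise ValueError("ASV counts must be positive")
        if self.n_planted_modules < 2:
            raise ValueError("need at least 2 planted modules")

    @property
    def n_sites(self) -> int:
        return sum(self.n_sites_per_zone)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings shared by all stages."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    k_ec: float = 0.45
    f_o_dna: float = 0.31
    r_min: float = 0.8
    alpha: float = 0.05
    zi_thr: float = 2.5
    pi_thr: float = 0.62
    min_prevalence: float = 0.2
    min_rel_abundance: float = 0.0
    use_fdr: bool = False
    compute_pd: bool = True
    index_on_specific_activity: bool = False
    rf_trees: int = 500
    rf_permutations: int = 999

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        if not 0 < self.k_ec <= 1:
            raise ValueError("k_ec must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.r_min < 1:
            raise ValueError("r_min must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
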