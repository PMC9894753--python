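"""Simulation and pipeline configuration.

``SimConfig`` describes the evolutionary scenario the simulator plants: two
clonal populations (A, 5 genomes; B, 8 genomes by default) that diverged to a
raw between-population distance of ~0.034 substitutions/site with
within-population diversity of ~0.003, sharing ~90% of their gene content,
each population carrying a block of population-specific genes, population A
carrying a recently imported (SNP-free) segment, and population B carrying a
duplicated two-variant gene whose 3' tail has been homogenized between the
copies.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration violates an invariant; names the field."""


@dataclass
class SimConfig:
    seed: int = 0
    genome_length: int = 500_000
    n_genes: int = 1500
    gene_length_mean: int = 280
    n_genomes_a: int = 5
    n_genomes_b: int = 8
    # raw per-site divergences: d_between is the expected genome-to-genome
    # distance across populations, d_within the expected pairwise distance
    # within a population.
    d_between: float = 0.034
    d_within: float = 0.003
    core_fraction: float = 0.90
    n_pop_specific_a: int = 40
    n_pop_specific_b: int = 45
    pop_specific_block: int = 5      # genes per contiguous gain/loss cluster
    flexible_max_missing: int = 4    # most genomes a generic flexible gene is absent from
    sweep_region_length: int = 8000
    sweep_region_divergence: float = 0.15
    dup_gene_length: int = 1500
    dup_homogenized_tail: int = 500
    dup_copy_divergence: float = 0.10
    read_length: int = 150
    depth: float = 50.0
    error_rate: float = 0.0
    nb_dispersion: float = 0.05
    nb_mean_log: float = 4.5         # log-scale location of baseline expression
    nb_mean_sd: float = 1.0
    n_de_genes: int = 50
    de_log2fc: float = 2.0
    n_samples: int = 6               # transcriptome samples per population context
    covariate_effect: float = 1.0    # slope (sd units) linking pop-A abundance to covariate 1
    covariate_noise_sd: float = 1.0
    n_cov_samples: int = 94

    def validate(self) -> "SimConfig":
        ordered = 0 <= self.d_within <= self.d_between < 0.25
        if not ordered or (self.d_within == self.d_between and self.d_between > 0):
            # equality is only meaningful in the degenerate zero-mutation case
            raise ConfigError(
                "d_within/d_between: require 0 <= d_within < d_between < 0.25 "
                "(or both zero), "
                f"got d_within={self.d_within}, d_between={self.d_between}"
            )
        if not (0 < self.core_fraction <= 1):
            raise ConfigError(f"core_fraction must be in (0,1], got {self.core_fraction}")
        if self.sweep_region_length >= self.genome_length:
            raise ConfigError("sweep_region_length must be smaller than genome_length")
        for name in (
            "genome_length", "n_genes", "gene_length_mean", "n_genomes_a",
            "n_genomes_b", "n_pop_specific_a", "n_pop_specific_b",
            "sweep_region_length", "dup_gene_length", "dup_homogenized_tail",
            "read_length", "n_de_genes", "n_samples", "n_cov_samples",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.nb_dispersion <= 0:
            raise ConfigError(f"nb_dispersion must be > 0, got {self.nb_dispersion}")
        if self.dup_homogenized_tail > self.dup_gene_length:
            raise ConfigError("dup_homogenized_tail cannot exceed dup_gene_length")
        if self.error_rate < 0 or self.error_rate >= 1:
            raise ConfigError(f"error_rate must be in [0,1), got {self.error_rate}")
        n_flex = self.n_genes - round(self.core_fraction * self.n_genes)
        if self.n_pop_specific_a + self.n_pop_specific_b > n_flex:
            raise ConfigError(
                "n_pop_specific_a + n_pop_specific_b exceeds the flexible gene budget "
                f"({n_flex} genes at core_fraction={self.core_fraction})"
            )
        return self

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw).validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration fields: {sorted(unknown)}")
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("simulate", data))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
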