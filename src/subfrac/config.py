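"""Simulation configuration for the synthetic two-subgenome dataset.

Defaults encode the study conditions the pipeline is meant to recover: two
chromosomes per subgenome at maize-like arm/peri contrasts, per-copy gene-loss
probabilities back-derived from observed singleton:WGD ratios (maize1 arms
1.7:1, maize1 peri 2.2:1, maize2 arms 0.7:1, maize2 peri 0.9:1 via
p = r / (1 + r)), outgroup-scale substitution rates with the recessive
subgenome evolving faster in arms, a 2.5x expression-dominance effect in 40%
of arm-located dominant-subgenome pairs across 24 tissues, flanking CHH/siRNA
islands, and subgenome/region-biased ACR retention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

SUBGENOMES = ("maize1", "maize2")
REGIONS = ("arm", "peri")

RateMap = dict[tuple[str, str], float]  # (subgenome, region) -> value


def _ratemap(m1_arm, m1_peri, m2_arm, m2_peri) -> RateMap:
    return {
        ("maize1", "arm"): m1_arm,
        ("maize1", "peri"): m1_peri,
        ("maize2", "arm"): m2_arm,
        ("maize2", "peri"): m2_peri,
    }


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    seed: int = 0
    n_chromosomes: int = 2  # per subgenome
    chrom_length: int = 100_000_000  # bp
    peri_fraction: float = 0.4
    gene_density_arm: float = 15.0  # genes / Mb
    gene_density_peri: float = 5.0
    te_density_arm: float = 0.3  # fraction of bp
    te_density_peri: float = 0.7
    n_blocks_per_chromosome: int = 28
    tandem_frac: float = 0.03

    # per-copy deletion probabilities, keyed by the copy's own location
    loss_prob: RateMap = field(default_factory=lambda: _ratemap(0.41, 0.47, 0.63, 0.69))
    # substitutions/site relative to the shared (sorghum-like) ancestor
    syn_rate: RateMap = field(default_factory=lambda: _ratemap(0.28, 0.24, 0.32, 0.24))
    nonsyn_rate: RateMap = field(default_factory=lambda: _ratemap(0.045, 0.05, 0.06, 0.05))
    n_codons: int = 300

    # expression model
    dominance_effect: float = 2.5  # multiplier on maize1 in affected pairs
    dominance_fraction: float = 0.4  # fraction of arm-maize1 pairs affected
    expr_log_mean: float = 2.0  # log FPKM baseline
    expr_log_sd: float = 1.0
    expr_noise_sd: float = 0.6  # per-tissue log-scale noise
    n_tissues: int = 24
    n_protein_samples: int = 10

    # flanking chromatin islands
    chh_island_height: float = 0.6
    meth_background: float = 0.05
    island_offset: int = 200  # peak centre, bp beyond TSS/TTS
    island_width: int = 300  # gaussian sigma*2 of the island bump
    sirna_background: float = 0.02  # expected reads / bp
    sirna_island: float = 0.4  # added expected reads / bp at the peak
    sirna_island_factor_m1: float = 0.7  # maize1 islands are shallower
    meth_coverage: float = 20.0  # mean reads per cytosine
    histone_input_rate: float = 10.0  # reads per 100 bp bin
    histone_body_boost: RateMap = field(
        default_factory=lambda: _ratemap(0.5, 0.2, 0.25, 0.2)
    )

    # recombination map
    marker_spacing: int = 500_000
    recomb_arm: float = 2.5  # cM/Mb
    recomb_peri: float = 0.2

    # SNP / genetic-load model
    snps_per_kb: float = 2.0
    n_panel_individuals: int = 20
    load_bias_m2_arm: float = 1.8  # derived-allele frequency multiplier

    # ACRs and loops
    acr_prob: float = 0.8  # ancestral gene has an ancestral ACR
    acr_retention_prob: RateMap = field(
        default_factory=lambda: _ratemap(0.75, 0.55, 0.55, 0.45)
    )
    acr_syntenic_prob: float = 0.6  # ancestral ACR has a sorghum syntelog
    acr_length: tuple[int, int] = (150, 500)
    acr_k_rate: RateMap = field(default_factory=lambda: _ratemap(0.10, 0.13, 0.14, 0.13))
    accessibility_bias_m1_arm: float = 1.35  # score multiplier
    n_loops: int = 300
    loop_bias_m1_arm: float = 1.5  # sampling weight

    def validate(self) -> "SimConfig":
        def _check_prob(name, value):
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {value}")

        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if self.chrom_length < 2_000_000:
            raise ConfigError("chrom_length must be >= 2 Mb")
        if not (0.0 < self.peri_fraction < 1.0):
            raise ConfigError(f"peri_fraction must be in (0, 1), got {self.peri_fraction}")
        for name in ("gene_density_arm", "gene_density_peri"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        for name in ("te_density_arm", "te_density_peri", "tandem_frac",
                     "dominance_fraction", "acr_prob", "acr_syntenic_prob",
                     "chh_island_height", "meth_background"):
            _check_prob(name, getattr(self, name))
        for name in ("loss_prob", "acr_retention_prob"):
            m = getattr(self, name)
            for key in ((s, r) for s in SUBGENOMES for r in REGIONS):
                if key not in m:
                    raise ConfigError(f"{name} missing entry for {key}")
                _check_prob(f"{name}[{key}]", m[key])
        for name in ("syn_rate", "nonsyn_rate", "acr_k_rate"):
            m = getattr(self, name)
            for key, v in m.items():
                if v < 0:
                    raise ConfigError(f"{name}[{key}] must be >= 0, got {v}")
        if self.n_tissues < 1:
            raise ConfigError("n_tissues must be >= 1")
        if self.n_codons < 10:
            raise ConfigError("n_codons must be >= 10")
        return self

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("loss_prob", "syn_rate", "nonsyn_rate", "acr_retention_prob",
                    "acr_k_rate", "histone_body_boost"):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = {
                    tuple(k.split(".")): v for k, v in raw[key].items()
                }  # yaml keys like "maize1.arm"
        if "acr_length" in raw:
            raw["acr_length"] = tuple(raw["acr_length"])
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw).validate()
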