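"""Simulation configuration.

The defaults encode the study conditions the generator emulates: 185
mRNA-sequenced samples, a per-exon allelic effect profile peaking at about
-0.2 SD per risk allele (-0.24 SD combined), a heterozygote allelic read
ratio of 0.545, and planted co-expression gene sets of 80 (ribosomal
protein genes) and 7 (super-elongation complex) members.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


# Per-exon effect sizes (SD units per risk allele) across the 12 annotated
# exons of the target gene; exon 7 is near-null and exons 9-11 carry the
# strongest signal, mirroring the distal-exon effect profile of the study.
DEFAULT_BETA_PER_EXON: tuple[float, ...] = (
    -0.15, -0.16, -0.17, -0.16, -0.15, -0.14,
    -0.04, -0.11, -0.20, -0.20, -0.19, -0.12,
)


@dataclass(frozen=True)
class LDBlockSpec:
    """One founder-haplotype LD block.

    Parameters
    ----------
    n_variants : int
        Number of variant sites in the block.
    n_founders : int
        Number of founder haplotypes the block mosaics are copied from.
    founder_freqs : tuple of float
        Sampling frequency of each founder; must sum to 1.
    """

    n_variants: int
    n_founders: int
    founder_freqs: tuple[float, ...]

    def validate(self) -> None:
        if self.n_variants <= 0:
            raise ConfigError("block n_variants must be positive")
        if self.n_founders <= 0:
            raise ConfigError("block n_founders must be positive")
        if len(self.founder_freqs) != self.n_founders:
            raise ConfigError(
                f"founder_freqs has {len(self.founder_freqs)} entries for "
                f"{self.n_founders} founders"
            )
        if any(f < 0 for f in self.founder_freqs):
            raise ConfigError("founder frequencies must be nonnegative")
        if abs(sum(self.founder_freqs) - 1.0) > 1e-9:
            raise ConfigError(
                f"founder frequencies sum to {sum(self.founder_freqs)}, not 1"
            )


def _default_blocks() -> tuple[LDBlockSpec, ...]:
    return (
        LDBlockSpec(24, 4, (0.35, 0.30, 0.20, 0.15)),
        LDBlockSpec(24, 4, (0.40, 0.25, 0.20, 0.15)),
        LDBlockSpec(24, 4, (0.30, 0.30, 0.25, 0.15)),
    )


@dataclass(frozen=True)
class PlantedSet:
    """A gene set planted into the co-expression simulation.

    ``shift`` is the coefficient (in SD units) linking member-gene latent
    expression to the standardized anchor-gene expression; non-members get
    coefficient 0 and are exchangeable.
    """

    name: str
    size: int
    shift: float


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-data generator.

    Attributes
    ----------
    n_samples : int
        Diploid sample count (the haplotype panel holds ``2 * n_samples``).
    ld_block_spec : tuple of LDBlockSpec
        Independent founder-haplotype blocks; total variant count is the sum.
    risk_variant_index : int
        Index (0-based, over the concatenated blocks) of the causal variant.
    beta_per_exon : tuple of float
        Allelic effect per exon in SD units per risk-allele copy.
    noise_sd : float or None
        Residual SD of latent exon expression. ``None`` sets it per exon to
        ``sqrt(1 - beta**2)`` so latent expression has unit variance and the
        planted beta equals the expected Pearson correlation.
    allelic_ratio : float
        Bernoulli probability that a simulated heterozygote read carries the
        alternate allelic key (0.545 emulates the observed imbalance).
    n_reads, read_length : int
        Read count and length for the allelic-read simulator.
    n_genes : int
        Genes in the co-expression simulation (including the anchor).
    anchor_beta : float
        Allelic effect on the anchor gene in the co-expression simulation.
    planted_sets : tuple of PlantedSet
        Gene sets whose members track the anchor.
    fpkm_scale : float
        Baseline of the monotone latent-to-FPKM map ``fpkm = scale * 2**z``;
        recorded in output metadata so log transforms invert it exactly.
    flip_noise : float
        Per-site allele flip probability applied to block mosaics.
    seed : int
        Root seed; every output is a deterministic function of (config, seed).
    """

    n_samples: int = 185
    ld_block_spec: tuple[LDBlockSpec, ...] = field(default_factory=_default_blocks)
    risk_variant_index: int = 12
    beta_per_exon: tuple[float, ...] = DEFAULT_BETA_PER_EXON
    noise_sd: float | None = None
    allelic_ratio: float = 0.545
    n_reads: int = 2000
    read_length: int = 50
    n_genes: int = 5000
    anchor_beta: float = -0.24
    planted_sets: tuple[PlantedSet, ...] = (
        PlantedSet("RPG", 80, 1.0),
        PlantedSet("SEC", 7, 1.0),
    )
    fpkm_scale: float = 100.0
    flip_noise: float = 0.01
    seed: int = 0

    @property
    def n_variants(self) -> int:
        return sum(b.n_variants for b in self.ld_block_spec)

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigError("n_samples must be positive")
        if not self.ld_block_spec:
            raise ConfigError("at least one LD block is required")
        for block in self.ld_block_spec:
            block.validate()
        if not 0 <= self.risk_variant_index < self.n_variants:
            raise ConfigError(
                f"risk_variant_index {self.risk_variant_index} outside "
                f"[0, {self.n_variants})"
            )
        if not self.beta_per_exon:
            raise ConfigError("beta_per_exon must be non-empty")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if not 0.0 <= self.allelic_ratio <= 1.0:
            raise ConfigError("allelic_ratio must lie in [0, 1]")
        if self.n_reads <= 0 or self.read_length <= 0:
            raise ConfigError("n_reads and read_length must be positive")
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        names = [s.name for s in self.planted_sets]
        if len(set(names)) != len(names):
            raise ConfigError("planted set names must be unique (sets may not overlap)")
        if any(s.size <= 0 for s in self.planted_sets):
            raise ConfigError("planted set sizes must be positive")
        # anchor occupies one gene slot
        if sum(s.size for s in self.planted_sets) > self.n_genes - 1:
            raise ConfigError("planted set sizes exceed available genes")
        if self.fpkm_scale <= 0:
            raise ConfigError("fpkm_scale must be positive")
        if not 0.0 <= self.flip_noise <= 1.0:
            raise ConfigError("flip_noise must lie in [0, 1]")

    def exon_noise_sd(self, exon_index: int) -> float:
        """Residual SD for one exon (unit total latent variance by default)."""
        beta = self.beta_per_exon[exon_index]
        if self.noise_sd is not None:
            return self.noise_sd
        if abs(beta) >= 1.0:
            return 0.0
        return float((1.0 - beta * beta) ** 0.5)

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ld_block_spec"] = [
            {"n_variants": b.n_variants, "n_founders": b.n_founders,
             "founder_freqs": list(b.founder_freqs)}
            for b in self.ld_block_spec
        ]
        d["planted_sets"] = [
            {"name": s.name, "size": s.size, "shift": s.shift}
            for s in self.planted_sets
        ]
        d["beta_per_exon"] = list(self.beta_per_exon)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "ld_block_spec" in d:
            d["ld_block_spec"] = tuple(
                LDBlockSpec(b["n_variants"], b["n_founders"],
                            tuple(b["founder_freqs"]))
                for b in d["ld_block_spec"]
            )
        if "planted_sets" in d:
            d["planted_sets"] = tuple(
                PlantedSet(s["name"], s["size"], s["shift"])
                for s in d["planted_sets"]
            )
        if "beta_per_exon" in d:
            d["beta_per_exon"] = tuple(d["beta_per_exon"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def stage_seed(config: SimulationConfig, stage: str) -> int:
    """Derive a per-stage seed (< 2**31) from the config's root seed.

    Every stage draws from its own ``numpy.random.Generator`` seeded here, so
    no stage reads global random state and stages are order-independent.
    """
    import hashlib

    h = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)
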