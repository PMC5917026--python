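"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a deterministic function of (config, seed) and emulates
one layer of the real study's data:

* a phased haplotype panel built as a founder-haplotype block mosaic, which
  yields tunable within-block r2 structure without coalescent machinery;
* exon-level expression with a planted per-exon allelic effect in SD units,
  mapped to an FPKM-like scale by ``fpkm = fpkm_scale * 2**latent`` (the map
  is recorded in the output metadata so a log2 transform inverts it);
* heterozygote reads carrying one of two allele-distinguishing key
  sequences, drawn Bernoulli(pi) for the alternate key — or planted with
  exact counts in a deterministic interleaving mode for bookkeeping tests;
* a gene co-expression matrix with an anchor gene under genotype control
  and planted gene sets whose members track the anchor;
* a small motif fixture: a count matrix whose consensus matches the
  reference-allele core of the EMSA-style probe pair, so the reference
  window scores a high-affinity hit and the alternate window does not.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from allelreg.config import ConfigError, SimulationConfig, stage_seed
from allelreg.eqtl import reverse_complement
from allelreg.genomics_io import (
    ExpressionMatrix,
    GeneSetCollection,
    GenotypeData,
    HaplotypePanel,
    ReadCollection,
    VariantRecord,
    exon_feature_id,
)
from allelreg.motif import PositionCountMatrix

#: Allele-distinguishing key sequences at the exonic marker variant: the
#: first base is the variant site, the remaining 26 bases are its 3' flank.
DEFAULT_KEY_REF = "CAGCATTCTGAGACGGATTTAGTTTTC"
DEFAULT_KEY_ALT = "TAGCATTCTGAGACGGATTTAGTTTTC"

#: 25-base probe pair around the regulatory variant; the central base
#: (0-based offset 12) is G on the high-affinity allele and C on the
#: low-affinity allele.
PROBE_REF = "ACAGTGCTGACTGAGCTCAAAATAC"
PROBE_ALT = "ACAGTGCTGACTCAGCTCAAAATAC"
PROBE_VARIANT_OFFSET = 12

#: Annotated exon intervals (1-based, inclusive) of the 12-exon target gene.
DEFAULT_EXON_COORDS: tuple[tuple[int, int], ...] = (
    (95885097, 95888987), (95889085, 95889130), (95891102, 95891274),
    (95895627, 95895691), (95898239, 95898810), (95900692, 95900780),
    (95900955, 95901080), (95906522, 95906782), (95913770, 95913934),
    (95919423, 95919545), (95913001, 95913049), (95911574, 95912071),
)

_LOCUS_CHROM = "chr5"
_LOCUS_START = 95_880_000
_VARIANT_SPACING = 1_000


def _block_founders(rng: np.random.Generator, n_founders: int,
                    n_variants: int) -> np.ndarray:
    founders = rng.integers(0, 2, size=(n_founders, n_variants)).astype(np.int8)
    # guarantee each site segregates among the founders so LD is defined
    mono = founders.min(axis=0) == founders.max(axis=0)
    founders[0, mono] ^= 1
    return founders


def simulate_haplotype_panel(config: SimulationConfig) -> HaplotypePanel:
    """Founder-haplotype block mosaic panel of 2 * n_samples haplotypes.

    Within each block every haplotype is a copy of one founder haplotype
    (drawn at the block's founder frequencies) with independent per-site
    flips at rate ``flip_noise``; blocks are independent, so between-block
    LD is null in expectation while within-block LD is governed by the
    founder structure.
    """
    config.validate()
    rng = np.random.default_rng(stage_seed(config, "haplotype_panel"))
    n_hap = 2 * config.n_samples
    columns: list[np.ndarray] = []
    for block in config.ld_block_spec:
        founders = _block_founders(rng, block.n_founders, block.n_variants)
        assign = rng.choice(block.n_founders, size=n_hap,
                            p=np.asarray(block.founder_freqs))
        haps = founders[assign].copy()
        if config.flip_noise > 0:
            flips = rng.random(haps.shape) < config.flip_noise
            haps ^= flips.astype(np.int8)
        columns.append(haps)
    haplotypes = np.concatenate(columns, axis=1)
    variants = [
        VariantRecord(id=f"var{i:04d}", chrom=_LOCUS_CHROM,
                      pos=_LOCUS_START + i * _VARIANT_SPACING,
                      ref="T", alt="C")
        for i in range(config.n_variants)
    ]
    return HaplotypePanel(variants, haplotypes)


def panel_to_genotypes(panel: HaplotypePanel) -> GenotypeData:
    """Wrap a panel as genotype data with its derived dosage matrix."""
    return GenotypeData(panel.variants, panel.dosage(), panel)


def simulate_exon_expression(dosage: GenotypeData | pd.Series,
                             config: SimulationConfig) -> ExpressionMatrix:
    """Exon-level FPKM expression with a planted allelic effect per exon.

    Latent exon expression is ``beta_e * z + N(0, sigma_e)`` with z the
    standardized risk-allele dosage; by default ``sigma_e`` makes the
    latent variance 1 so beta_e is the expected Pearson correlation. The
    positive FPKM scale is ``fpkm_scale * 2**latent``.
    """
    config.validate()
    if isinstance(dosage, GenotypeData):
        vid = dosage.variants[config.risk_variant_index].id
        dose = dosage.dosage.loc[vid]
    else:
        dose = dosage
    d = dose.to_numpy(dtype=float)
    if np.ptp(d) == 0:
        raise ValueError("risk-variant dosage is constant; cannot plant effect")
    z = (d - d.mean()) / d.std()
    rng = np.random.default_rng(stage_seed(config, "exon_expression"))
    n_exons = len(config.beta_per_exon)
    rows = []
    ids = []
    for e in range(n_exons):
        beta = config.beta_per_exon[e]
        sigma = config.exon_noise_sd(e)
        latent = beta * z + rng.normal(0.0, 1.0, size=z.size) * sigma
        rows.append(config.fpkm_scale * np.exp2(latent))
        start, end = DEFAULT_EXON_COORDS[e % len(DEFAULT_EXON_COORDS)]
        ids.append(exon_feature_id("ELL2", e + 1, _LOCUS_CHROM, start, end))
    values = pd.DataFrame(rows, index=ids, columns=list(dose.index))
    return ExpressionMatrix(values, transform="raw",
                            metadata={"fpkm_scale": config.fpkm_scale,
                                      "latent_map": "fpkm=fpkm_scale*2**latent"})


_BASES = np.array(list("ACGT"))


def _embed_key(rng: np.random.Generator, key: str, read_length: int,
               offset: int | None = None) -> str:
    flank = read_length - len(key)
    if offset is None:
        offset = int(rng.integers(0, flank + 1)) if flank else 0
    left = "".join(rng.choice(_BASES, size=offset))
    right = "".join(rng.choice(_BASES, size=flank - offset))
    return left + key + right


def simulate_allelic_reads(config: SimulationConfig,
                           key_ref: str = DEFAULT_KEY_REF,
                           key_alt: str = DEFAULT_KEY_ALT,
                           planted_counts: tuple[int, int] | None = None,
                           ) -> ReadCollection:
    """Reads from a heterozygote, each carrying exactly one allelic key.

    The alternate key is chosen Bernoulli(``allelic_ratio``) per read; the
    key sits at a random offset with random flanking bases, and every
    second read is emitted as the reverse complement of the constructed
    read. ``planted_counts=(n_ref, n_alt)`` switches to the deterministic
    interleaving mode that plants exact counts (ref reads first, then alt,
    offsets cycling), bypassing Bernoulli sampling.
    """
    config.validate()
    if len(key_ref) != len(key_alt) or key_ref == key_alt:
        raise ValueError("keys must be distinct and of equal length")
    if sum(a != b for a, b in zip(key_ref, key_alt)) != 1:
        raise ValueError("keys must differ at exactly one base")
    if config.read_length < len(key_ref):
        raise ConfigError(
            f"read_length {config.read_length} cannot embed a "
            f"{len(key_ref)}-base key")
    rng = np.random.default_rng(stage_seed(config, "allelic_reads"))
    seqs: list[str] = []
    if planted_counts is not None:
        n_ref, n_alt = planted_counts
        flank = config.read_length - len(key_ref)
        for i in range(n_ref + n_alt):
            key = key_ref if i < n_ref else key_alt
            offset = i % (flank + 1)
            pad = "A" * offset + key + "A" * (flank - offset)
            seqs.append(reverse_complement(pad) if i % 2 else pad)
    else:
        is_alt = rng.random(config.n_reads) < config.allelic_ratio
        for i in range(config.n_reads):
            key = key_alt if is_alt[i] else key_ref
            read = _embed_key(rng, key, config.read_length)
            if i % 2:
                read = reverse_complement(read)
            seqs.append(read)
    ids = [f"read{i:06d}" for i in range(len(seqs))]
    return ReadCollection(ids, seqs)


def simulate_coexpression_and_sets(config: SimulationConfig,
                                   dosage: GenotypeData | pd.Series,
                                   anchor_gene: str = "ELL2",
                                   ) -> tuple[ExpressionMatrix,
                                              GeneSetCollection]:
    """Gene-level co-expression matrix with planted anchor-tracking sets.

    The anchor gene's latent expression carries the allelic effect
    ``anchor_beta``; each planted set's members follow
    ``shift * anchor_std + N(0, 1)``, so their correlation with the anchor
    (and, through it, with genotype) is shifted while non-members stay
    exchangeable. Gene sets are returned as a GMT-style collection.
    """
    config.validate()
    if isinstance(dosage, GenotypeData):
        vid = dosage.variants[config.risk_variant_index].id
        dose = dosage.dosage.loc[vid]
    else:
        dose = dosage
    d = dose.to_numpy(dtype=float)
    if np.ptp(d) == 0:
        raise ValueError("risk-variant dosage is constant; cannot plant effect")
    z = (d - d.mean()) / d.std()
    n = z.size
    rng = np.random.default_rng(stage_seed(config, "coexpression"))
    beta = config.anchor_beta
    sigma = (1.0 - beta * beta) ** 0.5 if abs(beta) < 1 else 0.0
    anchor_latent = beta * z + rng.normal(0.0, 1.0, n) * sigma
    a_std = (anchor_latent - anchor_latent.mean()) / anchor_latent.std()

    gene_ids = [anchor_gene] + [f"G{i:05d}" for i in range(1, config.n_genes)]
    shifts = np.zeros(config.n_genes)
    sets = GeneSetCollection()
    cursor = 1
    for ps in config.planted_sets:
        members = gene_ids[cursor:cursor + ps.size]
        shifts[cursor:cursor + ps.size] = ps.shift
        sets.sets[ps.name] = members
        sets.descriptions[ps.name] = (
            f"planted set, shift {ps.shift:+g} SD toward the anchor")
        cursor += ps.size

    latent = np.empty((config.n_genes, n))
    latent[0] = anchor_latent
    noise = rng.normal(0.0, 1.0, size=(config.n_genes - 1, n))
    latent[1:] = shifts[1:, None] * a_std[None, :] + noise
    values = pd.DataFrame(config.fpkm_scale * np.exp2(latent),
                          index=gene_ids, columns=list(dose.index))
    mat = ExpressionMatrix(values, transform="raw",
                           metadata={"fpkm_scale": config.fpkm_scale,
                                     "latent_map": "fpkm=fpkm_scale*2**latent",
                                     "anchor_gene": anchor_gene})
    return mat, sets


def make_motif_fixture() -> tuple[PositionCountMatrix, str, str]:
    """Synthetic bZIP-like motif fixture plus the allelic probe pair.

    The count matrix is the 11-mer core of the reference probe
    (``PROBE_REF[7:18]``) with 85/5/5/5 counts per column: the reference
    window contains the exact consensus (best-hit P well below 5e-4) while
    the alternate window carries a single core mismatch, inflating its
    best-hit P by the full single-mismatch tail (fold change above 5),
    which yields a "loss" call for the alternate allele.
    """
    core = PROBE_REF[7:18]  # TGACTGAGCTC
    counts = np.full((len(core), 4), 5.0)
    base_index = {b: i for i, b in enumerate("ACGT")}
    for i, b in enumerate(core):
        counts[i, base_index[b]] = 85.0
    pcm = PositionCountMatrix(name="SYNMAF", counts=counts)
    return pcm, PROBE_REF, PROBE_ALT
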