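"""End-to-end orchestration: simulate -> eQTL -> meta -> ASE -> prioritize
-> motif -> signatures -> enrichment, from one config, fully seeded.

Every stage draws from its own generator seeded off the config seed, logs
the sample sizes, transforms, and thresholds it used, and writes a TSV with
fixed column order (floats at 6 significant digits, P values in scientific
notation). A manifest records the config snapshot, all thresholds, and
SHA-256 digests of every emitted file, so a re-run with the same manifest
reproduces the report byte for byte.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from allelreg import synthdata
from allelreg.config import SimulationConfig
from allelreg.enrichment import correlation_signature, rank_enrichment
from allelreg.eqtl import (
    count_allelic_reads,
    fisher_combine,
    pearson_eqtl,
)
from allelreg.genomics_io import (
    IntervalTrack,
    parse_exon_feature_id,
    write_bed,
    write_expression,
    write_fastq,
    write_genotypes_tsv,
    write_genotypes_vcf,
    write_gmt,
    write_haplotypes_tsv,
    write_pcm,
)
from allelreg.ld import classify_2d, ld_neighborhood, ld_pair, select_candidates
from allelreg.motif import pcm_to_pwm, scan_variant

log = logging.getLogger("allelreg.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed its precondition; names stage and input."""


@dataclass(frozen=True)
class PipelineParams:
    """Every threshold the analysis depends on, surfaced explicitly."""

    cohort_sizes: tuple[int, ...] = (185, 658, 183, 604)
    transform: str = "log2"
    r2_threshold: float = 0.8
    r2_inclusive: bool = True
    eqtl_alpha: float = 1e-3
    gwas_alpha: float = 1e-3
    motif_p_threshold: float = 0.0005
    motif_fc_threshold: float = 5.0
    motif_rule: str = "both"
    fdr_alpha: float = 0.05
    min_mean_fpkm: float = 5.0
    gwas_n: int = 2000
    gwas_gamma: float = 0.15


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def _fmt_p(p: float) -> str:
    return f"{p:.6e}"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def _cohort_config(config: SimulationConfig, n: int, tag: str) -> SimulationConfig:
    # per-cohort derived seed keeps cohorts independent yet reproducible
    sub = int(hashlib.sha256(f"{config.seed}:cohort:{tag}".encode())
              .digest()[:4].hex(), 16) % (2**31)
    return replace(config, n_samples=n, seed=sub,
                   beta_per_exon=(config.anchor_beta,))


def _simulate_cohort(config: SimulationConfig, n: int, tag: str):
    """Panel + gene-level anchor expression for one validation cohort."""
    ccfg = _cohort_config(config, n, tag)
    panel = synthdata.simulate_haplotype_panel(ccfg)
    geno = synthdata.panel_to_genotypes(panel)
    expr = synthdata.simulate_exon_expression(geno, ccfg)
    return ccfg, geno, expr


def default_tracks(config: SimulationConfig,
                   variants) -> list[IntervalTrack]:
    """Synthetic regulatory annotation: an internal-promoter-style H3K4me3
    track over the causal variant and a sparse enhancer track."""
    risk = variants[config.risk_variant_index]
    promoter = IntervalTrack("H3K4me3_internal_promoter",
                             [(risk.chrom, risk.pos - 200, risk.pos + 200)])
    enh = [(v.chrom, v.pos - 50, v.pos + 50)
           for i, v in enumerate(variants) if i % 7 == 3]
    enhancer = IntervalTrack("enhancer_marks", enh)
    return [promoter, enhancer]


def run_pipeline(config: SimulationConfig, out_dir: str | Path,
                 params: PipelineParams | None = None) -> Path:
    """Run the whole chain on synthetic data and write the report directory.

    Returns the output directory. Any stage precondition failure raises
    :class:`StageError` naming the stage.
    """
    params = params or PipelineParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def emit(name: str, path: Path) -> None:
        files[name] = path

    # ---- stage: simulate -------------------------------------------------
    try:
        config.validate()
    except Exception as err:
        raise StageError(f"simulate: invalid config: {err}") from err
    panel = synthdata.simulate_haplotype_panel(config)
    geno = synthdata.panel_to_genotypes(panel)
    risk = panel.variants[config.risk_variant_index]
    log.info("simulate: n=%d samples, %d variants, risk variant %s",
             config.n_samples, config.n_variants, risk.id)
    write_genotypes_vcf(geno, out / "genotypes.vcf")
    write_genotypes_tsv(geno, out / "genotypes.tsv")
    write_haplotypes_tsv(panel, out / "haplotypes.tsv")
    config.to_yaml(out / "config.yaml")
    for n in ("genotypes.vcf", "genotypes.tsv", "haplotypes.tsv", "config.yaml"):
        emit(n, out / n)

    exon_expr = synthdata.simulate_exon_expression(geno, config)
    write_expression(exon_expr, out / "exon_expression.tsv")
    emit("exon_expression.tsv", out / "exon_expression.tsv")

    # ---- stage: exon eQTL (per-exon table) -------------------------------
    dose = geno.dosage_vector(risk.id)
    rows = []
    for fid in exon_expr.features:
        meta = parse_exon_feature_id(fid)
        try:
            res = pearson_eqtl(dose, exon_expr.values.loc[fid],
                               transform=params.transform,
                               feature_id=fid, variant_id=risk.id)
        except Exception as err:
            raise StageError(f"eqtl: feature {fid}: {err}") from err
        rows.append({"exon": meta["exon"], "chrom": meta["chrom"],
                     "start": meta["start"], "end": meta["end"],
                     "variant": risk.id, "n": res.n,
                     "beta": _fmt(res.beta), "r2": _fmt(res.r2),
                     "p": _fmt_p(res.p), "transform": res.transform})
    eqtl_df = pd.DataFrame(rows).sort_values("exon")
    _write_tsv(eqtl_df, out / "eqtl_exons.tsv")
    emit("eqtl_exons.tsv", out / "eqtl_exons.tsv")
    log.info("eqtl: %d exons, n=%d, transform=%s", len(rows),
             config.n_samples, params.transform)

    # ---- stage: meta-analysis across cohorts -----------------------------
    cohorts = []
    for ci, n in enumerate(params.cohort_sizes):
        cohorts.append(_simulate_cohort(config, n, f"c{ci}"))
    ps, betas, ses, ns = [], [], [], []
    for ccfg, cgeno, cexpr in cohorts:
        cdose = cgeno.dosage_vector(cgeno.variants[ccfg.risk_variant_index].id)
        res = pearson_eqtl(cdose, cexpr.values.iloc[0],
                           transform=params.transform,
                           feature_id="ELL2", variant_id=risk.id)
        ps.append(res.p)
        betas.append(res.beta)
        ses.append(res.se)
        ns.append(res.n)
    meta = fisher_combine(ps, feature_id="ELL2", betas=betas, ses=ses)
    meta_df = pd.DataFrame([{
        "feature": "ELL2", "k": meta.k, "cohort_ns": ",".join(map(str, ns)),
        "cohort_ps": ",".join(_fmt_p(p) for p in ps),
        "chi2": _fmt(meta.chi2), "df": meta.df,
        "p_combined": _fmt_p(meta.p_combined),
        "beta_combined": _fmt(meta.beta_combined),
        "se_combined": _fmt(meta.se_combined)}])
    _write_tsv(meta_df, out / "meta.tsv")
    emit("meta.tsv", out / "meta.tsv")
    log.info("meta: k=%d cohorts (n=%s), p_combined=%.3g, beta=%.3f",
             meta.k, ns, meta.p_combined, meta.beta_combined)

    # ---- stage: allele-specific expression -------------------------------
    reads = synthdata.simulate_allelic_reads(config)
    write_fastq(reads, out / "reads.fastq")
    emit("reads.fastq", out / "reads.fastq")
    ac = count_allelic_reads(reads, synthdata.DEFAULT_KEY_REF,
                             synthdata.DEFAULT_KEY_ALT)
    ase_df = pd.DataFrame([{
        "key_ref": synthdata.DEFAULT_KEY_REF,
        "key_alt": synthdata.DEFAULT_KEY_ALT,
        "n_ref": ac.n_ref, "n_alt": ac.n_alt,
        "ratio_alt": _fmt(ac.ratio), "p_binomial": _fmt_p(ac.p_binomial)}])
    _write_tsv(ase_df, out / "ase.tsv")
    emit("ase.tsv", out / "ase.tsv")
    log.info("ase: %d/%d reads, ratio=%.4f, p=%.3g", ac.n_ref, ac.n_alt,
             ac.ratio, ac.p_binomial)

    # ---- stage: LD prioritization ----------------------------------------
    try:
        neighborhood = ld_neighborhood(panel, config.risk_variant_index,
                                       params.r2_threshold,
                                       inclusive=params.r2_inclusive)
    except Exception as err:
        raise StageError(f"prioritize: lead {risk.id}: {err}") from err
    ld_map = {}
    for v in neighborhood:
        if v.id == risk.id:
            ld_map[v.id] = 1.0
        else:
            ld_map[v.id] = ld_pair(panel, risk.id, v.id).r2
    # per-variant eQTL P: Fisher combination across the four cohorts
    all_vids = [v.id for v in panel.variants]
    eqtl_p_map: dict[str, float] = {}
    for vid in all_vids:
        pvals = []
        for ccfg, cgeno, cexpr in cohorts:
            try:
                r = pearson_eqtl(cgeno.dosage_vector(vid),
                                 cexpr.values.iloc[0],
                                 transform=params.transform,
                                 feature_id="ELL2", variant_id=vid)
                pvals.append(r.p)
            except Exception:
                continue
        if pvals:
            eqtl_p_map[vid] = fisher_combine(pvals, feature_id=vid).p_combined
    # synthetic trait association consumed as a precomputed map
    gcfg = replace(config, n_samples=params.gwas_n,
                   seed=int(hashlib.sha256(f"{config.seed}:gwas".encode())
                            .digest()[:4].hex(), 16) % (2**31))
    gpanel = synthdata.simulate_haplotype_panel(gcfg)
    ggeno = synthdata.panel_to_genotypes(gpanel)
    grng = np.random.default_rng(
        int(hashlib.sha256(f"{config.seed}:gwas-trait".encode())
            .digest()[:4].hex(), 16) % (2**31))
    gd = ggeno.dosage_vector(gpanel.variants[config.risk_variant_index].id)
    gz = (gd - gd.mean()) / gd.std()
    trait = params.gwas_gamma * gz.to_numpy() + grng.normal(
        0.0, 1.0, params.gwas_n)
    gwas_p_map: dict[str, float] = {}
    for vid in all_vids:
        try:
            r = pearson_eqtl(ggeno.dosage_vector(vid), trait,
                             transform="raw", feature_id="trait",
                             variant_id=vid)
            gwas_p_map[vid] = r.p
        except Exception:
            continue
    quad = classify_2d(eqtl_p_map, gwas_p_map, all_vids,
                       eqtl_alpha=params.eqtl_alpha,
                       gwas_alpha=params.gwas_alpha)
    tracks = default_tracks(config, panel.variants)
    for t in tracks:
        write_bed(t, out / f"track_{t.name}.bed")
        emit(f"track_{t.name}.bed", out / f"track_{t.name}.bed")
    candidates = select_candidates(neighborhood, quad["labels"], tracks,
                                   eqtl_p=eqtl_p_map, gwas_p=gwas_p_map,
                                   ld_r2=ld_map)
    cand_df = pd.DataFrame([{
        "variant": c.variant.id, "chrom": c.variant.chrom,
        "pos": c.variant.pos,
        "eqtl_p": _fmt_p(c.eqtl_p) if c.eqtl_p is not None else "NA",
        "gwas_p": _fmt_p(c.gwas_p) if c.gwas_p is not None else "NA",
        "ld_r2_with_lead": _fmt(c.ld_r2_with_lead),
        "quadrant": c.quadrant,
        "tracks_hit": ";".join(c.regulatory_tracks_hit) or "none",
        "candidate": int(c.is_candidate)} for c in candidates])
    _write_tsv(cand_df, out / "candidates.tsv")
    emit("candidates.tsv", out / "candidates.tsv")
    n_cand = int(cand_df["candidate"].sum()) if len(cand_df) else 0
    log.info("prioritize: r2>=%.2f neighborhood=%d, quadrant counts=%s, "
             "candidates=%d", params.r2_threshold, len(neighborhood),
             quad["counts"], n_cand)

    # ---- stage: motif disruption -----------------------------------------
    pcm, probe_ref, probe_alt = synthdata.make_motif_fixture()
    write_pcm(pcm, out / "motif_pcm.txt")
    emit("motif_pcm.txt", out / "motif_pcm.txt")
    pwm = pcm_to_pwm(pcm)
    hits = scan_variant([pwm], probe_ref, probe_alt,
                        synthdata.PROBE_VARIANT_OFFSET,
                        variant_id=risk.id,
                        p_threshold=params.motif_p_threshold,
                        fc_threshold=params.motif_fc_threshold,
                        rule=params.motif_rule)
    motif_df = pd.DataFrame([{
        "motif": h.motif, "variant": h.variant,
        "p_ref": _fmt_p(h.p_ref), "p_alt": _fmt_p(h.p_alt),
        "fold_change": _fmt(h.fold_change), "direction": h.direction,
        "rule": params.motif_rule} for h in hits])
    _write_tsv(motif_df, out / "motif_hits.tsv")
    emit("motif_hits.tsv", out / "motif_hits.tsv")
    log.info("motif: %d hits, rule=%s (p<%g, fc>%g)", len(hits),
             params.motif_rule, params.motif_p_threshold,
             params.motif_fc_threshold)

    # ---- stage: signatures and enrichment --------------------------------
    coexpr, sets = synthdata.simulate_coexpression_and_sets(config, geno)
    write_expression(coexpr, out / "coexpression.tsv")
    write_gmt(sets, out / "gene_sets.gmt")
    emit("coexpression.tsv", out / "coexpression.tsv")
    emit("gene_sets.gmt", out / "gene_sets.gmt")
    anchor_sig = correlation_signature(coexpr, "ELL2",
                                       min_mean_fpkm=params.min_mean_fpkm)
    geno_sig = correlation_signature(coexpr, dose.to_numpy(),
                                     min_mean_fpkm=params.min_mean_fpkm)
    enr_rows = []
    for sig_name, sig in (("anchor_correlation", anchor_sig),
                          ("genotype_correlation", geno_sig)):
        for set_name in sets:
            e = rank_enrichment(sig, sets[set_name], set_name=set_name)
            enr_rows.append({"signature": sig_name, "set": e.set_name,
                             "n_in": e.n_in, "n_out": e.n_out,
                             "z": _fmt(e.statistic), "direction": e.direction,
                             "p": _fmt_p(e.p)})
    enr_df = pd.DataFrame(enr_rows)
    _write_tsv(enr_df, out / "enrichment.tsv")
    emit("enrichment.tsv", out / "enrichment.tsv")
    n_sig = sum(1 for s in anchor_sig
                if not np.isnan(s.q) and s.q < params.fdr_alpha)
    log.info("signatures: %d genes scored, %d at q<%g; enrichment rows=%d",
             len(anchor_sig), n_sig, params.fdr_alpha, len(enr_rows))

    # ---- manifest --------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "params": asdict(params),
        "files": {name: _sha256(path) for name, path in sorted(files.items())},
        "summary": {
            "risk_variant": risk.id,
            "p_combined": float(meta.p_combined),
            "beta_combined": float(meta.beta_combined),
            "ase_ratio_alt": float(ac.ratio),
            "neighborhood_size": len(neighborhood),
            "n_candidates": n_cand,
            "causal_is_candidate": bool(
                cand_df.loc[cand_df["variant"] == risk.id, "candidate"].any()
                if len(cand_df) else False),
            "motif_direction": hits[0].direction if hits else "none",
            "n_genes_fdr_significant": n_sig,
        },
    }
    (out / "manifest.yaml").write_text(yaml.safe_dump(manifest,
                                                      sort_keys=True))
    return out
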