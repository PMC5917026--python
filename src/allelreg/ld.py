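"""Linkage disequilibrium and candidate causal-variant prioritization.

LD metrics are computed from phased haplotype indicator columns: with
alt-allele frequencies p_A, p_B and joint alt-alt frequency p_AB,
D = p_AB - p_A p_B, r2 = D^2 / (p_A (1-p_A) p_B (1-p_B)), and D' = |D| /
D_max with D_max the tightest frequency bound in the direction of D.
Candidates are variants in the lead's r2 neighborhood that are significant
on both the eQTL and the trait-association axis and overlap at least one
regulatory interval track.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from allelreg.genomics_io import HaplotypePanel, IntervalTrack, VariantRecord


class LDError(ValueError):
    """LD is undefined (monomorphic variant)."""


@dataclass(frozen=True)
class LDResult:
    variant_a: str
    variant_b: str
    D: float
    d_prime: float
    r2: float

    def __post_init__(self):
        assert -0.25 - 1e-12 <= self.D <= 0.25 + 1e-12
        assert 0.0 <= self.d_prime <= 1.0 + 1e-12
        assert 0.0 <= self.r2 <= 1.0 + 1e-12


@dataclass(frozen=True)
class CandidateVariant:
    variant: VariantRecord
    eqtl_p: float | None
    gwas_p: float | None
    ld_r2_with_lead: float
    quadrant: str  # both | eqtl_only | gwas_only | neither
    regulatory_tracks_hit: tuple[str, ...]
    is_candidate: bool
    missing_p: bool = False


def ld_pair(panel: HaplotypePanel, v1: str | int, v2: str | int) -> LDResult:
    """Pairwise D, D', and r2 between two variants of a phased panel."""
    i = panel.variant_index(v1) if isinstance(v1, str) else v1
    j = panel.variant_index(v2) if isinstance(v2, str) else v2
    a = panel.haplotypes[:, i].astype(float)
    b = panel.haplotypes[:, j].astype(float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0):
        raise LDError(f"variant {panel.variants[i].id} is monomorphic")
    if pb in (0.0, 1.0):
        raise LDError(f"variant {panel.variants[j].id} is monomorphic")
    pab = float(np.mean(a * b))
    D = pab - pa * pb
    r2 = D * D / (pa * (1 - pa) * pb * (1 - pb))
    if D > 0:
        d_max = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        d_max = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = abs(D) / d_max if D != 0.0 else 0.0
    name_i = panel.variants[i].id
    name_j = panel.variants[j].id
    return LDResult(variant_a=name_i, variant_b=name_j, D=float(D),
                    d_prime=float(min(d_prime, 1.0)), r2=float(min(r2, 1.0)))


def ld_neighborhood(panel: HaplotypePanel, lead: str | int,
                    r2_threshold: float = 0.8,
                    inclusive: bool = True) -> list[VariantRecord]:
    """Variants correlated with the lead at r2 >= threshold (lead included).

    ``inclusive`` applies the threshold as >= (default, logged by callers);
    set False for a strict >. Monomorphic variants are skipped. The result
    is sorted by (chrom, pos).
    """
    li = panel.variant_index(lead) if isinstance(lead, str) else lead
    a = panel.haplotypes[:, li].astype(float)
    if a.mean() in (0.0, 1.0):
        raise LDError(f"lead variant {panel.variants[li].id} is monomorphic")
    hits = [panel.variants[li]]
    for j, v in enumerate(panel.variants):
        if j == li:
            continue
        try:
            res = ld_pair(panel, li, j)
        except LDError:
            continue
        ok = res.r2 >= r2_threshold if inclusive else res.r2 > r2_threshold
        if ok:
            hits.append(v)
    return sorted(hits, key=lambda v: (v.chrom, v.pos))


def classify_2d(eqtl_p: Mapping[str, float], gwas_p: Mapping[str, float],
                variant_ids: Sequence[str],
                eqtl_alpha: float = 1e-3,
                gwas_alpha: float = 1e-3) -> dict:
    """Quadrant labels from joint eQTL/trait significance.

    A variant is significant on an axis when its P value is <= the axis
    alpha (equivalently -log10 p >= -log10 alpha). Variants missing a P
    value on either axis are labeled "neither" and flagged missing.
    Returns ``{"labels": {id: label}, "counts": {label: n},
    "missing": [ids]}``.
    """
    labels: dict[str, str] = {}
    missing: list[str] = []
    counts = {"both": 0, "eqtl_only": 0, "gwas_only": 0, "neither": 0}
    for vid in variant_ids:
        pe = eqtl_p.get(vid)
        pg = gwas_p.get(vid)
        if pe is None or pg is None or np.isnan(pe) or np.isnan(pg):
            labels[vid] = "neither"
            missing.append(vid)
            counts["neither"] += 1
            continue
        sig_e = pe <= eqtl_alpha
        sig_g = pg <= gwas_alpha
        label = ("both" if sig_e and sig_g else
                 "eqtl_only" if sig_e else
                 "gwas_only" if sig_g else "neither")
        labels[vid] = label
        counts[label] += 1
    return {"labels": labels, "counts": counts, "missing": missing}


def select_candidates(neighborhood: Sequence[VariantRecord],
                      quadrants: Mapping[str, str],
                      tracks: Sequence[IntervalTrack],
                      eqtl_p: Mapping[str, float] | None = None,
                      gwas_p: Mapping[str, float] | None = None,
                      ld_r2: Mapping[str, float] | None = None,
                      ) -> list[CandidateVariant]:
    """Candidate causal variants: neighborhood AND quadrant "both" AND
    overlap with at least one regulatory track.

    Returns one record per neighborhood variant (sorted by position) with
    its hit tracks; ``is_candidate`` marks the selected ones.
    """
    out: list[CandidateVariant] = []
    for v in sorted(neighborhood, key=lambda v: (v.chrom, v.pos)):
        hit = tuple(t.name for t in tracks
                    if t.contains_position(v.chrom, v.pos))
        quad = quadrants.get(v.id, "neither")
        pe = eqtl_p.get(v.id) if eqtl_p else None
        pg = gwas_p.get(v.id) if gwas_p else None
        r2 = ld_r2.get(v.id, float("nan")) if ld_r2 else float("nan")
        out.append(CandidateVariant(
            variant=v, eqtl_p=pe, gwas_p=pg, ld_r2_with_lead=r2,
            quadrant=quad, regulatory_tracks_hit=hit,
            is_candidate=(quad == "both" and len(hit) > 0),
            missing_p=(eqtl_p is not None and pe is None)
                      or (gwas_p is not None and pg is None)))
    return out
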