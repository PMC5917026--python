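"""Exon-level eQTL testing, meta-analysis, and allele-specific expression.

The association test is the plain Pearson correlation between risk-allele
dosage and (transformed) expression: the standardized regression slope
equals r, so effect sizes are reported in SD units per risk-allele copy.
Cohort P values are combined with Fisher's inverse chi-square method and
effect sizes by inverse-variance weighting. Allelic imbalance is measured
by exact substring counting of two allele-distinguishing key sequences in
raw reads, tested against a symmetric binomial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from allelreg.genomics_io import ExpressionMatrix, GenotypeData, ReadCollection

#: Smallest positive tail probability we ever report; exact zeros are clamped
#: here and flagged, never printed as 0.
MIN_P = 5e-324


class StatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


@dataclass(frozen=True)
class EqtlResult:
    """Per-(feature, variant) association statistics."""

    feature_id: str
    variant_id: str
    n: int
    r: float
    beta: float
    se: float
    r2: float
    p: float
    transform: str = "log2"
    p_underflow: bool = False

    def __post_init__(self):
        assert self.n >= 3
        assert -1.0 <= self.r <= 1.0
        assert abs(self.r2 - self.r * self.r) < 1e-12
        assert 0.0 <= self.p <= 1.0


@dataclass(frozen=True)
class MetaResult:
    """Fisher-combined association across k cohorts."""

    feature_id: str
    k: int
    chi2: float
    df: int
    p_combined: float
    beta_combined: float
    se_combined: float
    combine_method: str = "fisher+inverse_variance"

    def __post_init__(self):
        assert self.chi2 >= 0.0
        assert self.df == 2 * self.k
        assert 0.0 <= self.p_combined <= 1.0


@dataclass(frozen=True)
class AllelicCount:
    """Allele-specific read counts at a heterozygous site."""

    n_ref: int
    n_alt: int
    ratio: float        # n_alt / (n_ref + n_alt)
    p_binomial: float   # exact two-sided binomial test vs 0.5

    def __post_init__(self):
        assert 0.0 <= self.ratio <= 1.0
        assert 0.0 < self.p_binomial <= 1.0


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided Pearson P from a correlation and sample size.

    t = r sqrt(n - 2) / sqrt(1 - r^2) referred to the t distribution with
    n - 2 df. |r| = 1 underflows to the smallest representable tail.
    """
    if n < 3:
        raise StatisticError("need n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("r must lie in [-1, 1]")
    if abs(r) == 1.0:
        return MIN_P
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return float(min(2.0 * stats.t.sf(abs(t), df=n - 2), 1.0))


def pearson_eqtl(dosage: np.ndarray | pd.Series,
                 expression: np.ndarray | pd.Series,
                 transform: str = "log2",
                 feature_id: str = "feature",
                 variant_id: str = "variant") -> EqtlResult:
    """Pearson association between risk-allele dosage and expression.

    ``transform`` is applied to the raw expression vector: ``log2`` is
    log2(x + 1), ``rank`` uses average ranks, ``raw`` leaves it untouched.
    Missing values in either vector are removed pairwise. P is the two-sided
    tail of t = r sqrt(n - 2) / sqrt(1 - r^2) with n - 2 df;
    se = sqrt((1 - r^2) / (n - 2)) is the SE of the standardized slope.
    """
    d = np.asarray(dosage, dtype=float)
    e = np.asarray(expression, dtype=float)
    if d.shape != e.shape:
        raise ValueError("dosage and expression lengths differ")
    keep = ~(np.isnan(d) | np.isnan(e))
    d, e = d[keep], e[keep]
    n = d.size
    if n < 3:
        raise StatisticError(f"{feature_id}/{variant_id}: fewer than 3 "
                             "complete pairs")
    if transform == "log2":
        e = np.log2(e + 1.0)
    elif transform == "rank":
        e = stats.rankdata(e)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    if np.ptp(d) == 0:
        raise StatisticError(f"{variant_id}: constant dosage")
    if np.ptp(e) == 0:
        raise StatisticError(f"{feature_id}: constant expression")
    r = float(stats.pearsonr(d, e).statistic)
    r = max(-1.0, min(1.0, r))
    p = pearson_p_from_r(r, n)
    underflow = p <= MIN_P or abs(r) == 1.0
    p = max(p, MIN_P)
    se = math.sqrt((1.0 - r * r) / (n - 2)) if abs(r) < 1.0 else 0.0
    return EqtlResult(feature_id=feature_id, variant_id=variant_id, n=n,
                      r=r, beta=r, se=se, r2=r * r, p=p,
                      transform=transform, p_underflow=underflow)


def eqtl_scan(genotypes: GenotypeData, expression: ExpressionMatrix,
              variant_ids: list[str] | None = None,
              transform: str = "log2") -> list[EqtlResult | dict]:
    """All (feature, variant) associations over the shared samples.

    Features or variants for which the statistic is undefined are returned
    as flag dictionaries (``{"feature_id", "variant_id", "error"}``) rather
    than dropped silently.
    """
    shared = [s for s in expression.samples if s in set(genotypes.samples)]
    if not shared:
        raise ValueError("no samples shared between genotypes and expression")
    if variant_ids is None:
        variant_ids = [v.id for v in genotypes.variants]
    results: list[EqtlResult | dict] = []
    raw = expression.values[shared]
    for vid in variant_ids:
        dose = genotypes.dosage.loc[vid, shared]
        for fid in expression.features:
            try:
                results.append(pearson_eqtl(dose, raw.loc[fid],
                                            transform=transform,
                                            feature_id=fid, variant_id=vid))
            except StatisticError as err:
                results.append({"feature_id": fid, "variant_id": vid,
                                "error": str(err)})
    return results


def fisher_combine(p_values: list[float], feature_id: str = "feature",
                   betas: list[float] | None = None,
                   ses: list[float] | None = None) -> MetaResult:
    """Fisher's inverse chi-square combination of independent P values.

    chi2 = -2 sum(ln p_i) follows a chi-square with 2k df under the joint
    null; ``p_combined`` is its upper tail. When per-cohort effects and SEs
    are supplied, ``beta_combined`` is their inverse-variance weighted mean.
    """
    if len(p_values) < 1:
        raise ValueError("need at least one P value")
    for p in p_values:
        if p <= 0.0:
            raise ValueError(
                "p = 0 is not combinable; clamp to the smallest positive "
                "representable tail (allelreg.eqtl.MIN_P) explicitly first")
        if p > 1.0:
            raise ValueError(f"p = {p} > 1")
    k = len(p_values)
    chi2 = -2.0 * float(np.sum(np.log(p_values)))
    p_combined = float(stats.chi2.sf(chi2, df=2 * k))
    if betas is not None and ses is not None:
        beta_c, se_c = combine_beta(betas, ses)
    else:
        beta_c, se_c = float("nan"), float("nan")
    return MetaResult(feature_id=feature_id, k=k, chi2=chi2, df=2 * k,
                      p_combined=max(p_combined, MIN_P),
                      beta_combined=beta_c, se_combined=se_c)


def combine_beta(betas: list[float], ses: list[float]) -> tuple[float, float]:
    """Inverse-variance weighted effect size and its standard error."""
    if len(betas) != len(ses):
        raise ValueError("betas and ses length mismatch")
    if not betas:
        raise ValueError("need at least one effect")
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if (s <= 0).any():
        raise ValueError("all ses must be positive")
    w = 1.0 / (s * s)  # se -> inf gives weight -> 0
    beta = float(np.sum(w * b) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    return beta, se


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def literal_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def count_allelic_reads(reads: ReadCollection, key_ref: str, key_alt: str,
                        complement_mode: str = "reverse") -> AllelicCount:
    """Count reads carrying each allelic key by exact substring matching.

    A read counts toward an allele if it contains the key or — depending on
    ``complement_mode`` ('reverse', 'literal', or 'off') — the key's reverse
    complement / literal complement. A read matching both keys counts once
    per key. ``p_binomial`` is the exact two-sided binomial test of
    n_alt successes in n_ref + n_alt trials against 0.5.
    """
    if len(key_ref) != len(key_alt):
        raise ValueError("allelic keys must have equal length")
    if key_ref == key_alt:
        raise ValueError("allelic keys must differ")
    if len(reads) == 0:
        raise StatisticError("empty read collection: allelic ratio undefined")
    if complement_mode == "reverse":
        extra = reverse_complement
    elif complement_mode == "literal":
        extra = literal_complement
    elif complement_mode == "off":
        extra = None
    else:
        raise ValueError(f"unknown complement_mode {complement_mode!r}")
    keys_ref = [key_ref] + ([extra(key_ref)] if extra else [])
    keys_alt = [key_alt] + ([extra(key_alt)] if extra else [])
    n_ref = n_alt = 0
    for seq in reads:
        if any(k in seq for k in keys_ref):
            n_ref += 1
        if any(k in seq for k in keys_alt):
            n_alt += 1
    total = n_ref + n_alt
    if total == 0:
        raise StatisticError("no read matched either allelic key")
    p = float(stats.binomtest(n_alt, total, 0.5).pvalue)
    return AllelicCount(n_ref=n_ref, n_alt=n_alt, ratio=n_alt / total,
                        p_binomial=max(p, MIN_P))


def genotype_group_summary(expression: np.ndarray | pd.Series,
                           dosage: np.ndarray | pd.Series) -> pd.DataFrame:
    """Raw-scale group means by dosage and percent change vs the 0 group.

    Returns one row per dosage group 0/1/2 with columns ``n``, ``mean``,
    ``pct_change`` (100 * (1 - mean_g / mean_0); NaN when a group is empty
    or the reference group mean is 0) and ``low_n`` flagging groups with a
    single sample.
    """
    e = np.asarray(expression, dtype=float)
    d = np.asarray(dosage, dtype=float)
    keep = ~(np.isnan(e) | np.isnan(d))
    e, d = e[keep], d[keep]
    rows = []
    mean0 = np.nan
    for g in (0, 1, 2):
        vals = e[d == g]
        mean = float(np.mean(vals)) if vals.size else np.nan
        if g == 0:
            mean0 = mean
        if g == 0 or np.isnan(mean) or np.isnan(mean0) or mean0 == 0:
            pct = 0.0 if (g == 0 and not np.isnan(mean)) else np.nan
        else:
            pct = 100.0 * (1.0 - mean / mean0)
        rows.append({"dosage": g, "n": int(vals.size), "mean": mean,
                     "pct_change": pct, "low_n": vals.size == 1})
    return pd.DataFrame(rows).set_index("dosage")
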