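"""Downstream transcriptional signatures and gene-set enrichment.

Signatures score every expressed gene against an anchor — the target gene's
own expression, a risk-allele dosage, or a two-group contrast — yielding a
ranked gene list. Enrichment of a gene set in that list is tested with a
tie-corrected two-sided rank-sum z (normal approximation), with a seeded
score-permutation mode as an alternative. Two-group contrasts use either an
empirical-Bayes moderated t (per-gene variances shrunk toward a scaled
inverse-chi-square prior whose parameters d0, s0^2 are estimated by
moment-matching the log sample variances) or plain log2 ratios of group
means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from allelreg.genomics_io import ExpressionMatrix


@dataclass(frozen=True)
class GeneScore:
    gene: str
    score: float
    score_type: str         # correlation | moderated_t | log2_ratio
    p: float = float("nan")
    q: float = float("nan")
    flagged: bool = False   # e.g. zero variance in both groups

    def __post_init__(self):
        if not math.isnan(self.p):
            assert 0.0 <= self.p <= 1.0
        if not math.isnan(self.q):
            assert 0.0 <= self.q <= 1.0


@dataclass(frozen=True)
class ModeratedTParams:
    """Empirical-Bayes variance prior: d0 prior df, s0_sq prior variance."""

    d0: float
    s0_sq: float
    d_g: float              # residual df per gene (common design)
    n_genes_fit: int

    def __post_init__(self):
        assert self.d0 >= 0.0
        assert self.s0_sq > 0.0


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    n_in: int
    n_out: int
    statistic: float        # tie-corrected rank-sum z
    direction: str          # up | down
    p: float
    mode: str = "ranksum"

    def __post_init__(self):
        assert 0.0 <= self.p <= 1.0


@dataclass(frozen=True)
class LuciferaseEffect:
    construct: str
    n_replicates: int
    replicate_log2_ratios: tuple[float, ...]
    effect: float           # median over replicates


# ---------------------------------------------------------------------------
# FDR


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# anchor-correlation signature


def correlation_signature(expression: ExpressionMatrix,
                          anchor: str | pd.Series | np.ndarray,
                          min_mean_fpkm: float = 5.0,
                          transform: str = "log2") -> list[GeneScore]:
    """Pearson correlation of every expressed gene with an anchor.

    Genes with mean raw FPKM <= ``min_mean_fpkm`` are dropped. When the
    anchor is a gene id it is excluded from its own signature; otherwise the
    anchor is a per-sample numeric vector (e.g. risk-allele dosage). P is
    the usual t transform of r; q is BH.
    """
    raw = expression.values
    if raw.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if isinstance(anchor, str):
        if anchor not in raw.index:
            raise KeyError(f"anchor gene {anchor!r} not in matrix")
        anchor_vec = expression.transformed(transform).loc[anchor].to_numpy()
        exclude = {anchor}
    else:
        anchor_vec = np.asarray(anchor, dtype=float)
        if anchor_vec.size != raw.shape[1]:
            raise ValueError("anchor vector length must match sample count")
        exclude = set()
    if np.ptp(anchor_vec) == 0:
        raise ValueError("anchor is constant; correlation undefined")
    keep = raw.index[(raw.mean(axis=1) > min_mean_fpkm)
                     & ~raw.index.isin(exclude)]
    mat = expression.transformed(transform).loc[keep].to_numpy()
    n = mat.shape[1]
    a = (anchor_vec - anchor_vec.mean()) / anchor_vec.std()
    centered = mat - mat.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    ok = sd > 0
    r = np.full(mat.shape[0], np.nan)
    r[ok] = centered[ok] @ a / (n * sd[ok])
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) == 1.0, 5e-324, p)
    p = np.where(ok, p, np.nan)
    q = np.full_like(p, np.nan)
    q[ok] = bh_fdr(p[ok])
    return [GeneScore(gene=g, score=float(r[i]), score_type="correlation",
                      p=float(p[i]) if ok[i] else float("nan"),
                      q=float(q[i]) if ok[i] else float("nan"),
                      flagged=not ok[i])
            for i, g in enumerate(keep)]


# ---------------------------------------------------------------------------
# moderated t


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return float("inf")
    # trigamma(x) ~ 1/x for large x, ~ 1/x^2 for small x
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = float(special.polygamma(1, x))
        delta = (tri - y) / float(special.polygamma(2, x))
        x_new = x - delta
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < tol * max(1.0, x):
            return x_new
        x = x_new
    return x


def fit_variance_prior(s2: np.ndarray, d_g: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled inverse-chi-square variance
    prior from observed sample variances with d_g df each.

    Uses the digamma/trigamma relations of the scaled-F model for
    z = log(s2): the excess variance of z over trigamma(d_g/2) identifies
    trigamma(d0/2), and the mean identifies s0^2. Returns (inf, exp(mean))
    when there is no excess variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise ValueError("need at least two positive variances to fit prior")
    z = np.log(s2)
    e = z - special.polygamma(0, d_g / 2.0) + math.log(d_g / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, d_g / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(special.polygamma(0, d0 / 2.0))
                         - math.log(d0 / 2.0))
    else:
        d0 = float("inf")
        s0_sq = math.exp(emean)
    return d0, s0_sq


def moderated_t(group_a: ExpressionMatrix, group_b: ExpressionMatrix,
                d0_override: float | None = None
                ) -> tuple[list[GeneScore], ModeratedTParams]:
    """Empirical-Bayes moderated two-sample t on log2(FPKM + 1).

    Per gene: mean difference (a - b), pooled within-group variance s_g^2
    with d_g = n_a + n_b - 2 df; the prior (d0, s0^2) is estimated across
    genes by :func:`fit_variance_prior` (genes with zero variance in both
    groups are flagged and excluded from the fit); the posterior variance
    (d0 s0^2 + d_g s_g^2) / (d0 + d_g) yields t with d0 + d_g df.
    ``d0_override`` forces the prior df (0 gives the ordinary t; inf the
    constant-variance z limit).
    """
    shared = [g for g in group_a.features if g in set(group_b.features)]
    if not shared:
        raise ValueError("no genes shared between the groups")
    A = group_a.transformed("log2").loc[shared].to_numpy()
    B = group_b.transformed("log2").loc[shared].to_numpy()
    n_a, n_b = A.shape[1], B.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 samples per group")
    d_g = float(n_a + n_b - 2)
    diff = A.mean(axis=1) - B.mean(axis=1)
    ss = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) \
        + ((B - B.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / d_g
    flagged = s2 <= 0
    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.median(s2[~flagged])) if (~flagged).any() else 1.0
        if not math.isinf(d0) and d0 > 0:
            # keep the moment-matched scale when only df is forced
            _, s0_sq = fit_variance_prior(s2[~flagged], d_g)
    else:
        d0, s0_sq = fit_variance_prior(s2[~flagged], d_g)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_post = np.inf
    elif d0 == 0:
        s2_post = s2.copy()
        df_post = d_g
    else:
        s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df_post = d0 + d_g
    se = np.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf))
    if math.isinf(df_post):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_post)
    p = np.clip(p, 5e-324, 1.0)
    q = bh_fdr(p)
    scores = [GeneScore(gene=g, score=float(t[i]), score_type="moderated_t",
                        p=float(p[i]), q=float(q[i]), flagged=bool(flagged[i]))
              for i, g in enumerate(shared)]
    params = ModeratedTParams(d0=d0, s0_sq=s0_sq, d_g=d_g,
                              n_genes_fit=int((~flagged).sum()))
    return scores, params


# ---------------------------------------------------------------------------
# log2-ratio signature


def log2_ratio_signature(group_a: ExpressionMatrix, group_b: ExpressionMatrix,
                         floor: float = 0.5) -> list[GeneScore]:
    """Per-gene log2((mean_a + floor) / (mean_b + floor)) on raw means.

    Score-only: no P values are attached (the floor guards low-expression
    genes against ratio blow-up).
    """
    shared = [g for g in group_a.features if g in set(group_b.features)]
    if not shared:
        raise ValueError("no genes shared between the groups")
    ma = group_a.values.loc[shared].mean(axis=1).to_numpy()
    mb = group_b.values.loc[shared].mean(axis=1).to_numpy()
    score = np.log2((ma + floor) / (mb + floor))
    return [GeneScore(gene=g, score=float(score[i]), score_type="log2_ratio")
            for i, g in enumerate(shared)]


# ---------------------------------------------------------------------------
# rank enrichment


def _ranksum_z(ranks: np.ndarray, in_set: np.ndarray,
               all_scores: np.ndarray) -> float:
    n = ranks.size
    n_in = int(in_set.sum())
    n_out = n - n_in
    r_in = float(ranks[in_set].sum())
    mu = n_in * (n + 1) / 2.0
    _, counts = np.unique(all_scores, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (n * (n - 1)))
    var = n_in * n_out / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 0.0
    return (r_in - mu) / math.sqrt(var)


def rank_enrichment(scores: list[GeneScore], gene_set,
                    set_name: str | None = None,
                    mode: str = "ranksum",
                    n_permutations: int = 10000,
                    seed: int = 0) -> EnrichmentResult:
    """Rank-based enrichment of a gene set in a scored gene list.

    ``mode="ranksum"``: two-sided tie-corrected Mann-Whitney rank-sum z
    with normal-approximation P. ``mode="permutation"``: the same z
    referred to its seeded gene-label permutation distribution. Direction
    is "up" when the set's mean rank exceeds the complement's (higher
    scores = higher ranks).
    """
    members = set(gene_set)
    genes = np.array([s.gene for s in scores])
    vals = np.array([s.score for s in scores], dtype=float)
    if np.isnan(vals).any():
        keep = ~np.isnan(vals)
        genes, vals = genes[keep], vals[keep]
    in_set = np.isin(genes, list(members))
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValueError("gene set does not intersect the scored genes")
    if n_in == genes.size:
        raise ValueError("gene set covers every scored gene")
    ranks = stats.rankdata(vals)
    z = _ranksum_z(ranks, in_set, vals)
    direction = "up" if float(ranks[in_set].mean()) >= float(
        ranks[~in_set].mean()) else "down"
    if mode == "ranksum":
        p = 2.0 * stats.norm.sf(abs(z))
    elif mode == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(genes.size)[:n_in]
            mask = np.zeros(genes.size, dtype=bool)
            mask[perm] = True
            if abs(_ranksum_z(ranks, mask, vals)) >= abs(z):
                count += 1
        p = (count + 1) / (n_permutations + 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if set_name is None:
        set_name = getattr(gene_set, "name", "gene_set")
    return EnrichmentResult(set_name=set_name, n_in=n_in,
                            n_out=genes.size - n_in, statistic=float(z),
                            direction=direction, p=float(min(p, 1.0)),
                            mode=mode)


# ---------------------------------------------------------------------------
# luciferase


def luciferase_effect(measurements: pd.DataFrame,
                      construct: str = "construct") -> LuciferaseEffect:
    """Median log2 ratio of renilla-normalized luminescence, risk over
    protective allele.

    ``measurements`` needs one row per replicate with positive columns
    ``firefly_risk``, ``renilla_risk``, ``firefly_prot``, ``renilla_prot``;
    3 to 7 replicates are accepted.
    """
    required = ["firefly_risk", "renilla_risk", "firefly_prot", "renilla_prot"]
    missing = [c for c in required if c not in measurements.columns]
    if missing:
        raise ValueError(f"missing measurement columns {missing}")
    n = len(measurements)
    if not 3 <= n <= 7:
        raise ValueError(f"replicate count {n} outside 3..7")
    if (measurements[required] <= 0).any().any():
        raise ValueError("luminescence readings must be positive")
    ratios = np.log2(
        (measurements["firefly_risk"] / measurements["renilla_risk"])
        / (measurements["firefly_prot"] / measurements["renilla_prot"]))
    return LuciferaseEffect(construct=construct, n_replicates=n,
                            replicate_log2_ratios=tuple(float(x) for x in ratios),
                            effect=float(np.median(ratios)))
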