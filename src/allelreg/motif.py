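"""PWM motif models, exact hit P values, and allelic gain/loss calls.

A position count matrix is turned into a log-odds PWM against a background
distribution. The P value of a score threshold is the probability that a
random background word scores at least that high; it is computed by dynamic
programming over the score distribution — exactly (merging identical
partial sums) for short motifs, or on an epsilon-discretized score grid for
long ones. A variant's two alleles are scored over every motif placement
overlapping the variant on both strands; the allele-wise best-hit P values
yield a fold change and a gain/loss call under P and fold-change
thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from allelreg.eqtl import reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Motif length up to which the exact (merge-equal-sums) DP is the default.
EXACT_LENGTH_LIMIT = 12


@dataclass
class PositionCountMatrix:
    """Observed base counts per motif position (L x 4, columns A,C,G,T)."""

    name: str
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be an (L, 4) array")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))


@dataclass
class ScoredPwm:
    """Log-odds weights (natural log) against a background distribution."""

    name: str
    weights: np.ndarray          # (L, 4)
    background: np.ndarray       # (4,)
    granularity: float = 0.001   # score grid for the discretized DP

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        if (self.background <= 0).any():
            raise ValueError("background probabilities must be positive")

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    def score(self, word: str) -> float:
        """Additive log-odds score of a word of exactly the motif length."""
        if len(word) != self.length:
            raise ValueError(f"word length {len(word)} != motif length "
                             f"{self.length}")
        total = 0.0
        for i, base in enumerate(word):
            try:
                total += self.weights[i, _BASE_INDEX[base]]
            except KeyError:
                raise ValueError(f"non-ACGT base {base!r} in word") from None
        return total

    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())


@dataclass(frozen=True)
class MotifHit:
    """Allelic best-hit comparison for one motif at one variant."""

    motif: str
    variant: str
    p_ref: float
    p_alt: float
    fold_change: float
    direction: str                    # gain | loss | none
    best_offset_ref: int
    best_strand_ref: str
    best_offset_alt: int
    best_strand_alt: str

    def __post_init__(self):
        assert 0.0 < self.p_ref <= 1.0 and 0.0 < self.p_alt <= 1.0
        assert self.fold_change >= 1.0 - 1e-12


def uniform_background() -> np.ndarray:
    return np.full(4, 0.25)


def pcm_to_pwm(pcm: PositionCountMatrix, pseudocount: float = 1.0,
               background: np.ndarray | None = None,
               granularity: float = 0.001) -> ScoredPwm:
    """Standard log-odds PWM with a background-distributed pseudocount.

    weight[i][b] = ln((count[i][b] + pseudocount * bg[b]) /
    (total_i + pseudocount)) - ln(bg[b]).
    """
    bg = uniform_background() if background is None else np.asarray(background,
                                                                    dtype=float)
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    totals = pcm.counts.sum(axis=1)
    if pseudocount == 0 and (totals == 0).any():
        raise ValueError("zero-total column requires a positive pseudocount")
    num = pcm.counts + pseudocount * bg[None, :]
    if (num <= 0).any():
        raise ValueError("column with zero probability; increase pseudocount")
    weights = np.log(num / (totals + pseudocount)[:, None]) - np.log(bg)[None, :]
    return ScoredPwm(name=pcm.name, weights=weights, background=bg,
                     granularity=granularity)


def _pvalue_exact(pwm: ScoredPwm, threshold: float) -> float:
    # DP over exact partial-sum scores; identical sums are merged, so the
    # result equals exhaustive enumeration up to summation order.
    dist: dict[float, float] = {0.0: 1.0}
    for i in range(pwm.length):
        nxt: dict[float, float] = {}
        for s, p in dist.items():
            for b in range(4):
                key = s + pwm.weights[i, b]
                nxt[key] = nxt.get(key, 0.0) + p * pwm.background[b]
        dist = nxt
    return float(sum(p for s, p in dist.items() if s >= threshold))


def _pvalue_discretized(pwm: ScoredPwm, threshold: float) -> float:
    eps = pwm.granularity
    w_int = np.rint(pwm.weights / eps).astype(np.int64)
    # DP on integer grid scores, tracking the achievable range per step
    cur = np.array([1.0])
    cur_lo = 0
    for i in range(pwm.length):
        step_lo = int(w_int[i].min())
        step_hi = int(w_int[i].max())
        new_lo = cur_lo + step_lo
        new_hi = cur_lo + len(cur) - 1 + step_hi
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            shift = int(w_int[i, b]) - step_lo
            new[shift:shift + len(cur)] += cur * pwm.background[b]
        cur, cur_lo = new, new_lo
    t_int = math.ceil(threshold / eps - 1e-9)
    idx = t_int - cur_lo
    if idx <= 0:
        return 1.0
    if idx >= len(cur):
        return 0.0
    return float(cur[idx:].sum())


def score_pvalue(pwm: ScoredPwm, threshold: float,
                 method: str = "auto") -> float:
    """P(score(W) >= threshold) for a background-random word W.

    ``method``: "exact" (merge-equal-sums DP; practical for short motifs),
    "dp" (epsilon-discretized grid DP, any length), or "auto" (exact up to
    length 12, else discretized).
    """
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if method == "auto":
        method = "exact" if pwm.length <= EXACT_LENGTH_LIMIT else "dp"
    if method == "exact":
        p = _pvalue_exact(pwm, threshold)
    elif method == "dp":
        p = _pvalue_discretized(pwm, threshold)
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(max(p, 0.0), 1.0)


def _best_overlapping_score(pwm: ScoredPwm, window: str,
                            variant_offset: int) -> tuple[float, int, str]:
    """Best motif score over all placements covering the variant position,
    on both strands."""
    L = pwm.length
    best = -math.inf
    best_at, best_strand = -1, "+"
    rc_window = reverse_complement(window)
    rc_offset = len(window) - 1 - variant_offset
    for strand, seq, off in (("+", window, variant_offset),
                             ("-", rc_window, rc_offset)):
        for start in range(max(0, off - L + 1),
                           min(len(seq) - L, off) + 1):
            s = pwm.score(seq[start:start + L])
            if s > best:
                best, best_at, best_strand = s, start, strand
    if best == -math.inf:
        raise ValueError("no motif placement overlaps the variant")
    return best, best_at, best_strand


def best_allele_pvalue(pwm: ScoredPwm, window_ref: str, window_alt: str,
                       variant_offset: int,
                       method: str = "auto") -> tuple[float, float, dict]:
    """Best-hit P value per allele over placements covering the variant.

    The two windows must be identical except at ``variant_offset`` and long
    enough (>= 2L - 1) that a motif placement can cover the variant from
    every register. Returns (p_ref, p_alt, details) where details records
    the best offset and strand per allele.
    """
    window_ref = window_ref.upper()
    window_alt = window_alt.upper()
    if len(window_ref) != len(window_alt):
        raise ValueError("allele windows must have equal length")
    diffs = [i for i, (a, b) in enumerate(zip(window_ref, window_alt))
             if a != b]
    if window_ref != window_alt and diffs != [variant_offset]:
        raise ValueError(
            f"windows differ at positions {diffs}, expected only at "
            f"{variant_offset}")
    if not 0 <= variant_offset < len(window_ref):
        raise ValueError("variant_offset outside the window")
    if len(window_ref) < 2 * pwm.length - 1:
        raise ValueError(
            f"window length {len(window_ref)} < 2L-1 = {2 * pwm.length - 1} "
            f"for motif {pwm.name}")
    s_ref, off_ref, strand_ref = _best_overlapping_score(pwm, window_ref,
                                                         variant_offset)
    s_alt, off_alt, strand_alt = _best_overlapping_score(pwm, window_alt,
                                                         variant_offset)
    p_ref = max(score_pvalue(pwm, s_ref, method=method), 5e-324)
    p_alt = max(score_pvalue(pwm, s_alt, method=method), 5e-324)
    return p_ref, p_alt, {"best_offset_ref": off_ref,
                          "best_strand_ref": strand_ref,
                          "best_offset_alt": off_alt,
                          "best_strand_alt": strand_alt}


def call_gain_loss(p_ref: float, p_alt: float,
                   p_threshold: float = 0.0005,
                   fc_threshold: float = 5.0,
                   rule: str = "both") -> str:
    """Gain/loss decision from allelic best-hit P values.

    Under the default ``rule="both"`` a call requires both alleles' best-hit
    P values below ``p_threshold`` and a fold change above ``fc_threshold``;
    ``rule="either"`` requires the threshold for at least one allele.
    Direction: "loss" when the alternate (risk) allele binds more weakly
    (p_ref < p_alt), "gain" when it binds more strongly.
    """
    if p_ref == p_alt:
        return "none"
    fc = max(p_ref, p_alt) / min(p_ref, p_alt)
    if rule == "both":
        passes = p_ref < p_threshold and p_alt < p_threshold
    elif rule == "either":
        passes = p_ref < p_threshold or p_alt < p_threshold
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if not passes or fc <= fc_threshold:
        return "none"
    return "loss" if p_ref < p_alt else "gain"


def scan_variant(pwm_library: list[ScoredPwm], window_ref: str,
                 window_alt: str, variant_offset: int,
                 variant_id: str = "variant",
                 p_threshold: float = 0.0005, fc_threshold: float = 5.0,
                 rule: str = "both", method: str = "auto") -> list[MotifHit]:
    """Allelic motif screen of one variant against a PWM library.

    One hit per library motif (duplicates kept as-is), sorted by descending
    fold change.
    """
    hits: list[MotifHit] = []
    for pwm in pwm_library:
        p_ref, p_alt, det = best_allele_pvalue(pwm, window_ref, window_alt,
                                               variant_offset, method=method)
        fc = max(p_ref, p_alt) / min(p_ref, p_alt)
        direction = call_gain_loss(p_ref, p_alt, p_threshold=p_threshold,
                                   fc_threshold=fc_threshold, rule=rule)
        hits.append(MotifHit(motif=pwm.name, variant=variant_id,
                             p_ref=p_ref, p_alt=p_alt, fold_change=fc,
                             direction=direction, **det))
    return sorted(hits, key=lambda h: -h.fold_change)
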