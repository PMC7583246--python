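"""Two-locus haplotype analysis from unphased genotypes.

Haplotype frequencies are estimated with the standard two-locus EM algorithm
(only the double heterozygote has ambiguous phase; it is split between the
coupling and repulsion resolutions in proportion to the current frequency
estimates).  From the fitted frequencies come D, D' and r², case/control
haplotype odds ratios on expected (fractional) counts, and a Welch contrast
of a quantitative trait between carriers of two haplotypes assigned by
maximum-posterior diplotype.

Allele coding: 0 = ref, 1 = alt at each locus; haplotype (a, b) means allele
``a`` at the first locus and ``b`` at the second.  Frequencies are stored in
the order (h00, h01, h10, h11).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateVarianceError,
    UndefinedLDError,
    ValidationError,
)

HAP_ORDER = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass
class HaplotypeFreqs:
    freqs: np.ndarray  # (h00, h01, h10, h11)
    loglik: float
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(self.freqs < -1e-12) or abs(self.freqs.sum() - 1) > 1e-9:
            raise ValidationError("haplotype frequencies must be a probability vector")

    def freq(self, hap: tuple[int, int]) -> float:
        return float(self.freqs[2 * hap[0] + hap[1]])


@dataclass
class LDStats:
    D: float
    D_prime: float
    r2: float


@dataclass
class HaplotypeEffect:
    target: tuple[int, int]
    odds_ratio: float
    ci_low: float
    ci_high: float
    case_counts: tuple[float, float]  # (target, other) expected haplotype counts
    control_counts: tuple[float, float]
    corrected: bool = False  # Haldane–Anscombe 0.5 applied


@dataclass
class TraitContrast:
    difference: float
    se: float
    p: float
    n_a: int
    n_b: int


def genotype_table(ga, gb) -> np.ndarray:
    """3×3 cross-tabulation of alt-allele counts at two loci."""
    ga = np.asarray(ga, dtype=int)
    gb = np.asarray(gb, dtype=int)
    if ga.shape != gb.shape:
        raise ValidationError("genotype vectors must have equal length")
    if np.any((ga < 0) | (ga > 2) | (gb < 0) | (gb > 2)):
        raise ValidationError("genotypes must lie in {0, 1, 2}")
    table = np.zeros((3, 3), dtype=float)
    np.add.at(table, (ga, gb), 1.0)
    return table


def _cell_probs(h: np.ndarray) -> np.ndarray:
    """P(gA, gB) for each 3×3 genotype cell under random union of haplotypes."""
    h00, h01, h10, h11 = h
    return np.array(
        [
            [h00**2, 2 * h00 * h01, h01**2],
            [2 * h00 * h10, 2 * h00 * h11 + 2 * h01 * h10, 2 * h01 * h11],
            [h10**2, 2 * h10 * h11, h11**2],
        ]
    )


def em_haplotype_freqs(
    table: np.ndarray, tol: float = 1e-10, max_iter: int = 1000
) -> HaplotypeFreqs:
    """EM fixed point of the two-locus likelihood for a 3×3 genotype table.

    Initialized at linkage equilibrium; converged when the log-likelihood
    gain drops below ``tol``.  The log-likelihood is non-decreasing across
    iterations (an EM guarantee, also recorded in ``loglik_trace``).
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (3, 3) or np.any(table < 0):
        raise ValidationError("need a non-negative 3×3 genotype count table")
    n = table.sum()
    if n <= 0:
        raise ValidationError("zero total genotype count")

    ga = np.arange(3)[:, None] * np.ones(3)[None, :]
    gb = np.ones(3)[:, None] * np.arange(3)[None, :]
    pa = (table * ga).sum() / (2 * n)
    pb = (table * gb).sum() / (2 * n)
    h = np.array(
        [(1 - pa) * (1 - pb), (1 - pa) * pb, pa * (1 - pb), pa * pb]
    )
    h = np.clip(h, 1e-12, None)
    h /= h.sum()

    def loglik(hv):
        probs = _cell_probs(hv)
        mask = table > 0
        if np.any(probs[mask] <= 0):
            return -np.inf
        return float((table[mask] * np.log(probs[mask])).sum())

    trace = [loglik(h)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        h00, h01, h10, h11 = h
        denom = h00 * h11 + h01 * h10
        w = 0.5 if denom == 0 else (h00 * h11) / denom  # coupling share of dbl het
        ndh = table[1, 1]
        c = np.zeros(4)
        c[0] = 2 * table[0, 0] + table[0, 1] + table[1, 0] + ndh * w
        c[1] = 2 * table[0, 2] + table[0, 1] + table[1, 2] + ndh * (1 - w)
        c[2] = 2 * table[2, 0] + table[1, 0] + table[2, 1] + ndh * (1 - w)
        c[3] = 2 * table[2, 2] + table[2, 1] + table[1, 2] + ndh * w
        h_new = c / (2 * n)
        ll = loglik(h_new)
        trace.append(ll)
        gain = ll - trace[-2]
        h = h_new
        if abs(gain) < tol:
            converged = True
            break
    return HaplotypeFreqs(
        freqs=h, loglik=trace[-1], n_iter=it, converged=converged,
        loglik_trace=trace,
    )


def ld_stats(freqs: HaplotypeFreqs | np.ndarray) -> LDStats:
    """D, D' and r² from two-locus haplotype frequencies."""
    h = freqs.freqs if isinstance(freqs, HaplotypeFreqs) else np.asarray(freqs, float)
    h00, h01, h10, h11 = h
    pa = h10 + h11  # alt at locus A
    pb = h01 + h11
    if min(pa, 1 - pa, pb, 1 - pb) <= 0:
        raise UndefinedLDError("monomorphic locus: LD undefined")
    D = h11 - pa * pb
    if D > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif D < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        dmax = 1.0
    r2 = D * D / (pa * (1 - pa) * pb * (1 - pb))
    return LDStats(D=float(D), D_prime=float(D / dmax), r2=float(r2))


def _expected_hap_counts(ga, gb, target: tuple[int, int]) -> tuple[float, float, HaplotypeFreqs]:
    fit = em_haplotype_freqs(genotype_table(ga, gb))
    n_hap = 2 * len(np.asarray(ga))
    t = fit.freq(target) * n_hap
    return t, n_hap - t, fit


def haplotype_case_control_or(
    ga, gb, case, target: tuple[int, int] = (1, 1)
) -> HaplotypeEffect:
    """Case/control odds ratio for carrying the target haplotype.

    Frequencies are estimated by EM separately within cases and controls;
    the 2×2 table uses expected (fractional) haplotype counts.  CI: Woolf
    log-OR ± 1.96·SE; Haldane–Anscombe 0.5 added to every cell when any
    expected cell is below 0.5.
    """
    case = np.asarray(case).astype(bool)
    ga = np.asarray(ga)
    gb = np.asarray(gb)
    if case.sum() == 0 or (~case).sum() == 0:
        raise ValidationError("both case and control groups must be non-empty")
    t1, o1, _ = _expected_hap_counts(ga[case], gb[case], target)
    t0, o0, _ = _expected_hap_counts(ga[~case], gb[~case], target)
    cells = np.array([t1, o1, t0, o0], dtype=float)
    corrected = bool(np.any(cells < 0.5))
    if corrected:
        cells = cells + 0.5
    t1c, o1c, t0c, o0c = cells
    or_ = (t1c / o1c) / (t0c / o0c)
    se = float(np.sqrt((1 / cells).sum()))
    lo, hi = np.exp(np.log(or_) + np.array([-1.96, 1.96]) * se)
    return HaplotypeEffect(
        target=target, odds_ratio=float(or_), ci_low=float(lo), ci_high=float(hi),
        case_counts=(float(t1), float(o1)), control_counts=(float(t0), float(o0)),
        corrected=corrected,
    )


def _map_diplotypes(ga, gb, freqs: HaplotypeFreqs) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Maximum-posterior diplotype per individual; only the double heterozygote
    is ambiguous and is resolved toward the more probable phase (coupling on
    ties)."""
    h = freqs.freqs
    coupling = h[0] * h[3] >= h[1] * h[2]
    out = []
    for a, b in zip(np.asarray(ga, int), np.asarray(gb, int)):
        if a == 1 and b == 1:
            out.append((((0, 0), (1, 1)) if coupling else ((0, 1), (1, 0))))
        else:
            ha = (0, 0) if a == 0 else (1, 1) if a == 2 else (0, 1)
            hb = (0, 0) if b == 0 else (1, 1) if b == 2 else (0, 1)
            out.append(((ha[0], hb[0]), (ha[1], hb[1])))
    return out


def haplotype_trait_contrast(
    ga, gb, trait, hap_a: tuple[int, int] = (0, 0), hap_b: tuple[int, int] = (1, 1)
) -> TraitContrast:
    """Welch comparison of the trait between exclusive carrier groups.

    Diplotypes are assigned by maximum posterior under pooled EM frequencies;
    carriers hold at least one copy.  Groups are exclusive: A-not-B vs
    B-not-A.
    """
    trait = np.asarray(trait, dtype=float)
    if not np.all(np.isfinite(trait)):
        raise ValidationError("trait contains non-finite values")
    fit = em_haplotype_freqs(genotype_table(ga, gb))
    diplos = _map_diplotypes(ga, gb, fit)
    has_a = np.array([hap_a in d for d in diplos])
    has_b = np.array([hap_b in d for d in diplos])
    grp_a = has_a & ~has_b
    grp_b = has_b & ~has_a
    if grp_a.sum() == 0 or grp_b.sum() == 0:
        raise ValidationError("an exclusive carrier group is empty")
    xa, xb = trait[grp_a], trait[grp_b]
    if np.var(xa) == 0 and np.var(xb) == 0:
        raise DegenerateVarianceError("trait constant within both carrier groups")
    res = stats.ttest_ind(xa, xb, equal_var=False)
    se = float(
        np.sqrt(np.var(xa, ddof=1) / len(xa) + np.var(xb, ddof=1) / len(xb))
    )
    return TraitContrast(
        difference=float(xa.mean() - xb.mean()), se=se, p=float(res.pvalue),
        n_a=int(grp_a.sum()), n_b=int(grp_b.sum()),
    )
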