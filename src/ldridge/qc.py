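"""Variant and sample quality control.

Filters mirror standard array-genotyping QC: per-variant call rate, minor
allele frequency, exact Hardy–Weinberg test, per-sample call rate, and
removal of one member of each sample pair whose identity state (mean
proportion of shared alleles) exceeds a ceiling.  Defaults: call rates 0.95,
HWE p floor 1e-6, MAF floor 1e-3, identity-state ceiling 0.4.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import EmptyResultError, ValidationError
from .simulate import Cohort

log = logging.getLogger(__name__)


@dataclass
class QcThresholds:
    variant_call_rate: float = 0.95
    sample_call_rate: float = 0.95
    hwe_p_floor: float = 1e-6
    maf_floor: float = 1e-3
    ibs_ceiling: float = 0.4
    ibs_max_variants: int = 500  # identity state estimated on a variant subset
    # below this many variants the pairwise relatedness estimate is too noisy
    # (sd ~ 1/sqrt(M)) and the duplicate screen would flag unrelated pairs;
    # the screen is skipped with a warning instead
    ibs_min_variants: int = 400

    def __post_init__(self):
        for name in ("variant_call_rate", "sample_call_rate", "hwe_p_floor",
                     "maf_floor", "ibs_ceiling"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"threshold {name}={v} outside [0, 1]")


@dataclass
class QcReport:
    variant_stats: pd.DataFrame  # variant_id, call_rate, maf, hwe_p
    sample_stats: pd.DataFrame  # sample_id, call_rate
    excluded_variants: pd.DataFrame  # variant_id, reason
    excluded_samples: pd.DataFrame  # sample_id, reason
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)


def hwe_exact_test(counts) -> float:
    """Exact Hardy–Weinberg test p-value for genotype counts (hom-ref, het, hom-alt).

    Conditions on the allele counts and sums the probabilities of all
    heterozygote configurations no more probable than the observed one.
    """
    n_aa, n_ab, n_bb = (int(c) for c in counts)
    if min(n_aa, n_ab, n_bb) < 0:
        raise ValidationError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n == 0:
        raise ValidationError("zero total genotype count: HWE undefined")
    n_b = n_ab + 2 * n_bb  # alt allele count
    n_minor = min(n_b, 2 * n - n_b)
    if n_minor == 0:
        return 1.0
    # heterozygote count shares the parity of the minor allele count
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    homs_minor = (n_minor - hets) // 2
    homs_major = n - hets - homs_minor
    # log P(het = h | n, n_minor), Levene-Haldane distribution
    logp = (
        np.log(2.0) * hets
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homs_minor + 1)
        - gammaln(homs_major + 1)
        + gammaln(n_minor + 1)
        + gammaln(2 * n - n_minor + 1)
        - gammaln(2 * n + 1)
    )
    p = np.exp(logp - logp.max())
    p /= p.sum()
    obs_het = n_ab
    p_obs = p[hets == obs_het]
    if len(p_obs) == 0:
        raise ValidationError(
            f"genotype counts {counts} inconsistent with allele parity"
        )
    return float(min(1.0, p[p <= p_obs[0] * (1 + 1e-12)].sum()))


def variant_stats(G: np.ndarray, variant_ids) -> pd.DataFrame:
    """Call rate, MAF and exact HWE p per variant (missing coded −1)."""
    n = G.shape[0]
    obs = G >= 0
    call = obs.mean(axis=0)
    stats = []
    for j in range(G.shape[1]):
        g = G[obs[:, j], j]
        nj = len(g)
        if nj == 0:
            stats.append((0.0, 0.0, 1.0))
            continue
        af = g.sum() / (2 * nj)
        maf = min(af, 1 - af)
        counts = (int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum()))
        stats.append((call[j], maf, hwe_exact_test(counts)))
    df = pd.DataFrame(stats, columns=["call_rate", "maf", "hwe_p"])
    df.insert(0, "variant_id", list(variant_ids))
    return df


def ibs_matrix(G: np.ndarray, max_variants: int | None = None,
               rng: np.random.Generator | None = None) -> np.ndarray:
    """Raw pairwise allele sharing: mean of 1 − |g_i − g_j|/2 over loci.

    This is ~0.7 even for unrelated pairs at common variants, so the QC
    duplicate screen uses :func:`relatedness_matrix` instead; this raw form
    is kept for reporting.
    """
    m = G.shape[1]
    if max_variants is not None and m > max_variants:
        rng = rng or np.random.default_rng(0)
        G = G[:, rng.choice(m, size=max_variants, replace=False)]
    Gf = G.astype(np.float64)
    Gf[G < 0] = np.nan
    ind = [(Gf == k).astype(np.float64) for k in (0.0, 1.0, 2.0)]
    same = ind[0] @ ind[0].T + ind[1] @ ind[1].T + ind[2] @ ind[2].T
    near = (
        ind[0] @ ind[1].T + ind[1] @ ind[0].T + ind[1] @ ind[2].T + ind[2] @ ind[1].T
    )
    obs = (~np.isnan(Gf)).astype(np.float64)
    n_obs = obs @ obs.T
    with np.errstate(invalid="ignore", divide="ignore"):
        ibs = (same + 0.5 * near) / n_obs
    return ibs


def relatedness_matrix(G: np.ndarray, max_variants: int | None = None,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Pairwise identity state as allele-frequency-centered relatedness:
    r_ij = mean over loci of (g_i − 2p)(g_j − 2p)/(2p(1−p)).

    Duplicate samples score ≈ 1, unrelated pairs ≈ 0, so a ceiling of 0.4
    flags duplicates and first-degree relatives.  Missing entries are mean
    imputed (they contribute 0 to the centered product)."""
    m = G.shape[1]
    if max_variants is not None and m > max_variants:
        rng = rng or np.random.default_rng(0)
        G = G[:, rng.choice(m, size=max_variants, replace=False)]
    Gf = G.astype(np.float64)
    miss = G < 0
    Gf[miss] = np.nan
    p = np.nanmean(Gf, axis=0) / 2.0
    denom = 2.0 * p * (1.0 - p)
    keep = denom > 0
    Z = (Gf[:, keep] - 2.0 * p[keep]) / np.sqrt(denom[keep])
    Z[np.isnan(Z)] = 0.0
    return (Z @ Z.T) / keep.sum()


def qc_filter(
    cohort: Cohort, thresholds: QcThresholds | None = None
) -> tuple[Cohort, QcReport]:
    """Apply all QC rules; returns the filtered cohort and a full report.

    Order: sample call rate → identity-state duplicates (later-indexed member
    removed) → variant call rate / MAF / HWE, each recomputed on the retained
    samples.  Raises EmptyResultError if nothing survives.
    """
    thr = thresholds or QcThresholds()
    G = cohort.genotypes
    n = G.shape[0]
    sample_ids = cohort.phenotypes["sample_id"].to_numpy()

    sample_call = (G >= 0).mean(axis=1)
    sample_stats = pd.DataFrame(dict(sample_id=sample_ids, call_rate=sample_call))
    excl_samples: list[tuple[str, str]] = []
    keep_s = sample_call >= thr.sample_call_rate
    for sid in sample_ids[~keep_s]:
        excl_samples.append((sid, "call_rate"))

    flagged: list[tuple[str, str, float]] = []
    if G.shape[1] < thr.ibs_min_variants:
        log.warning(
            "relatedness screen skipped: %d variants < %d needed for a stable "
            "estimate", G.shape[1], thr.ibs_min_variants,
        )
    elif keep_s.sum() > 1 and thr.ibs_ceiling < 1.0:
        idx = np.flatnonzero(keep_s)
        ibs = relatedness_matrix(G[idx], max_variants=thr.ibs_max_variants)
        iu, ju = np.triu_indices(len(idx), k=1)
        hot = ibs[iu, ju] > thr.ibs_ceiling
        dropped: set[int] = set()
        for a, b in zip(iu[hot], ju[hot]):
            flagged.append((sample_ids[idx[a]], sample_ids[idx[b]], float(ibs[a, b])))
            if a not in dropped and b not in dropped:
                dropped.add(b)  # the later-indexed member goes
                excl_samples.append((sample_ids[idx[b]], "ibs"))
                keep_s[idx[b]] = False

    if keep_s.sum() == 0:
        raise EmptyResultError("all samples removed by QC")
    sub = cohort.subset_samples(np.flatnonzero(keep_s))

    vstats = variant_stats(sub.genotypes, sub.variants["variant_id"])
    excl_variants: list[tuple[str, str]] = []
    keep_v = np.ones(len(vstats), dtype=bool)
    for j, row in vstats.iterrows():
        if row["call_rate"] < thr.variant_call_rate:
            excl_variants.append((row["variant_id"], "call_rate"))
            keep_v[j] = False
        elif row["maf"] < thr.maf_floor:
            excl_variants.append((row["variant_id"], "maf"))
            keep_v[j] = False
        elif row["hwe_p"] < thr.hwe_p_floor:
            excl_variants.append((row["variant_id"], "hwe"))
            keep_v[j] = False
    if keep_v.sum() == 0:
        raise EmptyResultError("all variants removed by QC")
    sub = sub.subset_variants(np.flatnonzero(keep_v))

    report = QcReport(
        variant_stats=vstats,
        sample_stats=sample_stats,
        excluded_variants=pd.DataFrame(
            excl_variants, columns=["variant_id", "reason"]
        ),
        excluded_samples=pd.DataFrame(excl_samples, columns=["sample_id", "reason"]),
        flagged_pairs=flagged,
    )
    log.info(
        "QC: %d/%d samples, %d/%d variants retained",
        sub.n, n, sub.n_variants, cohort.n_variants,
    )
    return sub, report
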