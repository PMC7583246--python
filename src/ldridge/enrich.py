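"""Gene-set over-representation analysis.

For a study gene list against an explicit background, each category is
scored by its expected study count (|study| x |category∩background| /
|background|), the observed count, fold enrichment (observed/expected), a
direction sign, a hypergeometric two-sided p (doubled smaller tail, capped
at 1) with a binomial test as a secondary column, and BH-FDR across
categories (significance cutoff 0.05).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .scan import bh_fdr

log = logging.getLogger(__name__)


def fold_enrichment(observed: float, expected: float) -> tuple[float, str, str]:
    """(fold, direction, flag).  Direction '+' when observed >= expected.

    expected = 0 with observed = 0 -> NaN flagged 'undefined'; expected = 0
    with observed > 0 -> +inf flagged 'infinite'.
    """
    if observed < 0 or expected < 0:
        raise ValidationError("counts must be non-negative")
    if expected == 0:
        if observed == 0:
            return math.nan, "+", "undefined"
        return math.inf, "+", "infinite"
    fold = observed / expected
    return fold, ("+" if observed >= expected else "-"), ""


def _hypergeom_tails(k: int, N: int, K: int, n: int) -> tuple[float, float]:
    """(P(X >= k), P(X <= k)) for k category genes in a study draw of n from
    a background of N holding K category genes."""
    upper = float(stats.hypergeom.sf(k - 1, N, K, n))
    lower = float(stats.hypergeom.cdf(k, N, K, n))
    return upper, lower


def overrepresentation_test(
    study_genes, category_map: dict[str, set], background_genes
) -> pd.DataFrame:
    """One EnrichmentRecord row per category, FDR-adjusted across categories.

    ``study_genes`` must be a subset of ``background_genes``; categories are
    intersected with the background before scoring.
    """
    study = set(study_genes)
    background = set(background_genes)
    missing = sorted(study - background)
    if missing:
        raise ValidationError(f"study gene(s) absent from background: {missing[:5]}")
    if not category_map:
        raise ValidationError("category map is empty")
    N, n = len(background), len(study)
    rows = []
    for cat, genes in sorted(category_map.items()):
        cat_bg = set(genes) & background
        K = len(cat_bg)
        observed = len(cat_bg & study)
        expected = n * K / N
        fold, direction, flag = fold_enrichment(observed, expected)
        upper, lower = _hypergeom_tails(observed, N, K, n)
        # p follows the observed direction (over-representation tail for '+');
        # the doubled-smaller-tail two-sided value rides along
        p_hyper = upper if direction == "+" else lower
        p_two = min(1.0, 2.0 * min(upper, lower))
        p_binom = float(
            stats.binomtest(observed, n, K / N).pvalue if K > 0 and n > 0 else 1.0
        )
        rows.append(
            dict(
                category=cat, background_count=K, expected=expected,
                observed=observed, fold=fold, direction=direction,
                p=p_hyper, p_two_sided=p_two, p_binomial=p_binom, flag=flag,
            )
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["fdr"] < 0.05
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def read_gene_list(path: str) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def read_gene_set_tsv(path: str) -> dict[str, set]:
    """Two-column (gene, category) TSV -> {category: genes}."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene", "category"])
    out: dict[str, set] = {}
    for gene, cat in zip(df["gene"], df["category"]):
        out.setdefault(str(cat), set()).add(str(gene))
    return out


def read_gaf(path: str) -> dict[str, set]:
    """GO annotation (GAF 2.x) -> {GO id: gene symbols}.  Comment lines start
    with '!'; column 3 is the gene symbol, column 5 the GO id."""
    out: dict[str, set] = {}
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("!"):
                continue
            parts = ln.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            symbol, go_id = parts[2], parts[4]
            if symbol and go_id:
                out.setdefault(go_id, set()).add(symbol)
    return out
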