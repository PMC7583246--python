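"""Dual-trait capture: SNPs significant for both traits, coding-class filter,
and per-gene summaries.

Default capture rule: genome-wide p < 5e-8 for the binary drinking trait AND
BH q < 0.05 for γ-GT; a both-FDR mode is available.  The coding filter keeps
missense, coding-synonymous, 5'-UTR, 3'-UTR/ncRNA, cds-indel and frameshift
classes, dropping intronic/intergenic variants.
"""

from __future__ import annotations

import logging

import pandas as pd

from .errors import ConsistencyError, ValidationError

log = logging.getLogger(__name__)

CODING_CLASSES = frozenset(
    {"missense", "coding-synonymous", "utr5", "utr3-ncRNA", "cds-indel", "frameshift"}
)
NONCODING_CLASSES = frozenset({"intronic", "intergenic"})
KNOWN_CLASSES = CODING_CLASSES | NONCODING_CLASSES


def dual_significant(
    drink: pd.DataFrame,
    ggt: pd.DataFrame,
    p_threshold: float = 5e-8,
    fdr_threshold: float = 0.05,
    mode: str = "p_and_fdr",
) -> pd.DataFrame:
    """Variants passing both trait filters, sorted by drinking p ascending.

    ``mode='p_and_fdr'`` (default): drinking p < p_threshold and γ-GT BH q <
    fdr_threshold.  ``mode='both_fdr'``: BH q < fdr_threshold for both traits.
    """
    if mode not in ("p_and_fdr", "both_fdr"):
        raise ValidationError(f"unknown capture mode {mode!r}")
    a, b = set(drink["variant_id"]), set(ggt["variant_id"])
    if a != b:
        raise ConsistencyError(
            f"variant universes differ: {len(a - b)} only in drinking table, "
            f"{len(b - a)} only in γ-GT table"
        )
    g = ggt.set_index("variant_id")
    merged = drink.set_index("variant_id")
    merged = merged.join(g[["p", "q"]], rsuffix="_ggt")
    if mode == "p_and_fdr":
        keep = (merged["p"] < p_threshold) & (merged["q_ggt"] < fdr_threshold)
    else:
        keep = (merged["q"] < fdr_threshold) & (merged["q_ggt"] < fdr_threshold)
    out = merged[keep].sort_values("p", kind="stable").reset_index()
    out = out.rename(columns={"p": "p_drink", "q": "q_drink", "p_ggt": "p_ggt"})
    return out


def coding_filter(hits: pd.DataFrame, allowed=CODING_CLASSES) -> pd.DataFrame:
    """Retain hits whose function class is in ``allowed``; unknown labels error."""
    if "func_class" not in hits.columns:
        raise ValidationError("hits must carry a 'func_class' column")
    labels = set(hits["func_class"])
    bad = labels - KNOWN_CLASSES
    if bad:
        raise ValidationError(f"unknown function class label(s): {sorted(bad)}")
    counts = hits["func_class"].value_counts()
    for cls, cnt in counts.items():
        log.info("coding_filter: class %-18s %d hits", cls, cnt)
    out = hits[hits["func_class"].isin(allowed)].reset_index(drop=True)
    if out.empty:
        log.warning("coding_filter: no hits in allowed classes %s", sorted(allowed))
    return out


def gene_summary(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per gene: positional span, minimum drinking p, SNP count.

    A hit with several '|'-separated gene labels contributes to each of them.
    """
    req = {"gene", "pos", "p_drink"}
    if not req <= set(hits.columns):
        raise ValidationError(f"hits must carry columns {sorted(req)}")
    rows = hits.copy()
    multi = rows["gene"].astype(str).str.contains(r"\|")
    if multi.any():
        log.info("%d hits overlap several genes; duplicated per gene", multi.sum())
        rows = rows.assign(gene=rows["gene"].astype(str).str.split(r"\|")).explode(
            "gene"
        )
    out = (
        rows.groupby("gene")
        .agg(
            start=("pos", "min"),
            end=("pos", "max"),
            min_p_drink=("p_drink", "min"),
            n_snps=("p_drink", "size"),
        )
        .sort_values("min_p_drink", kind="stable")
        .reset_index()
    )
    return out
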