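"""Reading and writing cohorts: VCF v4.2 genotypes + tab-separated phenotypes.

Genotypes are biallelic SNVs with unphased GT ("0/0", "0/1", "1/1") and the
per-variant annotations carried in INFO as ``GENE=<symbol>;FUNC=<class>``.
The phenotype table has columns sample_id, drink (0/1), ggt (U/L), age, sex
(1 = male).  ``read_cohort(write_cohort(c))`` reproduces ``c`` exactly.
"""

from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import ConsistencyError, ParseError, ValidationError
from .simulate import Cohort

log = logging.getLogger(__name__)

PHENO_COLUMNS = ["sample_id", "drink", "ggt", "age", "sex"]
_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_cohort(cohort: Cohort, vcf_path: str, pheno_path: str) -> None:
    """Write the cohort as a plain-text VCF v4.2 plus a phenotype TSV."""
    samples = list(cohort.phenotypes["sample_id"])
    contigs = list(dict.fromkeys(cohort.variants["chrom"].astype(str)))
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ldridge\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write(
            '##INFO=<ID=FUNC,Number=1,Type=String,Description="Function class">\n'
        )
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        # sort by (chrom, pos) as VCF requires; remember the permutation is
        # applied identically on read, so round-tripping a sorted cohort is exact
        order = np.lexsort(
            (cohort.variants["pos"].to_numpy(), cohort.variants["chrom"].to_numpy())
        )
        for j in order:
            v = cohort.variants.iloc[j]
            gts = "\t".join(_GT_STRINGS[int(g)] for g in cohort.genotypes[:, j])
            info = f"GENE={v['gene']};FUNC={v['func_class']}"
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['variant_id']}\t{v['ref']}\t"
                f"{v['alt']}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )
    cohort.phenotypes[PHENO_COLUMNS].to_csv(pheno_path, sep="\t", index=False)


def _read_vcf(vcf_path: str) -> tuple[np.ndarray, pd.DataFrame, list[str]]:
    try:
        vcf = VCF(vcf_path, gts012=True)
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed headers
        raise ParseError(f"cannot open VCF {vcf_path!r}: {exc}") from exc
    samples = list(vcf.samples)
    geno_cols: list[np.ndarray] = []
    rows: list[dict] = []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise ParseError(
                f"variant {rec.ID or rec.POS} is not biallelic", line=i + 1
            )
        gene = rec.INFO.get("GENE")
        if gene is None:
            log.warning("variant %s lacks GENE annotation; set to 'unknown'", rec.ID)
            gene = "unknown"
        func = rec.INFO.get("FUNC")
        if func is None:
            log.warning("variant %s lacks FUNC annotation; set to 'intergenic'", rec.ID)
            func = "intergenic"
        # gts012: 0/1/2 alt copies, 3 = missing
        g = np.asarray(rec.gt_types, dtype=np.int8)
        g[g == 3] = -1
        geno_cols.append(g)
        rows.append(
            dict(
                variant_id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                ref=rec.REF,
                alt=rec.ALT[0],
                gene=gene,
                func_class=func,
            )
        )
    if not rows:
        raise ParseError(f"VCF {vcf_path!r} contains no variants")
    G = np.stack(geno_cols, axis=1)
    return G, pd.DataFrame(rows), samples


def read_phenotypes(pheno_path: str) -> pd.DataFrame:
    pheno = pd.read_csv(pheno_path, sep="\t", float_precision="round_trip")
    missing = [c for c in PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValidationError(f"phenotype table missing columns: {missing}")
    for col in ("drink", "sex"):
        if (pheno[col] % 1 == 0).all():
            pheno[col] = pheno[col].astype(np.int8)
    return pheno


def read_cohort(vcf_path: str, pheno_path: str) -> Cohort:
    """Load a cohort from VCF + phenotype TSV; sample sets must match exactly."""
    G, variants, samples = _read_vcf(vcf_path)
    pheno = read_phenotypes(pheno_path)
    vcf_set, pheno_set = set(samples), set(pheno["sample_id"])
    if vcf_set != pheno_set:
        only_vcf = sorted(vcf_set - pheno_set)
        only_pheno = sorted(pheno_set - vcf_set)
        parts = []
        if only_vcf:
            parts.append(f"in VCF only: {only_vcf[:5]}")
        if only_pheno:
            parts.append(f"in phenotypes only: {only_pheno[:5]}")
        raise ConsistencyError("sample mismatch between VCF and phenotypes; " + "; ".join(parts))
    pheno = pheno.set_index("sample_id").loc[samples].reset_index()
    return Cohort(genotypes=G, variants=variants, phenotypes=pheno)


def write_assoc(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_assoc(path: str) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t")
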