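"""End-to-end orchestration: simulate (optional) → QC → PCs → dual scans →
diagnostics → dual capture → coding filter → ridge path + stability selection
→ haplotype analysis of the top stable pair → conditional models →
enrichment.

Stages communicate through files under the run directory so each is
independently inspectable and re-runnable; a JSON manifest records per-stage
inputs, outputs and counts, and reruns with an identical config reproduce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .capture import coding_filter, dual_significant, gene_summary
from .conditional import fit_linear, forward_conditional, partial_f_test
from .errors import ValidationError
from .haplotype import (
    em_haplotype_freqs,
    genotype_table,
    haplotype_case_control_or,
    haplotype_trait_contrast,
    ld_stats,
)
from .io import read_cohort, write_assoc, write_cohort
from .qc import QcThresholds, qc_filter
from .ridge import ridge_path, stability_select, standardize_design
from .scan import (
    build_covariates,
    compute_pcs,
    linear_scan,
    logistic_scan,
    scan_diagnostics,
)
from .simulate import default_config, sample_cohort
from .enrich import overrepresentation_test

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated stage thresholds, input paths and toggles for one run."""

    out_dir: str = "ldridge_run"
    seed: int = 0
    # inputs: either a simulation block or explicit files
    simulate: dict | None = None  # keys: n, plus CohortConfig overrides
    vcf: str | None = None
    pheno: str | None = None
    # stage toggles
    run_qc: bool = True
    run_ridge: bool = True
    run_haplotype: bool = True
    run_conditional: bool = True
    run_enrichment: bool = True
    # thresholds
    n_pcs: int = 10
    p_threshold: float = 5e-8
    fdr_threshold: float = 0.05
    capture_mode: str = "p_and_fdr"
    qc: dict = field(default_factory=dict)
    ridge_grid_size: int = 64
    tau: float = 0.2
    magnitude_mult: float = 3.0
    entry_alpha: float = 1e-4
    gene_set_map: str | None = None
    ldsc_window: int = 100

    def __post_init__(self):
        if self.simulate is None and (self.vcf is None or self.pheno is None):
            raise ValidationError("config needs either a 'simulate' block or vcf+pheno")
        for name, lo, hi in [
            ("p_threshold", 0, 1), ("fdr_threshold", 0, 1),
            ("tau", 0, 10), ("entry_alpha", 0, 1),
        ]:
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValidationError(f"{name}={v} outside ({lo}, {hi}]")
        if self.capture_mode not in ("p_and_fdr", "both_fdr"):
            raise ValidationError(f"unknown capture_mode {self.capture_mode!r}")
        if self.ridge_grid_size < 8:
            raise ValidationError("ridge_grid_size must be >= 8")


def load_config(path: str) -> PipelineConfig:
    """Parse and validate a YAML/JSON config; unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError("config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValidationError(f"unknown config key(s): {unknown}")
    cfg = PipelineConfig(**raw)
    for pth in (cfg.vcf, cfg.pheno, cfg.gene_set_map):
        if pth is not None and not Path(pth).exists():
            raise ValidationError(f"referenced path does not exist: {pth}")
    return cfg


def echo_config(cfg: PipelineConfig, out_dir: Path) -> None:
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)


@dataclass
class CohortSummary:
    n_case: int
    n_control: int
    pct_case: float
    pct_control: float
    male_case: int
    male_control: int
    pct_male_case: float
    pct_male_control: float
    trait_mean_case: float
    trait_sd_case: float
    trait_mean_control: float
    trait_sd_control: float
    trait_p: float | None  # Welch; None when one group is empty
    degenerate: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def cohort_summary(pheno: pd.DataFrame, trait: str = "ggt") -> CohortSummary:
    """Table-1-style per-group summary with a Welch trait comparison.

    Percentages are rounded to 2 decimals; with a single group present the
    comparison p is undefined and the summary is flagged degenerate.
    """
    for col in ("drink", "sex", trait):
        if col not in pheno.columns:
            raise ValidationError(f"phenotype table lacks column {col!r}")
    case = pheno[pheno["drink"] == 1]
    ctrl = pheno[pheno["drink"] == 0]
    n, nc, nn = len(pheno), len(case), len(ctrl)
    degenerate = nc == 0 or nn == 0
    if degenerate:
        p = None
    else:
        p = float(
            stats.ttest_ind(case[trait], ctrl[trait], equal_var=False).pvalue
        )

    def pct(a, b):
        return round(100.0 * a / b, 2) if b else float("nan")

    def mstats(df):
        if len(df) == 0:
            return float("nan"), float("nan")
        return float(df[trait].mean()), float(df[trait].std(ddof=1))

    mc, sc = mstats(case)
    mn, sn = mstats(ctrl)
    return CohortSummary(
        n_case=nc, n_control=nn,
        pct_case=pct(nc, n), pct_control=pct(nn, n),
        male_case=int((case["sex"] == 1).sum()),
        male_control=int((ctrl["sex"] == 1).sum()),
        pct_male_case=pct(int((case["sex"] == 1).sum()), nc) if nc else float("nan"),
        pct_male_control=pct(int((ctrl["sex"] == 1).sum()), nn) if nn else float("nan"),
        trait_mean_case=mc, trait_sd_case=sc,
        trait_mean_control=mn, trait_sd_control=sn,
        trait_p=p, degenerate=degenerate,
    )


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _default_gene_sets(genes: list[str]) -> dict[str, set]:
    """Round-robin synthetic categories over the observed gene labels, used
    when no external gene-set map is configured for a simulated run."""
    cats: dict[str, set] = {}
    for i, g in enumerate(sorted(set(genes))):
        cats.setdefault(f"set{i % 3}", set()).add(g)
    return cats


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all enabled stages; returns (and writes) the artifact manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    echo_config(cfg, out)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    runlog = open(out / "run.log", "w")

    def note(stage, **kv):
        manifest["stages"][stage] = kv
        runlog.write(f"stage={stage} " + " ".join(f"{k}={v}" for k, v in kv.items() if not isinstance(v, (list, dict))) + "\n")
        runlog.flush()

    try:
        # --- input / simulate ------------------------------------------------
        if cfg.simulate is not None:
            sim = dict(cfg.simulate)
            n = int(sim.pop("n", 2000))
            cohort = sample_cohort(default_config(n=n, seed=cfg.seed, **sim))
            vcf_p, pheno_p = str(out / "cohort.vcf"), str(out / "cohort.tsv")
            write_cohort(cohort, vcf_p, pheno_p)
            cohort.variants.to_csv(out / "truth_manifest.tsv", sep="\t", index=False)
            note("simulate", n=cohort.n, variants=cohort.n_variants,
                 vcf=Path(vcf_p).name, pheno=Path(pheno_p).name)
        else:
            try:
                cohort = read_cohort(cfg.vcf, cfg.pheno)
            except Exception as exc:
                raise StageFailure("input", exc)
            note("input", n=cohort.n, variants=cohort.n_variants)

        summ = cohort_summary(cohort.phenotypes)
        with open(out / "cohort_summary.json", "w") as fh:
            json.dump(summ.to_dict(), fh, indent=2)
        note("summary", n_case=summ.n_case, n_control=summ.n_control,
             pct_case=summ.pct_case)

        # --- QC --------------------------------------------------------------
        if cfg.run_qc:
            try:
                thr = QcThresholds(**cfg.qc)
                n_in, m_in = cohort.n, cohort.n_variants
                cohort, report = qc_filter(cohort, thr)
                report.excluded_variants.to_csv(
                    out / "qc_excluded_variants.tsv", sep="\t", index=False)
                report.excluded_samples.to_csv(
                    out / "qc_excluded_samples.tsv", sep="\t", index=False)
                note("qc", samples_in=n_in, samples_out=cohort.n,
                     variants_in=m_in, variants_out=cohort.n_variants)
            except Exception as exc:
                raise StageFailure("qc", exc)
        else:
            note("qc", skipped=True)

        # --- PCs and scans ---------------------------------------------------
        try:
            k = min(cfg.n_pcs, cohort.n - 1, cohort.n_variants - 1)
            C = build_covariates(cohort, n_pcs=k)
            drink = logistic_scan(cohort, C)
            ggt = linear_scan(cohort, C)
            write_assoc(drink, str(out / "assoc_drink.tsv"))
            write_assoc(ggt, str(out / "assoc_ggt.tsv"))
            diag = scan_diagnostics(drink, cohort.genotypes,
                                    window=cfg.ldsc_window)
            with open(out / "diagnostics.json", "w") as fh:
                json.dump(diag.to_dict(), fh, indent=2)
            note("scan", variants=len(drink), pcs=C.shape[1] - 2,
                 lambda_gc=round(diag.lambda_gc, 4))
        except Exception as exc:
            raise StageFailure("scan", exc)

        # --- capture + coding filter ----------------------------------------
        try:
            hits = dual_significant(drink, ggt, cfg.p_threshold,
                                    cfg.fdr_threshold, mode=cfg.capture_mode)
            ann = cohort.variants.set_index("variant_id")[["gene", "func_class"]]
            hits = hits.join(ann, on="variant_id")
            hits.to_csv(out / "dual_hits.tsv", sep="\t", index=False)
            coding = coding_filter(hits)
            coding.to_csv(out / "coding_hits.tsv", sep="\t", index=False)
            if len(coding):
                gene_summary(coding).to_csv(out / "gene_summary.tsv",
                                            sep="\t", index=False)
            note("capture", dual_hits=len(hits), coding_hits=len(coding))
        except Exception as exc:
            raise StageFailure("capture", exc)

        # --- ridge path + stability selection --------------------------------
        selected: list[str] = []
        if cfg.run_ridge and len(coding) >= 2:
            try:
                ids = list(coding["variant_id"])
                cols = [cohort.variant_index(v) for v in ids]
                design = standardize_design(
                    cohort.genotypes[:, cols].astype(float),
                    cohort.phenotypes["drink"].to_numpy(float), ids)
                path = ridge_path(design)
                pd.DataFrame(path.coefs, index=path.grid, columns=path.ids)\
                    .rename_axis("lambda").to_csv(out / "ridge_path.tsv", sep="\t")
                selected = stability_select(path, cfg.tau, cfg.magnitude_mult)
                with open(out / "ridge_selection.json", "w") as fh:
                    json.dump({"selected": selected, "tau": cfg.tau,
                               "magnitude_mult": cfg.magnitude_mult}, fh, indent=2)
                note("ridge", predictors=len(ids), selected=len(selected))
            except Exception as exc:
                raise StageFailure("ridge", exc)
        else:
            note("ridge", skipped=True)

        # --- haplotype analysis on the top stable pair -----------------------
        if cfg.run_haplotype:
            pair = selected[:2]
            if len(pair) < 2 and len(coding) >= 2:
                pair = list(coding["variant_id"][:2])
            if len(pair) == 2:
                try:
                    ja, jb = (cohort.variant_index(v) for v in pair)
                    ga, gb = cohort.genotypes[:, ja], cohort.genotypes[:, jb]
                    fit = em_haplotype_freqs(genotype_table(ga, gb))
                    ld = ld_stats(fit)
                    eff = haplotype_case_control_or(
                        ga, gb, cohort.phenotypes["drink"].to_numpy(bool))
                    try:
                        contrast = haplotype_trait_contrast(
                            ga, gb, cohort.phenotypes["ggt"].to_numpy(float))
                        contrast_d = dataclasses.asdict(contrast)
                    except Exception as e:  # empty exclusive group is data-dependent
                        contrast_d = {"error": str(e)}
                    with open(out / "haplotype.json", "w") as fh:
                        json.dump({
                            "loci": pair,
                            "freqs": list(map(float, fit.freqs)),
                            "converged": fit.converged,
                            "ld": dataclasses.asdict(ld),
                            "odds_ratio": dataclasses.asdict(eff),
                            "ggt_contrast": contrast_d,
                        }, fh, indent=2)
                    note("haplotype", loci=",".join(pair), r2=round(ld.r2, 4))
                except Exception as exc:
                    raise StageFailure("haplotype", exc)
            else:
                note("haplotype", skipped=True)
        else:
            note("haplotype", skipped=True)

        # --- conditional models ---------------------------------------------
        if cfg.run_conditional and len(coding) >= 1:
            try:
                cand_ids = list(coding["variant_id"])
                cols = [cohort.variant_index(v) for v in cand_ids]
                Gc = cohort.genotypes[:, cols].astype(float)
                y = np.log(cohort.phenotypes["ggt"].to_numpy(float))
                steps = forward_conditional(y, C, Gc, cand_ids,
                                            alpha=cfg.entry_alpha)
                report = {"entry_alpha": cfg.entry_alpha,
                          "steps": [dataclasses.asdict(s) for s in steps]}
                if len(steps) >= 2:
                    ids2 = [s.variant_id for s in steps[:2]]
                    cols2 = [cohort.variant_index(v) for v in ids2]
                    red = fit_linear(y, C, cohort.genotypes[:, cols2[:1]].astype(float),
                                     ids2[:1])
                    full = fit_linear(y, C, cohort.genotypes[:, cols2].astype(float),
                                      ids2)
                    cmpr = partial_f_test(red, full)
                    report["two_snp_vs_one"] = dataclasses.asdict(cmpr)
                with open(out / "conditional.json", "w") as fh:
                    json.dump(report, fh, indent=2)
                note("conditional", signals=len(steps))
            except Exception as exc:
                raise StageFailure("conditional", exc)
        else:
            note("conditional", skipped=True)

        # --- enrichment ------------------------------------------------------
        if cfg.run_enrichment:
            try:
                genes = sorted(set(cohort.variants["gene"]) - {"unknown"})
                study = sorted(set(coding["gene"]) - {"unknown"}) if len(coding) else []
                if cfg.gene_set_map:
                    from .enrich import read_gene_set_tsv
                    cats = read_gene_set_tsv(cfg.gene_set_map)
                else:
                    cats = _default_gene_sets(genes)
                if study and genes:
                    table = overrepresentation_test(study, cats, genes)
                    table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                    note("enrichment", categories=len(table),
                         significant=int(table["significant"].sum()))
                else:
                    note("enrichment", skipped=True, reason="no study genes")
            except Exception as exc:
                raise StageFailure("enrichment", exc)
        else:
            note("enrichment", skipped=True)
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        runlog.close()
    return manifest
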