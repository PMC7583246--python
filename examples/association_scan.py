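"""Dual-trait association scan with QC and inflation diagnostics.

Simulates a cohort with a planted dual-trait causal variant, runs QC, the
logistic (drinking) and linear (log γ-GT) scans with age/sex/PC covariates,
and prints the top hits plus λ_GC.
"""

import ldridge as lr

cfg = lr.default_config(n=3000, seed=2)
cfg.drink_effects = {"rsA": 1.0}
cfg.ggt_effects = {"rsA": 0.25}
cfg.n_null = 800
cohort = lr.sample_cohort(cfg)

cohort, report = lr.qc_filter(cohort)
print(f"QC: {len(report.excluded_variants)} variants, "
      f"{len(report.excluded_samples)} samples excluded")

C = lr.build_covariates(cohort, n_pcs=4)
drink = lr.logistic_scan(cohort, C)
ggt = lr.linear_scan(cohort, C)

top = drink.nsmallest(3, "p")[["variant_id", "beta", "or", "p", "q"]]
print("top drinking hits:\n", top.to_string(index=False))
diag = lr.scan_diagnostics(drink)
print(f"lambda_GC = {diag.lambda_gc:.4f}")
# The planted variant rsA tops both scans (OR = exp(beta) per alt copy);
# lambda_GC near 1 plus a few real hits says the scan is calibrated, not
# inflated: significance is concentrated, not genome-wide.

hits = lr.dual_significant(drink, ggt, p_threshold=1e-4, fdr_threshold=0.05)
print(f"dual-trait capture: {len(hits)} variant(s):",
      ", ".join(hits['variant_id']))
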