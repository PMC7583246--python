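"""Two-locus haplotype analysis: EM frequencies, LD, odds ratio, γ-GT contrast.

Simulates the focal causal pair with a drinking effect, estimates haplotype
frequencies by EM from unphased genotypes, and prints D/D'/r², the
case/control odds ratio of the coupling haplotype, and the γ-GT contrast
between exclusive carrier groups.
"""

import ldridge as lr

cfg = lr.default_config(n=4000, seed=4)
cfg.drink_effects = {"rsA": -0.9, "rsB": -0.4}  # alt (minor) alleles protective
cfg.ggt_effects = {"rsA": -0.15}
cohort = lr.sample_cohort(cfg)

ja, jb = cohort.variant_index("rsA"), cohort.variant_index("rsB")
ga, gb = cohort.genotypes[:, ja], cohort.genotypes[:, jb]

fit = lr.em_haplotype_freqs(lr.genotype_table(ga, gb))
print("haplotype freqs (ref-ref, ref-alt, alt-ref, alt-alt):",
      [round(f, 4) for f in fit.freqs], "converged:", fit.converged)
ld = lr.ld_stats(fit)
print(f"D = {ld.D:.4f}, D' = {ld.D_prime:.3f}, r2 = {ld.r2:.4f}")

case = cohort.phenotypes["drink"].to_numpy(bool)
eff = lr.haplotype_case_control_or(ga, gb, case, target=(0, 0))
print(f"ref-ref (risk-coupling) haplotype OR = {eff.odds_ratio:.2f} "
      f"(95% CI {eff.ci_low:.2f}-{eff.ci_high:.2f})")

contrast = lr.haplotype_trait_contrast(
    ga, gb, cohort.phenotypes["ggt"].to_numpy(float),
    hap_a=(0, 0), hap_b=(1, 1),
)
print(f"gamma-GT, ref-ref carriers minus alt-alt carriers: "
      f"{contrast.difference:.2f} +/- {contrast.se:.2f} U/L (p = {contrast.p:.3g})")
# r2 ~ 0.98 reflects the designed coupling; the OR > 1 for the risk haplotype
# mirrors the planted protective effect of the alt alleles, and the gamma-GT
# difference tracks the planted log-scale shift.
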