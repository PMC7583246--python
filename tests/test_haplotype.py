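"""Two-locus EM, LD statistics, haplotype odds ratios and trait contrasts."""

import numpy as np
import pytest

import ldridge as lr
from ldridge.errors import (
    DegenerateVarianceError,
    UndefinedLDError,
    ValidationError,
)
from ldridge.haplotype import (
    _cell_probs,
    em_haplotype_freqs,
    genotype_table,
)


def _sample_two_locus(freqs, n, rng):
    """Genotypes at two loci from random union of haplotypes with the given
    (h00, h01, h10, h11) frequencies."""
    haps = rng.choice(4, size=(n, 2), p=np.asarray(freqs))
    a = (haps >= 2).sum(axis=1)  # alt allele at locus A = haplotypes 2, 3
    b = (haps % 2).sum(axis=1)  # alt allele at locus B = haplotypes 1, 3
    return a, b


def loglik(h, table):
    probs = _cell_probs(np.asarray(h))
    mask = table > 0
    return float((table[mask] * np.log(probs[mask])).sum())


class TestEmHaplotypeFreqs:
    def test_phase_unambiguous_counts(self):
        # only double-homozygote cells: phase certain, coupling freq = allele freq
        table = np.zeros((3, 3))
        table[0, 0] = 60
        table[2, 2] = 40
        fit = em_haplotype_freqs(table)
        assert fit.freqs[3] == pytest.approx(0.4, abs=1e-9)
        assert lr.ld_stats(fit).r2 == pytest.approx(1.0, abs=1e-9)

    def test_equilibrium_counts_give_product_freqs(self, rng):
        a, b = _sample_two_locus([0.36, 0.24, 0.24, 0.16], 20_000, rng)
        fit = em_haplotype_freqs(genotype_table(a, b))
        pa = fit.freqs[2] + fit.freqs[3]
        pb = fit.freqs[1] + fit.freqs[3]
        assert fit.freqs[3] == pytest.approx(pa * pb, abs=0.01)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_profile_grid_search_mle(self, seed):
        # EM preserves the observed allele frequencies, so the likelihood has a
        # single free parameter h11 within its Frechet bounds; a fine grid over
        # it is an independent maximizer.
        rng = np.random.default_rng(seed)
        table = rng.integers(0, 30, (3, 3)).astype(float)
        if table.sum() == 0:
            table[1, 1] = 5
        fit = em_haplotype_freqs(table)
        n = table.sum()
        ga = np.arange(3)[:, None] * np.ones(3)
        gb = np.ones(3)[:, None] * np.arange(3)
        pa = (table * ga).sum() / (2 * n)
        pb = (table * gb).sum() / (2 * n)
        if min(pa, 1 - pa, pb, 1 - pb) == 0:
            return  # monomorphic: nothing to optimize
        lo = max(0.0, pa + pb - 1.0)
        hi = min(pa, pb)
        best = -np.inf
        for h11 in np.linspace(lo, hi, 2001):
            h = np.array(
                [1 - pa - pb + h11, pb - h11, pa - h11, h11]
            )
            if np.any(h < -1e-12):
                continue
            ll = loglik(np.clip(h, 0, None), table)
            best = max(best, ll)
        assert fit.loglik >= best - 1e-6

    def test_loglik_monotone_over_iterations(self, rng):
        for _ in range(100):
            table = rng.integers(0, 25, (3, 3)).astype(float)
            if table.sum() == 0:
                continue
            fit = em_haplotype_freqs(table)
            diffs = np.diff(fit.loglik_trace)
            assert np.all(diffs >= -1e-9)

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            em_haplotype_freqs(np.zeros((3, 3)))


class TestLdStats:
    def test_perfect_coupling(self):
        s = lr.ld_stats(np.array([0.5, 0.0, 0.0, 0.5]))
        assert s.D == pytest.approx(0.25)
        assert s.D_prime == pytest.approx(1.0)
        assert s.r2 == pytest.approx(1.0)

    def test_equilibrium(self):
        s = lr.ld_stats(np.array([0.25, 0.25, 0.25, 0.25]))
        assert s.D == pytest.approx(0.0)
        assert s.r2 == pytest.approx(0.0)

    def test_focal_pair_closed_form(self, focal_freqs):
        s = lr.ld_stats(np.array(focal_freqs))
        assert s.r2 == pytest.approx(0.9797, abs=1e-4)
        assert s.r2 == pytest.approx(
            s.D**2 / (0.29 * 0.71 * 0.29 * 0.71), abs=1e-12
        )

    def test_monomorphic_rejected(self):
        with pytest.raises(UndefinedLDError):
            lr.ld_stats(np.array([1.0, 0.0, 0.0, 0.0]))

    def test_em_ld_converges_to_pool_truth(self, focal_freqs):
        rng = np.random.default_rng(5)
        a, b = _sample_two_locus(focal_freqs, 5000, rng)
        fit = em_haplotype_freqs(genotype_table(a, b))
        truth = lr.ld_stats(np.array(focal_freqs))
        est = lr.ld_stats(fit)
        assert est.r2 == pytest.approx(truth.r2, abs=0.01)
        assert est.D == pytest.approx(truth.D, abs=0.01)


def _true_hap_or(freqs, per_copy_or, base_p, target=3):
    """Exact case/control haplotype odds ratio implied by the generative
    model: per-individual case odds multiplied by per_copy_or per target
    haplotype copy; a random haplotype drawn from a random individual."""
    freqs = np.asarray(freqs)
    joint = {}  # (copies of target) -> prob
    for i in range(4):
        for j in range(4):
            c = (i == target) + (j == target)
            joint[c] = joint.get(c, 0.0) + freqs[i] * freqs[j]
    base_odds = base_p / (1 - base_p)
    # P(case, random hap is target), P(case, other), same for controls
    tc = to = cc = co = 0.0
    for c, pr in joint.items():
        p_case = base_odds * per_copy_or**c / (1 + base_odds * per_copy_or**c)
        share_t = c / 2.0
        tc += pr * p_case * share_t
        to += pr * p_case * (1 - share_t)
        cc += pr * (1 - p_case) * share_t
        co += pr * (1 - p_case) * (1 - share_t)
    return (tc / to) / (cc / co)


class TestHaplotypeCaseControlOr:
    def test_no_association_gives_unit_or(self, rng):
        a, b = _sample_two_locus([0.4, 0.1, 0.1, 0.4], 400, rng)
        a2, b2 = np.concatenate([a, a]), np.concatenate([b, b])
        case = np.concatenate([np.ones(400, bool), np.zeros(400, bool)])
        eff = lr.haplotype_case_control_or(a2, b2, case, target=(1, 1))
        assert eff.odds_ratio == pytest.approx(1.0, abs=1e-9)

    def test_haldane_correction_flagged(self):
        # tiny monomorphic-ish groups force an expected cell below 0.5
        ga = np.array([0, 0, 0, 2, 2, 2])
        gb = np.array([0, 0, 0, 2, 2, 2])
        case = np.array([True, True, True, False, False, False])
        eff = lr.haplotype_case_control_or(ga, gb, case, target=(1, 1))
        assert eff.corrected

    def test_coverage_of_planted_or(self, focal_freqs):
        rng = np.random.default_rng(77)
        reps, n, per_copy = 200, 4000, 2.0
        truth = _true_hap_or(focal_freqs, per_copy, base_p=0.15)
        hit = 0
        for _ in range(reps):
            hapc = rng.choice(4, size=(n, 2), p=np.asarray(focal_freqs))
            copies = (hapc == 3).sum(axis=1)
            odds = 0.15 / 0.85 * per_copy**copies
            case = rng.random(n) < odds / (1 + odds)
            a = (hapc >= 2).sum(axis=1)
            b = (hapc % 2).sum(axis=1)
            eff = lr.haplotype_case_control_or(a, b, case, target=(1, 1))
            if eff.ci_low <= truth <= eff.ci_high:
                hit += 1
        assert hit / reps >= 0.93

    def test_empty_group_rejected(self, rng):
        a, b = _sample_two_locus([0.4, 0.1, 0.1, 0.4], 50, rng)
        with pytest.raises(ValidationError):
            lr.haplotype_case_control_or(a, b, np.ones(50, bool))

    def test_invariant_to_allele_relabelling(self, rng):
        a, b = _sample_two_locus([0.5, 0.1, 0.1, 0.3], 600, rng)
        case = rng.random(600) < 0.3
        eff = lr.haplotype_case_control_or(a, b, case, target=(1, 1))
        # flip both loci's allele coding and relabel the target consistently
        eff_flip = lr.haplotype_case_control_or(2 - a, 2 - b, case, target=(0, 0))
        assert eff.odds_ratio == pytest.approx(eff_flip.odds_ratio, abs=1e-9)


class TestHaplotypeTraitContrast:
    def test_recovers_planted_shift(self, focal_freqs):
        rng = np.random.default_rng(88)
        reps, n, shift = 100, 2000, 5.0
        ok = 0
        for _ in range(reps):
            hapc = rng.choice(4, size=(n, 2), p=np.asarray(focal_freqs))
            a = (hapc >= 2).sum(axis=1)
            b = (hapc % 2).sum(axis=1)
            carrier_a = (hapc == 0).any(axis=1)  # ref-ref haplotype
            trait = rng.normal(30, 8, n) + shift * carrier_a
            c = lr.haplotype_trait_contrast(a, b, trait, hap_a=(0, 0), hap_b=(1, 1))
            if abs(c.difference - shift) < 2 * c.se:
                ok += 1
        assert ok / reps >= 0.90

    def test_null_calibration(self, focal_freqs):
        rng = np.random.default_rng(89)
        reps = 200
        rejections = 0
        for _ in range(reps):
            hapc = rng.choice(4, size=(1000, 2), p=np.asarray(focal_freqs))
            a = (hapc >= 2).sum(axis=1)
            b = (hapc % 2).sum(axis=1)
            trait = rng.normal(30, 8, 1000)
            c = lr.haplotype_trait_contrast(a, b, trait, hap_a=(0, 0), hap_b=(1, 1))
            rejections += c.p < 0.05
        assert abs(rejections / reps - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_constant_trait_rejected(self, rng, focal_freqs):
        a, b = _sample_two_locus(focal_freqs, 300, rng)
        with pytest.raises(DegenerateVarianceError):
            lr.haplotype_trait_contrast(
                a, b, np.full(300, 25.0), hap_a=(0, 0), hap_b=(1, 1)
            )
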