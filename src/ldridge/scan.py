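"""Per-variant association scans and inflation diagnostics.

The binary drinking trait is tested with per-variant multivariate logistic
regression (additive genotype coding, covariates age, sex and the top
principal components; Wald p-values from IRLS maximum likelihood).  The
quantitative γ-GT trait is tested with per-variant ordinary least squares on
the log scale by default.  Diagnostics: Benjamini–Hochberg q-values, the
genomic inflation factor λ_GC, in-sample window LD scores with a simplified
(unweighted, in-sample) LD-score-regression intercept, and Q–Q coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import (
    CollinearityError,
    DegenerateDesignError,
    ValidationError,
)
from .simulate import Cohort

log = logging.getLogger(__name__)

# median of the chi-square distribution with 1 df, used by lambda_GC
CHI2_1_MEDIAN = 0.4549364


@dataclass
class ScanDiagnostics:
    lambda_gc: float
    ldsc_intercept: float | None = None
    ldsc_slope: float | None = None
    ldsc_intercept_se: float | None = None
    ldsc_slope_se: float | None = None

    def to_dict(self) -> dict:
        return {
            "lambda_gc": self.lambda_gc,
            "ldsc_intercept": self.ldsc_intercept,
            "ldsc_slope": self.ldsc_slope,
            "ldsc_intercept_se": self.ldsc_intercept_se,
            "ldsc_slope_se": self.ldsc_slope_se,
            "ldsc_note": "simplified: unweighted OLS on in-sample window LD scores",
        }


def standardize_genotypes(G: np.ndarray, variant_ids=None) -> np.ndarray:
    """Column-standardize a genotype matrix; monomorphic columns are an error."""
    G = np.asarray(G, dtype=float)
    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = (
            [variant_ids[j] for j in dead[:5]]
            if variant_ids is not None
            else list(dead[:5])
        )
        raise DegenerateDesignError(f"monomorphic variant(s): {names}")
    return (G - mu) / sd


def compute_pcs(G: np.ndarray, k: int = 10, variant_ids=None) -> np.ndarray:
    """Top-k principal-component scores of the column-standardized genotypes.

    Components are ordered by decreasing explained variance; each component's
    sign is fixed so its largest-magnitude loading is positive.  Wide matrices
    use a seeded randomized solver.
    """
    Z = standardize_genotypes(G, variant_ids)
    n, m = Z.shape
    if k > min(n, m):
        raise ValidationError(f"k={k} exceeds rank bound min(n, m)={min(n, m)}")
    solver = "full" if min(n, m) <= 500 else "randomized"
    pca = PCA(n_components=k, svd_solver=solver, random_state=0)
    scores = pca.fit_transform(Z)
    for j in range(k):
        i = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, i] < 0:
            scores[:, j] *= -1.0
    return scores


def _irls_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 100) -> tuple[np.ndarray, np.ndarray, bool, bool]:
    """Newton/IRLS fit of a logistic model.

    Returns (beta, se, converged, separated).  Convergence: max |score| < tol.
    Separation heuristic: fitted probabilities pinned to 0/1 with diverging
    coefficients.
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    separated = False
    for _ in range(max_iter):
        eta = X @ beta
        eta = np.clip(eta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        XtWX = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(XtWX, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if np.max(np.abs(beta)) > 1e3:
            separated = True
            break
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    XtWX = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(XtWX)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        separated = True
    return beta, se, converged, separated


def ld_prune(G: np.ndarray, r2_threshold: float = 0.2,
             window: int = 100) -> np.ndarray:
    """Greedy LD pruning: scan left to right, keep a variant only if its r²
    with every already-kept variant in the trailing window stays below the
    threshold.  Returns the kept column indices."""
    Z = standardize_genotypes(G)
    n, m = Z.shape
    kept: list[int] = []
    # circular buffer of the last `window` kept columns (contiguous slices
    # keep the inner product BLAS-fast)
    buf = np.empty((n, min(window, m)), order="F")
    buf_idx = np.full(min(window, m), -(window + 1), dtype=int)
    pos = 0
    filled = 0
    for j in range(m):
        if filled:
            r = buf[:, :filled].T @ Z[:, j] / n
            near = j - buf_idx[:filled] <= window
            if near.any() and np.max(r[near] ** 2) >= r2_threshold:
                continue
        kept.append(j)
        buf[:, pos] = Z[:, j]
        buf_idx[pos] = j
        pos = (pos + 1) % buf.shape[1]
        filled = min(filled + 1, buf.shape[1])
    return np.asarray(kept, dtype=int)


def build_covariates(cohort: Cohort, n_pcs: int = 10,
                     pcs: np.ndarray | None = None,
                     prune_r2: float | None = 0.2) -> np.ndarray:
    """Covariate matrix [age, sex, PC1..PCk] for the scans.

    PCs default to being computed on an LD-pruned variant subset: without
    pruning, a tight LD block dominates the top components at desk scale and
    the PC adjustment absorbs the very signal being scanned for.
    """
    cols = [cohort.phenotypes["age"].to_numpy(float),
            cohort.phenotypes["sex"].to_numpy(float)]
    if n_pcs > 0:
        if pcs is None:
            G = cohort.genotypes
            if prune_r2 is not None:
                keep = ld_prune(G, r2_threshold=prune_r2)
                G = G[:, keep]
            k = min(n_pcs, G.shape[1] - 1, G.shape[0] - 1)
            pcs = compute_pcs(G, k)
        cols.extend(pcs[:, j] for j in range(pcs.shape[1]))
    return np.column_stack(cols)


def logistic_scan(cohort: Cohort, covariates: np.ndarray,
                  outcome: str = "drink",
                  p_method: str = "wald") -> pd.DataFrame:
    """Per-variant logistic regression of the binary outcome on genotype + covariates.

    One row per variant with beta (log-odds per alt copy), SE, OR, p and BH
    q.  ``p_method`` is "wald" (default, standard GWAS practice) or "lr" for
    the likelihood-ratio test against the covariate-only null.  Perfect
    separation or non-convergence is flagged and p set missing.
    """
    if p_method not in ("wald", "lr"):
        raise ValidationError(f"unknown p_method {p_method!r}")
    y = cohort.phenotypes[outcome].to_numpy(float)
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise ValidationError(
            f"outcome {outcome!r} must be binary with both classes present; "
            f"saw values {classes}"
        )
    return _scan(cohort, covariates, y, model="logistic", test="drink",
                 p_method=p_method)


def _logistic_loglik(X, y, beta) -> float:
    eta = np.clip(X @ beta, -35, 35)
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def linear_scan(cohort: Cohort, covariates: np.ndarray, trait: str = "ggt",
                log_transform: bool = True) -> pd.DataFrame:
    """Per-variant OLS of the quantitative trait (log scale by default)."""
    y = cohort.phenotypes[trait].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValidationError(f"trait {trait!r} contains non-finite values")
    if log_transform:
        if np.any(y <= 0):
            raise ValidationError("log transform requires positive trait values")
        y = np.log(y)
    return _scan(cohort, covariates, y, model="linear", test=trait)


def _scan(cohort: Cohort, C: np.ndarray, y: np.ndarray, model: str,
          test: str, p_method: str = "wald") -> pd.DataFrame:
    G = cohort.genotypes
    n, m = G.shape
    if C.shape[0] != n:
        raise ValidationError("covariate rows do not match cohort size")
    const_cols = np.flatnonzero(G.std(axis=0) == 0)
    if const_cols.size:
        names = [cohort.variants["variant_id"].iloc[j] for j in const_cols[:5]]
        raise DegenerateDesignError(f"constant genotype column(s): {names}")

    rows = []
    if model == "linear":
        # Frisch–Waugh–Lovell: residualize y and each genotype on [1, C] once
        Q, _ = np.linalg.qr(np.column_stack([np.ones(n), C]))
        y_r = y - Q @ (Q.T @ y)
        df_resid = n - C.shape[1] - 2  # intercept + covariates + genotype
        for j in range(m):
            g = G[:, j].astype(float)
            g_r = g - Q @ (Q.T @ g)
            gg = g_r @ g_r
            if gg <= 1e-12:
                rows.append((np.nan, np.nan, np.nan, False, True))
                continue
            beta = (g_r @ y_r) / gg
            resid = y_r - beta * g_r
            sigma2 = (resid @ resid) / df_resid
            se = np.sqrt(sigma2 / gg)
            t = beta / se
            p = 2.0 * stats.t.sf(abs(t), df_resid)
            rows.append((beta, se, p, True, False))
    else:
        ll_null = None
        if p_method == "lr":
            null_design = np.column_stack([np.ones(n), C])
            beta0, _, _, _ = _irls_logistic(null_design, y)
            ll_null = _logistic_loglik(null_design, y, beta0)
        base = np.column_stack([np.ones(n), np.zeros(n), C])
        for j in range(m):
            base[:, 1] = G[:, j]
            beta, se, conv, sep = _irls_logistic(base, y)
            if sep or not conv or not np.isfinite(se[1]):
                if sep:
                    warnings.warn(
                        f"possible separation at variant "
                        f"{cohort.variants['variant_id'].iloc[j]}; p set missing"
                    )
                p = np.nan if sep else 2.0 * stats.norm.sf(abs(beta[1] / se[1]))
                rows.append((beta[1], se[1], p, conv, sep))
                continue
            if p_method == "lr":
                lr_stat = 2.0 * (_logistic_loglik(base, y, beta) - ll_null)
                p = float(stats.chi2.sf(max(lr_stat, 0.0), df=1))
            else:
                z = beta[1] / se[1]
                p = 2.0 * stats.norm.sf(abs(z))
            rows.append((beta[1], se[1], p, True, False))

    out = pd.DataFrame(rows, columns=["beta", "se", "p", "converged", "flagged"])
    out.insert(0, "variant_id", cohort.variants["variant_id"].to_numpy())
    out.insert(1, "chrom", cohort.variants["chrom"].to_numpy())
    out.insert(2, "pos", cohort.variants["pos"].to_numpy())
    out.insert(3, "effect_allele", cohort.variants["alt"].to_numpy())
    if model == "logistic":
        out["or"] = np.exp(out["beta"])
    ok = out["p"].notna()
    q = np.full(m, np.nan)
    if ok.any():
        q[ok.to_numpy()] = bh_fdr(out.loc[ok, "p"].to_numpy())
    out["q"] = q
    out["n"] = len(y)
    out["test"] = test
    return out


def bh_fdr(p) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (order-preserving, q >= p)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def genomic_lambda(p=None, chi2=None) -> float:
    """Genomic inflation factor: median 1-df chi-square over the null median."""
    if chi2 is None:
        if p is None:
            raise ValidationError("provide p-values or chi-square statistics")
        p = np.asarray(p, dtype=float)
        if p.size == 0:
            raise ValidationError("empty input")
        chi2 = stats.chi2.isf(p, df=1)
    chi2 = np.asarray(chi2, dtype=float)
    if chi2.size == 0:
        raise ValidationError("empty input")
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def ld_scores(G: np.ndarray, window: int = 100, adjusted: bool = True) -> np.ndarray:
    """In-sample LD score per variant: 1 + sum of squared sample correlations
    with the ``window`` nearest variants on each side.

    With ``adjusted`` (default) each r² is replaced by the unbiased estimate
    r² − (1 − r²)/(n − 2), removing the upward O(window/n) bias that in-sample
    correlations would otherwise add to every score.
    """
    Z = standardize_genotypes(G)
    n, m = Z.shape
    ell = np.ones(m)
    chunk = max(1, min(512, m))
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        wlo, whi = max(0, lo - window), min(m, hi + window)
        R = (Z[:, lo:hi].T @ Z[:, wlo:whi]) / n
        R2 = R * R
        if adjusted:
            R2 = R2 - (1.0 - R2) / (n - 2)
        for j in range(lo, hi):
            a = max(wlo, j - window) - wlo
            b = min(m, j + window + 1) - wlo
            ell[j] += R2[j - lo, a:b].sum() - R2[j - lo, j - wlo]
    return ell


def ldsc_intercept(chi2, ell, sample_size: int | None = None):
    """Simplified LD-score regression: unweighted OLS of chi-square on LD score.

    Returns (intercept, slope, intercept_se, slope_se).  This is a desk-scale
    diagnostic analog of LD-score regression — unweighted, with in-sample
    window LD scores — not the reference-panel tool.
    """
    chi2 = np.asarray(chi2, dtype=float)
    ell = np.asarray(ell, dtype=float)
    if chi2.shape != ell.shape or chi2.size < 10:
        raise ValidationError("need equal-length vectors of length >= 10")
    sxx = np.var(ell)
    if sxx <= 1e-14:
        raise CollinearityError("LD scores are constant; intercept unidentified")
    mx, my = ell.mean(), chi2.mean()
    slope = float(((ell - mx) @ (chi2 - my)) / ((ell - mx) @ (ell - mx)))
    intercept = float(my - slope * mx)
    resid = chi2 - intercept - slope * ell
    s2 = (resid @ resid) / (chi2.size - 2)
    sxx_total = (ell - mx) @ (ell - mx)
    slope_se = float(np.sqrt(s2 / sxx_total))
    intercept_se = float(np.sqrt(s2 * (1.0 / chi2.size + mx**2 / sxx_total)))
    return intercept, slope, intercept_se, slope_se


def qq_points(p) -> tuple[np.ndarray, np.ndarray]:
    """(expected, observed) −log10 p coordinates for a Q–Q plot, both ascending."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty input")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("zero p-values clipped to the smallest positive float")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    m = p.size
    expected = -np.log10(np.arange(m, 0, -1) / (m + 1))
    observed = -np.log10(np.sort(p)[::-1])
    return expected, observed


def wald_chi2(table: pd.DataFrame) -> np.ndarray:
    """1-df Wald chi-square statistics (beta/se)² from a scan table."""
    z = table["beta"].to_numpy() / table["se"].to_numpy()
    return z * z


def scan_diagnostics(table: pd.DataFrame, G: np.ndarray | None = None,
                     window: int = 100) -> ScanDiagnostics:
    """λ_GC plus, when genotypes are supplied, the simplified LDSC fit."""
    chi2 = wald_chi2(table)
    ok = np.isfinite(chi2)
    lam = genomic_lambda(chi2=chi2[ok])
    if G is None:
        return ScanDiagnostics(lambda_gc=lam)
    ell = ld_scores(G, window=window)
    icpt, slope, icpt_se, slope_se = ldsc_intercept(chi2[ok], ell[ok])
    return ScanDiagnostics(lam, icpt, slope, icpt_se, slope_se)
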