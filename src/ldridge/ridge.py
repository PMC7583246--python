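"""Ridge coefficient paths and stability selection for LD-dense SNP blocks.

Among a set of strongly correlated significant SNPs, ordinary least squares
is unusable (hypercollinearity), but the ridge estimator

    beta_hat(lambda) = argmin ||y - X beta||_2^2 + lambda ||beta||_2^2
                     = (X'X + lambda I)^{-1} X'y

exists for every lambda > 0.  Tracing beta_hat over a wide lambda grid (the
classical ridge trace) separates two behaviours: coefficients of redundant
LD proxies collapse quickly toward zero, while genuinely informative
predictors keep a large, nearly constant coefficient across the grid.  The
selection rule here quantifies that: a predictor is selected when its
coefficient path is flat (relative range <= tau) and large (mean |beta| >=
mult x the median across predictors).

The outcome is the centered 0/1 status with squared-error loss; predictors
are standardized, and centering X and y makes the (penalized) intercept
exactly zero.  As lambda -> 0 the path approaches OLS on full-rank designs;
as lambda -> infinity all coefficients approach 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDesignError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class RidgeDesign:
    """Standardized predictors (columns mean 0, SD 1) and centered outcome."""

    X: np.ndarray
    y: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    y_mean: float
    ids: list[str]
    _svd: tuple | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def svd(self):
        """Economy SVD of X, cached: X = U diag(d) Vt."""
        if self._svd is None:
            self._svd = np.linalg.svd(self.X, full_matrices=False)
        return self._svd

    def to_raw_scale(self, beta_std: np.ndarray) -> tuple[np.ndarray, float]:
        """Map standardized-scale coefficients back to raw genotype scale."""
        beta_raw = beta_std / self.col_sds
        intercept = self.y_mean - float(self.col_means @ beta_raw)
        return beta_raw, intercept


@dataclass
class RidgePathResult:
    grid: np.ndarray  # ascending positive lambdas
    coefs: np.ndarray  # len(grid) x p
    ids: list[str]
    stability: np.ndarray  # relative range of |beta| per predictor (window)
    magnitude: np.ndarray  # mean |beta| per predictor (window)
    se: np.ndarray  # ridge sampling SE per predictor at the window mid-lambda
    selected: list[str]

    def norms(self) -> np.ndarray:
        return np.linalg.norm(self.coefs, axis=1)


def standardize_design(G: np.ndarray, y: np.ndarray, ids=None) -> RidgeDesign:
    """Column-standardize predictors and center the outcome."""
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    if G.ndim != 2 or G.shape[0] != y.shape[0]:
        raise ValidationError("predictor matrix and outcome sizes disagree")
    ids = list(ids) if ids is not None else [f"x{j}" for j in range(G.shape[1])]
    mu = G.mean(axis=0)
    sd = G.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise DegenerateDesignError(
            f"monomorphic predictor(s): {[ids[j] for j in dead[:5]]}"
        )
    return RidgeDesign(
        X=(G - mu) / sd,
        y=y - y.mean(),
        col_means=mu,
        col_sds=sd,
        y_mean=float(y.mean()),
        ids=ids,
    )


def ridge_fit(design: RidgeDesign, lam: float) -> np.ndarray:
    """beta_hat(lambda) via the SVD: V diag(d/(d^2+lambda)) U'y.  lambda > 0."""
    if not np.isscalar(lam) or lam <= 0:
        raise ValidationError(f"lambda must be a positive scalar, got {lam!r}")
    U, d, Vt = design.svd()
    uty = U.T @ design.y
    return Vt.T @ ((d / (d**2 + lam)) * uty)


def ols_fit(design: RidgeDesign) -> np.ndarray:
    """Unpenalized least squares (requires full column rank)."""
    U, d, Vt = design.svd()
    if d.min() <= 1e-10 * d.max():
        raise DegenerateDesignError("design is rank deficient; OLS undefined")
    return Vt.T @ ((U.T @ design.y) / d)


def default_lambda_grid(design: RidgeDesign, num: int = 64) -> np.ndarray:
    """64 log-spaced lambdas from 1e-3 to 1e3 x mean diagonal of X'X."""
    scale = float(np.mean((design.X**2).sum(axis=0)))
    return np.logspace(np.log10(1e-3 * scale), np.log10(1e3 * scale), num)


def ridge_path(design: RidgeDesign, grid=None) -> RidgePathResult:
    """Coefficient matrix over an ascending lambda grid (single SVD reused).

    ||beta_hat(lambda)||_2 is non-increasing along the grid.  Stability and
    magnitude scores (and a default selection) are attached; re-select with
    other knobs via :func:`stability_select`.
    """
    if grid is None:
        grid = default_lambda_grid(design)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ValidationError("all lambda values must be positive")
    uniq = np.unique(grid)
    if uniq.size != grid.size:
        warnings.warn("duplicate lambda values removed from the grid")
    grid = uniq  # np.unique sorts ascending
    if grid.size < 8:
        raise ValidationError("lambda grid must hold at least 8 distinct points")

    U, d, Vt = design.svd()
    uty = U.T @ design.y
    shrink = d[None, :] / (d[None, :] ** 2 + grid[:, None])  # len(grid) x r
    coefs = (shrink * uty[None, :]) @ Vt

    scale = float(np.mean((design.X**2).sum(axis=0)))
    stability, magnitude, se = _path_scores(design, coefs, grid, scale)
    result = RidgePathResult(
        grid=grid, coefs=coefs, ids=design.ids,
        stability=stability, magnitude=magnitude, se=se, selected=[],
    )
    result.selected = stability_select(result)
    return result


#: stability window as fractions of the design scale (mean diagonal of X'X).
#: Below the lower edge the ridge estimate still carries the sampling noise of
#: the near-singular contrasts between tightly linked predictors (the OLS end
#: of the trace wobbles); above the upper edge every direction is shrunk
#: roughly uniformly toward zero, so the trace's tail says nothing about which
#: predictors are stable.  The window is where proxy coefficients reallocate
#: while genuine signals hold their level.
STABILITY_WINDOW = (0.08, 0.2)


def _path_scores(design: RidgeDesign, coefs: np.ndarray, grid: np.ndarray,
                 scale: float, window: tuple[float, float] = STABILITY_WINDOW,
                 eps: float = 1e-12):
    sub = (grid >= window[0] * scale) & (grid <= window[1] * scale)
    if sub.sum() < 2:
        sub = np.ones(len(grid), dtype=bool)
    a = np.abs(coefs[sub])
    amax = a.max(axis=0)
    stability = (amax - a.min(axis=0)) / np.maximum(amax, eps)
    magnitude = a.mean(axis=0)
    # sampling SE of the ridge estimate at the window's mid-lambda, with the
    # conservative sigma-hat = sd(y); used as the noise floor for "large"
    lam_mid = float(np.exp(np.mean(np.log(grid[sub]))))
    U, d, Vt = design.svd()
    var_scale = (Vt.T**2) @ (d**2 / (d**2 + lam_mid) ** 2)
    se = np.sqrt(np.var(design.y) * var_scale)
    return stability, magnitude, se


def stability_select(
    path: RidgePathResult, tau: float = 0.2, mult: float = 3.0,
    z_min: float = 4.0,
) -> list[str]:
    """Predictors whose ridge trace is flat and large across the stability
    window, in descending magnitude order.

    Selected = { j : s_j <= tau, g_j >= mult x median_k g_k, g_j >= z_min x
    se_j } where s_j is the relative range of |beta_j| over the window, g_j
    the mean |beta_j| there, and se_j the predictor's ridge sampling SE at the
    window's mid-lambda (the noise floor).  The bundle-median rule needs a
    bundle; it is waived for panels of fewer than 5 predictors.
    """
    if not (0 <= tau):
        raise ValidationError("tau must be non-negative")
    if path.coefs.size == 0 or np.all(path.coefs == 0):
        warnings.warn("all-zero ridge path: empty selection")
        return []
    keep = (path.stability <= tau) & (path.magnitude >= z_min * path.se)
    if len(path.ids) >= 5:
        keep &= path.magnitude >= mult * float(np.median(path.magnitude))
    order = np.argsort(-path.magnitude, kind="stable")
    return [path.ids[j] for j in order if keep[j]]
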