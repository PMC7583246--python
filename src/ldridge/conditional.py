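"""Nested linear models, partial F-tests, and forward conditional selection.

Counting independent signals in an associated region: variants are added to
a base covariate model one at a time, each entry justified by the partial
F-test of the nested comparison (does adding this variant significantly
reduce the residual sum of squares?).  Selection stops when no remaining
candidate enters below the entry threshold.  The default outcome is the
quantitative trait (γ-GT on the U/L scale), so coefficients read as U/L per
alt-allele copy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import CollinearityError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class LinearFit:
    coef: np.ndarray  # intercept, covariates..., variants...
    ci_low: np.ndarray
    ci_high: np.ndarray
    se: np.ndarray
    sse: float
    df_resid: int
    variant_ids: tuple[str, ...]
    term_names: tuple[str, ...]
    n: int
    _y_key: int = field(default=0, repr=False)  # nestedness guard

    def coef_for(self, name: str) -> float:
        return float(self.coef[self.term_names.index(name)])


@dataclass
class NestedComparison:
    f_stat: float
    df_num: int
    df_den: int
    p: float


def _design(y, covariates, G, variant_ids):
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    cols = [np.ones(n)]
    names = ["intercept"]
    if covariates is not None and np.size(covariates):
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if C.shape[0] != n:
            raise ValidationError("covariate rows do not match outcome length")
        cols.append(C)
        names += [f"cov{j}" for j in range(C.shape[1])]
    if G is not None and np.size(G):
        G = np.asarray(G, dtype=float)
        if G.ndim == 1:
            G = G[:, None]
        if G.shape[0] != n:
            raise ValidationError("variant rows do not match outcome length")
        cols.append(G)
        names += list(variant_ids)
    X = np.column_stack(cols)
    return X, tuple(names), y


def fit_linear(y, covariates=None, variants=None, variant_ids=()) -> LinearFit:
    """OLS with t-based 95% CIs; errors on rank deficiency naming the columns."""
    variant_ids = tuple(variant_ids)
    if variants is not None and np.size(variants):
        Gv = np.asarray(variants, dtype=float)
        k = 1 if Gv.ndim == 1 else Gv.shape[1]
        if len(variant_ids) != k:
            variant_ids = tuple(f"v{j}" for j in range(k))
    X, names, y = _design(y, covariates, variants, variant_ids)
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"n={n} too small for {p} parameters")
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    bad = np.flatnonzero(diag <= 1e-10 * max(diag.max(), 1.0))
    if bad.size:
        raise CollinearityError(
            f"rank-deficient design; collinear column(s): {[names[j] for j in bad]}"
        )
    coef = np.linalg.solve(r, q.T @ y)
    resid = y - X @ coef
    sse = float(resid @ resid)
    df = n - p
    sigma2 = sse / df
    rinv = np.linalg.inv(r)
    cov = sigma2 * (rinv @ rinv.T)
    se = np.sqrt(np.diag(cov))
    tq = stats.t.ppf(0.975, df)
    return LinearFit(
        coef=coef, ci_low=coef - tq * se, ci_high=coef + tq * se, se=se,
        sse=sse, df_resid=df, variant_ids=variant_ids, term_names=names, n=n,
        _y_key=hash(y.tobytes()),
    )


def partial_f_test(reduced: LinearFit, full: LinearFit) -> NestedComparison:
    """F = ((SSE_r − SSE_f)/(df_r − df_f)) / (SSE_f/df_f), p from F(df_num, df_den)."""
    if reduced.n != full.n or reduced._y_key != full._y_key:
        raise ValidationError("models must share the same outcome vector")
    if not set(reduced.variant_ids) <= set(full.variant_ids):
        raise ValidationError("reduced model's variants must nest inside the full model")
    df_num = reduced.df_resid - full.df_resid
    if df_num <= 0:
        if df_num == 0 and set(reduced.variant_ids) == set(full.variant_ids):
            return NestedComparison(f_stat=0.0, df_num=0, df_den=full.df_resid, p=1.0)
        raise ValidationError("models are not strictly nested")
    f = max(0.0, (reduced.sse - full.sse) / df_num) / (full.sse / full.df_resid)
    p = float(stats.f.sf(f, df_num, full.df_resid)) if df_num > 0 else 1.0
    return NestedComparison(f_stat=float(f), df_num=df_num, df_den=full.df_resid, p=p)


@dataclass
class ForwardStep:
    variant_id: str
    p_entry: float
    f_stat: float
    t_stat: float


def forward_conditional(
    y, covariates, candidates: np.ndarray, candidate_ids, alpha: float = 1e-4
) -> list[ForwardStep]:
    """Greedy forward selection of independent signals by conditional p-value.

    At each step the candidate with the smallest partial-F p against the
    current model enters (ties: larger |t|, then smaller variant index);
    stops when min p >= alpha.  Candidates collinear with the current model
    are skipped.
    """
    y = np.asarray(y, dtype=float)
    G = np.asarray(candidates, dtype=float)
    ids = list(candidate_ids)
    if G.shape[1] != len(ids):
        raise ValidationError("candidate ids do not match matrix columns")
    if not (0 < alpha < 1):
        raise ValidationError("entry alpha must lie in (0, 1)")
    n = y.shape[0]
    base, _, _ = _design(y, covariates, None, ())
    Q, _ = np.linalg.qr(base)
    # residualize incrementally: Q spans [1, covariates, chosen variants]
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)
    chosen: list[ForwardStep] = []
    active = list(range(len(ids)))
    p_base = base.shape[1]
    while active:
        df_full = n - p_base - len(chosen) - 1
        if df_full <= 0:
            break
        gg = (G_r[:, active] ** 2).sum(axis=0)
        yy = float(y_r @ y_r)
        best = None  # (p, -|t|, index, j, t, f)
        for pos, j in enumerate(active):
            if gg[pos] <= 1e-10 * n:
                continue  # collinear with current model
            gy = float(G_r[:, j] @ y_r)
            sse_full = yy - gy * gy / gg[pos]
            if sse_full <= 0:
                sse_full = 1e-300
            f = (yy - sse_full) / (sse_full / df_full)
            t = np.sign(gy) * np.sqrt(f)
            p = float(stats.f.sf(f, 1, df_full))
            key = (p, -abs(t), j)
            if best is None or key < best[0]:
                best = (key, j, float(t), float(f))
        if best is None:
            break
        (p, _, _), j, t, f = best
        if p >= alpha:
            break
        chosen.append(ForwardStep(variant_id=ids[j], p_entry=p, f_stat=f, t_stat=t))
        # orthogonalize the accepted column into the basis
        g = G_r[:, j].copy()
        g /= np.linalg.norm(g)
        y_r = y_r - g * float(g @ y_r)
        G_r = G_r - np.outer(g, g @ G_r)
        active.remove(j)
    return chosen
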