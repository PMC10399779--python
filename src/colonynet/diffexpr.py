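"""Negative-binomial Wald differential expression.

A desk-scale NB GLM engine for gene x worker count matrices: median-of-ratios
size factors, method-of-moments dispersions shrunk toward a monotone
mean-dispersion trend, per-gene Wald tests of a continuous covariate with
colony indicator terms and an optional second (control) covariate, and
Benjamini-Hochberg multiple-testing correction.  Genes are differentially
expressed (DE) when the BH-adjusted p-value falls below 0.05.

Compared with full empirical-Bayes DE frameworks this engine uses
method-of-moments + trend-shrinkage dispersions instead of Cox-Reid empirical
Bayes, no independent filtering, and no fold-change shrinkage; conclusions
here rest on DE counts, for which this simplification is calibrated (see the
type-I error tests).

The per-gene model for worker w with size factor s_w is

    count_gw ~ NB(mu_gw, alpha_g),
    log mu_gw = log s_w + colony terms + beta_g * covariate_w [+ gamma_g * control_w]

and the Wald statistic is beta_g / SE(beta_g).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_low_count_genes",
    "size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "bh_adjust",
    "de_accounting",
    "NegativeBinomialWald",
    "DEAccounting",
]

_DISP_FLOOR = 1e-8


def filter_low_count_genes(counts: pd.DataFrame, min_total: int = 100) -> pd.DataFrame:
    """Remove genes with fewer than ``min_total`` reads summed over all
    workers (the conventional <100-read prefilter)."""
    kept = counts[counts.sum(axis=1) >= min_total]
    if kept.empty:
        raise ValueError("all genes removed by the low-count filter")
    return kept


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-worker normalisation factors.

    Ratios are taken over genes expressed in every worker (falling back to
    genes expressed in >= 90% of workers when none qualifies); the factors
    are rescaled to geometric mean 1.
    """
    arr = counts.to_numpy(dtype=float)
    nonzero = arr > 0
    universal = nonzero.all(axis=1)
    if not universal.any():
        universal = nonzero.mean(axis=1) >= 0.9
        if not universal.any():
            raise ValueError("no gene expressed in >=90% of workers")
    ref = arr[universal]
    log_geomean = np.log(ref).mean(axis=1, where=ref > 0)
    with np.errstate(divide="ignore"):
        ratios = np.log(ref) - log_geomean[:, None]
    ratios = np.where(ref > 0, ratios, np.nan)
    sf = np.exp(np.nanmedian(ratios, axis=0))
    sf /= np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _design_matrix(
    n: int,
    colony: pd.Series | None,
    covariate: np.ndarray | None = None,
    control: np.ndarray | None = None,
) -> np.ndarray:
    cols = [np.ones(n)]
    if colony is not None:
        levels = pd.unique(colony)
        for lv in levels[1:]:
            cols.append((colony == lv).to_numpy(dtype=float))
    if control is not None:
        cols.append(np.asarray(control, dtype=float))
    if covariate is not None:
        cols.append(np.asarray(covariate, dtype=float))
    return np.column_stack(cols)


def _nb_irls(Y, X, offset, disp, max_iter=30, tol=1e-6, ridge=1e-8):
    """Vectorised IRLS for per-gene NB GLMs with known dispersion.

    Y is (G, n); X (n, p); offset (n,); disp (G,).  Returns coefficients
    (G, p), standard errors (G, p) and a converged flag (G,).
    """
    G, n = Y.shape
    p = X.shape[1]
    XtX = X.T @ X + ridge * np.eye(p)
    L = np.log((Y + 0.5)) - offset[None, :]
    B = np.linalg.solve(XtX, X.T @ L.T).T  # OLS warm start on the log scale
    alpha = np.asarray(disp, dtype=float)[:, None]
    converged = np.zeros(G, dtype=bool)
    A = None
    for _ in range(max_iter):
        eta = np.clip(B @ X.T + offset[None, :], -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha * mu)
        z = (eta - offset[None, :]) + (Y - mu) / mu
        A = np.einsum("gn,np,nq->gpq", W, X, X)
        A += ridge * np.eye(p)[None, :, :]
        b = np.einsum("gn,np->gp", W * z, X)
        B_new = np.linalg.solve(A, b[:, :, None])[:, :, 0]
        delta = np.max(np.abs(B_new - B), axis=1)
        newly = delta < tol
        B = B_new
        converged |= newly
        if newly.all():
            break
    cov = np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    bad = ~np.all(np.isfinite(B), axis=1) | ~np.all(np.isfinite(se), axis=1)
    converged &= ~bad
    return B, se, converged


def estimate_dispersions(
    counts: pd.DataFrame,
    design: np.ndarray | None = None,
    size_factors_: pd.Series | None = None,
    colony: pd.Series | None = None,
    shrink_weight: float = 0.25,
) -> pd.Series:
    """Per-gene NB dispersions: design-aware method of moments shrunk toward
    a monotone mean-dispersion trend.

    Fitted means come from a Poisson GLM on the design; the raw estimate is
    sum((y - mu)^2 - mu) / mu^2 over workers divided by the residual degrees
    of freedom, floored at 1e-8.  A decreasing isotonic trend in mean
    normalised expression is fitted to the raw values and the final estimate
    is a log-scale convex combination (weight ``shrink_weight`` on the
    trend).
    """
    Y = counts.to_numpy(dtype=float)
    G, n = Y.shape
    if n < 4:
        raise ValueError("dispersion estimation needs at least 4 workers")
    if size_factors_ is None:
        size_factors_ = size_factors(counts)
    sf = size_factors_.reindex(counts.columns).to_numpy()
    offset = np.log(sf)
    if design is None:
        design = _design_matrix(n, colony)
    p = design.shape[1]
    # Poisson fit (dispersion 0) supplies the fitted means
    B, _, _ = _nb_irls(Y, design, offset, np.zeros(G))
    mu = np.exp(np.clip(B @ design.T + offset[None, :], -30.0, 30.0))
    dof = max(n - p, 1)
    raw = np.sum(((Y - mu) ** 2 - mu) / mu**2, axis=1) / dof
    raw = np.maximum(raw, _DISP_FLOOR)

    mean_norm = (Y / sf[None, :]).mean(axis=1)
    order = np.argsort(mean_norm)
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    trend = np.empty(G)
    trend[order] = iso.fit_transform(mean_norm[order], raw[order])
    trend = np.maximum(trend, _DISP_FLOOR)
    disp = np.exp(
        (1.0 - shrink_weight) * np.log(raw) + shrink_weight * np.log(trend)
    )
    return pd.Series(np.maximum(disp, _DISP_FLOOR), index=counts.index, name="dispersion")


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, ties kept)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_wald_test(
    counts: pd.DataFrame,
    covariate: pd.Series,
    control: pd.Series | None = None,
    colony: pd.Series | None = None,
    size_factors_: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene NB Wald test of a continuous covariate.

    Returns a DataFrame indexed by gene with baseMean, log2FoldChange (per
    unit covariate), lfcSE, stat, pvalue, padj, significant and converged
    columns.  Colony enters as fixed indicator terms; ``control`` adds a
    second covariate whose effect is partialled out.  Non-convergent genes
    are flagged and assigned p = 1 (conservative).
    """
    workers = counts.columns
    cov = covariate.reindex(workers).to_numpy(dtype=float)
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariate contains non-finite values")
    if np.std(cov) == 0:
        raise ValueError("covariate is constant: effect unidentifiable")
    ctl = None
    if control is not None:
        ctl = control.reindex(workers).to_numpy(dtype=float)
        if not np.all(np.isfinite(ctl)):
            raise ValueError("control covariate contains non-finite values")
    col = colony.reindex(workers) if colony is not None else None

    if size_factors_ is None:
        size_factors_ = size_factors(counts)
    sf = size_factors_.reindex(workers).to_numpy()
    offset = np.log(sf)
    X = _design_matrix(len(workers), col, covariate=cov, control=ctl)
    if dispersions is None:
        dispersions = estimate_dispersions(
            counts, design=X, size_factors_=size_factors_
        )
    disp = dispersions.reindex(counts.index).to_numpy()

    Y = counts.to_numpy(dtype=float)
    B, SE, converged = _nb_irls(Y, X, offset, disp)
    # the covariate of interest is the last design column; scale to log2
    ln2 = np.log(2.0)
    beta = B[:, -1] / ln2
    se = SE[:, -1] / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, beta / se, 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(stat))
    pval = np.where(converged, pval, 1.0)
    padj = bh_adjust(np.nan_to_num(pval, nan=1.0))
    return pd.DataFrame(
        {
            "baseMean": (Y / sf[None, :]).mean(axis=1),
            "log2FoldChange": beta,
            "lfcSE": se,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
            "significant": padj < alpha,
            "converged": converged,
        },
        index=counts.index,
    )


class NegativeBinomialWald(BaseEstimator):
    """Estimator wrapper around :func:`nb_wald_test`.

    ``fit(counts, covariate=..., control=..., colony=...)`` stores the DE
    table in ``results_`` and the significant gene index in ``de_genes_``.
    """

    def __init__(self, alpha: float = 0.05, min_total: int = 100):
        self.alpha = alpha
        self.min_total = min_total

    def fit(self, counts, y=None, covariate=None, control=None, colony=None):
        if covariate is None:
            raise ValueError("covariate is required")
        filtered = filter_low_count_genes(counts, self.min_total)
        self.size_factors_ = size_factors(filtered)
        self.results_ = nb_wald_test(
            filtered,
            covariate,
            control=control,
            colony=colony,
            size_factors_=self.size_factors_,
            alpha=self.alpha,
        )
        self.de_genes_ = self.results_.index[self.results_["significant"]]
        return self


@dataclass
class DEAccounting:
    """Controlled differential-expression accounting.

    ``table`` has one row per variable: the uncontrolled DE gene count
    (n_de) followed by, for each other variable, the percentage of those
    genes that remain DE when that variable is added to the model (diagonal
    NaN).  ``controlled_only_pct`` reports the companion reading where the
    controlled model's DE set is used regardless of overlap, and
    ``fraction_of_genes`` gives controlled DE sets as percentages of all
    tested genes.
    """

    table: pd.DataFrame
    controlled_only_pct: pd.DataFrame
    fraction_of_genes: pd.DataFrame
    n_genes_tested: int


def de_accounting(
    counts: pd.DataFrame,
    variables: pd.DataFrame,
    colony: pd.Series,
    alpha: float = 0.05,
    min_total: int = 100,
) -> DEAccounting:
    """Build the DE accounting matrix over a set of per-worker variables.

    For each variable v, column 1 is the number of DE genes under the
    uncontrolled model (colony + v); the cell (v, c) is
    100 * |DE(v) ∩ DE(v controlling c)| / |DE(v)|.  Near-collinear controls
    (|r| > 0.999, e.g. a variable against itself) yield an empty controlled
    set by the collinearity guard.
    """
    filtered = filter_low_count_genes(counts, min_total)
    sf = size_factors(filtered)
    base_design = _design_matrix(filtered.shape[1], colony.reindex(filtered.columns))
    disp = estimate_dispersions(filtered, design=base_design, size_factors_=sf)

    names = list(variables.columns)
    de_sets: dict[str, set] = {}
    for v in names:
        res = nb_wald_test(
            filtered, variables[v], colony=colony, size_factors_=sf,
            dispersions=disp, alpha=alpha,
        )
        de_sets[v] = set(res.index[res["significant"]])

    table = pd.DataFrame(index=names, columns=["n_de"] + names, dtype=float)
    only = pd.DataFrame(index=names, columns=names, dtype=float)
    frac = pd.DataFrame(index=names, columns=["uncontrolled"] + names, dtype=float)
    G = len(filtered)
    for v in names:
        table.loc[v, "n_de"] = len(de_sets[v])
        frac.loc[v, "uncontrolled"] = 100.0 * len(de_sets[v]) / G
        for c in names:
            if c == v:
                continue
            r = np.corrcoef(variables[v], variables[c])[0, 1]
            if abs(r) > 0.999:
                controlled: set = set()
            else:
                res = nb_wald_test(
                    filtered, variables[v], control=variables[c], colony=colony,
                    size_factors_=sf, dispersions=disp, alpha=alpha,
                )
                controlled = set(res.index[res["significant"]])
            if de_sets[v]:
                table.loc[v, c] = 100.0 * len(de_sets[v] & controlled) / len(de_sets[v])
            only.loc[v, c] = (
                100.0 * len(controlled & de_sets[v]) / len(controlled)
                if controlled
                else 0.0
            )
            frac.loc[v, c] = 100.0 * len(de_sets[v] & controlled) / G
    return DEAccounting(
        table=table,
        controlled_only_pct=only,
        fraction_of_genes=frac,
        n_genes_tested=G,
    )
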