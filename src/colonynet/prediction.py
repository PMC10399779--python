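"""Predicting individual biology from brain gene expression.

Feature selection first runs a differential-expression analysis of the target
variable on all samples with colony identity in the model and keeps genes
with BH-adjusted p < alpha.  Prediction accuracy is then quantified by
repeated half-splits: at each of 100 iterations workers are split in half
(stratified by colony), a linear epsilon-insensitive support-vector
regression is trained on the normalised log expression of the selected genes,
and the squared Pearson correlation between predicted and observed values on
the held-out half is recorded.  The distribution of these R^2 scores over
iterations measures how strongly the variable is reflected in the brain
transcriptome; Welch two-sample t-tests compare distributions across
variables.

Selecting features on all samples follows the analysis convention this
package reproduces; it leaks target information across the split, so a
``strict_cv`` option re-selects features inside each training half for
leakage-free estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.svm import SVR

from . import diffexpr

__all__ = [
    "select_features_de",
    "iterate_prediction",
    "IteratedSVRPredictor",
    "PredictionResult",
    "compare_r2_distributions",
]


def select_features_de(
    counts: pd.DataFrame,
    target: pd.Series,
    colony: pd.Series,
    alpha: float = 0.05,
    size_factors_: pd.Series | None = None,
    dispersions: pd.Series | None = None,
) -> pd.Index:
    """Genes differentially expressed by the target (BH-adjusted p < alpha)
    under the pooled model colony + target.  Counts are assumed pre-filtered
    by the <100-read rule."""
    res = diffexpr.nb_wald_test(
        counts, target, colony=colony, alpha=alpha,
        size_factors_=size_factors_, dispersions=dispersions,
    )
    genes = res.index[res["significant"]]
    if len(genes) == 0:
        raise ValueError(
            "no differentially expressed genes at this alpha; relax alpha"
        )
    return genes


@dataclass
class PredictionResult:
    """Held-out R^2 scores of one target over the half-split iterations."""

    variable: str
    r2: np.ndarray
    n_features: int
    n_workers: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.r2))

    @property
    def median(self) -> float:
        return float(np.median(self.r2))


def _stratified_half_split(colony: np.ndarray, rng: np.random.Generator):
    train = np.zeros(colony.size, dtype=bool)
    for lv in np.unique(colony):
        idx = np.flatnonzero(colony == lv)
        idx = rng.permutation(idx)
        train[idx[: idx.size // 2]] = True
    return train


class IteratedSVRPredictor(BaseEstimator):
    """Iterated half-split support-vector regression on DE-gene features.

    Parameters mirror the conventional eps-regression defaults (linear
    kernel, cost 1, epsilon 0.1).  ``fit(counts, target, colony=...)`` runs
    the full feature-selection + iteration procedure and stores a
    :class:`PredictionResult` in ``result_``.
    """

    def __init__(
        self,
        n_iterations: int = 100,
        alpha: float = 0.05,
        C: float = 1.0,
        epsilon: float = 0.1,
        strict_cv: bool = False,
        feature_genes=None,
        random_state: int | None = None,
    ):
        self.n_iterations = n_iterations
        self.alpha = alpha
        self.C = C
        self.epsilon = epsilon
        self.strict_cv = strict_cv
        self.feature_genes = feature_genes
        self.random_state = random_state

    def fit(self, counts: pd.DataFrame, target: pd.Series, colony: pd.Series = None):
        workers = counts.columns
        y = target.reindex(workers).to_numpy(dtype=float)
        if workers.size < 20:
            raise ValueError("need at least 20 workers")
        col = (
            colony.reindex(workers).to_numpy()
            if colony is not None
            else np.zeros(workers.size)
        )
        colony_s = pd.Series(col, index=workers)
        rng = np.random.default_rng(self.random_state)

        sf = diffexpr.size_factors(counts)
        logX_all = np.log2(counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
        logX_all = pd.DataFrame(logX_all, index=counts.index, columns=workers)

        genes = None
        if self.feature_genes is not None:
            genes = pd.Index(self.feature_genes)
            missing = genes.difference(counts.index)
            if len(missing):
                raise ValueError(f"feature genes absent from counts: {list(missing)[:5]}")
        elif not self.strict_cv:
            disp = diffexpr.estimate_dispersions(
                counts, colony=colony_s, size_factors_=sf
            )
            genes = select_features_de(
                counts, target, colony_s, alpha=self.alpha,
                size_factors_=sf, dispersions=disp,
            )

        r2 = np.empty(self.n_iterations)
        n_feat_last = 0
        for it in range(self.n_iterations):
            train = _stratified_half_split(col, rng)
            if self.strict_cv:
                genes = select_features_de(
                    counts.loc[:, workers[train]],
                    target,
                    colony_s[workers[train]],
                    alpha=self.alpha,
                )
            F = logX_all.loc[genes].to_numpy().T  # workers x genes
            mu = F[train].mean(axis=0)
            sd = F[train].std(axis=0)
            sd[sd == 0] = 1.0
            Z = (F - mu) / sd
            svr = SVR(kernel="linear", C=self.C, epsilon=self.epsilon)
            svr.fit(Z[train], y[train])
            pred = svr.predict(Z[~train])
            obs = y[~train]
            if np.std(pred) == 0 or np.std(obs) == 0:
                warnings.warn(f"constant predictions at iteration {it}; R^2 = 0")
                r2[it] = 0.0
            else:
                r2[it] = np.corrcoef(pred, obs)[0, 1] ** 2
            n_feat_last = len(genes)

        self.genes_ = pd.Index(genes)
        self.result_ = PredictionResult(
            variable=str(target.name),
            r2=r2,
            n_features=n_feat_last,
            n_workers=int(workers.size),
        )
        return self


def iterate_prediction(
    counts: pd.DataFrame,
    target: pd.Series,
    colony: pd.Series | None = None,
    n_iterations: int = 100,
    seed: int | None = None,
    alpha: float = 0.05,
    strict_cv: bool = False,
    feature_genes=None,
) -> PredictionResult:
    """Functional wrapper around :class:`IteratedSVRPredictor`."""
    est = IteratedSVRPredictor(
        n_iterations=n_iterations,
        alpha=alpha,
        strict_cv=strict_cv,
        feature_genes=feature_genes,
        random_state=seed,
    ).fit(counts, target, colony=colony)
    return est.result_


def compare_r2_distributions(a: PredictionResult, b: PredictionResult) -> dict:
    """Welch two-sample t-test between two R^2 distributions."""
    if len(a.r2) < 2 or len(b.r2) < 2:
        raise ValueError("need at least 2 iterations per result")
    if np.var(a.r2) == 0 and np.var(b.r2) == 0:
        return {
            "t": 0.0 if np.mean(a.r2) == np.mean(b.r2) else np.inf,
            "df": float("nan"),
            "pvalue": float("nan"),
            "note": "zero variance in both distributions; p undefined",
        }
    res = stats.ttest_ind(a.r2, b.r2, equal_var=False)
    # Welch-Satterthwaite degrees of freedom
    va, vb = np.var(a.r2, ddof=1) / len(a.r2), np.var(b.r2, ddof=1) / len(b.r2)
    df = (va + vb) ** 2 / (va**2 / (len(a.r2) - 1) + vb**2 / (len(b.r2) - 1))
    return {"t": float(res.statistic), "df": float(df), "pvalue": float(res.pvalue)}
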