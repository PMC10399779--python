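"""Soft community detection and the social maturity score.

The weighted interaction network is factorised as W ~ X diag(lam) X^T with
nonnegative X (columns summing to 1) and community weights lam (summing to 1),
by minimising the KL divergence D(W || X lam X^T) over the network normalised
to total weight 1.  This is the static soft community model popularised as
FacetNet: the multiplicative updates are the M-step of an EM algorithm on the
mixture-over-communities model of edge mass, so the objective is
non-increasing at every iteration.

With k = 2 communities, the row-normalised soft membership of the
forager-associated community — oriented against the foraging fraction — is
the worker's *social maturity*, a continuous score in [0, 1] running from the
nurse to the forager community.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FacetNet",
    "facetnet_decompose",
    "orient_social_maturity",
    "maturity_distribution_diagnostic",
]

_EPS = 1e-12


def _kl(W, What):
    """KL divergence between nonnegative matrices of equal total mass."""
    mask = W > 0
    return float(
        np.sum(W[mask] * np.log(W[mask] / np.maximum(What[mask], _EPS)))
        - W.sum()
        + What.sum()
    )


class FacetNet(BaseEstimator):
    """Soft community decomposition of a weighted undirected network.

    Parameters
    ----------
    n_communities : int
        Number of overlapping communities k (fixed at 2 for the social
        maturity analysis).
    n_restarts : int
        Number of Dirichlet random initialisations; the best (lowest KL)
        solution is kept.
    max_iter, tol : int, float
        Per-restart iteration budget and stopping threshold on the decrease
        of the KL objective.
    random_state : int or None
        Seed for the initialisations.

    Attributes
    ----------
    X_ : ndarray (n, k)
        Nonnegative factor, columns sum to 1.
    weights_ : ndarray (k,)
        Community weights lam, summing to 1.
    membership_ : ndarray (n, k)
        Row-stochastic soft membership, M_ic ∝ X_ic * lam_c.
    kl_ : float
        Converged KL objective of the kept restart.
    objective_path_ : ndarray
        KL value after every iteration of the kept restart (non-increasing).
    isolated_ : ndarray (n,) bool
        Workers with zero strength; their membership is uniform 1/k.
    """

    def __init__(
        self,
        n_communities: int = 2,
        n_restarts: int = 10,
        max_iter: int = 2000,
        tol: float = 1e-9,
        random_state: int | None = None,
    ):
        self.n_communities = n_communities
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # one EM run from a given initialisation
    def _run(self, W, X, lam):
        path = []
        prev = np.inf
        for _ in range(self.max_iter):
            What = (X * lam) @ X.T
            R = W / np.maximum(What, _EPS)
            # shared responsibilities -> simultaneous M-step for X and lam
            X_new = X * (R @ (X * lam))
            lam_new = lam * np.einsum("ij,ic,jc->c", R, X, X)
            col = X_new.sum(axis=0)
            X = X_new / np.maximum(col, _EPS)
            lam = lam_new / max(lam_new.sum(), _EPS)
            obj = _kl(W, (X * lam) @ X.T)
            path.append(obj)
            if prev - obj < self.tol:
                break
            prev = obj
        return X, lam, np.array(path)

    def fit(self, W, y=None):
        """Fit the decomposition on a symmetric nonnegative matrix (array or
        square DataFrame of interaction counts)."""
        if isinstance(W, pd.DataFrame):
            self.worker_ids_ = np.asarray(W.index)
            W = W.to_numpy(dtype=float)
        else:
            W = np.asarray(W, dtype=float)
            self.worker_ids_ = np.arange(W.shape[0])
        k = self.n_communities
        if k < 1:
            raise ValueError("n_communities must be >= 1")
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if np.any(W < 0):
            raise ValueError("W must be nonnegative")
        if not np.allclose(W, W.T):
            raise ValueError("W must be symmetric")
        total = W.sum()
        if total <= 0:
            raise ValueError("W needs at least one positive entry")
        n = W.shape[0]
        strength = W.sum(axis=1)
        isolated = strength == 0
        Wn = W / total

        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_restarts):
            X0 = rng.dirichlet(np.ones(n), size=k).T  # columns sum to 1
            lam0 = rng.dirichlet(np.ones(k))
            X, lam, path = self._run(Wn, X0, lam0)
            if best is None or path[-1] < best[2][-1]:
                best = (X, lam, path)
        X, lam, path = best

        M = X * lam
        rowsum = M.sum(axis=1, keepdims=True)
        M = np.divide(M, np.maximum(rowsum, _EPS))
        M[isolated] = 1.0 / k
        if isolated.any():
            warnings.warn(
                f"{int(isolated.sum())} isolated worker(s) assigned uniform membership"
            )

        self.X_ = X
        self.weights_ = lam
        self.membership_ = M
        self.kl_ = float(path[-1])
        self.objective_path_ = path
        self.n_iter_ = len(path)
        self.isolated_ = isolated
        return self

    def fit_transform(self, W, y=None):
        return self.fit(W).membership_

    def reconstruct(self):
        """Model edge-mass matrix X diag(lam) X^T (total mass 1)."""
        check_is_fitted(self, "X_")
        return (self.X_ * self.weights_) @ self.X_.T


def facetnet_decompose(
    W,
    k: int = 2,
    max_iter: int = 2000,
    tol: float = 1e-9,
    seed: int | None = None,
    n_restarts: int = 10,
) -> FacetNet:
    """Functional wrapper: fit a :class:`FacetNet` on W and return it."""
    return FacetNet(
        n_communities=k,
        n_restarts=n_restarts,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(W)


def orient_social_maturity(
    membership, foraging, worker_ids=None
) -> pd.Series:
    """Social maturity: the membership column of the forager community.

    The forager community is the one whose membership correlates best
    (Pearson) with the foraging fraction, so the output is invariant to
    column permutation of the input.  Exact ties are broken toward the column
    whose top-decile members forage most, with a warning.
    """
    if isinstance(membership, FacetNet):
        worker_ids = membership.worker_ids_
        membership = membership.membership_
    M = np.asarray(membership, dtype=float)
    if M.ndim != 2 or M.shape[1] != 2:
        raise ValueError("orientation requires a two-community membership")
    if worker_ids is None:
        worker_ids = np.arange(M.shape[0])
    f = (
        foraging.reindex(worker_ids).to_numpy()
        if isinstance(foraging, pd.Series)
        else np.asarray(foraging, dtype=float)
    )
    ok = np.isfinite(f)
    if ok.sum() < 3:
        raise ValueError("need foraging fractions for at least 3 workers")

    def _corr(col):
        c = np.corrcoef(col[ok], f[ok])[0, 1]
        return -np.inf if not np.isfinite(c) else c

    r0, r1 = _corr(M[:, 0]), _corr(M[:, 1])
    if r0 == r1:
        warnings.warn("correlation tie while orienting maturity; using top-decile rule")
        means = []
        for c in range(2):
            top = np.argsort(M[:, c])[-max(1, M.shape[0] // 10):]
            means.append(np.nanmean(f[top]))
        forager_col = int(np.argmax(means))
    else:
        forager_col = int(r1 > r0)
    return pd.Series(M[:, forager_col], index=worker_ids, name="maturity")


def maturity_distribution_diagnostic(maturity) -> dict:
    """Decile histogram of maturity scores plus a U-shape summary.

    Returns the 10-bin histogram over [0, 1] and ``u_ratio``, the ratio of
    the mass in the two outer deciles to the mass in the two middle deciles
    (inf when the middle deciles are empty): values > 1 indicate the U-shaped
    (bimodal) profile expected when most workers sit deep inside one social
    community.
    """
    m = np.asarray(maturity, dtype=float)
    if m.size < 20:
        raise ValueError("need at least 20 scores for a decile diagnostic")
    hist, edges = np.histogram(m, bins=10, range=(0.0, 1.0))
    outer = hist[0] + hist[9]
    middle = hist[4] + hist[5]
    ratio = float("inf") if middle == 0 else outer / middle
    return {"histogram": hist, "bin_edges": edges, "u_ratio": ratio}
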