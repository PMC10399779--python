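"""The 5-layer multiplex network and the interlayer R-squared network.

Workers are the nodes of every layer (social interactions, behaviour, brain
gene expression, gut microbiota, physical environment).  Non-social layers
are pairwise Euclidean distances between per-worker profiles; intralayer
edges are unweighted and connect pairs whose interaction strength exceeds the
upper quartile of the edge-weight distribution (for distances: pairs closer
than the lower quartile); interlayer edges couple each worker with itself in
adjacent layers.

For correlation analysis each layer is reduced to one scalar per worker —
social maturity for the social layer, a principal component for the others —
and the 6 variables (5 layers + age) form a fully connected network weighted
by squared Pearson correlations, averaged across colonies.  The variable with
the largest strength (sum of incident R^2) is the hub.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

__all__ = [
    "similarity_layer",
    "upper_quartile_edges",
    "build_multiplex",
    "MultiplexNetwork",
    "reduce_layer",
    "select_expression_pc",
    "interlayer_r2_network",
    "CorrelationNetwork",
    "random_intercept_fit",
]

LAYER_ORDER = ["social", "behavior", "expression", "microbiota", "physical"]
SCORE_ORDER = LAYER_ORDER + ["age"]


def similarity_layer(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean distances between per-worker profile rows."""
    if profiles.isna().to_numpy().any():
        raise ValueError("profiles contain missing values; impute upstream")
    if len(profiles) < 2:
        return pd.DataFrame(index=profiles.index, columns=profiles.index, dtype=float)
    d = squareform(pdist(profiles.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(d, index=profiles.index, columns=profiles.index)


def upper_quartile_edges(weights: pd.DataFrame, kind: str = "interaction") -> list:
    """Unweighted edge set thresholded at the quartile of off-diagonal weights.

    kind='interaction': keep pairs strictly above the 75th percentile of the
    off-diagonal weight distribution.  kind='distance': weights are
    dissimilarities, so keep pairs strictly below the 25th percentile.
    Percentiles use linear interpolation of order statistics.  If every
    weight is equal the edge set is empty (strict inequality) and a warning
    is issued.
    """
    if kind not in ("interaction", "distance"):
        raise ValueError(f"unknown kind {kind!r}")
    ids = np.asarray(weights.index)
    W = weights.to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(ids), k=1)
    vals = W[iu, ju]
    if vals.size < 4:
        raise ValueError("need at least 4 worker pairs")
    if np.all(vals == vals[0]):
        warnings.warn("all edge weights equal; empty edge set under strict threshold")
        return []
    if kind == "interaction":
        thr = np.percentile(vals, 75, method="linear")
        keep = vals > thr
    else:
        thr = np.percentile(vals, 25, method="linear")
        keep = vals < thr
    return [(ids[i], ids[j]) for i, j in zip(iu[keep], ju[keep])]


@dataclass
class MultiplexNetwork:
    """Ordered layers with unweighted intralayer edge sets and implicit
    identity couplings between adjacent layers."""

    workers: list
    layer_names: list
    edges: dict = field(default_factory=dict)

    @property
    def n_interlayer_edges(self) -> int:
        return (len(self.layer_names) - 1) * len(self.workers)

    def to_networkx(self):
        """Flattened multigraph view: one node per (layer, worker)."""
        import networkx as nx

        g = nx.Graph()
        for li, layer in enumerate(self.layer_names):
            for w in self.workers:
                g.add_node((layer, w))
            for i, j in self.edges[layer]:
                g.add_edge((layer, i), (layer, j))
            if li:
                prev = self.layer_names[li - 1]
                for w in self.workers:
                    g.add_edge((prev, w), (layer, w))
        return g


def build_multiplex(layers: dict) -> MultiplexNetwork:
    """Assemble a multiplex network from per-layer weight matrices.

    ``layers`` maps layer name -> square DataFrame; the social layer is
    thresholded as interaction counts, all others as distances.  All layers
    must share the identical worker set.
    """
    names = [n for n in LAYER_ORDER if n in layers] + [
        n for n in layers if n not in LAYER_ORDER
    ]
    ref = list(layers[names[0]].index)
    for n in names[1:]:
        ids = list(layers[n].index)
        if ids != ref:
            offenders = sorted(set(ids) ^ set(ref))
            raise ValueError(f"worker set mismatch in layer {n!r}: {offenders[:5]}")
    edges = {
        n: upper_quartile_edges(
            layers[n], kind="interaction" if n == "social" else "distance"
        )
        for n in names
    }
    return MultiplexNetwork(workers=ref, layer_names=names, edges=edges)


def reduce_layer(
    profiles: pd.DataFrame,
    pc_index: int = 1,
    orient_to: pd.Series | None = None,
) -> pd.Series:
    """Score workers on one principal component of a profile matrix.

    ``pc_index`` is 1-based.  When ``orient_to`` (typically the foraging
    fraction) is given, the component's sign is fixed so the score correlates
    nonnegatively with it.
    """
    X = profiles.to_numpy(dtype=float)
    n = len(profiles)
    max_rank = min(n, X.shape[1])
    if pc_index < 1 or pc_index > max_rank:
        raise ValueError(f"pc_index {pc_index} exceeds the data rank {max_rank}")
    pca = PCA(n_components=pc_index, svd_solver="full")
    scores = pca.fit_transform(X - X.mean(axis=0))[:, pc_index - 1]
    out = pd.Series(scores, index=profiles.index, name=f"PC{pc_index}")
    if orient_to is not None:
        ref = orient_to.reindex(profiles.index).to_numpy(dtype=float)
        ok = np.isfinite(ref)
        if ok.sum() >= 3 and np.std(scores[ok]) > 0 and np.std(ref[ok]) > 0:
            if np.corrcoef(scores[ok], ref[ok])[0, 1] < 0:
                out = -out
    return out


def _grouped_r2(x: np.ndarray, groups: pd.Series) -> float:
    """One-way (between-group) R^2 of a scalar against a grouping factor."""
    gm = x.mean()
    ss_tot = np.sum((x - gm) ** 2)
    if ss_tot == 0:
        return 0.0
    ss_between = sum(
        len(idx) * (x[idx].mean() - gm) ** 2
        for _, idx in pd.Series(np.arange(len(x))).groupby(groups.to_numpy())
    )
    return float(ss_between / ss_tot)


def select_expression_pc(
    pc_scores: pd.DataFrame,
    batch: pd.Series,
    biological: pd.DataFrame,
) -> tuple[int, pd.DataFrame]:
    """Pick the expression principal component carrying biology, not batch.

    For each component, reports R^2 against the extraction batch (one-way
    grouped fit) and against every biological variable; recommends the
    smallest-index component whose best biological R^2 exceeds its batch R^2.
    With a single batch the batch R^2 is 0 and PC1 is recommended; if no
    component qualifies, falls back to PC1 with a warning.
    """
    batch = batch.reindex(pc_scores.index)
    rows = []
    for c, col in enumerate(pc_scores.columns, start=1):
        s = pc_scores[col].to_numpy(dtype=float)
        batch_r2 = 0.0 if batch.nunique() < 2 else _grouped_r2(s, batch)
        bio = {}
        for v in biological.columns:
            y = biological[v].reindex(pc_scores.index).to_numpy(dtype=float)
            ok = np.isfinite(y) & np.isfinite(s)
            if ok.sum() >= 3 and np.std(y[ok]) > 0 and np.std(s[ok]) > 0:
                bio[v] = float(np.corrcoef(s[ok], y[ok])[0, 1] ** 2)
            else:
                bio[v] = 0.0
        rows.append({"pc": c, "batch_r2": batch_r2, **{f"r2_{k}": v for k, v in bio.items()}})
    diag = pd.DataFrame(rows).set_index("pc")
    bio_cols = [c for c in diag.columns if c.startswith("r2_")]
    best_bio = diag[bio_cols].max(axis=1)
    passing = diag.index[best_bio > diag["batch_r2"]]
    if len(passing) == 0:
        warnings.warn("no component beats batch; falling back to PC1")
        return 1, diag
    return int(passing[0]), diag


def _pairwise_r2(scores: pd.DataFrame) -> pd.DataFrame:
    cols = list(scores.columns)
    n = len(cols)
    R = np.eye(n)
    X = scores.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = X[:, i], X[:, j]
            if np.std(xi) == 0 or np.std(xj) == 0:
                warnings.warn(
                    f"constant variable among ({cols[i]}, {cols[j]}); R^2 set to 0"
                )
                r2 = 0.0
            else:
                r2 = float(np.corrcoef(xi, xj)[0, 1] ** 2)
            R[i, j] = R[j, i] = r2
    return pd.DataFrame(R, index=cols, columns=cols)


@dataclass
class CorrelationNetwork:
    """Interlayer R^2 network: per-colony matrices, their average, and node
    strengths (sum of incident R^2; the argmax is the hub)."""

    per_colony: dict
    mean: pd.DataFrame
    strength: pd.Series
    hub: str


def interlayer_r2_network(
    scores: pd.DataFrame, colony: pd.Series | None = None
) -> CorrelationNetwork:
    """Squared Pearson correlations among per-worker summary variables.

    ``scores`` has one column per variable (social, behavior, expression,
    microbiota, physical, age) and one row per worker.  R^2 is computed per
    colony and averaged across colonies with equal weight.
    """
    if colony is None:
        colony = pd.Series("all", index=scores.index)
    colony = colony.reindex(scores.index)
    per_colony = {}
    for name, idx in scores.groupby(colony).groups.items():
        block = scores.loc[idx]
        if len(block) < 3:
            raise ValueError(f"colony {name!r} has fewer than 3 workers")
        per_colony[name] = _pairwise_r2(block)
    mean = sum(per_colony.values()) / len(per_colony)
    strength = mean.sum(axis=1) - np.diag(mean.to_numpy())
    hub = str(strength.idxmax())
    return CorrelationNetwork(
        per_colony=per_colony, mean=mean, strength=strength, hub=hub
    )


def random_intercept_fit(x, y, groups) -> dict:
    """Random-intercept regression y ~ x with a group intercept.

    Fitted by maximum likelihood (statsmodels MixedLM); with a single group
    it collapses to ordinary least squares.  Returns the slope, its Wald t,
    and R^2 defined as the squared Pearson correlation between the
    fixed-effect fitted values and y, plus the variance components.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    if np.std(x) == 0:
        raise ValueError("zero-variance predictor")
    X = np.column_stack([np.ones_like(x), x])
    if len(np.unique(groups)) < 2:
        res = stats.linregress(x, y)
        fitted = res.intercept + res.slope * x
        return {
            "slope": float(res.slope),
            "t": float(res.slope / res.stderr),
            "r2": float(np.corrcoef(fitted, y)[0, 1] ** 2),
            "sigma_group": 0.0,
            "sigma_resid": float(np.std(y - fitted, ddof=2)),
        }
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        fit = model.fit(reml=False)
    slope = float(fit.fe_params[1])
    t = float(slope / fit.bse_fe[1])
    fitted = X @ fit.fe_params
    r2 = float(np.corrcoef(fitted, y)[0, 1] ** 2) if np.std(fitted) > 0 else 0.0
    return {
        "slope": slope,
        "t": t,
        "r2": r2,
        "sigma_group": float(np.sqrt(max(np.asarray(fit.cov_re)[0, 0], 0.0))),
        "sigma_resid": float(np.sqrt(fit.scale)),
    }
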