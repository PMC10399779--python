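"""End-to-end orchestration: simulate -> features -> maturity -> layers ->
correlation network -> DE accounting -> prediction.

One master seed fans out to per-stage seeds through ``numpy``'s SeedSequence
spawning, so each stage is independently reproducible and two runs with the
same master seed produce identical artifacts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, microbiota, multiplex, prediction, tracking
from .community import FacetNet, orient_social_maturity, maturity_distribution_diagnostic
from .config import ColonyConfig
from .synthetic import ColonyDataset, generate_colony

__all__ = ["RunConfig", "run_full_analysis", "compute_layer_scores", "compute_maturity"]


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    colony: ColonyConfig = field(default_factory=ColonyConfig)
    master_seed: int = 0
    gap_bridge: int = 0
    interaction_mode: str = "head_head"
    k_sd: float = 2.0
    facetnet_restarts: int = 10
    facetnet_max_iter: int = 2000
    facetnet_tol: float = 1e-9
    de_alpha: float = 0.05
    de_min_total: int = 100
    prediction_iterations: int = 100
    run_de: bool = True
    run_prediction: bool = True


def _stage_seeds(master_seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def compute_maturity(
    interactions: dict,
    foraging: pd.Series,
    seed: int,
    n_restarts: int = 10,
    max_iter: int = 2000,
    tol: float = 1e-9,
) -> tuple[pd.Series, dict]:
    """FacetNet soft maturity per colony, oriented against foraging."""
    out = []
    models = {}
    for i, (colony_id, W) in enumerate(sorted(interactions.items())):
        fn = FacetNet(
            n_communities=2,
            n_restarts=n_restarts,
            max_iter=max_iter,
            tol=tol,
            random_state=seed + i,
        ).fit(W)
        out.append(orient_social_maturity(fn, foraging))
        models[colony_id] = fn
    return pd.concat(out), models


def compute_layer_scores(
    dataset: ColonyDataset,
    maturity: pd.Series,
    foraging: pd.Series,
    spatial: tracking.SpatialProfile,
    pooled: bool = False,
    max_expression_pcs: int = 5,
) -> tuple[pd.DataFrame, dict]:
    """One scalar per worker per layer.

    Social maturity scores the social layer; PCA scores the others (PC1,
    except for expression where the component carrying biology rather than
    extraction batch is selected).  Per-colony PCA by default; ``pooled``
    computes components on all colonies together, the convention used for
    the prediction analysis.
    """
    workers = maturity.index
    colony = dataset.workers.set_index("worker_id")["colony_id"].reindex(workers)
    batch = dataset.workers.set_index("worker_id")["batch_id"].reindex(workers)
    age = dataset.workers.set_index("worker_id")["age_weeks"].reindex(workers).astype(float)

    behav = dataset.behaviors.reindex(workers).copy()
    behav["foraging"] = foraging.reindex(workers)
    behav_norm = tracking.normalize_behaviors(behav, colony)

    sf = diffexpr.size_factors(dataset.expression[workers])
    expr_log = np.log2(
        dataset.expression[workers].to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0
    )
    expr_profiles = pd.DataFrame(expr_log.T, index=workers, columns=dataset.expression.index)

    micro_counts, _ = microbiota.exclude_endosymbiont(
        dataset.microbiota[workers], dataset.taxonomy
    )
    micro_profiles = microbiota.relative_abundance(micro_counts).T

    phys = spatial.counts.reindex(workers).fillna(0.0)
    totals = phys.sum(axis=1)
    phys = phys.div(totals.where(totals > 0, 1.0), axis=0)

    diagnostics: dict = {}

    def per_group(fn):
        if pooled:
            return fn(workers, "pooled")
        parts = [fn(idx, name) for name, idx in colony.groupby(colony).groups.items()]
        return pd.concat(parts).reindex(workers)

    def behavior_scores(idx, _name):
        return multiplex.reduce_layer(behav_norm.loc[idx], 1, orient_to=foraging)

    def micro_scores(idx, _name):
        return multiplex.reduce_layer(micro_profiles.loc[idx], 1, orient_to=foraging)

    def phys_scores(idx, _name):
        return multiplex.reduce_layer(phys.loc[idx], 1, orient_to=foraging)

    behavior = per_group(behavior_scores)

    def expr_scores(idx, name):
        from sklearn.decomposition import PCA

        X = expr_profiles.loc[idx].to_numpy()
        X = X - X.mean(axis=0)
        ncomp = min(max_expression_pcs, len(idx) - 1, X.shape[1])
        pcs = PCA(n_components=ncomp, svd_solver="full").fit_transform(X)
        pc_df = pd.DataFrame(
            pcs, index=idx, columns=[f"PC{i + 1}" for i in range(ncomp)]
        )
        bio = pd.DataFrame(
            {
                "maturity": maturity.reindex(idx),
                "age": age.reindex(idx),
                "behavior": behavior.reindex(idx),
            }
        )
        chosen, table = multiplex.select_expression_pc(pc_df, batch.reindex(idx), bio)
        diagnostics[f"expression_pc_{name}"] = {"chosen": chosen, "table": table}
        score = pc_df[f"PC{chosen}"]
        ref = foraging.reindex(idx)
        if np.std(score) > 0 and np.corrcoef(score, ref)[0, 1] < 0:
            score = -score
        return score

    scores = pd.DataFrame(
        {
            "social": maturity,
            "behavior": behavior,
            "expression": per_group(expr_scores),
            "microbiota": per_group(micro_scores),
            "physical": per_group(phys_scores),
            "age": age,
        }
    )
    return scores, diagnostics


def run_full_analysis(
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
    dataset: ColonyDataset | None = None,
) -> dict:
    """Run the full analysis; returns a results dict and optionally writes
    all artifacts plus a manifest under ``outdir``."""
    if config is None:
        config = RunConfig()
    seeds = _stage_seeds(config.master_seed)
    results: dict = {"config": config}

    # 1. simulate
    if dataset is None:
        import dataclasses

        colony_cfg = dataclasses.replace(config.colony, seed=seeds[0])
        dataset = generate_colony(colony_cfg)
    results["dataset"] = dataset
    workers_meta = dataset.workers.set_index("worker_id")
    colony = workers_meta["colony_id"]

    # 2. tracking features
    kept = tracking.filter_low_detection(dataset.detections, colony, k_sd=config.k_sd)
    det = dataset.detections[dataset.detections["worker_id"].isin(kept)]
    foraging = tracking.foraging_fraction(det, dataset.config.geometry)
    spatial = tracking.spatial_fidelity(det, dataset.config.body.mean_body_length)
    interactions = {}
    for colony_id, ids in colony.groupby(colony).groups.items():
        sub = det[det["worker_id"].isin(set(ids) & set(kept))]
        interactions[colony_id] = tracking.detect_interactions(
            sub,
            dataset.config.body,
            gap_bridge=config.gap_bridge,
            mode=config.interaction_mode,
        )
    results["kept_workers"] = kept
    results["foraging"] = foraging
    results["interactions"] = interactions

    # 3. social maturity
    maturity, facet_models = compute_maturity(
        interactions,
        foraging,
        seed=seeds[1],
        n_restarts=config.facetnet_restarts,
        max_iter=config.facetnet_max_iter,
        tol=config.facetnet_tol,
    )
    results["maturity"] = maturity
    results["facetnet"] = facet_models
    results["maturity_diagnostic"] = maturity_distribution_diagnostic(maturity)

    # 4. layers, multiplex, correlation network
    scores, diagnostics = compute_layer_scores(dataset, maturity, foraging, spatial)
    results["scores"] = scores
    results["score_diagnostics"] = diagnostics
    layer_weights = {
        "social": _pooled_interactions(interactions),
        "behavior": multiplex.similarity_layer(
            tracking.normalize_behaviors(
                _behaviors_with_foraging(dataset, foraging, maturity.index),
                colony.reindex(maturity.index),
            )
        ),
        "expression": multiplex.similarity_layer(_expression_profiles(dataset, maturity.index)),
        "microbiota": multiplex.similarity_layer(
            _microbiota_profiles(dataset, maturity.index)
        ),
        "physical": multiplex.similarity_layer(
            _physical_profiles(spatial, maturity.index)
        ),
    }
    results["multiplex"] = multiplex.build_multiplex(layer_weights)
    corrnet = multiplex.interlayer_r2_network(scores, colony.reindex(scores.index))
    results["corrnet"] = corrnet

    # mixed-model regressions with colony as a random factor
    cidx = colony.reindex(scores.index).to_numpy()
    results["lmer_age"] = multiplex.random_intercept_fit(
        scores["social"], scores["age"], cidx
    )
    results["lmer_foraging"] = multiplex.random_intercept_fit(
        scores["social"], foraging.reindex(scores.index), cidx
    )

    # 5. DE accounting
    if config.run_de:
        counts = dataset.expression[scores.index]
        variables = scores[["social", "behavior", "age", "physical", "microbiota"]]
        results["de_accounting"] = diffexpr.de_accounting(
            counts,
            variables,
            colony.reindex(scores.index),
            alpha=config.de_alpha,
            min_total=config.de_min_total,
        )

    # 6. prediction
    if config.run_prediction:
        counts = diffexpr.filter_low_count_genes(
            dataset.expression[scores.index], config.de_min_total
        )
        rng = np.random.default_rng(seeds[2])
        permuted = pd.Series(
            rng.permutation(scores["social"].to_numpy()),
            index=scores.index,
            name="permuted",
        )
        targets = {
            "social": scores["social"],
            "behavior_pc1": scores["behavior"],
            "age": scores["age"],
        }
        preds = {}
        social_genes = None
        for i, (name, target) in enumerate(targets.items()):
            target = target.rename(name)
            try:
                est = prediction.IteratedSVRPredictor(
                    n_iterations=config.prediction_iterations,
                    random_state=seeds[3] + i,
                ).fit(counts, target, colony=colony.reindex(scores.index))
            except ValueError as exc:  # e.g. no DE genes for this target
                warnings.warn(f"prediction skipped for {name}: {exc}")
                continue
            preds[name] = est.result_
            if name == "social":
                social_genes = est.genes_
        if social_genes is not None:
            # permutation null: the social feature set with a permuted target
            preds["permuted"] = prediction.iterate_prediction(
                counts,
                permuted,
                colony.reindex(scores.index),
                n_iterations=config.prediction_iterations,
                seed=seeds[3] + len(targets),
                feature_genes=social_genes,
            )
        results["prediction"] = preds

    if outdir is not None:
        _write_run(Path(outdir), config, results)
    return results


# -- profile helpers -----------------------------------------------------------


def _pooled_interactions(interactions: dict) -> pd.DataFrame:
    ids = sorted({w for W in interactions.values() for w in W.index})
    big = pd.DataFrame(0.0, index=ids, columns=ids)
    for W in interactions.values():
        big.loc[W.index, W.columns] = W.to_numpy(dtype=float)
    return big


def _behaviors_with_foraging(dataset, foraging, workers):
    behav = dataset.behaviors.reindex(workers).copy()
    behav["foraging"] = foraging.reindex(workers)
    return behav


def _expression_profiles(dataset, workers):
    counts = dataset.expression[workers]
    sf = diffexpr.size_factors(counts)
    log = np.log2(counts.to_numpy(dtype=float) / sf.to_numpy()[None, :] + 1.0)
    log = log - log.mean(axis=1, keepdims=True)  # gene-centred
    return pd.DataFrame(log.T, index=workers, columns=counts.index)


def _microbiota_profiles(dataset, workers):
    kept, _ = microbiota.exclude_endosymbiont(dataset.microbiota[workers], dataset.taxonomy)
    return microbiota.relative_abundance(kept).T


def _physical_profiles(spatial, workers):
    phys = spatial.counts.reindex(workers).fillna(0.0)
    totals = phys.sum(axis=1)
    return phys.div(totals.where(totals > 0, 1.0), axis=0)


def _write_run(outdir: Path, config: RunConfig, results: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    results["dataset"].write(outdir / "data")
    results["maturity"].rename("maturity").to_csv(outdir / "maturity.csv")
    results["scores"].to_csv(outdir / "layer_scores.csv")
    results["corrnet"].mean.to_csv(outdir / "correlation_network.csv")
    for name, mat in results["corrnet"].per_colony.items():
        mat.to_csv(outdir / f"correlation_network_{name}.csv")
    for layer, edges in results["multiplex"].edges.items():
        pd.DataFrame(edges, columns=["worker_i", "worker_j"]).to_csv(
            outdir / f"edges_{layer}.csv", index=False
        )
    for colony_id, W in results["interactions"].items():
        iu, ju = np.triu_indices(len(W), k=1)
        w = W.to_numpy()[iu, ju]
        keep = w > 0
        pd.DataFrame(
            {
                "worker_i": np.asarray(W.index)[iu[keep]],
                "worker_j": np.asarray(W.index)[ju[keep]],
                "weight": w[keep],
            }
        ).to_csv(outdir / f"interactions_{colony_id}.csv", index=False)
    if "de_accounting" in results:
        results["de_accounting"].table.to_csv(outdir / "de_accounting.csv")
    if "prediction" in results:
        pd.DataFrame(
            {name: res.r2 for name, res in results["prediction"].items()}
        ).to_csv(outdir / "prediction_r2.csv", index=False)

    strength = results["corrnet"].strength
    ranking = strength.sort_values(ascending=False)
    report = [
        f"hub variable: {results['corrnet'].hub}",
        "strength ranking: " + ", ".join(f"{k}={v:.3f}" for k, v in ranking.items()),
        f"maturity U-shape ratio: {results['maturity_diagnostic']['u_ratio']:.3f}",
        "LMER maturity~age: R2={r2:.3f} t={t:.2f}".format(**results["lmer_age"]),
        "LMER maturity~foraging: R2={r2:.3f} t={t:.2f}".format(**results["lmer_foraging"]),
    ]
    if "prediction" in results:
        means = {k: v.mean for k, v in results["prediction"].items()}
        report.append(
            "prediction mean R2: "
            + ", ".join(f"{k}={v:.3f}" for k, v in sorted(means.items(), key=lambda kv: -kv[1]))
        )
    (outdir / "report.txt").write_text("\n".join(report) + "\n")

    manifest = {
        "master_seed": config.master_seed,
        "colony_config": config.colony.to_dict(),
        "gap_bridge": config.gap_bridge,
        "interaction_mode": config.interaction_mode,
        "facetnet": {
            "restarts": config.facetnet_restarts,
            "max_iter": config.facetnet_max_iter,
            "tol": config.facetnet_tol,
        },
        "de_alpha": config.de_alpha,
        "prediction_iterations": config.prediction_iterations,
        "hub": results["corrnet"].hub,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
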