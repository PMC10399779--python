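"""Synthetic colony generator.

Produces datasets with the statistical structure the downstream analysis
assumes, so every stage of the pipeline is testable without any external
download.  A single latent "social maturity" score per worker, drawn from a
U-shaped Beta law, drives: position in a two-community interaction network,
time spent in the foraging arena, task behaviour counts, age (to a target
correlation), maturity-responsive brain gene expression, and the relative
abundance of a handful of minor gut taxa on top of a dominant intracellular
endosymbiont.

Two routes to an interaction network are provided: the full route simulates
trajectories in a two-chamber setup and lets the tracking module detect
head-overlap contacts; a fast path draws pairwise interaction counts directly
from a weighted two-community Poisson model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ArenaGeometry, ColonyConfig

MANUAL_BEHAVIORS = ["queen_tending", "guarding", "nursing", "cleaning", "trophallaxis"]
BEHAVIORS = ["foraging"] + MANUAL_BEHAVIORS


@dataclass
class ColonyDataset:
    """A simulated multi-colony dataset with its ground truth.

    Attributes
    ----------
    workers : DataFrame
        One row per worker: worker_id, colony_id, age_weeks, batch_id and the
        latent maturity ``m`` in [0, 1] (the ground-truth counterpart of the
        social maturity score recovered downstream).
    detections : DataFrame
        Frame-level tag detections (frame, worker_id, x_mm, y_mm, theta_rad,
        present).
    behaviors : DataFrame
        Per-worker foraging fraction plus 5 manual behaviour counts out of
        ``n_sampled_frames``.
    expression : DataFrame
        gene x worker integer counts.
    microbiota : DataFrame
        ASV x worker integer counts.
    taxonomy : DataFrame
        ASV sidecar: label and endosymbiont flag.
    truth : dict
        'maturity' (Series per worker) and 'beta' (Series of per-gene log2
        fold changes per unit maturity; nonzero exactly for planted genes).
    """

    config: ColonyConfig
    workers: pd.DataFrame
    detections: pd.DataFrame
    behaviors: pd.DataFrame
    expression: pd.DataFrame
    microbiota: pd.DataFrame
    taxonomy: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Write all tables as headered CSV files (coordinates in mm)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.workers.to_csv(outdir / "workers.csv", index=False)
        self.detections.to_csv(outdir / "detections.csv", index=False)
        self.behaviors.to_csv(outdir / "behaviors.csv")
        self.expression.to_csv(outdir / "gene_counts.csv")
        self.microbiota.to_csv(outdir / "asv_counts.csv")
        self.taxonomy.to_csv(outdir / "taxonomy.csv", index=False)
        truth = self.workers[["worker_id", "maturity"]].copy()
        truth.to_csv(outdir / "truth_maturity.csv", index=False)
        pd.DataFrame(
            {"gene": self.truth["beta"].index, "beta": self.truth["beta"].values}
        ).to_csv(outdir / "truth_beta.csv", index=False)


def _sample_maturity(rng: np.random.Generator, n: int, alpha: float, beta: float):
    if alpha <= 0 or beta <= 0:
        raise ValueError("Beta law parameters must be positive")
    return rng.beta(alpha, beta, size=n)


def _ages_from_maturity(rng, m, target_r):
    """Noisy rank-preserving-in-expectation transform of maturity into weeks.

    age score = r * standardized(m) + sqrt(1 - r^2) * N(0,1), mapped linearly
    to a plausible 1..52-week range, so the population Pearson correlation with
    maturity equals the target.
    """
    m = np.asarray(m, dtype=float)
    sd = m.std()
    z = (m - m.mean()) / (sd if sd > 0 else 1.0)
    score = target_r * z + np.sqrt(max(0.0, 1.0 - target_r**2)) * rng.standard_normal(
        m.size
    )
    age = 26.0 + 11.0 * score
    return np.clip(np.round(age), 1, 52).astype(int)


def generate_workers(config: ColonyConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for c in range(config.n_colonies):
        n = config.n_workers_per_colony
        m = _sample_maturity(rng, n, config.maturity_alpha, config.maturity_beta)
        age = _ages_from_maturity(rng, m, config.age_maturity_correlation)
        for w in range(n):
            rows.append(
                {
                    "worker_id": f"c{c + 1}_w{w + 1:03d}",
                    "colony_id": f"colony_{c + 1}",
                    "age_weeks": age[w],
                    "maturity": m[w],
                }
            )
    workers = pd.DataFrame(rows)
    # extraction batches cut across colonies, as in a molecular-lab workflow
    workers["batch_id"] = [
        f"batch_{b + 1}" for b in rng.integers(0, config.n_batches, size=len(workers))
    ]
    return workers


def generate_trajectories(
    workers: pd.DataFrame,
    config: ColonyConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Role-switching biased random walks in the two-chamber setup.

    Each worker alternates between a nurse role and a forager role, taking
    the forager role with probability equal to its maturity at every
    re-draw.  Roles pull workers toward role-specific sites (brood pile vs.
    foraging grounds), so two workers' contact rate is approximately
    bilinear in their community memberships — the overlapping two-community
    structure of real colony interaction networks.  Forager-role workers are
    mostly in the arena, so arena occupancy rises with maturity.  Occasional
    chamber-wide excursions create the background of passing-by contacts,
    and each worker has a per-frame detection probability (a small fraction
    of "bad tags" is much lower, mimicking workers later excluded by the
    detection filter).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    geom = config.geometry
    frames_out = []
    for colony_id, grp in workers.groupby("colony_id", sort=True):
        m = grp["maturity"].to_numpy()
        n = len(grp)
        switch = 0.08  # per-frame propensity to re-draw role and chamber
        # detection probability; a few workers carry unreadable tags
        det_p = np.full(n, 1.0 - config.miss_rate)
        bad = rng.random(n) < config.bad_tag_fraction
        det_p[bad] = rng.uniform(0.2, 0.6, size=bad.sum())

        # shared anchor sites (mm): the brood area in the nest and the food
        # source in the arena; both roles congregate at the same places, so
        # position reveals chamber choice but not task role — whom a worker
        # engages there does
        site_x = {
            ("nurse", False): 60.0, ("forager", False): 60.0,
            ("nurse", True): 290.0, ("forager", True): 290.0,
        }
        site_y = {
            ("nurse", False): 60.0, ("forager", False): 60.0,
            ("nurse", True): 60.0, ("forager", True): 60.0,
        }
        jit_x = rng.normal(0, 10, n)
        jit_y = rng.normal(0, 10, n)
        # shared landmarks (trash pile, water source, wall corners) visited
        # according to strong worker-specific preferences independent of
        # maturity: idiosyncratic site fidelity that the spatial profile
        # records but that carries no task information
        p_personal = 0.25
        n_landmarks = 4
        lm_x = {
            False: rng.uniform(geom.nest.x_min + 15, geom.nest.x_max - 15, n_landmarks),
            True: rng.uniform(geom.arena.x_min + 15, geom.arena.x_max - 15, n_landmarks),
        }
        lm_y = {
            False: rng.uniform(geom.nest.y_min + 15, geom.nest.y_max - 15, n_landmarks),
            True: rng.uniform(geom.nest.y_min + 15, geom.nest.y_max - 15, n_landmarks),
        }
        lm_pref = rng.dirichlet(np.full(n_landmarks, 0.3), size=n)
        lm_choice = np.array(
            [rng.choice(n_landmarks, p=lm_pref[i]) for i in range(n)]
        )
        pers_x = {c: lm_x[c][lm_choice] for c in (False, True)}
        pers_y = {c: lm_y[c][lm_choice] for c in (False, True)}

        def anchors(forager_role, in_arena, personal):
            ax = np.where(
                in_arena,
                np.where(forager_role, site_x[("forager", True)], site_x[("nurse", True)]),
                np.where(forager_role, site_x[("forager", False)], site_x[("nurse", False)]),
            )
            ay = np.where(
                in_arena,
                np.where(forager_role, site_y[("forager", True)], site_y[("nurse", True)]),
                np.where(forager_role, site_y[("forager", False)], site_y[("nurse", False)]),
            )
            px = np.where(in_arena, pers_x[True], pers_x[False])
            py = np.where(in_arena, pers_y[True], pers_y[False])
            return (
                np.where(personal, px, ax + jit_x),
                np.where(personal, py, ay + jit_y),
            )

        # worker-specific arena attendance (light tolerance), independent of
        # maturity: how often a forager-role worker actually crosses into the
        # lit arena varies idiosyncratically, so space use is a noisier
        # readout of task role than the interaction partners a worker chooses
        arena_tol = rng.uniform(0.45, 1.0, n)

        forager_role = rng.random(n) < m
        personal = rng.random(n) < p_personal
        in_arena = rng.random(n) < np.where(forager_role, 0.8 * arena_tol, 0.05)
        ax, ay = anchors(forager_role, in_arena, personal)
        x = ax + rng.normal(0, 10, n)
        y = ay + rng.normal(0, 10, n)
        theta = rng.uniform(-np.pi, np.pi, n)

        pad = 2.0
        excursion = 0.03  # chance of a chamber-wide excursion per frame
        encounter_rate = 0.35  # per-frame chance of seeking a partner
        cross_role_affinity = 0.10  # acceptance of a cross-community partner
        xs = np.empty((config.n_frames, n))
        ys = np.empty((config.n_frames, n))
        thetas = np.empty((config.n_frames, n))
        present = np.empty((config.n_frames, n), dtype=bool)
        for t in range(config.n_frames):
            redraw = rng.random(n) < switch
            forager_role = np.where(redraw, rng.random(n) < m, forager_role)
            personal = np.where(redraw, rng.random(n) < p_personal, personal)
            in_arena = np.where(
                redraw,
                rng.random(n) < np.where(forager_role, 0.8 * arena_tol, 0.05),
                in_arena,
            )
            ax, ay = anchors(forager_role, in_arena, personal)
            x = x + 0.2 * (ax - x) + rng.normal(0, 9, n)
            y = y + 0.2 * (ay - y) + rng.normal(0, 9, n)
            lo_x = np.where(in_arena, geom.arena.x_min, geom.nest.x_min) + pad
            hi_x = np.where(in_arena, geom.arena.x_max, geom.nest.x_max) - pad
            # occasional excursions anywhere in the current chamber mix the
            # communities, mimicking passing-by encounters
            wander = rng.random(n) < excursion
            x = np.where(wander, rng.uniform(lo_x, hi_x), x)
            y = np.where(
                wander,
                rng.uniform(geom.nest.y_min + pad, geom.nest.y_max - pad),
                y,
            )
            x = np.clip(x, lo_x, hi_x)
            y = np.clip(y, geom.nest.y_min + pad, geom.nest.y_max - pad)
            theta = np.mod(theta + rng.normal(0, 0.6, n) + np.pi, 2 * np.pi) - np.pi

            # directed encounter events: workers actively engage partners
            # (trophallaxis, antennation), preferentially within their role
            # community; the pair meets head-to-head for this frame
            cand = np.flatnonzero(rng.random(n) < encounter_rate)
            cand = rng.permutation(cand)
            for a, b in zip(cand[0::2], cand[1::2]):
                if in_arena[a] != in_arena[b]:
                    continue
                match = 1.0 if forager_role[a] == forager_role[b] else cross_role_affinity
                if rng.random() >= match:
                    continue
                phi = rng.uniform(-np.pi, np.pi)
                theta[a] = phi
                theta[b] = np.mod(phi + 2 * np.pi, 2 * np.pi) - np.pi  # facing back
                gap = 2.0 * config.body.head_offset
                x[b] = np.clip(x[a] + gap * np.cos(phi), lo_x[b], hi_x[b])
                y[b] = np.clip(
                    y[a] + gap * np.sin(phi),
                    geom.nest.y_min + pad,
                    geom.nest.y_max - pad,
                )

            xs[t], ys[t], thetas[t] = x, y, theta
            present[t] = rng.random(n) < det_p

        ids = grp["worker_id"].to_numpy()
        frame_idx = np.repeat(np.arange(config.n_frames), n)
        frames_out.append(
            pd.DataFrame(
                {
                    "frame": frame_idx,
                    "worker_id": np.tile(ids, config.n_frames),
                    "x_mm": xs.ravel(),
                    "y_mm": ys.ravel(),
                    "theta_rad": thetas.ravel(),
                    "present": present.ravel(),
                }
            )
        )
    return pd.concat(frames_out, ignore_index=True)


def generate_behaviors(
    workers: pd.DataFrame, config: ColonyConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Manual task-behaviour counts out of n_sampled_frames, plus a foraging
    fraction drawn as an increasing noisy function of maturity.

    Nursing and queen-tending decrease with maturity; guarding, cleaning and
    trophallaxis depend on it only weakly.  Behaviour is a *noisy* readout of
    maturity: a per-worker behavioural disposition shared across the manual
    behaviours (individual idiosyncrasy that sparse frame annotation cannot
    average away) shifts the worker's apparent position on the nurse-forager
    axis, and a Beta jitter adds per-behaviour heterogeneity on top of
    binomial annotation noise.
    """
    m = workers["maturity"].to_numpy()
    n = len(workers)
    ns = config.n_sampled_frames

    # shared behavioural disposition: correlated noise across the manual
    # behaviours, so the behaviour profile is a degraded proxy of maturity
    m_beh = np.clip(m + 0.30 * rng.standard_normal(n), 0.0, 1.0)

    def binom_counts(p, kappa=12.0):
        p = np.clip(p, 1e-3, 1 - 1e-3)
        p_eff = rng.beta(kappa * p, kappa * (1 - p))
        return rng.binomial(ns, p_eff)

    out = pd.DataFrame(index=workers["worker_id"])
    # foraging fraction bounded by [0,1]; arena time rises steeply with maturity
    f = np.clip(0.05 + 0.75 * m, 1e-3, 1 - 1e-3)
    out["foraging"] = rng.beta(25 * f, 25 * (1 - f))
    out["queen_tending"] = binom_counts(0.30 * (1 - m_beh) + 0.02)
    out["guarding"] = binom_counts(0.06 + 0.04 * m_beh)
    out["nursing"] = binom_counts(0.70 * (1 - m_beh) + 0.03)
    out["cleaning"] = binom_counts(0.10 + 0.02 * (1 - m_beh))
    out["trophallaxis"] = binom_counts(0.12 + 0.05 * m_beh)
    return out


def generate_expression(
    workers: pd.DataFrame, config: ColonyConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial gene x worker counts.

    mean_gw = s_w * q_g * 2^(beta_g * m_w + B_{g, batch(w)}) with beta_g equal
    to the configured effect size for the first n_de_genes genes and zero
    otherwise.  Batch effects are gene-specific so that technical batch, not
    sequencing depth, dominates the leading principal component of the
    normalized expression matrix.
    """
    n_w = len(workers)
    g = config.n_genes
    m = workers["maturity"].to_numpy()
    batch_idx = (
        workers["batch_id"].str.replace("batch_", "", regex=False).astype(int) - 1
    ).to_numpy()

    s_w = np.exp(rng.normal(0.0, 0.15, size=n_w))
    q_g = np.exp(rng.normal(np.log(config.mean_expression), 1.2, size=g))
    beta = np.zeros(g)
    beta[: config.n_de_genes] = config.de_effect_size
    B = rng.normal(0.0, config.batch_effect_sd, size=(g, config.n_batches))

    log2_mu = (
        np.log2(q_g)[:, None]
        + beta[:, None] * m[None, :]
        + B[:, batch_idx]
        + np.log2(s_w)[None, :]
    )
    mu = np.exp2(log2_mu)
    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    genes = [f"gene_{i + 1:05d}" for i in range(g)]
    expr = pd.DataFrame(counts, index=genes, columns=workers["worker_id"])
    return expr, pd.Series(beta, index=genes, name="beta")


def generate_microbiota(
    workers: pd.DataFrame, config: ColonyConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dirichlet-multinomial ASV counts dominated by one endosymbiont.

    The endosymbiont's Dirichlet weight is fixed at the configured fraction of
    the total concentration, so its expected relative abundance equals
    ``endosymbiont_fraction`` for every worker.  A configurable number of
    minor taxa have weights that rise exponentially with maturity, emulating
    forager-associated facultative species.
    """
    n_w = len(workers)
    a = config.n_asvs
    m = workers["maturity"].to_numpy()
    tau = config.dirichlet_concentration

    base = np.exp(rng.normal(0.0, 1.0, size=a - 1))  # minor-taxon base weights
    slope = np.zeros(a - 1)
    slope[: config.n_maturity_asvs] = 2.5
    minor = base[:, None] * np.exp(slope[:, None] * m[None, :])
    minor *= (1.0 - config.endosymbiont_fraction) * tau / minor.sum(axis=0)

    conc = np.vstack([np.full((1, n_w), config.endosymbiont_fraction * tau), minor])
    depth = rng.poisson(config.microbiota_depth, size=n_w)
    counts = np.empty((a, n_w), dtype=int)
    for w in range(n_w):
        p = rng.dirichlet(conc[:, w])
        counts[:, w] = rng.multinomial(depth[w], p)

    asv_ids = [f"asv_{i + 1:03d}" for i in range(a)]
    labels = ["Blochmannia-like endosymbiont"]
    labels += [
        "Acetobacteraceae sp." if i < config.n_maturity_asvs else f"facultative taxon {i + 1}"
        for i in range(a - 1)
    ]
    taxonomy = pd.DataFrame(
        {
            "asv_id": asv_ids,
            "label": labels,
            "endosymbiont": [True] + [False] * (a - 1),
        }
    )
    micro = pd.DataFrame(counts, index=asv_ids, columns=workers["worker_id"])
    return micro, taxonomy


def generate_colony(config: ColonyConfig | None = None, **overrides) -> ColonyDataset:
    """Generate a full multi-colony dataset from one config (deterministic in
    ``config.seed``)."""
    if config is None:
        config = ColonyConfig(**overrides)
    elif overrides:
        raise TypeError("pass either a config or keyword overrides, not both")
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(5)]

    workers = generate_workers(config, rngs[0])
    detections = generate_trajectories(workers, config, rng=rngs[1])
    behaviors = generate_behaviors(workers, config, rngs[2])
    expression, beta = generate_expression(workers, config, rngs[3])
    microbiota, taxonomy = generate_microbiota(workers, config, rngs[4])

    truth = {
        "maturity": workers.set_index("worker_id")["maturity"],
        "beta": beta,
    }
    return ColonyDataset(
        config=config,
        workers=workers,
        detections=detections,
        behaviors=behaviors,
        expression=expression,
        microbiota=microbiota,
        taxonomy=taxonomy,
        truth=truth,
    )


def generate_interaction_network(
    maturity: np.ndarray,
    mean_strength: float = 20.0,
    epsilon: float = 0.05,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Fast path: draw a symmetric interaction-count matrix directly from the
    weighted two-community model

        w_ij ~ Poisson(lambda * [m_i m_j + (1 - m_i)(1 - m_j) + epsilon]),

    with lambda set so the expected node strength (sum of incident counts)
    equals ``mean_strength``.  Bypasses trajectory simulation for tests that
    exercise community recovery alone.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    m = np.asarray(maturity, dtype=float)
    n = m.size
    affinity = np.outer(m, m) + np.outer(1 - m, 1 - m) + epsilon
    np.fill_diagonal(affinity, 0.0)
    lam = mean_strength / affinity.sum(axis=1).mean()
    upper = np.triu_indices(n, k=1)
    w = np.zeros((n, n))
    draws = rng.poisson(lam * affinity[upper])
    w[upper] = draws
    w += w.T
    return w
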