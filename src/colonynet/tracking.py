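"""Frame-level detections -> behavioural and environmental descriptors.

Implements the tracking-derived features of the analysis: pairwise
head-overlap interaction networks, hexagonal space-use ("spatial fidelity")
profiles, exclusion of poorly detected workers, the automatically quantified
foraging fraction, and within-colony min-max normalization of task-behaviour
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ArenaGeometry, BodyGeometry

__all__ = [
    "detect_interactions",
    "spatial_fidelity",
    "filter_low_detection",
    "foraging_fraction",
    "normalize_behaviors",
    "SpatialProfile",
]


def _frame_arrays(frames: pd.DataFrame):
    """Pivot a detections table into dense (n_frames, n_workers) arrays.

    Workers are ordered by sorted id; frames by index.  Rows with
    ``present == False`` and missing (frame, worker) combinations both count
    as absent.
    """
    det = frames[frames["present"]] if "present" in frames else frames
    workers = np.array(sorted(frames["worker_id"].unique()))
    widx = {w: i for i, w in enumerate(workers)}
    frame_ids = np.sort(frames["frame"].unique())
    fidx = {f: i for i, f in enumerate(frame_ids)}
    F, n = len(frame_ids), len(workers)
    x = np.full((F, n), np.nan)
    y = np.full((F, n), np.nan)
    theta = np.full((F, n), np.nan)
    present = np.zeros((F, n), dtype=bool)
    fi = det["frame"].map(fidx).to_numpy()
    wi = det["worker_id"].map(widx).to_numpy()
    x[fi, wi] = det["x_mm"].to_numpy()
    y[fi, wi] = det["y_mm"].to_numpy()
    theta[fi, wi] = det["theta_rad"].to_numpy()
    present[fi, wi] = True
    return workers, frame_ids, x, y, theta, present


def _count_bouts(contact: np.ndarray, gap_bridge: int) -> np.ndarray:
    """Count maximal contact runs along axis 0, merging runs separated by at
    most ``gap_bridge`` non-contact frames.  ``contact`` is (F, n_pairs)."""
    F = contact.shape[0]
    idx = np.arange(F)[:, None]
    last = np.where(contact, idx, -(10**9))
    last = np.maximum.accumulate(last, axis=0)
    # index of the most recent contact strictly before t
    prev = np.vstack([np.full((1, contact.shape[1]), -(10**9)), last[:-1]])
    starts = contact & (idx - prev - 1 > gap_bridge)
    return starts.sum(axis=0)


def detect_interactions(
    frames: pd.DataFrame,
    geometry: BodyGeometry | None = None,
    gap_bridge: int = 0,
    mode: str = "head_head",
    chunk: int = 256,
) -> pd.DataFrame:
    """Infer the weighted interaction network from tag detections.

    A pair is in contact in a frame when both workers are detected and their
    head disks (centres at tag + head_offset along the body axis, radius
    head_radius) intersect; in mode ``head_or_body`` contact additionally
    occurs when either head disk intersects the other's body disk.  The edge
    weight w_ij is the number of contact bouts: maximal contact runs after
    merging runs separated by <= ``gap_bridge`` non-contact frames.

    Returns a symmetric integer DataFrame with zero diagonal, indexed by
    worker id.
    """
    if mode not in ("head_head", "head_or_body"):
        raise ValueError(f"unknown mode {mode!r}")
    if geometry is None:
        geometry = BodyGeometry()
    if frames.empty:
        return pd.DataFrame(dtype=int)
    workers, frame_ids, x, y, theta, present = _frame_arrays(frames)
    n = len(workers)
    if n < 2:
        return pd.DataFrame(
            np.zeros((n, n), dtype=int), index=workers, columns=workers
        )
    hx = x + geometry.head_offset * np.cos(theta)
    hy = y + geometry.head_offset * np.sin(theta)
    iu, ju = np.triu_indices(n, k=1)
    F = x.shape[0]
    bouts = np.zeros(len(iu), dtype=int)
    r_hh = 2 * geometry.head_radius
    r_hb = geometry.head_radius + geometry.body_radius

    contact_all = np.empty((F, len(iu)), dtype=bool)
    for lo in range(0, F, chunk):
        hi = min(lo + chunk, F)
        both = present[lo:hi, iu] & present[lo:hi, ju]
        d_hh = np.hypot(
            hx[lo:hi, iu] - hx[lo:hi, ju], hy[lo:hi, iu] - hy[lo:hi, ju]
        )
        c = d_hh <= r_hh
        if mode == "head_or_body":
            d_hb = np.hypot(hx[lo:hi, iu] - x[lo:hi, ju], hy[lo:hi, iu] - y[lo:hi, ju])
            d_bh = np.hypot(x[lo:hi, iu] - hx[lo:hi, ju], y[lo:hi, iu] - hy[lo:hi, ju])
            c |= (d_hb <= r_hb) | (d_bh <= r_hb)
        contact_all[lo:hi] = np.where(both, c, False)
    bouts = _count_bouts(contact_all, gap_bridge)

    w = np.zeros((n, n), dtype=int)
    w[iu, ju] = bouts
    w += w.T
    return pd.DataFrame(w, index=workers, columns=workers)


# -- hexagonal spatial fidelity ------------------------------------------------

SQRT3 = np.sqrt(3.0)


def _xy_to_axial(x, y, size):
    """Fractional axial coordinates of flat-top hexagons with circumradius
    ``size``; grid anchored at the origin."""
    q = (2.0 / 3.0) * x / size
    r = (-x / 3.0 + SQRT3 / 3.0 * y) / size
    return q, r


def axial_to_xy(q, r, size):
    """Centres of flat-top hexagons in mm."""
    x = size * 1.5 * np.asarray(q, dtype=float)
    y = size * SQRT3 * (np.asarray(r, dtype=float) + np.asarray(q, dtype=float) / 2.0)
    return x, y


def cube_round(q, r):
    """Round fractional axial coordinates to the nearest hexagon by cube
    rounding with the largest-residual correction."""
    q = np.asarray(q, dtype=float)
    r = np.asarray(r, dtype=float)
    s = -q - r
    rq, rr, rs = np.round(q), np.round(r), np.round(s)
    dq, dr, ds = np.abs(rq - q), np.abs(rr - r), np.abs(rs - s)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    rq = np.where(fix_q, -rr - rs, rq)
    rr = np.where(fix_r, -rq - rs, rr)
    return rq.astype(int), rr.astype(int)


@dataclass
class SpatialProfile:
    """Worker x hexagon occupancy counts.

    ``counts`` rows are workers, columns are axial (q, r) cell coordinates;
    row sums equal each worker's number of detections.
    """

    counts: pd.DataFrame
    cell_diameter: float

    @property
    def cells(self) -> list[tuple[int, int]]:
        return list(self.counts.columns)


def spatial_fidelity(frames: pd.DataFrame, cell_diameter: float) -> SpatialProfile:
    """Bin detections into an equilateral grid of flat-top hexagons whose
    internal diameter (distance between parallel sides) is ``cell_diameter``
    mm — conventionally the mean ant body length."""
    if cell_diameter <= 0:
        raise ValueError("cell_diameter must be positive")
    det = frames[frames["present"]] if "present" in frames else frames
    size = cell_diameter / SQRT3  # circumradius of a flat-top hexagon
    qf, rf = _xy_to_axial(det["x_mm"].to_numpy(), det["y_mm"].to_numpy(), size)
    q, r = cube_round(qf, rf)
    tab = (
        pd.DataFrame({"worker_id": det["worker_id"].to_numpy(), "q": q, "r": r})
        .groupby(["worker_id", "q", "r"])
        .size()
        .unstack(["q", "r"], fill_value=0)
    )
    tab = tab.sort_index(axis=1)
    return SpatialProfile(counts=tab, cell_diameter=cell_diameter)


def filter_low_detection(
    frames: pd.DataFrame,
    colony: pd.Series | None = None,
    k_sd: float = 2.0,
) -> list:
    """Workers detected often enough to analyse.

    Within each colony, a worker is kept when its detection count is at least
    ``mean - k_sd * sd`` of the colony's counts (sample sd, n-1 denominator).
    Workers present in ``colony`` but never detected count as 0.  With a
    single worker (sd undefined) no exclusion is made.
    """
    det = frames[frames["present"]] if "present" in frames else frames
    counts = det.groupby("worker_id").size()
    if colony is None:
        colony = pd.Series("all", index=counts.index)
    counts = counts.reindex(colony.index, fill_value=0)
    kept: list = []
    for _, ids in colony.groupby(colony):
        c = counts.loc[ids.index]
        if len(c) < 2:
            kept.extend(c.index)
            continue
        threshold = c.mean() - k_sd * c.std(ddof=1)
        kept.extend(c.index[c >= threshold])
    return sorted(kept)


def foraging_fraction(
    frames: pd.DataFrame, geometry: ArenaGeometry | None = None
) -> pd.Series:
    """Fraction of a worker's detections that fall in the foraging arena."""
    if geometry is None:
        geometry = ArenaGeometry()
    det = frames[frames["present"]] if "present" in frames else frames
    if det.empty:
        return pd.Series(dtype=float, name="foraging")
    zone = geometry.classify(det["x_mm"].to_numpy(), det["y_mm"].to_numpy())
    in_arena = pd.Series(zone == "arena", index=det.index)
    grp = in_arena.groupby(det["worker_id"])
    frac = grp.sum() / grp.count()
    frac.name = "foraging"
    return frac


def normalize_behaviors(
    behaviors: pd.DataFrame, colony: pd.Series | None = None
) -> pd.DataFrame:
    """Min-max normalize each behaviour to [0, 1] within each colony.

    Constant columns map to 0, keeping downstream PCA input finite.
    """
    if colony is None:
        colony = pd.Series("all", index=behaviors.index)
    colony = colony.reindex(behaviors.index)

    def _minmax(block: pd.DataFrame) -> pd.DataFrame:
        lo = block.min()
        span = block.max() - lo
        out = (block - lo).div(span.where(span > 0, 1.0))
        out[span.index[span == 0]] = 0.0
        return out

    return (
        behaviors.groupby(colony, group_keys=False)
        .apply(_minmax)
        .reindex(behaviors.index)
    )
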