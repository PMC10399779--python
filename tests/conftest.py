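import numpy as np
import pandas as pd
import pytest

from colonynet.config import ColonyConfig
from colonynet.synthetic import generate_colony


@pytest.fixture(scope="session")
def tiny_config():
    """Small but complete colony configuration for fast unit tests."""
    return ColonyConfig(
        n_colonies=2,
        n_workers_per_colony=30,
        n_frames=200,
        n_genes=200,
        n_de_genes=20,
        n_asvs=12,
        n_maturity_asvs=3,
        microbiota_depth=5000,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return generate_colony(tiny_config)


@pytest.fixture(scope="session")
def default_dataset():
    """One dataset at the study-design scale (4 colonies x ~100 workers)."""
    return generate_colony(ColonyConfig(seed=5))


def make_detections(rows):
    """Build a detections frame from (frame, worker, x, y, theta) tuples."""
    return pd.DataFrame(
        [
            {
                "frame": f,
                "worker_id": w,
                "x_mm": x,
                "y_mm": y,
                "theta_rad": t,
                "present": True,
            }
            for f, w, x, y, t in rows
        ]
    )


def brute_force_interactions(frames, geometry, gap_bridge=0, mode="head_head"):
    """Independent per-frame disk-intersection oracle with explicit run
    counting; pure python, no vectorisation shared with the implementation."""
    det = frames[frames["present"]]
    workers = sorted(frames["worker_id"].unique())
    contact_frames = {}
    for f, grp in det.groupby("frame"):
        recs = {r.worker_id: r for r in grp.itertuples()}
        ids = sorted(recs)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = recs[ids[i]], recs[ids[j]]
                hax = a.x_mm + geometry.head_offset * np.cos(a.theta_rad)
                hay = a.y_mm + geometry.head_offset * np.sin(a.theta_rad)
                hbx = b.x_mm + geometry.head_offset * np.cos(b.theta_rad)
                hby = b.y_mm + geometry.head_offset * np.sin(b.theta_rad)
                touch = np.hypot(hax - hbx, hay - hby) <= 2 * geometry.head_radius
                if mode == "head_or_body":
                    touch = touch or (
                        np.hypot(hax - b.x_mm, hay - b.y_mm)
                        <= geometry.head_radius + geometry.body_radius
                    ) or (
                        np.hypot(a.x_mm - hbx, a.y_mm - hby)
                        <= geometry.head_radius + geometry.body_radius
                    )
                if touch:
                    contact_frames.setdefault((ids[i], ids[j]), []).append(f)
    W = pd.DataFrame(0, index=workers, columns=workers)
    for (i, j), fr in contact_frames.items():
        fr = sorted(fr)
        bouts = 1
        for prev, cur in zip(fr, fr[1:]):
            if cur - prev - 1 > gap_bridge:
                bouts += 1
        W.loc[i, j] = W.loc[j, i] = bouts
    return W
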