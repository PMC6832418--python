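"""Shared fixtures and the independent brute-force feature oracle.

The oracle recomputes every feature with O(N^2) all-pairs neighbor
search and direct per-neighborhood covariance/percentile arithmetic —
no KD-trees, no chunking, no reduceat — so it shares no code path with
the production transformer it checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mscloud import PointCloud, ScaleLadder, balanced_sample, extract
from mscloud.cloud import feature_names
from mscloud.scenes import SceneRecipe, build_scene, spatial_split


def brute_force_features(
    cloud: PointCloud, ladder: ScaleLadder, min_neighbors: int = 3
) -> pd.DataFrame:
    """Reference implementation: naive neighbor search + direct covariance."""
    coords = cloud.coords
    n = len(cloud)
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    dist_xy = np.linalg.norm(
        coords[:, None, :2] - coords[None, :, :2], axis=2
    )
    out = np.zeros((n, 5 * len(ladder)))
    for s, diameter in enumerate(ladder):
        r = diameter / 2.0
        for i in range(n):
            nbr = coords[dist[i] <= r]
            col_z = coords[dist_xy[i] <= r, 2]
            lo, hi = np.percentile(col_z, [5, 95])
            percz = hi - lo
            feats = np.array([0.0, 0.0, 0.0, 0.0, percz])
            if len(nbr) >= min_neighbors:
                centered = nbr - nbr.mean(axis=0)
                cov = centered.T @ centered / len(nbr)
                w, v = np.linalg.eigh(cov)
                l3, l2, l1 = np.clip(w, 0, None)
                if l1 > 0:
                    hor = np.degrees(np.arccos(min(abs(v[2, 0]), 1.0)))
                    feats[:4] = [
                        (l1 - l2) / l1, (l2 - l3) / l1, l3 / l1, hor,
                    ]
            out[i, 5 * s : 5 * (s + 1)] = feats
    return pd.DataFrame(out, columns=feature_names(ladder))


@pytest.fixture(scope="session")
def random_cloud_500() -> PointCloud:
    rng = np.random.default_rng(20260927)
    return PointCloud(rng.uniform(-1.0, 1.0, size=(500, 3)))


@pytest.fixture(scope="session")
def small_ladder() -> ScaleLadder:
    return ScaleLadder((0.2, 0.5))


@pytest.fixture(scope="session")
def forest_run():
    """Full-size forest scene with features and a spatial split (seed 1).

    Session-scoped because the ~50k-point extraction is the most
    expensive step in the suite; several end-to-end tests share it.
    """
    cloud = build_scene(SceneRecipe(scenario="forest", seed=1))
    feats = extract(cloud)
    train_idx, test_idx = spatial_split(cloud)
    x, y, _ = balanced_sample(
        feats.iloc[train_idx], cloud.labels[train_idx], per_class=1000, seed=1
    )
    return {
        "cloud": cloud,
        "features": feats,
        "train_idx": train_idx,
        "test_idx": test_idx,
        "x_train": x,
        "y_train": y,
    }


@pytest.fixture(scope="session")
def small_forest_run():
    """Downscaled forest scene for cheap pipeline-level tests."""
    cloud = build_scene(
        SceneRecipe(scenario="forest", seed=7, density_scale=0.15)
    )
    feats = extract(cloud)
    train_idx, test_idx = spatial_split(cloud)
    return {
        "cloud": cloud,
        "features": feats,
        "train_idx": train_idx,
        "test_idx": test_idx,
    }
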