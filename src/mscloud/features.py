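"""Multiscale eigenvalue features for 3D point clouds.

For every point and every scale (sphere diameter) of a
:class:`~mscloud.cloud.ScaleLadder`, the local neighborhood — all points
within half the diameter of the query point — is summarized by the
eigendecomposition of its covariance matrix

    Sigma = (1/M) sum_i (p_i - p_bar)(p_i - p_bar)^T = V Lambda V^T,

with eigenvalues lambda1 >= lambda2 >= lambda3 >= 0.  The eigenvalue
ratios classify the local geometry: one dominant eigenvalue means a
linear (1D) structure, two a planar (2D) one, three comparable
eigenvalues a volumetric (3D) one.  Five features are assigned to the
centre point per scale:

======  =====================================  ==========================
name    formula                                range / units
======  =====================================  ==========================
L       (lambda1 - lambda2) / lambda1          [0, 1], linearity
PL      (lambda2 - lambda3) / lambda1          [0, 1], planarity
SPH     lambda3 / lambda1                      [0, 1], sphericity
HOR     arccos(|v3 . z_hat|)                   [0, 90] degrees
PERCZ   p95(Z) - p5(Z) in the vertical column  metres, >= 0
======  =====================================  ==========================

HOR measures how horizontal the local surface is: v3, the eigenvector of
the smallest eigenvalue, is the surface normal of a planar patch, so flat
ground scores ~0 deg and vertical walls or facades ~90 deg.  PERCZ is an
outlier-robust vertical extent, taken over all points whose *horizontal*
distance to the query point is within half the scale diameter (a vertical
cylinder, unbounded in Z); the 5th-95th percentile span resists stray
outlier returns.

Neighborhoods with fewer than ``min_neighbors`` points, or with a zero
leading eigenvalue, fall back to L = PL = SPH = 0 and HOR = 0 (PERCZ is
always computed): such points are isolated noise, and the zero vector
keeps them finite and distinguishable for the classifiers downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .cloud import FEATURE_BLOCK, PointCloud, ScaleLadder, feature_names

__all__ = [
    "NeighborhoodSpectrum",
    "MultiscaleFeatures",
    "neighborhood",
    "spectrum",
    "point_features",
    "z_range",
    "extract",
]

_PERCZ_LO, _PERCZ_HI = 5.0, 95.0  # percentile bounds of the Z-range feature


@dataclass(frozen=True)
class NeighborhoodSpectrum:
    """Eigendecomposition of a neighborhood covariance matrix.

    ``eigvals`` are descending and clamped at zero (m^2); ``eigvecs``
    holds the matching orthonormal eigenvectors as columns (v1, v2, v3);
    ``n_pts`` is the neighborhood size.
    """

    eigvals: tuple[float, float, float]
    eigvecs: np.ndarray
    n_pts: int


def neighborhood(
    cloud: PointCloud, index: int, diameter: float
) -> np.ndarray:
    """Indices of all points within ``diameter / 2`` of point ``index``.

    The query point itself is always a member (distance 0).
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    d = np.linalg.norm(cloud.coords - cloud.coords[index], axis=1)
    return np.flatnonzero(d <= diameter / 2.0)


def spectrum(points: np.ndarray) -> NeighborhoodSpectrum:
    """Eigendecomposition of the (1/M)-normalized covariance of ``points``.

    Eigenvalues come back descending; negative rounding artefacts are
    clipped to 0.  Rank-deficient sets (collinear, coplanar, M < 3) simply
    have trailing zero eigenvalues.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
        raise ValueError("points must be an (M, 3) array with M >= 1")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / pts.shape[0]
    w, v = np.linalg.eigh(cov)  # ascending
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    return NeighborhoodSpectrum(tuple(w), v, pts.shape[0])


def point_features(spec: NeighborhoodSpectrum, z_span: float) -> np.ndarray:
    """The five-feature vector ``(L, PL, SPH, HOR, PERCZ)`` of a spectrum.

    Degenerate spectra (lambda1 = 0) yield zeros for the four shape
    features; ``z_span`` passes through as PERCZ unconditionally.
    """
    l1, l2, l3 = spec.eigvals
    if l1 <= 0.0:
        return np.array([0.0, 0.0, 0.0, 0.0, z_span])
    v3 = spec.eigvecs[:, 2]
    hor = np.degrees(np.arccos(np.clip(abs(v3[2]), 0.0, 1.0)))
    return np.array([(l1 - l2) / l1, (l2 - l3) / l1, l3 / l1, hor, z_span])


def z_range(cloud: PointCloud, index: int, diameter: float) -> float:
    """5th-95th percentile span of Z in the vertical column around a point.

    The column is a vertical cylinder of the scale's diameter centred on
    the query point, unbounded in Z.  Percentiles use linear interpolation
    between order statistics.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    dxy = np.linalg.norm(
        cloud.coords[:, :2] - cloud.coords[index, :2], axis=1
    )
    z = cloud.coords[dxy <= diameter / 2.0, 2]
    lo, hi = np.percentile(z, [_PERCZ_LO, _PERCZ_HI])
    return float(hi - lo)


class MultiscaleFeatures(TransformerMixin, BaseEstimator):
    """Transformer computing the five features per point at every scale.

    Stateless apart from input validation: ``fit`` records the scale
    ladder, ``transform`` maps an (N, 3) coordinate array to an
    (N, 5 * S) feature matrix with columns ``L1, PL1, SPH1, HOR1, PERCZ1,
    L2, ...`` (scale 1 = smallest diameter).

    Parameters
    ----------
    scales : sequence of float, default the 6-rung 5 cm - 50 cm ladder
        Strictly increasing sphere diameters in metres.
    min_neighbors : int, default 3
        Neighborhoods smaller than this use the degenerate zero fallback
        for the shape features.
    chunk_size : int, default 20000
        Points processed per block; bounds the memory of the flattened
        neighbor lists without changing the result.
    """

    def __init__(
        self,
        scales: tuple[float, ...] = ScaleLadder().diameters,
        min_neighbors: int = 3,
        chunk_size: int = 20000,
    ):
        self.scales = scales
        self.min_neighbors = min_neighbors
        self.chunk_size = chunk_size

    def fit(self, X, y=None) -> "MultiscaleFeatures":
        self.ladder_ = ScaleLadder(tuple(self.scales))
        self.n_features_in_ = 3
        return self

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        check_is_fitted(self, "ladder_")
        return np.asarray(feature_names(self.ladder_), dtype=object)

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "ladder_")
        coords = np.asarray(X, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("X must be an (N, 3) coordinate array")
        if coords.shape[0] == 0:
            raise ValueError("cannot extract features from an empty cloud")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")

        n = coords.shape[0]
        tree3 = cKDTree(coords)
        tree2 = cKDTree(coords[:, :2])
        out = np.empty((n, 5 * len(self.ladder_)))
        for s, diameter in enumerate(self.ladder_):
            block = self._scale_block(coords, tree3, tree2, diameter)
            out[:, 5 * s : 5 * (s + 1)] = block
        return out

    # -- internals ---------------------------------------------------------

    def _scale_block(
        self,
        coords: np.ndarray,
        tree3: cKDTree,
        tree2: cKDTree,
        diameter: float,
    ) -> np.ndarray:
        """(N, 5) feature block for one scale, computed in chunks."""
        n = coords.shape[0]
        r = diameter / 2.0
        block = np.empty((n, 5))
        for start in range(0, n, self.chunk_size):
            stop = min(start + self.chunk_size, n)
            q = coords[start:stop]
            shape = self._shape_features(coords, tree3, q, r)
            percz = self._z_ranges(coords, tree2, q, r)
            block[start:stop, :4] = shape
            block[start:stop, 4] = percz
        return block

    def _shape_features(
        self,
        coords: np.ndarray,
        tree3: cKDTree,
        queries: np.ndarray,
        radius: float,
    ) -> np.ndarray:
        """L, PL, SPH, HOR for a chunk of query points (vectorized).

        Per-neighborhood first and second moments are accumulated with
        ``np.add.reduceat`` over the flattened neighbor lists, then a
        batched eigendecomposition of the stacked 3x3 covariances.
        """
        neigh = tree3.query_ball_point(queries, radius)
        counts = np.fromiter(
            (len(ix) for ix in neigh), dtype=np.int64, count=len(neigh)
        )
        flat = np.concatenate(
            [np.asarray(ix, dtype=np.int64) for ix in neigh]
        )
        offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))

        p = coords[flat]
        s1 = np.add.reduceat(p, offsets, axis=0)
        # unique second moments xx, yy, zz, xy, xz, yz
        prod = p[:, [0, 1, 2, 0, 0, 1]] * p[:, [0, 1, 2, 1, 2, 2]]
        s2 = np.add.reduceat(prod, offsets, axis=0)
        m = counts[:, None].astype(np.float64)
        mean = s1 / m
        c = s2 / m
        cov = np.empty((len(queries), 3, 3))
        cov[:, 0, 0] = c[:, 0] - mean[:, 0] ** 2
        cov[:, 1, 1] = c[:, 1] - mean[:, 1] ** 2
        cov[:, 2, 2] = c[:, 2] - mean[:, 2] ** 2
        cov[:, 0, 1] = cov[:, 1, 0] = c[:, 3] - mean[:, 0] * mean[:, 1]
        cov[:, 0, 2] = cov[:, 2, 0] = c[:, 4] - mean[:, 0] * mean[:, 2]
        cov[:, 1, 2] = cov[:, 2, 1] = c[:, 5] - mean[:, 1] * mean[:, 2]

        w, v = np.linalg.eigh(cov)  # ascending eigenvalues
        w = np.clip(w, 0.0, None)
        l1, l2, l3 = w[:, 2], w[:, 1], w[:, 0]
        v3z = np.abs(v[:, 2, 0])  # z component of smallest eigenvector

        ok = (counts >= self.min_neighbors) & (l1 > 0.0)
        feats = np.zeros((len(queries), 4))
        safe_l1 = np.where(ok, l1, 1.0)
        feats[:, 0] = np.where(ok, (l1 - l2) / safe_l1, 0.0)
        feats[:, 1] = np.where(ok, (l2 - l3) / safe_l1, 0.0)
        feats[:, 2] = np.where(ok, l3 / safe_l1, 0.0)
        feats[:, 3] = np.where(
            ok, np.degrees(np.arccos(np.clip(v3z, 0.0, 1.0))), 0.0
        )
        return feats

    def _z_ranges(
        self,
        coords: np.ndarray,
        tree2: cKDTree,
        queries: np.ndarray,
        radius: float,
    ) -> np.ndarray:
        neigh = tree2.query_ball_point(queries[:, :2], radius)
        z = coords[:, 2]
        out = np.empty(len(neigh))
        for i, ix in enumerate(neigh):
            lo, hi = np.percentile(z[ix], [_PERCZ_LO, _PERCZ_HI])
            out[i] = hi - lo
        return out


def extract(
    cloud: PointCloud,
    ladder: ScaleLadder | None = None,
    min_neighbors: int = 3,
) -> pd.DataFrame:
    """Feature matrix of ``cloud`` over ``ladder`` as a named DataFrame.

    Row i, scale block s holds the five features of point i computed in
    the sphere (and vertical column) of diameter ``ladder.diameters[s]``.
    Deterministic for fixed input.
    """
    ladder = ladder or ScaleLadder()
    tf = MultiscaleFeatures(scales=ladder.diameters, min_neighbors=min_neighbors)
    values = tf.fit(cloud.coords).transform(cloud.coords)
    return pd.DataFrame(values, columns=feature_names(ladder))
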