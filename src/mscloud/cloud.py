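"""Core in-memory containers: labeled point clouds and scale ladders.

A :class:`PointCloud` is an N×3 array of coordinates in metres (Z up) with
optional per-point integer class labels.  A :class:`ScaleLadder` is the
ordered list of sphere diameters that defines the multiscale analysis: each
diameter delimits the spherical neighborhood used for the local PCA around
every point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PointCloud:
    """A 3D point cloud with optional per-point class labels.

    Parameters
    ----------
    coords : (N, 3) float array
        Point coordinates in metres.  Axes are X (east-ish), Y (north-ish),
        Z (up).  Must be finite, N >= 1.
    labels : (N,) int array, optional
        Non-negative integer class id per point.
    class_names : dict, optional
        Mapping from class id to a human-readable name.  When given, every
        id occurring in ``labels`` must be present.
    """

    coords: np.ndarray
    labels: np.ndarray | None = None
    class_names: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(
                f"coords must be an (N, 3) array, got shape {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise ValueError("a point cloud must contain at least one point")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self),):
                raise ValueError(
                    f"labels length {self.labels.shape} does not match "
                    f"point count {len(self)}"
                )
            if np.any(self.labels < 0):
                raise ValueError("class labels must be non-negative integers")
            if self.class_names is not None:
                missing = set(np.unique(self.labels)) - set(self.class_names)
                if missing:
                    raise ValueError(
                        f"labels {sorted(missing)} missing from class_names"
                    )

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def has_labels(self) -> bool:
        return self.labels is not None

    def subset(self, index: np.ndarray) -> "PointCloud":
        """Return a new cloud restricted to the given point indices."""
        labels = self.labels[index] if self.labels is not None else None
        return PointCloud(self.coords[index], labels, self.class_names)


@dataclass(frozen=True)
class ScaleLadder:
    """Ordered list of sphere diameters (metres) for multiscale analysis.

    The neighborhood of a point at scale ``d`` is the set of points within
    Euclidean distance ``d / 2`` of it (the sphere of diameter ``d``
    centred on the point).  Diameters must be strictly increasing; scale
    indices are 1-based with scale 1 the smallest diameter.

    The default six-rung ladder spans 5 cm to 50 cm, the range over which
    urban street furniture and forest stems switch between looking linear,
    planar and volumetric.
    """

    diameters: tuple[float, ...] = (0.05, 0.10, 0.20, 0.30, 0.40, 0.50)

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.diameters)
        if len(d) < 1:
            raise ValueError("a scale ladder needs at least one diameter")
        if any(x <= 0 for x in d):
            raise ValueError("scale diameters must be positive")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValueError("scale diameters must be strictly increasing")
        object.__setattr__(self, "diameters", d)

    def __len__(self) -> int:
        return len(self.diameters)

    def __iter__(self):
        return iter(self.diameters)


# Canonical per-scale feature block: the order in which the five features
# appear in every FeatureMatrix scale block and in feature CSV headers.
FEATURE_BLOCK = ("L", "PL", "SPH", "HOR", "PERCZ")


def feature_names(ladder: ScaleLadder | int) -> list[str]:
    """Canonical column names ``L1, PL1, SPH1, HOR1, PERCZ1, L2, ...``.

    Scale suffixes are 1-based, smallest diameter first.
    """
    n_scales = ladder if isinstance(ladder, int) else len(ladder)
    return [f"{name}{s}" for s in range(1, n_scales + 1) for name in FEATURE_BLOCK]
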