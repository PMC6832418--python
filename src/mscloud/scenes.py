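"""Synthetic labeled scenes for end-to-end testing and benchmarking.

Two scenarios mirror the geometric structure of the two settings the
method targets:

* ``forest`` — a rough ground surface, vertical cylinders for tree
  trunks (laser returns live on the stem surface), and thin oblique
  segments attached to the upper stems for branches; classes ground /
  trunk / branch.
* ``urban`` — a street scene: ground plane, tall vertical planar
  facades, thin vertical poles, volumetric vegetation blobs and low
  box-like slabs for parked cars; classes poles / ground / vegetation /
  buildings / cars.

Primitives realize the three local-geometry archetypes the eigenvalue
features respond to: segments and poles are linear (1D), planes and
cylinder surfaces are locally planar (2D), blobs are volumetric (3D).
Every sampled point gets isotropic Gaussian noise of ``noise_sd``
(default 1 cm, the order of low-cost mobile/wearable scanner noise) and
the label of its primitive.  Generation is fully deterministic given the
recipe seed.

This is not a LiDAR sensor simulator: there is no occlusion, beam
divergence, or range-dependent point density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import PointCloud

__all__ = [
    "SceneRecipe",
    "sample_plane",
    "sample_pole",
    "sample_cylinder",
    "sample_segment",
    "sample_blob",
    "build_scene",
    "spatial_split",
]

FOREST_CLASSES = {0: "ground", 1: "trunk", 2: "branch"}
URBAN_CLASSES = {
    0: "poles",
    1: "ground",
    2: "vegetation",
    3: "buildings",
    4: "cars",
}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _with_noise(pts: np.ndarray, noise_sd: float, rng) -> np.ndarray:
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return pts
    return pts + rng.normal(0.0, noise_sd, size=pts.shape)


def _check(n: int, *dims: float) -> None:
    if n < 1:
        raise ValueError("n must be >= 1")
    if any(d <= 0 for d in dims):
        raise ValueError(f"dimensions must be positive, got {dims}")


def sample_plane(
    origin, u, v, n: int, seed=None, noise_sd: float = 0.0, label: int = 0
) -> PointCloud:
    """Uniform points on the parallelogram ``origin + a*u + b*v``, a,b in [0,1]."""
    origin, u, v = (np.asarray(x, dtype=float) for x in (origin, u, v))
    _check(n, np.linalg.norm(u), np.linalg.norm(v))
    rng = _rng(seed)
    a = rng.uniform(size=(n, 1))
    b = rng.uniform(size=(n, 1))
    pts = origin + a * u + b * v
    return PointCloud(_with_noise(pts, noise_sd, rng), np.full(n, label))


def sample_segment(
    p0, p1, n: int, seed=None, noise_sd: float = 0.0,
    jitter: float = 0.0, label: int = 0,
) -> PointCloud:
    """Uniform points along the segment p0->p1 with radial ``jitter``."""
    p0, p1 = np.asarray(p0, dtype=float), np.asarray(p1, dtype=float)
    _check(n, np.linalg.norm(p1 - p0))
    rng = _rng(seed)
    t = rng.uniform(size=(n, 1))
    pts = p0 + t * (p1 - p0)
    if jitter > 0:
        pts = pts + rng.normal(0.0, jitter, size=pts.shape)
    return PointCloud(_with_noise(pts, noise_sd, rng), np.full(n, label))


def sample_pole(
    base, height: float, n: int, seed=None, noise_sd: float = 0.0,
    jitter: float = 0.02, label: int = 0,
) -> PointCloud:
    """A thin vertical pole: a vertical segment with small radial jitter."""
    base = np.asarray(base, dtype=float)
    _check(n, height)
    top = base + np.array([0.0, 0.0, height])
    return sample_segment(
        base, top, n, seed, noise_sd=noise_sd, jitter=jitter, label=label
    )


def sample_cylinder(
    center_xy, radius: float, z0: float, z1: float, n: int,
    seed=None, noise_sd: float = 0.0, label: int = 0,
) -> PointCloud:
    """Uniform points on the lateral surface of a vertical cylinder."""
    _check(n, radius, z1 - z0)
    rng = _rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    z = rng.uniform(z0, z1, size=n)
    cx, cy = center_xy
    pts = np.column_stack(
        [cx + radius * np.cos(theta), cy + radius * np.sin(theta), z]
    )
    return PointCloud(_with_noise(pts, noise_sd, rng), np.full(n, label))


def sample_blob(
    center, radius: float, n: int, seed=None, noise_sd: float = 0.0,
    label: int = 0,
) -> PointCloud:
    """Uniform points inside a ball (volumetric vegetation-like blob)."""
    center = np.asarray(center, dtype=float)
    _check(n, radius)
    rng = _rng(seed)
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    rad = radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    pts = center + d * rad
    return PointCloud(_with_noise(pts, noise_sd, rng), np.full(n, label))


@dataclass
class SceneRecipe:
    """Parameters of one synthetic scene.

    Densities are points per m^2 for surfaces, per m^3 for blobs and per
    metre of length for thin linear objects; ``density_scale`` rescales
    all of them at once (for quick small test scenes).  ``extent`` is the
    (X, Y) footprint in metres; the X axis carries the train/test split.
    """

    scenario: str = "forest"
    extent: tuple[float, float] = (20.0, 10.0)
    densities: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.01
    seed: int = 0
    density_scale: float = 1.0

    _DEFAULT_DENSITIES = {
        "forest": {"ground": 120.0, "trunk": 250.0, "branch": 100.0},
        "urban": {
            "ground": 25.0,
            "buildings": 40.0,
            "poles": 150.0,
            "vegetation": 60.0,
            "cars": 40.0,
        },
    }

    def __post_init__(self):
        if self.scenario not in ("forest", "urban"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "urban" and self.extent == (20.0, 10.0):
            self.extent = (40.0, 20.0)
        merged = dict(self._DEFAULT_DENSITIES[self.scenario])
        merged.update(self.densities)
        self.densities = merged
        if not self.densities or any(v <= 0 for v in self.densities.values()):
            raise ValueError("densities must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.density_scale <= 0:
            raise ValueError("density_scale must be positive")

    @property
    def class_names(self) -> dict[int, str]:
        return dict(FOREST_CLASSES if self.scenario == "forest" else URBAN_CLASSES)

    def _n(self, cls: str, measure: float) -> int:
        return max(1, int(round(self.densities[cls] * measure * self.density_scale)))

    def nominal_counts(self) -> dict[str, int]:
        """Expected number of points per class from the recipe arithmetic."""
        builder = _ForestBuilder if self.scenario == "forest" else _UrbanBuilder
        return builder(self).nominal_counts()


def build_scene(recipe: SceneRecipe) -> PointCloud:
    """Assemble the labeled scene described by a recipe (deterministic)."""
    builder = _ForestBuilder if recipe.scenario == "forest" else _UrbanBuilder
    return builder(recipe).build()


def spatial_split(
    cloud: PointCloud, fraction: float = 0.5, gap: float = 0.5, axis: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint train/test point indices split along one axis.

    The scene is cut at ``min + fraction * span`` along ``axis``; a strip
    of width ``gap`` centred on the cut is dropped from both sides so the
    two regions share no adjacent points (neighborhoods never straddle
    the boundary when ``gap`` exceeds the largest scale diameter).
    """
    x = cloud.coords[:, axis]
    cut = x.min() + fraction * (x.max() - x.min())
    train = np.flatnonzero(x < cut - gap / 2.0)
    test = np.flatnonzero(x > cut + gap / 2.0)
    return train, test


# ---------------------------------------------------------------------------
# Scene builders
# ---------------------------------------------------------------------------

class _SceneBuilder:
    def __init__(self, recipe: SceneRecipe):
        self.recipe = recipe
        self.rng = np.random.default_rng(recipe.seed)

    def build(self) -> PointCloud:
        parts = self.parts()
        coords = np.vstack([p.coords for p in parts])
        labels = np.concatenate([p.labels for p in parts])
        return PointCloud(coords, labels, self.recipe.class_names)

    def _rough_ground(self, n: int, label: int) -> PointCloud:
        """Gently undulating ground surface across the full extent."""
        ex, ey = self.recipe.extent
        rng = self.rng
        phase = rng.uniform(0.0, 2.0 * np.pi, size=4)
        x = rng.uniform(0.0, ex, size=n)
        y = rng.uniform(0.0, ey, size=n)
        z = (
            0.06 * np.sin(2.0 * np.pi * x / 7.3 + phase[0])
            + 0.05 * np.sin(2.0 * np.pi * y / 4.7 + phase[1])
            + 0.03 * np.sin(2.0 * np.pi * (x + y) / 11.1 + phase[2])
        )
        pts = _with_noise(
            np.column_stack([x, y, z]), self.recipe.noise_sd, rng
        )
        return PointCloud(pts, np.full(n, label))

    def _spread_positions(self, k: int, margin: float) -> np.ndarray:
        """Object XY positions, half in each X half (both split regions)."""
        ex, ey = self.recipe.extent
        rng = self.rng
        xs = np.empty(k)
        half = k // 2
        xs[:half] = rng.uniform(margin, ex / 2.0 - margin, size=half)
        xs[half:] = rng.uniform(ex / 2.0 + margin, ex - margin, size=k - half)
        ys = rng.uniform(margin, ey - margin, size=k)
        return np.column_stack([xs, ys])


class _ForestBuilder(_SceneBuilder):
    N_TREES = 10
    TRUNK_HEIGHT = (5.0, 7.0)
    TRUNK_RADIUS = (0.10, 0.20)
    BRANCHES_PER_TREE = 8
    BRANCH_LENGTH = (1.0, 1.8)

    def _tree_params(self):
        rng = self.rng
        pos = self._spread_positions(self.N_TREES, margin=1.5)
        radii = rng.uniform(*self.TRUNK_RADIUS, size=self.N_TREES)
        heights = rng.uniform(*self.TRUNK_HEIGHT, size=self.N_TREES)
        return pos, radii, heights

    def nominal_counts(self) -> dict[str, int]:
        r = self.recipe
        ex, ey = r.extent
        mean_r = sum(self.TRUNK_RADIUS) / 2.0
        mean_h = sum(self.TRUNK_HEIGHT) / 2.0
        mean_len = sum(self.BRANCH_LENGTH) / 2.0
        return {
            "ground": r._n("ground", ex * ey),
            "trunk": self.N_TREES
            * r._n("trunk", 2.0 * np.pi * mean_r * mean_h),
            "branch": self.N_TREES
            * self.BRANCHES_PER_TREE
            * r._n("branch", mean_len),
        }

    def parts(self) -> list[PointCloud]:
        r = self.recipe
        ex, ey = r.extent
        rng = self.rng
        parts = [self._rough_ground(r._n("ground", ex * ey), label=0)]
        pos, radii, heights = self._tree_params()
        mean_r = sum(self.TRUNK_RADIUS) / 2.0
        mean_h = sum(self.TRUNK_HEIGHT) / 2.0
        n_trunk = r._n("trunk", 2.0 * np.pi * mean_r * mean_h)
        mean_len = sum(self.BRANCH_LENGTH) / 2.0
        n_branch = r._n("branch", mean_len)
        for k in range(self.N_TREES):
            parts.append(
                sample_cylinder(
                    pos[k], radii[k], 0.0, heights[k], n_trunk,
                    seed=rng, noise_sd=r.noise_sd, label=1,
                )
            )
            for _ in range(self.BRANCHES_PER_TREE):
                zb = rng.uniform(0.45, 0.95) * heights[k]
                az = rng.uniform(0.0, 2.0 * np.pi)
                droop = np.radians(rng.uniform(5.0, 40.0))
                length = rng.uniform(*self.BRANCH_LENGTH)
                base = np.array(
                    [
                        pos[k, 0] + radii[k] * np.cos(az),
                        pos[k, 1] + radii[k] * np.sin(az),
                        zb,
                    ]
                )
                tip = base + length * np.array(
                    [
                        np.cos(az) * np.cos(droop),
                        np.sin(az) * np.cos(droop),
                        -np.sin(droop),
                    ]
                )
                parts.append(
                    sample_segment(
                        base, tip, n_branch, seed=rng,
                        noise_sd=r.noise_sd, jitter=0.015, label=2,
                    )
                )
        return parts


class _UrbanBuilder(_SceneBuilder):
    N_POLES = 8
    POLE_HEIGHT = (4.0, 8.0)
    N_BLOBS = 6
    BLOB_RADIUS = (1.0, 2.0)
    N_CARS = 6
    CAR_DIMS = (4.0, 1.8, 1.5)
    FACADE_HEIGHT = 10.0

    def nominal_counts(self) -> dict[str, int]:
        r = self.recipe
        ex, ey = r.extent
        lx, ly, lz = self.CAR_DIMS
        car_area = lx * ly + 2.0 * lz * (lx + ly)
        mean_blob_r = sum(self.BLOB_RADIUS) / 2.0
        blob_vol = 4.0 / 3.0 * np.pi * mean_blob_r**3
        mean_pole_h = sum(self.POLE_HEIGHT) / 2.0
        return {
            "ground": r._n("ground", ex * ey),
            "buildings": 2 * r._n("buildings", ex * self.FACADE_HEIGHT),
            "poles": self.N_POLES * r._n("poles", mean_pole_h),
            "vegetation": self.N_BLOBS * r._n("vegetation", blob_vol),
            "cars": self.N_CARS * r._n("cars", car_area),
        }

    def parts(self) -> list[PointCloud]:
        r = self.recipe
        ex, ey = r.extent
        rng = self.rng
        parts = [self._rough_ground(r._n("ground", ex * ey), label=1)]

        # two facades along the long edges of the street
        n_fac = r._n("buildings", ex * self.FACADE_HEIGHT)
        for y in (0.0, ey):
            parts.append(
                sample_plane(
                    (0.0, y, 0.0), (ex, 0.0, 0.0),
                    (0.0, 0.0, self.FACADE_HEIGHT),
                    n_fac, seed=rng, noise_sd=r.noise_sd, label=3,
                )
            )

        mean_pole_h = sum(self.POLE_HEIGHT) / 2.0
        n_pole = r._n("poles", mean_pole_h)
        for xy in self._spread_positions(self.N_POLES, margin=2.0):
            h = rng.uniform(*self.POLE_HEIGHT)
            parts.append(
                sample_pole(
                    (xy[0], xy[1], 0.0), h, n_pole, seed=rng,
                    noise_sd=r.noise_sd, jitter=0.03, label=0,
                )
            )

        mean_blob_r = sum(self.BLOB_RADIUS) / 2.0
        blob_vol = 4.0 / 3.0 * np.pi * mean_blob_r**3
        n_blob = r._n("vegetation", blob_vol)
        for xy in self._spread_positions(self.N_BLOBS, margin=3.0):
            rad = rng.uniform(*self.BLOB_RADIUS)
            parts.append(
                sample_blob(
                    (xy[0], xy[1], rad + rng.uniform(0.0, 1.0)), rad,
                    n_blob, seed=rng, noise_sd=r.noise_sd, label=2,
                )
            )

        lx, ly, lz = self.CAR_DIMS
        car_area = lx * ly + 2.0 * lz * (lx + ly)
        n_car = r._n("cars", car_area)
        for xy in self._spread_positions(self.N_CARS, margin=3.0):
            parts.append(self._car(xy, n_car, label=4))
        return parts

    def _car(self, xy, n: int, label: int) -> PointCloud:
        """Box-like slab: roof plus four side walls, no underside."""
        lx, ly, lz = self.CAR_DIMS
        rng = self.rng
        o = np.array([xy[0] - lx / 2.0, xy[1] - ly / 2.0, 0.0])
        faces = [
            ((0, 0, lz), (lx, 0, 0), (0, ly, 0), lx * ly),  # roof
            ((0, 0, 0), (lx, 0, 0), (0, 0, lz), lx * lz),
            ((0, ly, 0), (lx, 0, 0), (0, 0, lz), lx * lz),
            ((0, 0, 0), (0, ly, 0), (0, 0, lz), ly * lz),
            ((lx, 0, 0), (0, ly, 0), (0, 0, lz), ly * lz),
        ]
        total = sum(f[3] for f in faces)
        parts = []
        for origin, u, v, area in faces:
            nf = max(1, int(round(n * area / total)))
            parts.append(
                sample_plane(
                    o + origin, u, v, nf, seed=rng,
                    noise_sd=self.recipe.noise_sd, label=label,
                )
            )
        coords = np.vstack([p.coords for p in parts])
        return PointCloud(coords, np.full(len(coords), label))
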