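"""Centroidal Voronoi tessellations on the unrolled lateral surface of a cylinder.

A tube's lateral surface is developed into a flat raster whose abscissa
(``x``, the transverse axis) is periodic: a cell leaving the right edge of
the image re-enters on the left. Tessellations are built raster-wise, by
assigning every pixel to the seed that minimises the periodic Euclidean
distance; Lloyd relaxation iterates seed -> region centroid to approach a
centroidal Voronoi tessellation (CVT).

Conventions
-----------
* ``x`` = column index = transverse (periodic) axis; ``y`` = row index =
  longitudinal axis; both 0-based.
* Pixel centres sit at integer coordinates + 0.5; all seed-to-pixel
  distances are measured between seed positions and pixel centres.
* Equidistant pixels are assigned to the lowest seed id.

The construction mirrors the classical "triple and crop" recipe: the seed
set is replicated once to each side along the periodic axis, a plain
Euclidean diagram is computed on the widened domain, and the central copy
is retained. Because every replica is exactly one period away, this is
identical to using the periodic metric directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSet",
    "PeriodicLabelImage",
    "sample_seeds",
    "periodic_voronoi",
    "lloyd_relax",
    "cvt_energy",
]


@dataclass(frozen=True)
class SeedSet:
    """Seed positions on a periodic-x rectangular domain.

    Parameters
    ----------
    points : (n, 2) float array
        Seed coordinates as ``(x, y)`` pairs, ``x`` transverse (periodic),
        ``y`` longitudinal, in pixels.
    width_px, height_px : int
        Domain size; all points must satisfy ``0 <= x < width_px`` and
        ``0 <= y < height_px``.
    rng_seed : int or None
        Seed used to generate the points, kept for bookkeeping.
    """

    points: np.ndarray
    width_px: int
    height_px: int
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
            raise ValueError("points must be a non-empty (n, 2) array")
        object.__setattr__(self, "points", pts)
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("domain must be at least 1x1 pixels")
        if np.any(pts[:, 0] < 0) or np.any(pts[:, 0] >= self.width_px):
            raise ValueError("seed x coordinates outside [0, width_px)")
        if np.any(pts[:, 1] < 0) or np.any(pts[:, 1] >= self.height_px):
            raise ValueError("seed y coordinates outside [0, height_px)")
        if len(np.unique(pts, axis=0)) != len(pts):
            raise ValueError("duplicate seed positions are not allowed")

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class PeriodicLabelImage:
    """Integer raster partition of the periodic-x domain.

    ``labels[y, x]`` is the id (0-based row into the generating seed set) of
    the cell owning the pixel. Every pixel belongs to exactly one cell;
    there is no background.
    """

    labels: np.ndarray
    width_px: int = field(init=False)
    height_px: int = field(init=False)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError("labels must be a 2D raster")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "width_px", lab.shape[1])
        object.__setattr__(self, "height_px", lab.shape[0])

    @property
    def ids(self) -> np.ndarray:
        return np.unique(self.labels)


def sample_seeds(
    n: int,
    width_px: int,
    height_px: int,
    rng: np.random.Generator | int | None = None,
) -> SeedSet:
    """Draw ``n`` distinct uniform-random seeds on the periodic domain.

    The default study domain is 512 x 4096 px with 40-800 seeds.
    """
    if n < 1:
        raise ValueError("need at least one seed")
    if n > width_px * height_px:
        raise ValueError("seed count exceeds the number of pixels in the domain")
    seed_val = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng)
    pts = np.column_stack(
        [gen.uniform(0, width_px, size=n), gen.uniform(0, height_px, size=n)]
    )
    # continuous draws collide with probability zero; resample defensively
    while len(np.unique(pts, axis=0)) != n:  # pragma: no cover
        dup = len(pts) - len(np.unique(pts, axis=0))
        pts[-dup:] = np.column_stack(
            [gen.uniform(0, width_px, size=dup), gen.uniform(0, height_px, size=dup)]
        )
    return SeedSet(pts, width_px, height_px, rng_seed=seed_val)


def _tripled_points(seeds: SeedSet) -> np.ndarray:
    """Replicate seeds one period to each side: copies at x-W, x, x+W."""
    pts = seeds.points
    w = seeds.width_px
    return np.vstack([pts - [w, 0], pts, pts + [w, 0]])


def _pixel_centres(width: int, height: int, x0: float = 0.0) -> np.ndarray:
    xs = np.arange(width) + 0.5 + x0
    ys = np.arange(height) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


_TIE_ATOL = 1e-9


def _assign(points: np.ndarray, tripled: np.ndarray, n: int) -> np.ndarray:
    """Nearest-tripled-seed ids (mod n), lowest id winning exact ties."""
    tree = cKDTree(tripled)
    dist, idx = tree.query(points, k=2)
    ids = idx % n
    tie = np.abs(dist[:, 0] - dist[:, 1]) <= _TIE_ATOL
    ids0 = ids[:, 0].copy()
    ids0[tie] = np.minimum(ids[tie, 0], ids[tie, 1])
    return ids0


def periodic_voronoi(seeds: SeedSet) -> PeriodicLabelImage:
    """Label every pixel with the seed minimising periodic-x distance."""
    w, h, n = seeds.width_px, seeds.height_px, seeds.n
    centres = _pixel_centres(w, h)
    lab = _assign(centres, _tripled_points(seeds), n).reshape(h, w).astype(np.int32)
    return PeriodicLabelImage(lab)


def lloyd_relax(seeds: SeedSet, iterations: int = 4) -> SeedSet:
    """Lloyd relaxation with centroids computed on the tripled raster.

    One iteration labels the tripled (3W x H) raster with the 3n replicated
    seeds, computes each central-copy cell's centroid over its full tripled
    region, and keeps the centroids whose abscissa falls inside the central
    band ``[W, 2W)``; a cell whose region is empty or whose centroid drifts
    out of the band keeps its previous seed (logged). Four iterations give
    the fifth ("Voronoi 5") diagram used for analysis.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    cur = seeds
    w, h, n = seeds.width_px, seeds.height_px, seeds.n
    centres = _pixel_centres(3 * w, h, x0=-w)
    for _ in range(iterations):
        tripled = _tripled_points(cur)
        tree = cKDTree(tripled)
        _, idx = tree.query(centres)  # tripled-seed ids, 0..3n-1
        cnt = np.bincount(idx, minlength=3 * n)
        sx = np.bincount(idx, weights=centres[:, 0], minlength=3 * n)
        sy = np.bincount(idx, weights=centres[:, 1], minlength=3 * n)
        new = cur.points.copy()
        # a seam cell's central-copy centroid can drift out of the band;
        # the band then contains the centroid of one of its side replicas
        ok3 = (cnt > 0).reshape(3, n)
        cx3 = np.where(cnt > 0, sx / np.maximum(cnt, 1), np.nan).reshape(3, n)
        cy3 = np.where(cnt > 0, sy / np.maximum(cnt, 1), np.nan).reshape(3, n)
        in_band3 = ok3 & (cx3 >= 0) & (cx3 < w)
        updated = np.zeros(n, dtype=bool)
        for copy in (1, 0, 2):  # central replica preferred
            take = in_band3[copy] & ~updated
            new[take, 0] = cx3[copy, take]
            new[take, 1] = cy3[copy, take]
            updated |= take
        if not np.all(updated):
            logger.warning(
                "lloyd_relax: %d cell(s) kept their previous seed "
                "(no replica centroid inside the central band)",
                int(np.sum(~updated)),
            )
        cur = replace(cur, points=new)
    return cur


def cvt_energy(seeds: SeedSet, image: PeriodicLabelImage | None = None) -> float:
    """CVT quantisation energy: sum of squared periodic pixel-to-seed distances."""
    if image is None:
        image = periodic_voronoi(seeds)
    w, h = seeds.width_px, seeds.height_px
    centres = _pixel_centres(w, h)
    owners = seeds.points[image.labels.ravel()]
    dx = np.abs(centres[:, 0] - owners[:, 0])
    dx = np.minimum(dx, w - dx)
    dy = centres[:, 1] - owners[:, 1]
    return float(np.sum(dx * dx + dy * dy))
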