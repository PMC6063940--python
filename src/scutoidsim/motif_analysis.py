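"""Four-cell motif extraction and morphometry on paired label rasters.

A four-cell motif is the quadrilateral of cells (A, B, C, D) around a
central intercellular edge: A-B share the edge, C and D flank it. During an
apico-basal intercalation the central diagonal flips (A-B contact on one
surface, C-D on the other), so motifs are the unit in which transitions are
measured.

Geometry is measured on the raster: junction points are detected as 2x2
pixel windows where three or more labels meet (sub-pixel position by
averaging coincident windows), the central edge is the straight segment
between its two tri-junctions, and the motif quadrilateral is spanned by
the four outer junctions where two motif cells meet a non-motif cell.
Following the study conventions, motifs are discarded when a fourfold
vertex involves the four cells on either surface, when any cell is
non-valid, when the four cells do not stay together on both surfaces, or
when the central edge is 4 px or shorter.

Axis convention: ``x`` (columns) is the transverse/periodic axis, ``y``
(rows) the longitudinal axis. Motif height ``h`` extends transversely,
width ``w`` longitudinally, and the aspect ratio is ``epsilon = <h>/<w>``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .periodic_cvt import PeriodicLabelImage

logger = logging.getLogger(__name__)

__all__ = [
    "MotifGeometry",
    "FourCellMotif",
    "MotifSample",
    "JunctionIndex",
    "find_motifs",
    "edge_geometry",
    "motif_dimensions",
    "estimate_surface_ratio",
    "sample_motifs",
    "motifs_to_frame",
]

MIN_EDGE_LEN_PX = 4.0  # central edges at or below this length are discarded


def _as_labels(img) -> np.ndarray:
    return img.labels if isinstance(img, PeriodicLabelImage) else np.asarray(img)


class JunctionIndex:
    """Raster junction points: 2x2 windows where >= 3 labels meet.

    The shared corner of the window's four pixels is the junction estimate;
    windows along the periodic seam are included. ``triples`` maps each
    frozenset of window labels (3 or 4 members) to the corner coordinates
    of every window showing it.
    """

    def __init__(self, img, periodic: bool = True):
        lab = _as_labels(img)
        h, w = lab.shape
        self.width = w
        self.periodic = periodic
        right = np.roll(lab, -1, axis=1)
        A = lab[:-1, :]
        B = right[:-1, :]
        C = lab[1:, :]
        D = right[1:, :]
        quad = np.stack([A, B, C, D], axis=-1)
        s = np.sort(quad, axis=-1)
        ndist = 1 + np.sum(s[..., 1:] != s[..., :-1], axis=-1)
        cols = w if periodic else w - 1
        rr, cc = np.nonzero(ndist[:, :cols] >= 3)
        self.triples: dict[frozenset, list[tuple[float, float]]] = {}
        for r, c in zip(rr.tolist(), cc.tolist()):
            key = frozenset(int(v) for v in quad[r, c])
            # corner point between the four pixels: x = c+1, y = r+1
            self.triples.setdefault(key, []).append((float(c + 1), float(r + 1)))

    def find(self, labels: frozenset) -> list[tuple[float, float]]:
        """Corners of windows whose label set contains ``labels``."""
        out: list[tuple[float, float]] = []
        for key, pts in self.triples.items():
            if labels <= key:
                out.extend(pts)
        return out

    def has_fourfold(self, cells: frozenset) -> bool:
        return any(cells <= key for key in self.triples if len(key) == 4)


def _unwrap_x(xs: np.ndarray, x0: float, width: int) -> np.ndarray:
    return x0 + ((xs - x0 + width / 2.0) % width) - width / 2.0


def _mean_point(
    pts: list[tuple[float, float]], width: int
) -> tuple[float, float]:
    arr = np.asarray(pts, dtype=float)
    xs = _unwrap_x(arr[:, 0], arr[0, 0], width)
    return float(np.mean(xs)), float(np.mean(arr[:, 1]))


def _cluster_corner(
    pts: list[tuple[float, float]], width: int, tol: float = 3.0
) -> tuple[float, float] | None:
    """Average a window cluster; None if the points split into clusters."""
    if not pts:
        return None
    arr = np.asarray(pts, dtype=float)
    xs = _unwrap_x(arr[:, 0], arr[0, 0], width)
    if np.ptp(xs) > tol or np.ptp(arr[:, 1]) > tol:
        return None
    return float(np.mean(xs)), float(np.mean(arr[:, 1]))


@dataclass
class MotifGeometry:
    """Raster measurements of one motif on one surface."""

    central_pair: tuple[int, int]
    theta_deg: float
    edge_length: float
    corners: list[tuple[float, float]]
    w1: float
    w2: float
    h1: float
    h2: float
    mean_w: float
    mean_h: float
    epsilon: float
    L_T: float


@dataclass
class FourCellMotif:
    """Four cells around a central edge, with per-surface measurements.

    ``cells = (A, B, C, D)``: A-B is the central pair on the reference
    surface, C-D the flanking pair (the central pair on the opposite
    surface when the motif intercalates).
    """

    cells: tuple[int, int, int, int]
    reference: str
    has_transition: bool
    valid: bool
    invalid_reason: str | None = None
    geometry: dict[str, MotifGeometry] = field(default_factory=dict)
    surface_ratio: float | None = None

    @property
    def ref_geometry(self) -> MotifGeometry | None:
        return self.geometry.get(self.reference)


def _edge_endpoints(
    junctions: JunctionIndex,
    central: tuple[int, int],
    flanks: tuple[int, int],
    width: int,
) -> tuple[tuple[float, float], tuple[float, float]] | None:
    """Tri-junction endpoints of the central edge, or None if degenerate."""
    a, b = central
    ends = []
    for flank in flanks:
        pts = junctions.find(frozenset((a, b, flank)))
        if not pts:
            return None
        pt = _cluster_corner(pts, width)
        if pt is None:
            return None
        ends.append(pt)
    return ends[0], ends[1]


def _measure(
    img,
    junctions: JunctionIndex,
    central: tuple[int, int],
    flanks: tuple[int, int],
) -> MotifGeometry | None:
    """Measure a motif on one raster; None when the geometry degenerates."""
    lab = _as_labels(img)
    w_img = lab.shape[1]
    a, b = central
    c, d = flanks
    motif = frozenset((a, b, c, d))
    ends = _edge_endpoints(junctions, central, flanks, w_img)
    if ends is None:
        return None
    (x1, y1), (x2, y2) = ends
    dx = ((x2 - x1 + w_img / 2.0) % w_img) - w_img / 2.0
    dy = y2 - y1
    edge_len = float(np.hypot(dx, dy))
    theta = float(np.degrees(np.arctan2(abs(dy), abs(dx))))
    # edge midpoint: the unwrap reference closest to every motif point
    xm = x1 + dx / 2.0

    # outer corners: two motif cells meeting a non-motif cell
    corners: list[tuple[float, float]] = []
    radiating: list[float] = []
    for p, q, end in ((a, c, 0), (b, c, 0), (a, d, 1), (b, d, 1)):
        cand = [
            pt
            for key, pts in junctions.triples.items()
            if {p, q} <= set(key) and not set(key) <= motif
            for pt in pts
        ]
        corner = _cluster_corner(cand, w_img)
        if corner is None:
            return None
        corners.append(corner)
        ex, ey = ends[end]
        rdx = ((corner[0] - ex + w_img / 2.0) % w_img) - w_img / 2.0
        radiating.append(float(np.hypot(rdx, corner[1] - ey)))

    # order corners around their centroid (unwrapped near the edge midpoint)
    arr = np.asarray(corners, dtype=float)
    xs = _unwrap_x(arr[:, 0], xm, w_img)
    ys = arr[:, 1]
    cx, cy = np.mean(xs), np.mean(ys)
    order = np.argsort(np.arctan2(ys - cy, xs - cx))
    xs, ys = xs[order], ys[order]
    sides = []
    for i in range(4):
        j = (i + 1) % 4
        sides.append((xs[j] - xs[i], ys[j] - ys[i]))
    lens = [float(np.hypot(sx, sy)) for sx, sy in sides]
    # opposite pairs (0,2) and (1,3); the pair more aligned with the
    # longitudinal (y) axis gives w1, w2, the other h1, h2
    align = [abs(sy) - abs(sx) for sx, sy in sides]
    if align[0] + align[2] >= align[1] + align[3]:
        w1, w2, h1, h2 = lens[0], lens[2], lens[1], lens[3]
    else:
        w1, w2, h1, h2 = lens[1], lens[3], lens[0], lens[2]
    mean_w = 0.5 * (w1 + w2)
    mean_h = 0.5 * (h1 + h2)
    if mean_w <= 0 or mean_h <= 0:
        return None
    return MotifGeometry(
        central_pair=(a, b),
        theta_deg=theta,
        edge_length=edge_len,
        corners=[(float(x), float(y)) for x, y in zip(xs, ys)],
        w1=w1,
        w2=w2,
        h1=h1,
        h2=h2,
        mean_w=mean_w,
        mean_h=mean_h,
        epsilon=mean_h / mean_w,
        L_T=edge_len + float(np.sum(radiating)),
    )


def find_motifs(
    apical_adj: dict[int, set[int]],
    basal_adj: dict[int, set[int]],
    apical_img,
    basal_img,
    valid: set[int] | None = None,
    reference: str = "basal",
    min_edge_len: float = MIN_EDGE_LEN_PX,
    periodic: bool = True,
    measure_both: bool = True,
) -> list[FourCellMotif]:
    """Enumerate and measure four-cell motifs on the reference surface.

    Each reference edge (A, B) with exactly two common neighbours {C, D}
    generates one candidate; candidates failing the validity rules are
    returned with ``valid=False`` and a reason.
    """
    if reference not in ("apical", "basal"):
        raise ValueError("reference must be 'apical' or 'basal'")
    ref_adj, other_adj = (
        (basal_adj, apical_adj) if reference == "basal" else (apical_adj, basal_adj)
    )
    other_name = "apical" if reference == "basal" else "basal"
    imgs = {"apical": apical_img, "basal": basal_img}
    junctions = {
        name: JunctionIndex(img, periodic=periodic) for name, img in imgs.items()
    }
    if valid is None:
        valid_set = set(ref_adj)
        for img in imgs.values():
            lab = _as_labels(img)
            valid_set -= set(np.unique(lab[0]).tolist())
            valid_set -= set(np.unique(lab[-1]).tolist())
    else:
        valid_set = valid

    motifs: list[FourCellMotif] = []
    seen: set[tuple[int, ...]] = set()
    for a in sorted(ref_adj):
        for b in sorted(ref_adj[a]):
            if b <= a:
                continue
            common = ref_adj[a] & ref_adj[b]
            if len(common) != 2:
                continue
            c, d = sorted(common)
            key = tuple(sorted((a, b, c, d)))
            if key in seen:
                continue
            seen.add(key)
            if d in ref_adj[c]:
                continue  # not a quadrilateral around the edge
            ab_other = b in other_adj.get(a, set())
            cd_other = d in other_adj.get(c, set())
            if ab_other and cd_other:
                continue  # inconsistent topology
            has_transition = (not ab_other) and cd_other
            motif = FourCellMotif(
                cells=(a, b, c, d),
                reference=reference,
                has_transition=has_transition,
                valid=True,
            )
            if not all(x in valid_set for x in key):
                motif.valid = False
                motif.invalid_reason = "non-valid cell"
                motifs.append(motif)
                continue
            together = all(
                q in adj.get(p, set())
                for adj in (ref_adj, other_adj)
                for p, q in ((a, c), (a, d), (b, c), (b, d))
            )
            if not together:
                motif.valid = False
                motif.invalid_reason = "four cells not together on both surfaces"
                motifs.append(motif)
                continue
            if any(j.has_fourfold(frozenset(key)) for j in junctions.values()):
                motif.valid = False
                motif.invalid_reason = "fourfold vertex"
                motifs.append(motif)
                continue
            geo_ref = _measure(imgs[reference], junctions[reference], (a, b), (c, d))
            if geo_ref is None:
                motif.valid = False
                motif.invalid_reason = "degenerate junction geometry"
                motifs.append(motif)
                continue
            if geo_ref.edge_length <= min_edge_len:
                motif.valid = False
                motif.invalid_reason = "central edge too short"
                motifs.append(motif)
                continue
            motif.geometry[reference] = geo_ref
            if measure_both:
                central_other = (c, d) if has_transition else (a, b)
                flanks_other = (a, b) if has_transition else (c, d)
                geo_other = _measure(
                    imgs[other_name],
                    junctions[other_name],
                    central_other,
                    flanks_other,
                )
                if geo_other is None:
                    motif.valid = False
                    motif.invalid_reason = "degenerate geometry on opposite surface"
                    motifs.append(motif)
                    continue
                motif.geometry[other_name] = geo_other
            motifs.append(motif)
    return motifs


def edge_geometry(
    motif: FourCellMotif, img, periodic: bool = True
) -> tuple[float, float]:
    """(theta_deg, edge_length) of the motif's central edge on ``img``.

    Theta is the angle to the transverse (x) axis folded into [0, 90].
    """
    a, b, c, d = motif.cells
    lab = _as_labels(img)
    w_img = lab.shape[1]
    ends = _edge_endpoints(
        JunctionIndex(img, periodic=periodic), (a, b), (c, d), w_img
    )
    if ends is None:
        raise ValueError("central edge endpoints not found (fourfold or missing)")
    (x1, y1), (x2, y2) = ends
    dx = ((x2 - x1 + w_img / 2.0) % w_img) - w_img / 2.0
    dy = y2 - y1
    return float(np.degrees(np.arctan2(abs(dy), abs(dx)))), float(np.hypot(dx, dy))


def motif_dimensions(
    motif: FourCellMotif, img, periodic: bool = True
) -> MotifGeometry:
    """Full quadrilateral measurement of the motif on ``img``."""
    a, b, c, d = motif.cells
    geo = _measure(img, JunctionIndex(img, periodic=periodic), (a, b), (c, d))
    if geo is None:
        raise ValueError("motif geometry is degenerate on this raster")
    return geo


def estimate_surface_ratio(
    cells: tuple[int, ...] | FourCellMotif,
    apical_img,
    basal_img,
    inverted: bool = False,
) -> float:
    """Pixel-area ratio of the four-cell union, basal over apical.

    ``inverted=True`` returns apical/basal (the apical-reduction
    convention used for embryo-style measurements).
    """
    ids = cells.cells if isinstance(cells, FourCellMotif) else tuple(cells)
    a_lab = _as_labels(apical_img)
    b_lab = _as_labels(basal_img)
    area_a = int(np.isin(a_lab, ids).sum())
    area_b = int(np.isin(b_lab, ids).sum())
    if area_a == 0 or area_b == 0:
        raise ValueError("motif has zero area on one surface")
    ratio = area_b / area_a
    return 1.0 / ratio if inverted else ratio


@dataclass
class MotifSample:
    """Reproducible per-class subsample of measured motifs."""

    transition: list[FourCellMotif]
    no_transition: list[FourCellMotif]
    caps: tuple[int, int]


def sample_motifs(
    motifs: list[FourCellMotif],
    caps: tuple[int, int] = (200, 200),
    rng: np.random.Generator | int | None = None,
) -> MotifSample:
    """Uniform subsample per class (transition cap, no-transition cap)."""
    gen = np.random.default_rng(rng)
    pools = {
        True: [m for m in motifs if m.valid and m.has_transition],
        False: [m for m in motifs if m.valid and not m.has_transition],
    }
    out = {}
    for flag, cap in ((True, caps[0]), (False, caps[1])):
        pool = pools[flag]
        if len(pool) <= cap:
            out[flag] = list(pool)
        else:
            idx = gen.choice(len(pool), size=cap, replace=False)
            out[flag] = [pool[i] for i in sorted(idx)]
    return MotifSample(transition=out[True], no_transition=out[False], caps=caps)


def motifs_to_frame(motifs: list[FourCellMotif], surface: str | None = None):
    """Flatten motif measurements into a pandas DataFrame."""
    import pandas as pd

    rows = []
    for i, m in enumerate(motifs):
        surf = surface or m.reference
        g = m.geometry.get(surf)
        row = {
            "motif_id": i,
            "surface": surf,
            "cells": "-".join(str(c) for c in m.cells),
            "has_transition": m.has_transition,
            "valid": m.valid,
            "surface_ratio": m.surface_ratio,
        }
        if g is not None:
            row.update(
                theta_deg=g.theta_deg,
                edge_len_px=g.edge_length,
                w1=g.w1,
                w2=g.w2,
                h1=g.h1,
                h2=g.h2,
                mean_w=g.mean_w,
                mean_h=g.mean_h,
                epsilon=g.epsilon,
                L_T=g.L_T,
            )
        rows.append(row)
    return pd.DataFrame(rows)
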