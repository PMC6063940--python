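"""Paired apical/basal tube tessellations and apico-basal neighbour exchanges.

A tube is modelled by two developed cylinder surfaces sharing one seed set:
the apical (inner) raster of width ``W`` and a basal (outer) raster whose
width — and seed abscissas — are scaled by the surface ratio R_b/R_a >= 1.
Longitudinal length is physically unchanged, so raster height is shared.

Cells whose neighbour set differs between the two surfaces have at least
one apico-basal intercalation: they are *scutoids*. The neighbour exchange
is the spatial analogue of a T1 transition and is localised in a four-cell
motif whose central-edge diagonal flips between the surfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np

from .periodic_cvt import PeriodicLabelImage, SeedSet, periodic_voronoi

logger = logging.getLogger(__name__)

__all__ = [
    "TubeTessellation",
    "TransitionEvent",
    "surface_ratio_series",
    "expand_to_basal",
    "build_tube",
    "adjacency",
    "valid_cells",
    "detect_transitions",
    "scutoid_percentage",
    "intermediate_surface",
    "stack_scutoid_count",
]


@dataclass(frozen=True)
class TubeTessellation:
    """Apical and basal diagrams of one tube, with persistent cell identities."""

    apical: PeriodicLabelImage
    basal: PeriodicLabelImage
    surface_ratio: float
    apical_seeds: SeedSet | None = None
    basal_seeds: SeedSet | None = None

    def __post_init__(self) -> None:
        if self.surface_ratio < 1:
            raise ValueError("surface ratio must be >= 1")
        if self.apical.height_px != self.basal.height_px:
            raise ValueError("apical and basal rasters must share their height")
        if not np.array_equal(self.apical.ids, self.basal.ids):
            raise ValueError("apical and basal label sets differ")

    @property
    def R_a(self) -> float:
        """Apical radius implied by the raster circumference (bookkeeping)."""
        return self.apical.width_px / (2 * np.pi)

    @property
    def R_b(self) -> float:
        return self.basal.width_px / (2 * np.pi)


@dataclass(frozen=True)
class TransitionEvent:
    """Four cells around a central edge whose diagonal flips between surfaces.

    ``cells = (A, B, C, D)``: A-B are adjacent on ``ab_surface`` (and not on
    the other), C-D on the opposite surface; the four remaining pairs are in
    contact on both surfaces.
    """

    cells: tuple[int, int, int, int]
    ab_surface: str  # "apical" or "basal": where the A-B diagonal exists

    def __post_init__(self) -> None:
        if self.ab_surface not in ("apical", "basal"):
            raise ValueError("ab_surface must be 'apical' or 'basal'")


def surface_ratio_series() -> list[float]:
    """The nine-step expansion series f(x) = 1 / (1 - x/10), x = 1..9."""
    return [1.0 / (1.0 - x / 10.0) for x in range(1, 10)]


def expand_to_basal(seeds: SeedSet, ratio: float) -> SeedSet:
    """Scale seed abscissas (and the domain width) by the surface ratio."""
    if ratio < 1:
        raise ValueError("surface ratio must be >= 1")
    pts = seeds.points.copy()
    pts[:, 0] *= ratio
    new_w = int(round(seeds.width_px * ratio))
    pts[:, 0] = np.clip(pts[:, 0], 0, np.nextafter(float(new_w), 0.0))
    return SeedSet(pts, new_w, seeds.height_px, rng_seed=seeds.rng_seed)


def build_tube(apical_seeds: SeedSet, ratio: float) -> TubeTessellation:
    """Build matched apical and basal diagrams for one surface ratio."""
    basal_seeds = expand_to_basal(apical_seeds, ratio)
    return TubeTessellation(
        apical=periodic_voronoi(apical_seeds),
        basal=periodic_voronoi(basal_seeds),
        surface_ratio=ratio,
        apical_seeds=apical_seeds,
        basal_seeds=basal_seeds,
    )


def _contact_pairs(labels: np.ndarray, periodic: bool) -> np.ndarray:
    """(k, 2) array of distinct 4-connected label pairs, with multiplicity."""
    pairs = [
        np.stack([labels[:, :-1].ravel(), labels[:, 1:].ravel()], axis=1),
        np.stack([labels[:-1, :].ravel(), labels[1:, :].ravel()], axis=1),
    ]
    if periodic:
        pairs.append(np.stack([labels[:, -1], labels[:, 0]], axis=1))
    allp = np.concatenate(pairs)
    return allp[allp[:, 0] != allp[:, 1]]


def adjacency(
    img: PeriodicLabelImage | np.ndarray, periodic: bool = True
) -> dict[int, set[int]]:
    """Neighbour map from 4-connected pixel contacts (x-wrap included)."""
    labels = img.labels if isinstance(img, PeriodicLabelImage) else np.asarray(img)
    touching = _contact_pairs(labels, periodic)
    nbrs: dict[int, set[int]] = {int(i): set() for i in np.unique(labels)}
    if len(touching):
        uniq = np.unique(np.sort(touching, axis=1), axis=0)
        for a, b in uniq:
            nbrs[int(a)].add(int(b))
            nbrs[int(b)].add(int(a))
    return nbrs


def _border_cells(img: PeriodicLabelImage) -> set[int]:
    lab = img.labels
    return set(np.unique(lab[0]).tolist()) | set(np.unique(lab[-1]).tolist())


def valid_cells(tess: TubeTessellation) -> set[int]:
    """Cells not touching the tube tips (first/last row) on either surface."""
    all_ids = set(int(i) for i in tess.apical.ids)
    bad = _border_cells(tess.apical) | _border_cells(tess.basal)
    valid = all_ids - bad
    if not valid:
        raise ValueError("no valid cells: domain too small for tip exclusion")
    return valid


def detect_transitions(
    tess: TubeTessellation,
    apical_adj: dict[int, set[int]] | None = None,
    basal_adj: dict[int, set[int]] | None = None,
) -> tuple[list[TransitionEvent], dict[int, int]]:
    """Four-cell motif events whose central diagonal flips between surfaces.

    Only events whose four cells are all valid (non-tip on both surfaces)
    are recorded. Returns the event list and per-cell participation counts
    over all cells (0 for non-participants).
    """
    a_adj = apical_adj if apical_adj is not None else adjacency(tess.apical)
    b_adj = basal_adj if basal_adj is not None else adjacency(tess.basal)
    valid = valid_cells(tess)
    counts: dict[int, int] = {int(i): 0 for i in tess.apical.ids}
    events: list[TransitionEvent] = []
    seen: set[tuple[int, ...]] = set()
    for surf, adj1, adj2 in (("apical", a_adj, b_adj), ("basal", b_adj, a_adj)):
        for a in adj1:
            for b in adj1[a]:
                if b <= a or b in adj2.get(a, ()):  # need A-B on surf only
                    continue
                # flank candidates: common neighbours of A and B on both surfaces
                cand = (a_adj[a] & a_adj[b]) & (b_adj[a] & b_adj[b])
                for c, d in combinations(sorted(cand), 2):
                    if d in adj2[c] and c not in adj1[d]:
                        key = tuple(sorted((a, b, c, d)))
                        if key in seen:
                            continue
                        seen.add(key)
                        if all(x in valid for x in key):
                            events.append(TransitionEvent((a, b, c, d), surf))
                            for x in key:
                                counts[x] += 1
    return events, counts


def scutoid_percentage(
    tess: TubeTessellation,
    apical_adj: dict[int, set[int]] | None = None,
    basal_adj: dict[int, set[int]] | None = None,
) -> float:
    """Percentage of valid cells with at least one apico-basal transition.

    A valid cell is a scutoid when it shares an edge with another valid
    cell on exactly one of the two surfaces, i.e. its apical and basal
    neighbour sets (restricted to valid cells) differ.
    """
    valid = valid_cells(tess)
    a_adj = apical_adj if apical_adj is not None else adjacency(tess.apical)
    b_adj = basal_adj if basal_adj is not None else adjacency(tess.basal)
    n_scutoid = sum(
        1
        for c in valid
        if (a_adj.get(c, set()) & valid) != (b_adj.get(c, set()) & valid)
    )
    return 100.0 * n_scutoid / len(valid)


def intermediate_surface(tess: TubeTessellation, lam: float) -> PeriodicLabelImage:
    """Diagram at fractional depth ``lam``: seeds scaled by 1 + lam*(ratio-1)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must lie in [0, 1]")
    if tess.apical_seeds is None:
        raise ValueError("tessellation lacks stored seeds")
    if lam == 0.0:
        return tess.apical
    if lam == 1.0:
        return tess.basal
    factor = 1.0 + lam * (tess.surface_ratio - 1.0)
    return periodic_voronoi(expand_to_basal(tess.apical_seeds, factor))


def stack_scutoid_count(
    stack: list[np.ndarray] | list[PeriodicLabelImage],
    periodic: bool = True,
) -> tuple[dict[int, int], float]:
    """Neighbour-pair exchanges along a label stack, aggregated per cell.

    Counts pair gains/losses between consecutive planes. Denominator cells
    are present in every plane and touch no image border (first/last row;
    for non-periodic stacks also first/last column) in any plane. Returns
    (per-cell exchange counts, percentage of counted cells with >= 1).
    """
    planes = [
        p.labels if isinstance(p, PeriodicLabelImage) else np.asarray(p)
        for p in stack
    ]
    if len(planes) < 2:
        raise ValueError("need at least two planes")
    id_sets = [set(np.unique(p).tolist()) for p in planes]
    common = set.intersection(*id_sets)
    if not common:
        raise ValueError("no cell id present in every plane")
    border: set[int] = set()
    for p in planes:
        border |= set(np.unique(p[0]).tolist()) | set(np.unique(p[-1]).tolist())
        if not periodic:
            border |= set(np.unique(p[:, 0]).tolist()) | set(
                np.unique(p[:, -1]).tolist()
            )
    counted = common - border
    if not counted:
        raise ValueError("no interior cell present in all planes")
    counts: dict[int, int] = {c: 0 for c in sorted(counted)}
    adjs = [adjacency(p, periodic=periodic) for p in planes]
    for prev, nxt in zip(adjs[:-1], adjs[1:]):
        for c in counted:
            changed = prev.get(c, set()) ^ nxt.get(c, set())
            counts[c] += len(changed & counted)
    pct = 100.0 * sum(1 for c in counted if counts[c] > 0) / len(counted)
    return counts, pct
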