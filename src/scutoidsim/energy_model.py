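"""Line-tension energetics of four-cell packing configurations.

The minimal model able to produce a neighbour exchange assigns a constant
line tension ``sigma`` to every junctional edge of a four-cell motif of
width ``w`` (longitudinal) and height ``h`` (transverse). The motif can
open a central edge of length ``l_w`` along the width direction or ``l_h``
along the height direction; the total edge length gives the energy

    E = sigma * [l_w + 2*sqrt((w - l_w)^2 + h^2)] * H(l_w) H(w - l_w)
      + sigma * [l_h + 2*sqrt((h - l_h)^2 + w^2)] * H(l_h) H(h - l_h)

with H the Heaviside step. Scaling lengths by ``w`` and energies by the
fourfold-vertex reference E0 = 2*sigma*sqrt(h^2 + w^2) yields a
one-parameter family in the aspect ratio ``epsilon = h/w``, with a single
signed coordinate ``l`` in (-1, epsilon): negative values are the l_w
branch (in units of w), positive values the l_h branch.

Stable packings are the minima of the dimensionless energy: the l_w
configuration exists for epsilon < sqrt(3), the l_h configuration for
epsilon > 1/sqrt(3), and both coexist (bistability) in between, separated
by the unstable fourfold vertex at l = 0 with energy 1. A cell whose
aspect ratio crosses the bistable window between its apical and basal
surfaces can fall into different attractors at each end: a scutoid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SQRT3",
    "EnergyParams",
    "EnergyDecomposition",
    "Regime",
    "EdgeConfig",
    "dimensional_energy",
    "reference_energy",
    "dimensionless_energy",
    "minima",
    "regime",
    "relax",
    "experimental_energy",
    "decompose",
    "classify_edge_config",
    "trajectory",
    "landscape_grid",
    "epsilon_l_density",
]

SQRT3 = float(np.sqrt(3.0))


@dataclass(frozen=True)
class EnergyParams:
    """Dimensional motif parameters: tension sigma, sizes w, h, edge lengths."""

    sigma: float
    w: float
    h: float
    l_w: float = 0.0
    l_h: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("line tension sigma must be positive")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("motif sizes must be positive")
        if not 0 <= self.l_w <= self.w or not 0 <= self.l_h <= self.h:
            raise ValueError("edge lengths must satisfy 0 <= l_w <= w, 0 <= l_h <= h")
        if self.l_w > 0 and self.l_h > 0:
            raise ValueError("at most one of l_w, l_h can be open")


def reference_energy(params: EnergyParams) -> float:
    """Fourfold-vertex reference E0 = 2 sigma sqrt(h^2 + w^2)."""
    return 2.0 * params.sigma * float(np.hypot(params.h, params.w))


def dimensional_energy(params: EnergyParams) -> float:
    """Line-tension energy of the motif (fourfold l_w = l_h = 0 gives E0).

    H(0) is taken as 1, but the l_w = l_h = 0 state is treated as the
    single fourfold configuration (both branch limits agree at E0), so the
    two terms are never double counted.
    """
    s, w, h, lw, lh = params.sigma, params.w, params.h, params.l_w, params.l_h
    if lw == 0.0 and lh == 0.0:
        return reference_energy(params)
    if lw > 0.0:
        return s * (lw + 2.0 * np.hypot(w - lw, h))
    return s * (lh + 2.0 * np.hypot(h - lh, w))


def dimensionless_energy(l, epsilon: float):
    """Dimensionless energy E_hat(l; epsilon) on the domain l in (-1, epsilon).

    Negative l is the l_w branch (magnitude in units of w), positive l the
    l_h branch; E_hat is continuous at l = 0 with E_hat(0) = 1. Accepts
    scalars or arrays in ``l``.
    """
    l_arr = np.asarray(l, dtype=float)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if np.any(l_arr <= -1) or np.any(l_arr >= epsilon):
        raise ValueError("l outside the domain (-1, epsilon)")
    denom = 2.0 * np.sqrt(epsilon**2 + 1.0)
    neg = (-l_arr + 2.0 * np.sqrt((1.0 + l_arr) ** 2 + epsilon**2)) / denom
    pos = (l_arr + 2.0 * np.sqrt((epsilon - l_arr) ** 2 + 1.0)) / denom
    out = np.where(l_arr < 0, neg, pos)
    return float(out) if np.isscalar(l) or l_arr.ndim == 0 else out


def _d_energy(l: float, epsilon: float) -> float:
    """One-sided derivative dE_hat/dl on the branch containing l (l != 0)."""
    denom = 2.0 * np.sqrt(epsilon**2 + 1.0)
    if l < 0:
        return (-1.0 + 2.0 * (1.0 + l) / np.sqrt((1.0 + l) ** 2 + epsilon**2)) / denom
    return (1.0 - 2.0 * (epsilon - l) / np.sqrt((epsilon - l) ** 2 + 1.0)) / denom


def minima(epsilon: float) -> list[tuple[float, float]]:
    """Closed-form energy minima [(l*, E_hat*)] for a given aspect ratio.

    l_h branch: l* = epsilon - 1/sqrt(3), exists iff epsilon > 1/sqrt(3),
    with E* = (epsilon + sqrt(3)) / (2 sqrt(epsilon^2 + 1)).
    l_w branch: l* = -(1 - epsilon/sqrt(3)), exists iff epsilon < sqrt(3),
    with E* = (1 + sqrt(3) epsilon) / (2 sqrt(epsilon^2 + 1)).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    denom = 2.0 * np.sqrt(epsilon**2 + 1.0)
    out: list[tuple[float, float]] = []
    if epsilon < SQRT3:
        out.append((-(1.0 - epsilon / SQRT3), (1.0 + SQRT3 * epsilon) / denom))
    if epsilon > 1.0 / SQRT3:
        out.append((epsilon - 1.0 / SQRT3, (epsilon + SQRT3) / denom))
    return out


class Regime(Enum):
    LW_ONLY = "lw_only"
    BISTABLE = "bistable"
    LH_ONLY = "lh_only"


def regime(epsilon: float) -> tuple[Regime, bool]:
    """Stability regime and a degeneracy flag for the boundary values.

    Below 1/sqrt(3) only the l_w packing is stable, above sqrt(3) only
    l_h, in between both. Exactly at a boundary the vanishing branch is
    marginal; the value is classified BISTABLE with ``degenerate=True``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    lo, hi = 1.0 / SQRT3, SQRT3
    if epsilon == lo or epsilon == hi:
        return Regime.BISTABLE, True
    if epsilon < lo:
        return Regime.LW_ONLY, False
    if epsilon > hi:
        return Regime.LH_ONLY, False
    return Regime.BISTABLE, False


def relax(
    l0: float,
    epsilon: float,
    step: float = 1e-3,
    tol: float = 1e-10,
    max_iter: int = 10**6,
) -> float:
    """Explicit gradient descent on E_hat from l0 to its basin minimum.

    The fourfold vertex l = 0 is an unstable stationary point: started
    exactly there, the state stays. The descent may cross l = 0 when the
    starting branch has no minimum (the energy then decreases through the
    kink into the other branch).
    """
    if not -1.0 < l0 < epsilon:
        raise ValueError("l0 outside the domain (-1, epsilon)")
    if l0 == 0.0:
        return 0.0
    l = l0
    e_prev = dimensionless_energy(l, epsilon)
    for _ in range(max_iter):
        g = _d_energy(l if l != 0.0 else np.sign(l0) * 1e-12, epsilon)
        l_new = l - step * g
        l_new = float(np.clip(l_new, -1.0 + 1e-12, epsilon - 1e-12))
        e_new = dimensionless_energy(l_new, epsilon)
        if abs(e_new - e_prev) < tol:
            return l_new
        l, e_prev = l_new, e_new
    raise RuntimeError(
        f"relax did not converge after {max_iter} iterations (l={l}, eps={epsilon})"
    )


def experimental_energy(L_T_hat: float, mean_epsilon: float) -> float:
    """Dimensionless motif energy from measurements.

    ``L_T_hat`` is the summed motif edge length in units of <w>;
    E_exp = L_T_hat / (2 sqrt(1 + <epsilon>^2)).
    """
    if L_T_hat <= 0 or mean_epsilon <= 0:
        raise ValueError("inputs must be positive")
    return L_T_hat / (2.0 * np.sqrt(1.0 + mean_epsilon**2))


@dataclass(frozen=True)
class EnergyDecomposition:
    """Director-cosine split of a measured motif energy.

    E_w = E_exp sin(theta), E_h = E_exp cos(theta); the Pythagorean
    identity E_w^2 + E_h^2 = E_exp^2 holds by construction.
    """

    E_exp: float
    theta_deg: float
    E_w: float
    E_h: float


def decompose(E_exp: float, theta_deg: float) -> EnergyDecomposition:
    if not 0.0 <= theta_deg <= 90.0:
        raise ValueError("theta must lie in [0, 90] degrees")
    th = np.radians(theta_deg)
    return EnergyDecomposition(
        E_exp=E_exp,
        theta_deg=theta_deg,
        E_w=E_exp * float(np.sin(th)),
        E_h=E_exp * float(np.cos(th)),
    )


class EdgeConfig(Enum):
    LW = "lw"
    LH = "lh"
    DISCARDED = "discarded"


def classify_edge_config(theta_deg: float) -> EdgeConfig:
    """Edge-angle classification: > 50 deg -> l_w, < 40 deg -> l_h.

    Angles between 40 and 50 degrees are discarded to avoid artefacts.
    """
    if not 0.0 <= theta_deg <= 90.0:
        raise ValueError("theta must lie in [0, 90] degrees")
    if theta_deg > 50.0:
        return EdgeConfig.LW
    if theta_deg < 40.0:
        return EdgeConfig.LH
    return EdgeConfig.DISCARDED


def trajectory(
    basal: EnergyDecomposition, apical: EnergyDecomposition
) -> tuple[float, float]:
    """Basal-to-apical displacement in (E_h, E_w) energy space.

    Returns (length, direction in degrees, measured from the +E_h axis
    toward +E_w) of the vector apical - basal.
    """
    dh = apical.E_h - basal.E_h
    dw = apical.E_w - basal.E_w
    return float(np.hypot(dh, dw)), float(np.degrees(np.arctan2(dw, dh)))


def landscape_grid(
    epsilon_range: np.ndarray, l_range: np.ndarray
) -> np.ndarray:
    """E_hat on an (epsilon, l) grid for plotting; NaN outside the domain.

    Rows index epsilon, columns l. The ridge along l = 0 equals 1.
    """
    eps = np.asarray(epsilon_range, dtype=float)
    ls = np.asarray(l_range, dtype=float)
    out = np.full((len(eps), len(ls)), np.nan)
    for i, e in enumerate(eps):
        ok = (ls > -1.0) & (ls < e)
        if ok.any():
            out[i, ok] = dimensionless_energy(ls[ok], e)
    return out


def epsilon_l_density(
    points: np.ndarray,
    l_grid: np.ndarray | None = None,
    eps_grid: np.ndarray | None = None,
    bandwidth: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian-kernel density of measured (l, epsilon) pairs on a grid.

    ``points`` is (n, 2) with columns (l, epsilon); l is signed by the
    edge-configuration class and normalised by <w>. Returns (density,
    l_grid, eps_grid) with the grid mass summing to 1.
    """
    from scipy.stats import gaussian_kde

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) == 0:
        raise ValueError("empty sample")
    if l_grid is None:
        l_grid = np.linspace(pts[:, 0].min() - 0.5, pts[:, 0].max() + 0.5, 101)
    if eps_grid is None:
        eps_grid = np.linspace(
            max(pts[:, 1].min() - 0.5, 1e-3), pts[:, 1].max() + 0.5, 101
        )
    if len(pts) == 1:
        # gaussian_kde needs >= 2 distinct points; place a single bump
        bw = bandwidth or 0.1
        L, E = np.meshgrid(l_grid, eps_grid, indexing="ij")
        dens = np.exp(
            -((L - pts[0, 0]) ** 2 + (E - pts[0, 1]) ** 2) / (2 * bw**2)
        )
    else:
        kde = gaussian_kde(pts.T, bw_method=bandwidth)
        L, E = np.meshgrid(l_grid, eps_grid, indexing="ij")
        dens = kde(np.vstack([L.ravel(), E.ravel()])).reshape(L.shape)
    dens = dens / dens.sum()
    return dens, np.asarray(l_grid), np.asarray(eps_grid)
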